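"""Reader and writer for the *.2bit packed genome sequence format.

A 2bit archive stores each sequence as 2-bit base codes (T=0, C=1, A=2,
G=3; four bases per byte, first base in the two highest-order bits) plus
two side lists: N blocks (runs decoded as ``N`` — the packed codes under
them are meaningless) and mask blocks (runs reported in lowercase when
soft-masking is requested).  The header magic is 0x1A412743; the reader
detects little- or big-endian layout from it, the writer always emits
little-endian.  Only format version 0 (32-bit offsets) is supported.

Sequence records are parsed lazily on first access and cached.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import TwoBitEncodingError, TwoBitFormatError, TwoBitTruncationError
from .intervals import GenomicInterval

__all__ = [
    "SIGNATURE",
    "TwoBitArchive",
    "TwoBitSequenceRecord",
    "open_archive",
    "subseq",
    "write_archive",
]

SIGNATURE = 0x1A412743

# base code -> ASCII byte, order T C A G
_CODE_TO_BASE = np.frombuffer(b"TCAG", dtype=np.uint8)

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"TCAG"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lowercase
_BASE_TO_CODE[ord("N")] = 0  # N positions carry an arbitrary code (T); never exposed
_BASE_TO_CODE[ord("n")] = 0

_CASE_BIT = 32  # 'A' | 32 == 'a'


@dataclass
class TwoBitSequenceRecord:
    """One parsed sequence: size, N blocks, mask blocks, packed DNA."""

    dna_size: int
    n_blocks: list[tuple[int, int]]  # (start, size), 0-based bp
    mask_blocks: list[tuple[int, int]]
    packed_offset: int  # byte offset of packed DNA within the archive


class _Cursor:
    """Sequential reader over the archive bytes with truncation diagnostics."""

    def __init__(self, data: bytes, byte_order: str):
        self.data = data
        self.bo = byte_order
        self.pos = 0

    def seek(self, pos: int) -> None:
        self.pos = pos

    def bytes(self, n: int, what: str) -> bytes:
        if self.pos + n > len(self.data):
            raise TwoBitTruncationError(
                f"archive truncated while reading {what} "
                f"(need {n} bytes at offset {self.pos}, file has {len(self.data)})"
            )
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u32(self, what: str) -> int:
        return struct.unpack(self.bo + "I", self.bytes(4, what))[0]

    def u8(self, what: str) -> int:
        return self.bytes(1, what)[0]

    def u32_array(self, n: int, what: str) -> np.ndarray:
        raw = self.bytes(4 * n, what)
        return np.frombuffer(raw, dtype=np.dtype(self.bo + "u4"))


class TwoBitArchive:
    """A parsed 2bit archive: header, name index, and lazily parsed records."""

    def __init__(self, data: bytes, path: str | None = None):
        self._data = data
        self.path = path
        if len(data) < 16:
            raise TwoBitTruncationError(
                f"file too short for a 2bit header ({len(data)} bytes, need 16)"
            )
        sig_le = struct.unpack("<I", data[:4])[0]
        sig_be = struct.unpack(">I", data[:4])[0]
        if sig_le == SIGNATURE:
            self.byte_order = "<"
        elif sig_be == SIGNATURE:
            self.byte_order = ">"
        else:
            raise TwoBitFormatError(
                f"bad 2bit signature 0x{sig_le:08X} (expected 0x{SIGNATURE:08X} "
                "in either byte order)"
            )
        cur = _Cursor(data, self.byte_order)
        cur.seek(4)
        version = cur.u32("header version")
        if version != 0:
            raise TwoBitFormatError(f"unsupported 2bit version {version} (only 0)")
        count = cur.u32("header sequence count")
        cur.u32("header reserved field")
        self.index: list[tuple[str, int]] = []
        for i in range(count):
            name_size = cur.u8(f"index entry {i} name size")
            name = cur.bytes(name_size, f"index entry {i} name").decode("latin-1")
            offset = cur.u32(f"index entry {i} offset")
            if offset >= len(data):
                raise TwoBitFormatError(
                    f"index offset {offset} for {name!r} points past end of file"
                )
            self.index.append((name, offset))
        names = [n for n, _ in self.index]
        if len(set(names)) != len(names):
            raise TwoBitFormatError("duplicate sequence names in index")
        self._offsets: dict[str, int] = dict(self.index)
        self._records: dict[str, TwoBitSequenceRecord] = {}

    # -- access -----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        """Sequence names in file order."""
        return [n for n, _ in self.index]

    def __contains__(self, name: str) -> bool:
        return name in self._offsets

    def sequence(self, name: str) -> TwoBitSequenceRecord:
        """Parse (once) and return the record for ``name``."""
        if name in self._records:
            return self._records[name]
        if name not in self._offsets:
            raise KeyError(
                f"no sequence {name!r} in archive (has: {', '.join(self.names)})"
            )
        cur = _Cursor(self._data, self.byte_order)
        cur.seek(self._offsets[name])
        dna_size = cur.u32(f"{name} dnaSize")
        n_count = cur.u32(f"{name} nBlockCount")
        n_starts = cur.u32_array(n_count, f"{name} nBlockStarts")
        n_sizes = cur.u32_array(n_count, f"{name} nBlockSizes")
        m_count = cur.u32(f"{name} maskBlockCount")
        m_starts = cur.u32_array(m_count, f"{name} maskBlockStarts")
        m_sizes = cur.u32_array(m_count, f"{name} maskBlockSizes")
        cur.u32(f"{name} reserved field")
        packed_offset = cur.pos
        cur.bytes((dna_size + 3) // 4, f"{name} packed DNA")  # verify extent
        rec = TwoBitSequenceRecord(
            dna_size=dna_size,
            n_blocks=[(int(s), int(z)) for s, z in zip(n_starts, n_sizes)],
            mask_blocks=[(int(s), int(z)) for s, z in zip(m_starts, m_sizes)],
            packed_offset=packed_offset,
        )
        for blocks, label in ((rec.n_blocks, "N"), (rec.mask_blocks, "mask")):
            for s, z in blocks:
                if s + z > dna_size:
                    raise TwoBitFormatError(
                        f"{label} block ({s}, {z}) of {name!r} exceeds dnaSize {dna_size}"
                    )
        self._records[name] = rec
        return rec

    def dna_size(self, name: str) -> int:
        return self.sequence(name).dna_size

    def subseq(self, name: str, start: int, end: int, masked: bool = True) -> str:
        """Extract bases over the 0-based half-open span [start, end).

        Positions in N blocks yield ``N`` (``n`` when also mask-covered
        and ``masked`` is true); mask-block positions are lowercase when
        ``masked`` is true, uppercase otherwise.
        """
        rec = self.sequence(name)
        if not (0 <= start < end <= rec.dna_size):
            raise ValueError(
                f"span [{start}, {end}) outside [0, {rec.dna_size}] for {name!r}"
            )
        first_byte = start // 4
        last_byte = (end + 3) // 4
        packed = np.frombuffer(
            self._data,
            dtype=np.uint8,
            count=last_byte - first_byte,
            offset=rec.packed_offset + first_byte,
        )
        # unpack 4 codes per byte, high bits first
        codes = np.empty((packed.size, 4), dtype=np.uint8)
        codes[:, 0] = (packed >> 6) & 3
        codes[:, 1] = (packed >> 4) & 3
        codes[:, 2] = (packed >> 2) & 3
        codes[:, 3] = packed & 3
        chars = _CODE_TO_BASE[codes.reshape(-1)]
        chars = chars[start - first_byte * 4 : end - first_byte * 4].copy()

        for bs, bz in rec.n_blocks:
            lo, hi = max(bs, start), min(bs + bz, end)
            if lo < hi:
                chars[lo - start : hi - start] = ord("N")
        if masked:
            for bs, bz in rec.mask_blocks:
                lo, hi = max(bs, start), min(bs + bz, end)
                if lo < hi:
                    chars[lo - start : hi - start] |= _CASE_BIT
        return chars.tobytes().decode("ascii")


def open_archive(path: str | PathLike[str]) -> TwoBitArchive:
    """Open a *.2bit file; header and index parsed now, records lazily."""
    with open(path, "rb") as fh:
        data = fh.read()
    return TwoBitArchive(data, path=str(path))


def subseq(
    archive: TwoBitArchive,
    name: str,
    span: GenomicInterval | tuple[int, int],
    masked: bool = True,
) -> str:
    """Functional form of :meth:`TwoBitArchive.subseq`.

    ``span`` is 0-based half-open: a ``(start, end)`` pair or a
    :class:`GenomicInterval` (its chromosome name is not consulted).
    """
    if isinstance(span, GenomicInterval):
        start, end = span.start, span.end
    else:
        start, end = span
    return archive.subseq(name, start, end, masked=masked)


def _find_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, size) runs of True in a boolean array."""
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def write_archive(
    sequences: Sequence[tuple[str, str]] | Mapping[str, str],
    path: str | PathLike[str],
) -> None:
    """Write sequences to a little-endian, version-0 2bit archive.

    Lowercase runs become mask blocks; ``N``/``n`` runs become N blocks
    (their packed codes are written as T and never exposed on read).
    Characters must be in {A, C, G, T, N} in either case; names must be
    unique and at most 255 bytes.  Reading the file back and extracting
    each full sequence with ``masked=True`` reproduces the input exactly.
    """
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = list(sequences)
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("sequence names must be unique")
    for name, seq in items:
        if not name or len(name.encode("latin-1")) > 255:
            raise ValueError(f"sequence name {name!r} must be 1-255 bytes")
        if not seq:
            raise ValueError(f"sequence {name!r} is empty")

    records: list[bytes] = []
    for name, seq in items:
        try:
            encoded = seq.encode("ascii")
        except UnicodeEncodeError as exc:
            raise TwoBitEncodingError(
                f"illegal character {seq[exc.start]!r} at position {exc.start} in {name!r}"
            ) from exc
        raw = np.frombuffer(encoded, dtype=np.uint8)
        codes = _BASE_TO_CODE[raw]
        bad = np.flatnonzero(codes == 255)
        if bad.size:
            pos = int(bad[0])
            raise TwoBitEncodingError(
                f"illegal character {seq[pos]!r} at position {pos} in {name!r}"
            )
        upper = raw & ~np.uint8(_CASE_BIT)  # letters only, so this uppercases
        n_blocks = _find_runs(upper == ord("N"))
        mask_blocks = _find_runs((raw & _CASE_BIT) != 0)

        n = raw.size
        padded = np.zeros(((n + 3) // 4) * 4, dtype=np.uint8)
        padded[:n] = codes
        quads = padded.reshape(-1, 4)
        packed = (
            (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
        ).astype(np.uint8)

        buf = bytearray()
        buf += struct.pack("<II", n, len(n_blocks))
        buf += np.array([s for s, _ in n_blocks], dtype="<u4").tobytes()
        buf += np.array([z for _, z in n_blocks], dtype="<u4").tobytes()
        buf += struct.pack("<I", len(mask_blocks))
        buf += np.array([s for s, _ in mask_blocks], dtype="<u4").tobytes()
        buf += np.array([z for _, z in mask_blocks], dtype="<u4").tobytes()
        buf += struct.pack("<I", 0)  # reserved
        buf += packed.tobytes()
        records.append(bytes(buf))

    header = struct.pack("<IIII", SIGNATURE, 0, len(items), 0)
    index_size = sum(1 + len(n.encode("latin-1")) + 4 for n in names)
    offset = len(header) + index_size
    index = bytearray()
    for (name, _), rec in zip(items, records):
        nb = name.encode("latin-1")
        index += struct.pack("<B", len(nb)) + nb + struct.pack("<I", offset)
        offset += len(rec)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bytes(index))
        for rec in records:
            fh.write(rec)
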