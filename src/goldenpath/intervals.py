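"""Genomic intervals and coordinate-convention conversion.

The canonical in-memory convention is the UCSC *storage* convention:
0-based, half-open (``start`` inclusive, ``end`` exclusive), the same
convention ``chromStart``/``chromEnd`` columns use.  The browser's
1-based fully-closed convention ("chr1:123,456-456,789") appears only at
the parse/format boundary: :func:`parse_interval` converts browser
strings in, :func:`format_interval` converts back out.  Thousands
separators are accepted on input and never emitted.

Strand is deliberately not part of :class:`GenomicInterval`; interval
queries are strand-agnostic and strand ordering lives with gene models
(see :mod:`goldenpath.genepred`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from .errors import IntervalParseError

__all__ = [
    "GenomicInterval",
    "parse_interval",
    "format_interval",
    "overlaps",
    "contains",
    "read_bed3",
    "write_bed3",
]

_INTERVAL_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A span on one chromosome, 0-based half-open, in base pairs.

    Invariants enforced at construction: ``0 <= start < end`` (empty and
    inverted spans are rejected) and ``chrom`` is a non-empty name with
    no whitespace or colon.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if ":" in self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"chrom {self.chrom!r} contains whitespace or ':'")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise TypeError("start and end must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    def length(self) -> int:
        """Span length in base pairs (always positive)."""
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - thin alias
        return self.length()

    def __str__(self) -> str:
        return format_interval(self)


def parse_interval(text: str, chrom_length: int | None = None) -> GenomicInterval:
    """Parse a browser-style interval string into the internal convention.

    ``text`` is ``<chrom>:<start>-<end>`` with 1-based fully-closed
    coordinates, optionally containing thousands-separator commas, e.g.
    ``"chr1:123,456-456,789"``.  The result is 0-based half-open:
    internal start = parsed start - 1, internal end = parsed end.

    A bare chromosome name (no colon) means the whole chromosome and is
    accepted only when ``chrom_length`` supplies the length context.

    Raises
    ------
    IntervalParseError
        On malformed text; the message names the offending component.
    """
    if not isinstance(text, str) or not text.strip():
        raise IntervalParseError("empty interval string")
    text = text.strip()

    if ":" not in text:
        if chrom_length is None:
            raise IntervalParseError(
                f"bare chromosome name {text!r} needs a chromosome-length context"
            )
        if chrom_length < 1:
            raise IntervalParseError(f"chromosome length must be >= 1, got {chrom_length}")
        try:
            return GenomicInterval(text, 0, chrom_length)
        except ValueError as exc:
            raise IntervalParseError(str(exc)) from exc

    m = _INTERVAL_RE.match(text)
    if m is None:
        # Diagnose which component is wrong for a pointed message.
        chrom, _, rest = text.partition(":")
        if not chrom:
            raise IntervalParseError(f"missing chromosome name in {text!r}")
        if "-" not in rest:
            raise IntervalParseError(f"missing '-' between start and end in {text!r}")
        start_s, _, end_s = rest.partition("-")
        for label, comp in (("start", start_s), ("end", end_s)):
            if not re.fullmatch(r"[\d,]+", comp):
                raise IntervalParseError(f"non-numeric {label} {comp!r} in {text!r}")
        raise IntervalParseError(f"malformed interval string {text!r}")

    chrom = m.group("chrom")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1:
        raise IntervalParseError(f"start must be >= 1 (1-based), got {start1}")
    if start1 > end1:
        raise IntervalParseError(f"start {start1} is greater than end {end1}")
    return GenomicInterval(chrom, start1 - 1, end1)


def format_interval(iv: GenomicInterval) -> str:
    """Render an interval in the browser's 1-based closed convention.

    No thousands separators are emitted;
    ``parse_interval(format_interval(iv)) == iv`` for every valid interval.
    """
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Symmetric; abutting intervals (``a.end == b.start``) do not overlap,
    and intervals on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies completely within ``outer`` (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def read_bed3(handle: TextIO | Iterable[str]) -> Iterator[GenomicInterval]:
    """Yield intervals from BED3 text (chrom, chromStart, chromEnd; 0-based half-open).

    Blank lines and ``track``/``browser``/``#`` lines are skipped; extra
    columns beyond the first three are ignored.
    """
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise IntervalParseError(f"BED line {lineno}: fewer than 3 columns")
        try:
            yield GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise IntervalParseError(f"BED line {lineno}: {exc}") from exc


def write_bed3(intervals: Iterable[GenomicInterval], handle: TextIO) -> None:
    """Write intervals as BED3 (tab-separated, 0-based half-open)."""
    for iv in intervals:
        handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
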