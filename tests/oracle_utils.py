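"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written from first principles —
explicit bin-extent enumeration, nested-loop scans and joins — and never
calls the code paths it is used to check.
"""

from __future__ import annotations

import numpy as np

# -- bin scheme oracle -------------------------------------------------------
# Enumerate the extent of every bin at every level explicitly:
# level k (0 = coarsest) has 8^k bins of span 2^(29 - 3k) starting at
# offset 0, 1, 9, 73, 585.

_LEVEL_OFFSETS = (0, 1, 9, 73, 585)


def enumerate_bin_extents() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrays (start, end, span) indexed by bin number, 0..4680."""
    starts, ends, spans = [], [], []
    for k, offset in enumerate(_LEVEL_OFFSETS):
        span = 2 ** (29 - 3 * k)
        count = 8**k
        assert offset == len(starts)  # bins are numbered level by level
        for i in range(count):
            starts.append(i * span)
            ends.append((i + 1) * span)
            spans.append(span)
    return np.array(starts), np.array(ends), np.array(spans)


_BSTART, _BEND, _BSPAN = enumerate_bin_extents()


def oracle_smallest_bin(start: int, end: int) -> int:
    """Smallest-span bin fully containing [start, end), by full enumeration."""
    containing = np.flatnonzero((_BSTART <= start) & (end <= _BEND))
    return int(containing[np.argmin(_BSPAN[containing])])


def oracle_overlapping_bins(start: int, end: int) -> list[int]:
    """All bins whose extent intersects [start, end), by full enumeration."""
    return np.flatnonzero((_BSTART < end) & (start < _BEND)).tolist()


# -- interval scan oracles ---------------------------------------------------


def brute_overlap_scan(rows: list[dict], chrom: str, start: int, end: int) -> list[dict]:
    """Half-open overlap scan over snp-style row dicts."""
    return [
        r
        for r in rows
        if r["chrom"] == chrom and r["chromStart"] < end and r["chromEnd"] > start
    ]


def brute_containment_scan(
    rows: list[dict], chrom: str, start: int, end: int
) -> list[dict]:
    """Containment scan over snp-style row dicts."""
    return [
        r
        for r in rows
        if r["chrom"] == chrom and r["chromStart"] >= start and r["chromEnd"] <= end
    ]


def row_key(row: dict) -> tuple:
    return (row["chrom"], row["chromStart"], row["chromEnd"], row["name"], row["strand"])


# -- equijoin oracle ---------------------------------------------------------


def brute_equijoin(
    left: list[dict], left_key: str, right: list[dict], right_key: str
) -> dict:
    """Nested-loop equijoin: left key value -> list of matching right rows."""
    out: dict = {}
    for lrow in left:
        out.setdefault(lrow[left_key], [])
    for lrow in left:
        for rrow in right:
            if rrow[right_key] == lrow[left_key]:
                out[lrow[left_key]].append(rrow)
    # deduplicate accumulation from repeated left keys
    for k, v in out.items():
        seen, dedup = set(), []
        for r in v:
            t = tuple(sorted(r.items()))
            if t not in seen:
                seen.add(t)
                dedup.append(r)
        out[k] = dedup
    return out
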