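"""The UCSC hierarchical bin index.

Positions on a chromosome are partitioned into five levels of bins sized
512 Mb, 64 Mb, 8 Mb, 1 Mb and 128 kb (exact powers of two: 2^29 down to
2^17, each level 8x coarser than the next).  A stored feature is
assigned the smallest bin that encompasses its whole span
(:func:`bin_from_interval`); an interval query touches only the bins
that can hold an overlapping feature (:func:`bins_overlapping`), which
is what lets a ``bin IN (...)`` clause narrow a SQL range scan without
changing its result set.

Only the standard five-level scheme is implemented: coordinates at or
beyond 2^29 raise :class:`~goldenpath.errors.BinRangeError` rather than
silently switching to the extended scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import BinRangeError

__all__ = ["BinScheme", "STANDARD_SCHEME", "bin_from_interval", "bins_overlapping"]


@dataclass(frozen=True)
class BinScheme:
    """Constants of the five-level standard bin scheme.

    ``level_spans`` and ``level_offsets`` run coarsest to finest;
    ``offset[k] = offset[k-1] + 8**(k-1)``, giving bin numbers 0..4680.
    """

    first_shift: int = 17
    next_shift: int = 3
    level_count: int = 5
    max_position: int = 1 << 29

    @property
    def level_spans(self) -> tuple[int, ...]:
        """Bin span per level in bp, coarsest first: 2^29 .. 2^17."""
        finest = self.first_shift
        coarsest = finest + self.next_shift * (self.level_count - 1)
        return tuple(1 << s for s in range(coarsest, finest - 1, -self.next_shift))

    @property
    def level_offsets(self) -> tuple[int, ...]:
        """First bin number per level, coarsest first: 0, 1, 9, 73, 585."""
        offsets = [0]
        for k in range(1, self.level_count):
            offsets.append(offsets[-1] + 8 ** (k - 1))
        return tuple(offsets)

    @property
    def bin_count(self) -> int:
        """Total number of bins across all levels (4681)."""
        return self.level_offsets[-1] + 8 ** (self.level_count - 1)


STANDARD_SCHEME = BinScheme()


def _check_range(start: int, end: int, scheme: BinScheme) -> None:
    if start < 0:
        raise BinRangeError(f"start must be >= 0, got {start}")
    if start >= end:
        raise BinRangeError(f"invalid interval: start={start}, end={end}")
    if end > scheme.max_position:
        raise BinRangeError(
            f"end {end} exceeds the standard bin scheme maximum {scheme.max_position} "
            "(2^29); extended binning is not supported"
        )


def bin_from_interval(start: int, end: int, scheme: BinScheme = STANDARD_SCHEME) -> int:
    """Smallest bin whose extent fully contains [start, end), 0-based half-open.

    Walks levels finest to coarsest comparing ``start >> shift`` with
    ``(end - 1) >> shift``; the first level where both coordinates fall
    in the same bin wins.
    """
    _check_range(start, end, scheme)
    s = start >> scheme.first_shift
    e = (end - 1) >> scheme.first_shift
    for offset in reversed(scheme.level_offsets):
        if s == e:
            return offset + s
        s >>= scheme.next_shift
        e >>= scheme.next_shift
    raise AssertionError("unreachable: coarsest level always agrees in range")


def bins_overlapping(
    start: int, end: int, scheme: BinScheme = STANDARD_SCHEME
) -> list[int]:
    """All bins, at every level, whose extent intersects [start, end).

    Sorted ascending and duplicate-free.  Completeness guarantee: any
    feature assigned via :func:`bin_from_interval` that overlaps
    [start, end) has its bin in this list, so filtering stored rows to
    these bins never loses an overlapping feature.
    """
    _check_range(start, end, scheme)
    bins: list[int] = []
    shift = scheme.first_shift
    s = start >> shift
    e = (end - 1) >> shift
    for offset in reversed(scheme.level_offsets):
        bins.extend(range(offset + s, offset + e + 1))
        s >>= scheme.next_shift
        e >>= scheme.next_shift
    return sorted(bins)
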