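"""genePred gene models: exon, CDS and intron interval derivation.

A genePred row describes one transcript with a 0-based half-open
transcript span (txStart/txEnd), a coding span (cdsStart/cdsEnd;
``cdsStart == cdsEnd`` marks a non-coding transcript), and parallel
comma-separated exon start/end lists.  The accessors here derive exon,
CDS and intron intervals from such a row, ordered 5'→3' along the gene:
ascending genomic order on the ``+`` strand, descending on ``-``.  Each
returned interval itself keeps ``start < end``; only the list order
reflects strand.

Records violating the structural invariants (unsorted or overlapping
exons, exons outside the transcript span, CDS outside the transcript)
are rejected with :class:`~goldenpath.errors.ValidationError` naming the
offending field rather than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Mapping

from .errors import ValidationError
from .intervals import GenomicInterval

__all__ = ["GenePredRecord", "exons", "cdss", "introns", "parse_comma_list"]

# core columns in dump order
GENEPRED_COLUMNS = (
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


def parse_comma_list(blob: str | bytes | Iterable[int]) -> tuple[int, ...]:
    """Parse a UCSC comma-separated integer blob, tolerating one trailing comma.

    Already-numeric iterables pass through unchanged, so records can be
    built from parsed values as well as raw dump text.
    """
    if isinstance(blob, bytes):
        blob = blob.decode("ascii")
    if isinstance(blob, str):
        text = blob.rstrip()
        if text.endswith(","):
            text = text[:-1]
        if not text:
            return ()
        return tuple(int(tok) for tok in text.split(","))
    return tuple(int(x) for x in blob)


@dataclass(frozen=True)
class GenePredRecord:
    """One gene model row; all coordinates 0-based half-open."""

    name: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    cdsStart: int
    cdsEnd: int
    exonCount: int
    exonStarts: tuple[int, ...]
    exonEnds: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exonStarts", parse_comma_list(self.exonStarts))
        object.__setattr__(self, "exonEnds", parse_comma_list(self.exonEnds))
        self.validate()

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError naming the field."""
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand: expected '+' or '-', got {self.strand!r}")
        if self.exonCount < 1:
            raise ValidationError(f"exonCount: must be >= 1, got {self.exonCount}")
        if len(self.exonStarts) != self.exonCount:
            raise ValidationError(
                f"exonStarts: {len(self.exonStarts)} entries, exonCount={self.exonCount}"
            )
        if len(self.exonEnds) != self.exonCount:
            raise ValidationError(
                f"exonEnds: {len(self.exonEnds)} entries, exonCount={self.exonCount}"
            )
        prev_end = None
        for i, (s, e) in enumerate(zip(self.exonStarts, self.exonEnds)):
            if s >= e:
                raise ValidationError(f"exonEnds: exon {i} is empty or inverted ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"exonStarts: exon {i} overlaps or precedes exon {i - 1}"
                )
            prev_end = e
        if self.exonStarts[0] < self.txStart or self.exonEnds[-1] > self.txEnd:
            raise ValidationError(
                f"txStart/txEnd: exons [{self.exonStarts[0]}, {self.exonEnds[-1]}) "
                f"outside transcript span [{self.txStart}, {self.txEnd})"
            )
        if not (self.txStart <= self.cdsStart <= self.cdsEnd <= self.txEnd):
            raise ValidationError(
                f"cdsStart/cdsEnd: [{self.cdsStart}, {self.cdsEnd}] violates "
                f"txStart <= cdsStart <= cdsEnd <= txEnd "
                f"([{self.txStart}, {self.txEnd}])"
            )

    @property
    def is_coding(self) -> bool:
        return self.cdsStart < self.cdsEnd

    @classmethod
    def from_row(cls, row: Mapping[str, Any]) -> "GenePredRecord":
        """Build from any mapping exposing the genePred column names.

        Works with database records reflected by :mod:`goldenpath.ormcore`
        as well as plain dicts; extra keys (``bin``, scores, frames) are
        ignored.
        """
        return cls(**{col: row[col] for col in GENEPRED_COLUMNS})

    @classmethod
    def from_line(cls, line: str) -> "GenePredRecord":
        """Parse one tab-separated genePred line (10-column core).

        Extra trailing columns (score, name2, frames, ...) are ignored.
        """
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(GENEPRED_COLUMNS):
            raise ValidationError(
                f"genePred line has {len(parts)} columns, need {len(GENEPRED_COLUMNS)}"
            )
        (name, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_exon, ex_s, ex_e) = parts[:10]
        return cls(
            name=name,
            chrom=chrom,
            strand=strand,
            txStart=int(tx_s),
            txEnd=int(tx_e),
            cdsStart=int(cds_s),
            cdsEnd=int(cds_e),
            exonCount=int(n_exon),
            exonStarts=parse_comma_list(ex_s),
            exonEnds=parse_comma_list(ex_e),
        )

    def to_line(self) -> str:
        """Serialize to a tab-separated genePred line (trailing commas kept)."""
        return "\t".join(
            [
                self.name,
                self.chrom,
                self.strand,
                str(self.txStart),
                str(self.txEnd),
                str(self.cdsStart),
                str(self.cdsEnd),
                str(self.exonCount),
                "".join(f"{s}," for s in self.exonStarts),
                "".join(f"{e}," for e in self.exonEnds),
            ]
        )

    # convenience method forms of the module-level accessors
    def exons(self) -> list[GenomicInterval]:
        return exons(self)

    def cdss(self) -> list[GenomicInterval]:
        return cdss(self)

    def introns(self) -> list[GenomicInterval]:
        return introns(self)


def _coerce(g: GenePredRecord | Mapping[str, Any]) -> GenePredRecord:
    if isinstance(g, GenePredRecord):
        return g
    return GenePredRecord.from_row(g)


def _strand_order(ivs: list[GenomicInterval], strand: str) -> list[GenomicInterval]:
    return list(reversed(ivs)) if strand == "-" else ivs


def exons(g: GenePredRecord | Mapping[str, Any]) -> list[GenomicInterval]:
    """Exon intervals in gene order (genomic-descending for ``-`` strand)."""
    g = _coerce(g)
    ivs = [
        GenomicInterval(g.chrom, s, e) for s, e in zip(g.exonStarts, g.exonEnds)
    ]
    return _strand_order(ivs, g.strand)


def cdss(g: GenePredRecord | Mapping[str, Any]) -> list[GenomicInterval]:
    """Coding segments: per-exon intersection with [cdsStart, cdsEnd).

    Empty intersections are dropped; the list is empty for non-coding
    transcripts (``cdsStart == cdsEnd``).  Gene-strand ordered like
    :func:`exons`.
    """
    g = _coerce(g)
    if not g.is_coding:
        return []
    ivs = []
    for s, e in zip(g.exonStarts, g.exonEnds):
        lo, hi = max(s, g.cdsStart), min(e, g.cdsEnd)
        if lo < hi:
            ivs.append(GenomicInterval(g.chrom, lo, hi))
    return _strand_order(ivs, g.strand)


def introns(g: GenePredRecord | Mapping[str, Any]) -> list[GenomicInterval]:
    """Gaps between consecutive exons, gene-strand ordered.

    Empty for single-exon transcripts; zero-length gaps (abutting exons)
    are omitted.
    """
    g = _coerce(g)
    ivs = []
    for prev_end, next_start in zip(g.exonEnds, g.exonStarts[1:]):
        if prev_end < next_start:
            ivs.append(GenomicInterval(g.chrom, prev_end, next_start))
    return _strand_order(ivs, g.strand)
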