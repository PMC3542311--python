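"""Deterministic synthetic fixtures: databases, gene models, genomes, joiner text.

Every generator here is driven by a :class:`FixtureSpec` whose seed
fully determines the output, so tests and worked examples run offline
with reproducible content.  The generated artifacts follow the UCSC
schema families they emulate — a snp-style positional table with a
``bin`` column, a genePred gene-model table, a 2bit genome archive with
N runs and soft-masked runs, and an xref table linked through joiner
stanza text — and satisfy, by construction, every structural invariant
the corresponding modules enforce.

The fixtures emulate table *schemas* and coordinate statistics, not real
annotation content.
"""

from __future__ import annotations

import random
import sqlite3
from dataclasses import dataclass, field
from os import PathLike, fspath
from pathlib import Path
from typing import Mapping

import numpy as np

from .binindex import bin_from_interval
from .errors import BinRangeError
from .genepred import GenePredRecord
from .twobit import write_archive

__all__ = [
    "FixtureSpec",
    "AssociationFixture",
    "make_snp_table",
    "make_genepred_table",
    "make_genome_2bit",
    "make_association_fixture",
    "dump_sql",
]

_DEFAULT_CHROM_SIZES = {
    "chr1": 4_000_000,
    "chr2": 2_000_000,
    "chrX": 1_000_000,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``chrom_sizes`` maps chromosome names to lengths in bp (each at most
    2^29, the standard bin scheme's reach).  ``feature_count`` sizes
    each generated table; ``key_overlap`` is the fraction of snp-style
    keys that gain at least one xref partner in association fixtures.
    The same seed and spec always regenerate identical content.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_SIZES)
    )
    feature_count: int = 500
    key_overlap: float = 0.5

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
            if size > 1 << 29:
                raise BinRangeError(
                    f"chromosome {chrom!r} length {size} exceeds 2^29, beyond the "
                    "standard bin scheme"
                )
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must not be empty")
        if not 0.0 <= self.key_overlap <= 1.0:
            raise ValueError(f"key_overlap must be in [0, 1], got {self.key_overlap}")
        if self.feature_count < 0:
            raise ValueError("feature_count must be non-negative")


def _connect_rw(database: str | PathLike[str]) -> sqlite3.Connection:
    return sqlite3.connect(fspath(database))


def make_snp_table(
    database: str | PathLike[str],
    spec: FixtureSpec,
    table_name: str = "snpToy",
    with_bin: bool = True,
) -> list[dict]:
    """Create and populate a snp-style positional table.

    Columns are (bin, chrom, chromStart, chromEnd, name, strand) — the
    dbSNP family layout — or the same without ``bin`` when ``with_bin``
    is false.  Features are uniform over chromosomes with lengths
    1-10000 bp; the bin column is computed with
    :func:`~goldenpath.binindex.bin_from_interval`; names are ``rs<k>``.
    Returns the inserted rows as dicts, usable as a brute-force oracle.
    """
    rng = random.Random(spec.seed)
    chroms = sorted(spec.chrom_sizes)
    rows: list[dict] = []
    for k in range(spec.feature_count):
        chrom = chroms[rng.randrange(len(chroms))]
        size = spec.chrom_sizes[chrom]
        length = min(rng.randint(1, 10_000), size)
        start = rng.randrange(0, size - length + 1)
        end = start + length
        row = {
            "chrom": chrom,
            "chromStart": start,
            "chromEnd": end,
            "name": f"rs{k}",
            "strand": rng.choice("+-"),
        }
        if with_bin:
            row["bin"] = bin_from_interval(start, end)
        rows.append(row)

    cols = (["bin INTEGER"] if with_bin else []) + [
        "chrom TEXT",
        "chromStart INTEGER",
        "chromEnd INTEGER",
        "name TEXT",
        "strand TEXT",
    ]
    names = [c.split()[0] for c in cols]
    conn = _connect_rw(database)
    try:
        conn.execute(f'DROP TABLE IF EXISTS "{table_name}"')
        conn.execute(f'CREATE TABLE "{table_name}" ({", ".join(cols)})')
        conn.executemany(
            f'INSERT INTO "{table_name}" VALUES ({",".join("?" * len(names))})',
            [tuple(r[n] for n in names) for r in rows],
        )
        conn.commit()
    finally:
        conn.close()
    return rows


def make_genepred_table(
    database: str | PathLike[str],
    spec: FixtureSpec,
    table_name: str = "refGeneToy",
) -> list[GenePredRecord]:
    """Create and populate a genePred gene-model table.

    Gene models have 1-20 exons (sorted, disjoint), CDS within the
    transcript span, and a 10% non-coding fraction; strand is a fair
    coin.  Exon lists are stored as comma blobs with the UCSC trailing
    comma.  All :class:`GenePredRecord` invariants hold by construction
    (each record is validated before insertion).  Returns the records.
    """
    rng = random.Random(spec.seed)
    chroms = sorted(spec.chrom_sizes)
    records: list[GenePredRecord] = []
    for k in range(spec.feature_count):
        chrom = chroms[rng.randrange(len(chroms))]
        size = spec.chrom_sizes[chrom]
        n_exons = rng.randint(1, 20)
        # scale exon/intron lengths so 20 exons fit on the smallest chromosome
        budget = max(size // (4 * n_exons), 4)
        starts, ends = [], []
        pos = rng.randrange(0, max(1, size // 2))
        for _ in range(n_exons):
            exon_len = rng.randint(1, max(1, min(2000, budget)))
            starts.append(pos)
            ends.append(pos + exon_len)
            pos = ends[-1] + rng.randint(1, max(1, min(5000, budget)))
        tx_start, tx_end = starts[0], ends[-1]
        if tx_end > size:  # rare overflow near the end: shift left
            shift = tx_end - size
            starts = [s - shift for s in starts]
            ends = [e - shift for e in ends]
            tx_start, tx_end = starts[0], ends[-1]
        if rng.random() < 0.10:
            cds_start = cds_end = tx_start  # non-coding
        else:
            cds_start = rng.randrange(tx_start, tx_end)
            cds_end = rng.randrange(cds_start + 1, tx_end + 1)
        rec = GenePredRecord(
            name=f"gm{k}",
            chrom=chrom,
            strand=rng.choice("+-"),
            txStart=tx_start,
            txEnd=tx_end,
            cdsStart=cds_start,
            cdsEnd=cds_end,
            exonCount=n_exons,
            exonStarts=tuple(starts),
            exonEnds=tuple(ends),
        )
        records.append(rec)

    conn = _connect_rw(database)
    try:
        conn.execute(f'DROP TABLE IF EXISTS "{table_name}"')
        conn.execute(
            f'CREATE TABLE "{table_name}" (name TEXT, chrom TEXT, strand TEXT, '
            "txStart INTEGER, txEnd INTEGER, cdsStart INTEGER, cdsEnd INTEGER, "
            "exonCount INTEGER, exonStarts TEXT, exonEnds TEXT)"
        )
        conn.executemany(
            f'INSERT INTO "{table_name}" VALUES (?,?,?,?,?,?,?,?,?,?)',
            [
                (
                    r.name,
                    r.chrom,
                    r.strand,
                    r.txStart,
                    r.txEnd,
                    r.cdsStart,
                    r.cdsEnd,
                    r.exonCount,
                    "".join(f"{s}," for s in r.exonStarts),
                    "".join(f"{e}," for e in r.exonEnds),
                )
                for r in records
            ],
        )
        conn.commit()
    finally:
        conn.close()
    return records


def make_genome_2bit(
    out_path: str | PathLike[str],
    spec: FixtureSpec,
    truth_path: str | PathLike[str] | None = None,
) -> dict[str, str]:
    """Write a synthetic genome as a 2bit archive plus a FASTA truth file.

    One random sequence per chromosome in ``spec.chrom_sizes``, with
    random N runs and random soft-masked (lowercase) runs.  The truth
    file records the exact emitted strings for oracle comparison; the
    function also returns them.  ``truth_path`` defaults to the archive
    path with a ``.truth.fa`` suffix appended.
    """
    nrng = np.random.default_rng(spec.seed)
    prng = random.Random(spec.seed)
    sequences: dict[str, str] = {}
    for chrom in sorted(spec.chrom_sizes):
        size = spec.chrom_sizes[chrom]
        codes = nrng.integers(0, 4, size=size)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()
        # sprinkle N runs and soft-mask runs, ~1 of each per 50 kb
        for kind in ("N", "mask"):
            n_runs = max(1, size // 50_000)
            for _ in range(n_runs):
                run_len = prng.randint(1, max(2, size // 200))
                run_start = prng.randrange(0, size)
                run_end = min(size, run_start + run_len)
                if kind == "N":
                    arr[run_start:run_end] = ord("N")
                else:
                    arr[run_start:run_end] |= 32  # lowercase
        sequences[chrom] = arr.tobytes().decode("ascii")

    write_archive(list(sequences.items()), out_path)
    if truth_path is None:
        truth_path = fspath(out_path) + ".truth.fa"
    with open(truth_path, "w", encoding="ascii") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return sequences


@dataclass
class AssociationFixture:
    """Everything a table-association test needs, with brute-force truth."""

    snp_rows: list[dict]
    xref_rows: list[dict]
    joiner_text: str
    expected: dict[str, list[tuple]]  # snp name -> matching xref row tuples
    snp_table: str
    xref_table: str
    database_name: str


def make_association_fixture(
    database: str | PathLike[str],
    spec: FixtureSpec,
    snp_table: str = "snpToy",
    xref_table: str = "xrefToy",
    database_name: str | None = None,
) -> AssociationFixture:
    """Create two linked tables plus the joiner stanza that relates them.

    A snp-style table and an xref table (snpId, geneId, submitter) share
    ``spec.key_overlap`` of their key values: that fraction of snp names
    receives 1-3 xref partners; the xref table also carries orphan keys
    matching nothing.  The expected equijoin is computed by brute force
    and returned alongside, so navigation results can be checked exactly.
    """
    if database_name is None:
        database_name = Path(fspath(database)).stem
    snp_rows = make_snp_table(database, spec, table_name=snp_table)
    rng = random.Random(spec.seed + 1)

    names = [r["name"] for r in snp_rows]
    k = round(spec.key_overlap * len(names))
    linked = rng.sample(names, k) if k else []
    xref_rows: list[dict] = []
    gene_no = 0
    for nm in linked:
        for _ in range(rng.randint(1, 3)):
            xref_rows.append(
                {
                    "snpId": nm,
                    "geneId": f"gene{gene_no}",
                    "submitter": rng.choice(["labA", "labB", "labC"]),
                }
            )
            gene_no += 1
    for j in range(max(1, len(names) // 10)):  # orphans matching no snp
        xref_rows.append(
            {"snpId": f"orphan{j}", "geneId": f"gene{gene_no + j}", "submitter": "labZ"}
        )
    rng.shuffle(xref_rows)

    conn = _connect_rw(database)
    try:
        conn.execute(f'DROP TABLE IF EXISTS "{xref_table}"')
        conn.execute(
            f'CREATE TABLE "{xref_table}" (snpId TEXT, geneId TEXT, submitter TEXT)'
        )
        conn.executemany(
            f'INSERT INTO "{xref_table}" VALUES (?,?,?)',
            [(r["snpId"], r["geneId"], r["submitter"]) for r in xref_rows],
        )
        conn.commit()
    finally:
        conn.close()

    expected: dict[str, list[tuple]] = {
        nm: [
            (r["snpId"], r["geneId"], r["submitter"])
            for r in xref_rows
            if r["snpId"] == nm
        ]
        for nm in names
    }
    joiner_text = (
        f"set db {database_name}\n"
        "identifier snpName\n"
        f'  "snp accession shared between {snp_table} and {xref_table}"\n'
        f"  $db.{snp_table}.name\n"
        f"  $db.{xref_table}.snpId\n"
    )
    return AssociationFixture(
        snp_rows=snp_rows,
        xref_rows=xref_rows,
        joiner_text=joiner_text,
        expected=expected,
        snp_table=snp_table,
        xref_table=xref_table,
        database_name=database_name,
    )


def dump_sql(database: str | PathLike[str]) -> str:
    """Dump a fixture database as portable SQL text (CREATE + INSERT).

    Lets the same content be loaded into a server backend for
    integration runs outside the test suite.
    """
    conn = _connect_rw(database)
    try:
        return "\n".join(conn.iterdump())
    finally:
        conn.close()
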