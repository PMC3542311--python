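"""Exons, CDSs and introns from genePred gene models.

Builds a genePred table, reads one transcript back through the
reflection layer, and derives its sub-structures in gene order.
"""

import tempfile
from pathlib import Path

from goldenpath import GenePredRecord, connect, fixtures

with tempfile.TemporaryDirectory() as tmp:
    db_path = Path(tmp) / "hgToy.db"
    fixtures.make_genepred_table(db_path, fixtures.FixtureSpec(seed=5, feature_count=50))

    genes = connect(db_path).table("refGeneToy")
    row = genes.order("exonCount", "desc").first()  # the most exon-rich model
    g = GenePredRecord.from_row(row)
    print(f"{g.name} on {g.chrom}{g.strand}: tx [{g.txStart}, {g.txEnd}), "
          f"{g.exonCount} exons, coding={g.is_coding}")

    # lists are ordered 5'->3' along the gene (reversed for '-' strand)
    print("first two exons:  ", [str(iv) for iv in g.exons()[:2]])
    print("first two introns:", [str(iv) for iv in g.introns()[:2]])
    print("first two CDS segments:", [str(iv) for iv in g.cdss()[:2]])
    exon_bp = sum(iv.length() for iv in g.exons())
    intron_bp = sum(iv.length() for iv in g.introns())
    print(f"exon bp + intron bp = {exon_bp} + {intron_bp} = {exon_bp + intron_bp} "
          f"= transcript span {g.txEnd - g.txStart} (exact tiling)")
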