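"""Bin-accelerated interval queries against an annotation table.

Generates a snp-style table (bin, chrom, chromStart, chromEnd, name,
strand), reflects it, and runs overlap and containment queries through
the chainable query builder.
"""

import tempfile
from pathlib import Path

from goldenpath import connect, fixtures, parse_interval

with tempfile.TemporaryDirectory() as tmp:
    db_path = Path(tmp) / "hgToy.db"
    fixtures.make_snp_table(db_path, fixtures.FixtureSpec(seed=3, feature_count=500))

    db = connect(db_path)
    snp = db.table("snpToy")  # schema reflected lazily, once
    print(f"reflected columns: {', '.join(snp.column_names)} (has_bin={snp.has_bin})")

    window = parse_interval("chr1:1,000,000-1,400,000")
    overlapping = snp.with_interval(window).all()
    contained = snp.with_interval_excl(window).all()
    print(f"{len(overlapping)} features overlap {window}, "
          f"{len(contained)} lie completely within it")

    # clauses chain; nothing executes until a terminal (all/first/count)
    top = snp.with_interval(window).where("strand = ?", "+").select("name").limit(3).all()
    print("first three '+'-strand names in the window:", [r.name for r in top])
    print(f"'+' strand features genome-wide: {snp.where('strand = ?', '+').count()}")
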