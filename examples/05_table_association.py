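"""Table association through a joiner schema.

Generates two linked tables plus the joiner stanza relating them,
derives the association automatically, and navigates from a record to
its partners; then declares the same link manually.
"""

import tempfile
from pathlib import Path

from goldenpath import connect, declare_association, define_association, fixtures, load_joiner

with tempfile.TemporaryDirectory() as tmp:
    db_path = Path(tmp) / "hgToy.db"
    fx = fixtures.make_association_fixture(
        db_path, fixtures.FixtureSpec(seed=9, feature_count=100, key_overlap=0.6)
    )
    print("joiner stanza:\n" + fx.joiner_text)

    db = connect(db_path)
    snp = db.table(fx.snp_table)
    schema = load_joiner(fx.joiner_text)
    assoc = define_association(schema, snp, [db])[0]
    print(f"derived link: {assoc.from_table.table_name}.{assoc.from_field} -> "
          f"{assoc.to_table.table_name}.{assoc.to_field}")

    linked_name = next(n for n, rows in fx.expected.items() if rows)
    rec = snp.find_by("name", linked_name)
    partners = assoc.navigate(rec)  # always a list, possibly empty
    print(f"{linked_name} has {len(partners)} xref partner(s): "
          f"{[p.geneId for p in partners]}")

    manual = declare_association(snp, "many", db.table(fx.xref_table), ("name", "snpId"))
    assert manual.navigate(rec) == partners
    print("manual has_many declaration navigates to the same partners")
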