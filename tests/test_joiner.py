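import pytest
from oracle_utils import brute_equijoin

from goldenpath import fixtures, ormcore
from goldenpath.errors import JoinerParseError, UnknownFieldError
from goldenpath.joiner import (
    declare_association,
    define_association,
    load_joiner,
    navigate,
)

EXAMPLE = (
    "set db hg19\n"
    "identifier geneName\n"
    '  "gene symbol namespace"\n'
    "  $db.refGeneToy.name\n"
    "  $db.xrefToy.geneId\n"
)


def _xref_tuple(rec):
    return (rec.snpId, rec.geneId, rec.submitter)


class TestParsing:
    def test_variables_and_members_expand(self):
        schema = load_joiner(EXAMPLE)
        assert schema.variables == {"db": "hg19"}
        assert len(schema.identifiers) == 1
        stanza = schema.identifiers[0]
        assert stanza.name == "geneName" and stanza.description
        members = schema.resolve_members(stanza)
        assert members == [
            ("hg19", "refGeneToy", "name", ()),
            ("hg19", "xrefToy", "geneId", ()),
        ]

    def test_empty_input_yields_empty_schema(self):
        schema = load_joiner("\n# only a comment\n")
        assert schema.variables == {} and schema.identifiers == []

    def test_database_list_variable_fans_out(self):
        schema = load_joiner("set gbd hg19,mm9\nidentifier x\n  $gbd.t.f\n")
        members = schema.resolve_members(schema.identifiers[0])
        assert [(m[0], m[1], m[2]) for m in members] == [
            ("hg19", "t", "f"),
            ("mm9", "t", "f"),
        ]

    def test_option_tokens_are_retained_inert(self):
        schema = load_joiner("identifier x\n  hg19.t.f chopBefore=NM_ dupeOk\n")
        members = schema.resolve_members(schema.identifiers[0])
        assert members[0][3] == ("chopBefore=NM_", "dupeOk")

    def test_short_member_is_a_parse_error_with_line_number(self):
        with pytest.raises(JoinerParseError, match="line 2"):
            load_joiner("identifier x\n  onlytable.field\n")

    def test_undefined_variable_surfaces_at_resolution(self):
        schema = load_joiner("identifier x\n  $nope.t.f\n")
        with pytest.raises(JoinerParseError, match=r"\$nope"):
            schema.resolve_members(schema.identifiers[0])

    def test_file_source_is_accepted(self, tmp_path):
        p = tmp_path / "toy.joiner"
        p.write_text(EXAMPLE, encoding="utf-8")
        assert len(load_joiner(p).identifiers) == 1


class TestDefineAssociation:
    def test_navigation_equals_brute_force_equijoin(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        assocs = define_association(load_joiner(fx.joiner_text), t, [db])
        assert len(assocs) == 1
        truth = brute_equijoin(fx.snp_rows, "name", fx.xref_rows, "snpId")
        for row in fx.snp_rows:
            rec = t.find_by("name", row["name"])
            got = sorted(_xref_tuple(r) for r in assocs[0].navigate(rec))
            want = sorted(
                (r["snpId"], r["geneId"], r["submitter"]) for r in truth[row["name"]]
            )
            assert got == want
            # and the stored fixture expectation agrees with the fresh join
            assert got == sorted(fx.expected[row["name"]])

    def test_no_partner_rows_yield_empty_list_not_absent(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        assocs = define_association(load_joiner(fx.joiner_text), t, [db])
        lonely = [n for n, rows in fx.expected.items() if not rows]
        assert lonely, "fixture should contain unlinked keys at key_overlap=0.5"
        rec = t.find_by("name", lonely[0])
        assert assocs[0].navigate(rec) == []

    def test_members_on_missing_tables_are_skipped(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        text = fx.joiner_text + "  $db.ghostTable.name\n"
        assocs = define_association(load_joiner(text), t, [db])
        assert len(assocs) == 1  # ghost member skipped, real link kept

    def test_overwriting_the_database_variable_restricts_the_search(
        self, assoc_db, tmp_path
    ):
        """Re-pointing the stanza's database variable away from the open
        database removes the link; pointing it back restores it."""
        path, fx = assoc_db
        db = ormcore.connect(path)
        other_path = tmp_path / "otherDb.db"
        fixtures.make_association_fixture(
            other_path, fixtures.FixtureSpec(seed=8, feature_count=30)
        )
        other = ormcore.connect(other_path)
        t = db.table(fx.snp_table)

        schema = load_joiner(fx.joiner_text)
        both = define_association(schema, t, [db, other])
        assert {a.to_table.database.name for a in both} == {fx.database_name}

        schema.set_variable("db", other.name)  # overwrite: re-scope the search
        assert define_association(schema, t, [db, other]) == []

    def test_restricting_open_dbs_never_adds_associations(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        schema = load_joiner(fx.joiner_text)
        full = define_association(schema, t, [db])
        restricted = define_association(schema, t, [])
        assert len(restricted) <= len(full) and restricted == []

    def test_define_association_is_idempotent(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        schema = load_joiner(fx.joiner_text)
        first = define_association(schema, t, [db])
        second = define_association(schema, t, [db])
        assert [
            (a.from_field, a.to_table.table_name, a.to_field) for a in first
        ] == [(a.from_field, a.to_table.table_name, a.to_field) for a in second]


class TestDeclareAssociation:
    def test_manual_declaration_reproduces_schema_derived_links(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t, x = db.table(fx.snp_table), db.table(fx.xref_table)
        auto = define_association(load_joiner(fx.joiner_text), t, [db])[0]
        manual = declare_association(t, "many", x, ("name", "snpId"))
        for row in fx.snp_rows[:40]:
            rec = t.find_by("name", row["name"])
            assert sorted(map(_xref_tuple, manual.navigate(rec))) == sorted(
                map(_xref_tuple, auto.navigate(rec))
            )

    def test_has_one_returns_the_deterministic_first(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t, x = db.table(fx.snp_table), db.table(fx.xref_table)
        one = declare_association(t, "one", x, ("name", "snpId"))
        multi = next(n for n, rows in fx.expected.items() if len(rows) > 1)
        rec = t.find_by("name", multi)
        got = one.navigate(rec)
        assert len(got) == 1
        assert _xref_tuple(got[0]) == _xref_tuple(x.find_by("snpId", multi))

    def test_self_association_includes_self_matches(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t = db.table(fx.snp_table)
        self_assoc = declare_association(t, "many", t, ("name", "name"))
        rec = t.find_by("name", fx.snp_rows[0]["name"])
        assert rec in self_assoc.navigate(rec)

    def test_unknown_fields_are_errors(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t, x = db.table(fx.snp_table), db.table(fx.xref_table)
        with pytest.raises(UnknownFieldError):
            declare_association(t, "many", x, ("nope", "snpId"))
        with pytest.raises(UnknownFieldError):
            declare_association(t, "many", x, ("name", "nope"))

    def test_navigate_helper_deduplicates_across_duplicate_links(self, assoc_db):
        path, fx = assoc_db
        db = ormcore.connect(path)
        t, x = db.table(fx.snp_table), db.table(fx.xref_table)
        a = declare_association(t, "many", x, ("name", "snpId"))
        linked = next(n for n, rows in fx.expected.items() if rows)
        rec = t.find_by("name", linked)
        merged = navigate(rec, [a, a])  # same link twice
        assert sorted(map(_xref_tuple, merged)) == sorted(
            map(_xref_tuple, a.navigate(rec))
        )
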