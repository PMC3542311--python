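import random
import sqlite3

import pytest
from oracle_utils import brute_containment_scan, brute_overlap_scan, row_key

from goldenpath import fixtures, ormcore
from goldenpath.errors import (
    CapabilityError,
    ConfigurationError,
    ConnectionFailedError,
    UnknownFieldError,
    UnknownTableError,
)
from goldenpath.intervals import GenomicInterval


def _windows(spec, n, seed):
    rng = random.Random(seed)
    chroms = sorted(spec.chrom_sizes)
    for _ in range(n):
        chrom = chroms[rng.randrange(len(chroms))]
        size = spec.chrom_sizes[chrom]
        length = rng.randint(1, size // 4)
        start = rng.randrange(0, size - length)
        yield GenomicInterval(chrom, start, start + length)


class TestConnect:
    def test_missing_file_is_a_connection_error(self, tmp_path):
        with pytest.raises(ConnectionFailedError):
            ormcore.connect(tmp_path / "absent.db")

    @pytest.mark.parametrize("uri", ["bogus://x/y", "mysql://host/db"])
    def test_unsupported_locators_are_configuration_errors(self, uri):
        with pytest.raises(ConfigurationError):
            ormcore.connect(uri)

    def test_fresh_handle_has_empty_table_cache(self, snp_db):
        path, _ = snp_db
        db = ormcore.connect(path)
        assert db._tables == {} and db.reflection_count == 0

    def test_two_databases_are_independent(self, tmp_path):
        a, b = tmp_path / "a.db", tmp_path / "b.db"
        rows_a = fixtures.make_snp_table(a, fixtures.FixtureSpec(seed=1, feature_count=40))
        rows_b = fixtures.make_snp_table(b, fixtures.FixtureSpec(seed=2, feature_count=70))
        da, db_ = ormcore.connect(a), ormcore.connect(b)
        assert da.table("snpToy").count() == len(rows_a) == 40
        assert db_.table("snpToy").count() == len(rows_b) == 70
        assert da.name != db_.name


class TestReflection:
    def test_bin_and_positional_detection(self, snp_handle):
        db, _ = snp_handle
        t = db.table("snpToy")
        assert t.has_bin and t.positional_columns == ("chrom", "chromStart", "chromEnd")
        assert db.table("noBinToy").has_bin is False

    def test_genepred_positional_fallback(self, tmp_path):
        path = tmp_path / "gp.db"
        fixtures.make_genepred_table(path, fixtures.FixtureSpec(seed=3, feature_count=5))
        t = ormcore.connect(path).table("refGeneToy")
        assert t.positional_columns == ("chrom", "txStart", "txEnd")

    def test_reflection_happens_once_per_handle(self, snp_handle):
        db, _ = snp_handle
        db.table("snpToy")
        first = db.reflection_count
        assert db.table("snpToy") is db.table("snpToy")
        assert db.reflection_count == first

    def test_unknown_table_lists_available(self, snp_handle):
        db, _ = snp_handle
        with pytest.raises(UnknownTableError, match="snpToy"):
            db.table("nope")


class TestFindBy:
    @pytest.fixture()
    def tiny(self, tmp_path):
        path = tmp_path / "tiny.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE t (id INTEGER, name TEXT)")
        conn.executemany(
            "INSERT INTO t VALUES (?,?)", [(1, "rs1"), (2, "rs2"), (3, "rs2")]
        )
        conn.commit()
        conn.close()
        return ormcore.connect(path).table("t")

    def test_find_all_by_returns_every_match(self, tiny):
        assert len(tiny.find_all_by("name", "rs2")) == 2

    def test_find_by_absent_value_is_none_not_error(self, tiny):
        assert tiny.find_by("name", "absent") is None

    def test_find_by_first_is_deterministic(self, tiny):
        assert tiny.find_by("name", "rs2").id == 2  # first column ascending

    def test_unknown_field_is_an_error(self, tiny):
        with pytest.raises(UnknownFieldError):
            tiny.find_by("nope", 1)

    def test_find_all_by_equals_brute_force_filter(self, snp_handle):
        db, rows = snp_handle
        t = db.table("snpToy")
        for chrom in ("chr1", "chr2", "chrX"):
            got = {row_key(r.as_dict()) for r in t.find_all_by("chrom", chrom)}
            want = {row_key(r) for r in rows if r["chrom"] == chrom}
            assert got == want


class TestIntervalQueries:
    def test_overlap_equals_brute_force_with_and_without_bin(
        self, snp_handle, snp_spec
    ):
        db, rows = snp_handle
        t = db.table("snpToy")
        for w in _windows(snp_spec, 50, seed=21):
            want = {row_key(r) for r in brute_overlap_scan(rows, w.chrom, w.start, w.end)}
            with_bin = {row_key(r.as_dict()) for r in t.with_interval(w).all()}
            without = {
                row_key(r.as_dict()) for r in t.with_interval(w, use_bin=False).all()
            }
            assert with_bin == without == want

    def test_containment_equals_brute_force_and_is_subset_of_overlap(
        self, snp_handle, snp_spec
    ):
        db, rows = snp_handle
        t = db.table("snpToy")
        for w in _windows(snp_spec, 50, seed=22):
            want = {
                row_key(r) for r in brute_containment_scan(rows, w.chrom, w.start, w.end)
            }
            excl = {row_key(r.as_dict()) for r in t.with_interval_excl(w).all()}
            overl = {row_key(r.as_dict()) for r in t.with_interval(w).all()}
            assert excl == want and excl <= overl

    def test_tables_without_bin_use_plain_coordinate_scan(self, snp_handle, snp_spec):
        db, rows = snp_handle
        t = db.table("noBinToy")
        for w in _windows(snp_spec, 10, seed=23):
            got = {row_key(r.as_dict()) for r in t.with_interval(w).all()}
            assert got == {
                row_key(r) for r in brute_overlap_scan(rows, w.chrom, w.start, w.end)
            }

    def test_half_open_edge_semantics(self, tmp_path):
        path = tmp_path / "edge.db"
        conn = sqlite3.connect(path)
        conn.execute(
            "CREATE TABLE f (bin INTEGER, chrom TEXT, chromStart INTEGER, "
            "chromEnd INTEGER, name TEXT, strand TEXT)"
        )
        conn.execute("INSERT INTO f VALUES (585, 'chr1', 100, 200, 'a', '+')")
        conn.commit()
        conn.close()
        t = ormcore.connect(path).table("f")
        # feature abutting the window start is excluded
        assert t.with_interval(GenomicInterval("chr1", 200, 300)).count() == 0
        # window equal to the feature is contained (and overlapping)
        assert t.with_interval_excl(GenomicInterval("chr1", 100, 200)).count() == 1
        # window beyond all features is empty
        assert t.with_interval(GenomicInterval("chr1", 5000, 6000)).all() == []
        # feature spanning the whole window overlaps but is not contained
        w = GenomicInterval("chr1", 120, 180)
        assert t.with_interval(w).count() == 1
        assert t.with_interval_excl(w).count() == 0

    def test_table_without_positional_columns_is_a_capability_error(self, tmp_path):
        path = tmp_path / "np.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE t (id INTEGER, label TEXT)")
        conn.commit()
        conn.close()
        with pytest.raises(CapabilityError):
            ormcore.connect(path).table("t").with_interval(
                GenomicInterval("chr1", 0, 10)
            )


class TestChaining:
    def test_select_limit_projection(self, snp_handle):
        db, _ = snp_handle
        recs = db.table("snpToy").select("name").limit(5).all()
        assert len(recs) == 5
        assert all(r.keys() == ("name",) for r in recs)
        with pytest.raises(UnknownFieldError):
            recs[0].chrom  # projected away

    def test_order_equals_brute_force_sort(self, snp_handle):
        db, rows = snp_handle
        got = [r.chromStart for r in db.table("snpToy").order("chromStart").all()]
        assert got == sorted(r["chromStart"] for r in rows)
        got_desc = [
            r.chromStart for r in db.table("snpToy").order("chromStart", "desc").all()
        ]
        assert got_desc == sorted((r["chromStart"] for r in rows), reverse=True)

    def test_where_count_equals_brute_force(self, snp_handle):
        db, rows = snp_handle
        t = db.table("snpToy")
        assert t.where("strand = ?", "+").count() == sum(
            1 for r in rows if r["strand"] == "+"
        )

    def test_chained_clauses_compose(self, snp_handle, snp_spec):
        db, rows = snp_handle
        w = next(iter(_windows(snp_spec, 1, seed=77)))
        got = (
            db.table("snpToy")
            .select("name")
            .with_interval(w)
            .where("strand = ?", "-")
            .order("name")
            .limit(5)
            .all()
        )
        want = sorted(
            r["name"]
            for r in brute_overlap_scan(rows, w.chrom, w.start, w.end)
            if r["strand"] == "-"
        )[:5]
        assert [r.name for r in got] == want

    def test_group_by_counts(self, snp_handle, snp_spec):
        db, rows = snp_handle
        got = db.table("snpToy").select("chrom").group("chrom").all()
        assert {r.chrom for r in got} == set(snp_spec.chrom_sizes)

    def test_unknown_column_fails_before_execution(self, snp_handle):
        db, _ = snp_handle
        t = db.table("snpToy")
        before = db.query_count
        for build in (
            lambda: t.select("nope"),
            lambda: t.order("nope"),
            lambda: t.group("nope"),
            lambda: t.where("nope = ?", 1),
        ):
            with pytest.raises(UnknownFieldError):
                build()
        assert db.query_count == before

    def test_expressions_are_immutable_and_lazy(self, snp_handle, snp_spec):
        db, _ = snp_handle
        t = db.table("snpToy")
        before = db.query_count
        base = t.query()
        chained = base.with_interval(next(iter(_windows(snp_spec, 1, seed=5))))
        chained2 = chained.select("name").limit(3)
        assert db.query_count == before  # zero backend queries so far
        assert base.filters == () and chained.filters != ()
        assert chained.projection is None and chained2.projection == ("name",)
        chained2.all()
        assert db.query_count == before + 1  # exactly one statement per terminal

    def test_repeated_queries_return_identical_order(self, snp_handle):
        db, _ = snp_handle
        t = db.table("snpToy")
        a = [r.as_tuple() for r in t.find_all_by("chrom", "chr1")]
        b = [r.as_tuple() for r in t.find_all_by("chrom", "chr1")]
        assert a == b

    def test_values_are_bound_not_interpolated(self, tmp_path):
        path = tmp_path / "q.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE t (name TEXT)")
        tricky = "O'Reilly\"; DROP TABLE t; --"
        conn.execute("INSERT INTO t VALUES (?)", (tricky,))
        conn.commit()
        conn.close()
        t = ormcore.connect(path).table("t")
        assert t.find_by("name", tricky).name == tricky
        assert t.where("name = ?", tricky).count() == 1

    def test_placeholder_binding_count_is_checked(self, snp_handle):
        db, _ = snp_handle
        with pytest.raises(ValueError, match="placeholder"):
            db.table("snpToy").where("strand = ?")
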