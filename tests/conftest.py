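from __future__ import annotations

import pytest

from goldenpath import fixtures, ormcore


@pytest.fixture(scope="session")
def snp_spec() -> fixtures.FixtureSpec:
    return fixtures.FixtureSpec(seed=11, feature_count=500)


@pytest.fixture(scope="session")
def snp_db(tmp_path_factory, snp_spec):
    """A snp-style fixture database plus its in-memory truth rows."""
    path = tmp_path_factory.mktemp("db") / "hgToy.db"
    rows = fixtures.make_snp_table(path, snp_spec)
    fixtures.make_snp_table(path, snp_spec, table_name="noBinToy", with_bin=False)
    return path, rows


@pytest.fixture()
def snp_handle(snp_db):
    path, rows = snp_db
    db = ormcore.connect(path)
    yield db, rows
    db.close()


@pytest.fixture(scope="session")
def assoc_db(tmp_path_factory):
    path = tmp_path_factory.mktemp("assoc") / "hgAssoc.db"
    fx = fixtures.make_association_fixture(
        path, fixtures.FixtureSpec(seed=7, feature_count=120, key_overlap=0.5)
    )
    return path, fx
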