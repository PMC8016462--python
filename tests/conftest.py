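from __future__ import annotations

import pytest

from taxokit.store import TaxonomyStore
from taxokit.synthetic import FIX_A, Fixture, generate, write_fixture_dir


@pytest.fixture(scope="session")
def fix_a() -> Fixture:
    """The canonical 50-taxon fixture (seed 42) used across the suite."""
    return generate(FIX_A)


@pytest.fixture(scope="session")
def fix_a_dir(fix_a, tmp_path_factory):
    """FIX-A written out as dump-dialect files plus truth tables."""
    out = tmp_path_factory.mktemp("fix_a")
    return write_fixture_dir(fix_a, out)


@pytest.fixture()
def store(tmp_path) -> TaxonomyStore:
    """A fresh empty store in a temporary file."""
    with TaxonomyStore(tmp_path / "taxa.db") as s:
        yield s


@pytest.fixture()
def populated_store(tmp_path, fix_a) -> TaxonomyStore:
    """A store loaded with all FIX-A taxa and accessions."""
    with TaxonomyStore(tmp_path / "fixa.db") as s:
        s.import_taxa(fix_a.taxa_stream())
        s.add_accessions(fix_a.accession_to_record.values())
        yield s
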