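import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from rmlstkit.scheme import AlleleDatabase
from rmlstkit.synthgen import build_corpus, generate_scheme


def seed_database(scheme, ancestors) -> AlleleDatabase:
    db = AlleleDatabase()
    for locus in scheme:
        db.add_locus(locus)
        db.define_allele(locus.name, ancestors[locus.name])
    return db


@pytest.fixture(scope="session")
def small_scheme():
    """8 loci with their ancestral alleles (session-wide, read-only)."""
    return generate_scheme(8, seed=101)


@pytest.fixture
def small_db(small_scheme):
    # function-scoped: tests may define alleles
    scheme, ancestors = small_scheme
    return seed_database(scheme, ancestors)


@pytest.fixture(scope="session")
def small_corpus(small_scheme):
    scheme, ancestors = small_scheme
    return build_corpus(scheme, ancestors, 3, seed=101)
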