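import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from crgnet.synthetic_data import FixtureSpec, generate_fixture_bundle


SMALL_SPEC = FixtureSpec(
    n_genes=400,
    n_drugs=12,
    n_cells=60,
    n_seed_genes=20,
    n_seed_pairs=24,
    n_terms=40,
    seed_term_count=3,
    hub_bias=30.0,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study reused by pipeline-level tests."""
    return generate_fixture_bundle(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale default synthetic study (2000 genes, 50 drugs)."""
    return generate_fixture_bundle(FixtureSpec(rng_seed=11))


@pytest.fixture()
def bundle_dir(tmp_path, small_bundle):
    """The small bundle written to disk in the loader formats."""
    from crgnet.synthetic_data import write_bundle

    out = tmp_path / "bundle"
    write_bundle(small_bundle, out)
    return out
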