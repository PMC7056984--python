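import numpy as np
import pytest

from fasterx.align import CodonAlignment


def make_alignment(a: str, b: str) -> CodonAlignment:
    """Column-wise codon alignment of two equal-length in-frame sequences."""
    assert len(a) == len(b) and len(a) % 3 == 0
    return CodonAlignment(
        "a", "b", [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small on-disk synthetic input set shared across file-level tests."""
    from fasterx.simulate import (
        CodonSimParams,
        ExprSimParams,
        FixtureParams,
        emit_fixture_bundle,
    )

    out = tmp_path_factory.mktemp("bundle")
    paths = emit_fixture_bundle(
        CodonSimParams(n_codons=120, seed=42),
        ExprSimParams(n_genes=60, seed=43),
        out,
        FixtureParams(n_decoys=8),
    )
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
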