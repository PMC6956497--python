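import numpy as np
import pytest

from seedscan.energy import NucleotideSequence, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rna(rng, n: int, name: str = "seq") -> NucleotideSequence:
    return NucleotideSequence(name, "".join(rng.choice(list("ACGU"), n)))


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small generated screen shared across benchmark tests."""
    from seedscan.fixtures import FixtureSpec, generate_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(
        n_srna=4, n_targets_per_organism=25, n_verified=6, rng_seed=42
    )
    return generate_fixture(spec, outdir)
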