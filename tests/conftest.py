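import numpy as np
import pytest

from dicarn.hic_io import ContactMatrix
from dicarn.synthetic import SyntheticSpec, generate_pair, make_fixture_suite


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast 120-bin synthetic chromosome used across unit tests."""
    return SyntheticSpec(
        n_bins=120,
        read_depth=5e5,
        tad_boundaries=(40, 80),
        loops=((20, 50, 4.0, 2.0), (70, 100, 4.0, 2.0)),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return generate_pair(small_spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The canonical synthetic fixture suite (three 400-bin chromosomes)."""
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, n_bins=400, seed=0)
    return out


@pytest.fixture()
def random_contact_matrix():
    def make(n: int, seed: int = 0, density: float = 1.0) -> ContactMatrix:
        rng = np.random.default_rng(seed)
        m = rng.poisson(5.0, size=(n, n)).astype(float)
        if density < 1.0:
            m *= rng.random((n, n)) < density
        m = np.triu(m) + np.triu(m, 1).T
        return ContactMatrix(chrom="chrT", resolution=10_000, values=m)

    return make
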