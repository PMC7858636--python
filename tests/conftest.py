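import numpy as np
import pytest

from multicoloc import PriorSpec, RegionData, SimScenario, TraitMeta, simulate_region


@pytest.fixture
def default_priors():
    return PriorSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_region(z, se=0.02, ld=None, prior_sd=0.15, sample_size=None):
    """Region from a z-score matrix with constant standard errors."""
    z = np.asarray(z, dtype=float)
    m, q = z.shape
    se_mat = np.full((m, q), se, dtype=float) if np.isscalar(se) else np.asarray(se)
    return RegionData(
        snp_ids=[f"rs{j+1}" for j in range(q)],
        beta=z * se_mat,
        se=se_mat,
        traits=[
            TraitMeta(name=f"t{i+1}", prior_sd=prior_sd, sample_size=sample_size)
            for i in range(m)
        ],
        ld=ld,
    )


@pytest.fixture
def shared_signal_region():
    """Two identical traits with one strong shared signal among 20 SNPs."""
    z = np.zeros((2, 20))
    z[:, 7] = 12.0
    return make_region(z)


@pytest.fixture
def planted_region_iii(rng):
    """Ten traits in four planted clusters (3, 3, 2, 2), large samples."""
    scn = SimScenario(
        m=10, Q=150,
        clusters=((0, 1, 2), (3, 4, 5), (6, 7), (8, 9)),
        sample_sizes=15000,
    )
    region, truth = simulate_region(scn, rng=rng)
    return region, truth
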