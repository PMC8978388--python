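import numpy as np
import pytest

from ghsurv.baselines import BaselineFamily, BaselineParams
from ghsurv.gh import GHParameters, SurvivalDataset
from ghsurv.inference import PosteriorSamples, _to_unconstrained_baseline


FAMILY_EXAMPLES = {
    BaselineFamily.PGW: (2.0, 1.5, 0.8),
    BaselineFamily.LOGLOGISTIC: (1.5, 1.3),
    BaselineFamily.LOGNORMAL: (0.3, 0.9),
    BaselineFamily.GENGAMMA: (1.2, 1.5, 0.9),
    BaselineFamily.GAMMA: (1.4, 1.7),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_baseline(family: BaselineFamily, rng) -> BaselineParams:
    """Random but numerically tame parameters for each family."""
    if family is BaselineFamily.LOGNORMAL:
        return BaselineParams(family, (rng.normal(0, 0.5), rng.uniform(0.5, 1.5)))
    k = len(FAMILY_EXAMPLES[family])
    return BaselineParams(family, tuple(rng.uniform(0.5, 2.5, size=k)))


def toy_samples(rng, n_cov=2, M=7, family=BaselineFamily.PGW,
                theta=None) -> PosteriorSamples:
    """A tiny hand-built posterior: M random draws, no MCMC involved."""
    k = len(FAMILY_EXAMPLES[family])
    base = np.column_stack([rng.uniform(0.8, 2.0, M) for _ in range(k)])
    if theta is None:
        th = rng.normal(0, 0.5, size=(M, n_cov))
    else:
        th = np.tile(np.asarray(theta, float), (M, 1))
    tt = np.zeros((M, 0))
    uncon = np.hstack([_to_unconstrained_baseline(base, family), tt, th])
    from ghsurv.gh import GHStructure
    return PosteriorSamples(
        structure=GHStructure.PH, family=family,
        baseline_draws=base, theta_tilde_draws=tt, theta_draws=th,
        log_post=np.zeros(M), unconstrained=uncon,
        names=[f"z{j}" for j in range(n_cov)], tilde_names=[],
    )


def toy_dataset(rng, n=15, n_cov=2) -> SurvivalDataset:
    """Small dataset with one binary and one continuous-ish covariate mix."""
    Z = np.column_stack(
        [rng.integers(0, 2, n).astype(float)]
        + [rng.integers(0, 2, n).astype(float) for _ in range(n_cov - 1)]
    )
    # ensure both exposure levels of column 0 are present
    Z[0, 0], Z[1, 0] = 0.0, 1.0
    times = rng.uniform(0.2, 5.0, n)
    status = rng.integers(0, 2, n)
    status[0] = 1
    return SurvivalDataset(times, status, Z, np.zeros((n, 0)))
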