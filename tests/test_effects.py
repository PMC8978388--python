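"""Effect measures against brute-force nested-loop oracles, hand-evaluated
formula cases, and monotonicity/shape properties."""

import numpy as np
import pytest

from ghsurv.baselines import BaselineFamily
from ghsurv.effects import (
    ExposureSummary,
    conditional_survival,
    marginal_survival,
    ppar,
    ppas,
    ppce,
    ppme,
    rmst,
)
from ghsurv.gh import gh_cumhaz
from conftest import toy_dataset, toy_samples


@pytest.fixture
def fixture(rng):
    data = toy_dataset(rng, n=15, n_cov=2)
    samples = toy_samples(rng, n_cov=2, M=7)
    return samples, data


def brute_cs(grid, samples, data, k, r):
    """Triple loop over draws, subjects in stratum, grid points."""
    rows = [i for i in range(data.n) if data.Z[i, k] == r]
    out = np.zeros(len(grid))
    for gi, t in enumerate(grid):
        acc = 0.0
        for j in range(samples.M):
            par = samples.get(j)
            for i in rows:
                acc += np.exp(-gh_cumhaz(t, data.Z[i], data.Z_tilde[i], par))
        out[gi] = acc / (len(rows) * samples.M)
    return out


def brute_ms(grid, samples, data, k, r):
    out = np.zeros(len(grid))
    for gi, t in enumerate(grid):
        acc = 0.0
        for j in range(samples.M):
            par = samples.get(j)
            for i in range(data.n):
                z = data.Z[i].copy()
                z[k] = r
                acc += np.exp(-gh_cumhaz(t, z, data.Z_tilde[i], par))
        out[gi] = acc / (data.n * samples.M)
    return out


GRID = np.array([0.0, 0.5, 1.4, 3.0])


class TestSurvivalFunctions:
    @pytest.mark.parametrize("r", [0, 1])
    def test_conditional_matches_brute_force(self, fixture, r):
        samples, data = fixture
        curve = conditional_survival(samples, data, 0, r, grid=GRID)
        assert np.allclose(curve.estimate, brute_cs(GRID, samples, data, 0, r),
                           atol=1e-12)

    @pytest.mark.parametrize("r", [0, 1])
    def test_marginal_matches_brute_force(self, fixture, r):
        samples, data = fixture
        curve = marginal_survival(samples, data, 0, r, grid=GRID)
        assert np.allclose(curve.estimate, brute_ms(GRID, samples, data, 0, r),
                           atol=1e-12)

    def test_survival_one_at_origin_and_monotone(self, fixture):
        samples, data = fixture
        grid = np.linspace(0, 4, 30)
        for fn, r in ((conditional_survival, 0), (marginal_survival, 1)):
            c = fn(samples, data, 0, r, grid=grid)
            assert c.estimate[0] == pytest.approx(1.0, abs=1e-14)
            assert np.all(np.diff(c.estimate) <= 1e-12)
            assert np.all((c.lower <= c.estimate + 1e-12)
                          & (c.estimate <= c.upper + 1e-12))

    def test_mean_of_per_draw_curves_equals_double_sum(self, fixture):
        # linearity: averaging per-draw subgroup means reproduces the
        # full double sum exactly
        samples, data = fixture
        c = conditional_survival(samples, data, 0, 1, grid=GRID)
        assert np.allclose(c.draws.mean(axis=0), c.estimate, atol=1e-14)

    def test_null_coefficients_make_levels_identical(self, rng):
        data = toy_dataset(rng, n=10)
        samples = toy_samples(rng, n_cov=2, M=5, theta=[0.0, 0.0])
        c0 = marginal_survival(samples, data, 0, 0, grid=GRID)
        c1 = marginal_survival(samples, data, 0, 1, grid=GRID)
        assert np.array_equal(c0.estimate, c1.estimate)

    def test_empty_stratum_raises(self, rng):
        data = toy_dataset(rng, n=8)
        data.Z[:, 0] = 0.0
        samples = toy_samples(rng, n_cov=2)
        with pytest.raises(ValueError, match="no subjects"):
            conditional_survival(samples, data, 0, 1, grid=GRID)

    def test_continuous_exposure_rejected(self, rng):
        data = toy_dataset(rng, n=8)
        data.Z[:, 1] = rng.normal(size=8)
        samples = toy_samples(rng, n_cov=2)
        with pytest.raises(ValueError, match="not binary"):
            marginal_survival(samples, data, 1, 0, grid=GRID)


class TestMeasures:
    def test_ppce_is_difference_of_conditional_curves(self, fixture):
        samples, data = fixture
        c = ppce(samples, data, 0, grid=GRID)
        expect = (brute_cs(GRID, samples, data, 0, 0)
                  - brute_cs(GRID, samples, data, 0, 1))
        assert np.allclose(c.estimate, expect, atol=1e-12)
        assert c.estimate[0] == pytest.approx(0.0, abs=1e-14)

    def test_ppme_matches_brute_force_and_vanishes_when_null(self, fixture, rng):
        samples, data = fixture
        c = ppme(samples, data, 0, grid=GRID)
        expect = (brute_ms(GRID, samples, data, 0, 0)
                  - brute_ms(GRID, samples, data, 0, 1))
        assert np.allclose(c.estimate, expect, atol=1e-12)
        null = toy_samples(rng, n_cov=2, M=5, theta=[0.0, 0.3])
        cn = ppme(null, data, 0, grid=GRID)
        assert np.allclose(cn.estimate, 0.0, atol=1e-15)

    def test_ppas_hand_value(self):
        # CS0=0.8, CS1=0.6, pi_r=0.5 -> 0.5 * (1 - 0.6/0.8) = 0.125
        assert 0.5 * (1 - 0.6 / 0.8) == pytest.approx(0.125, abs=1e-15)

    def test_ppas_matches_per_draw_formula(self, fixture):
        samples, data = fixture
        exp_summary = ExposureSummary.from_data(data, 0)
        c = ppas(samples, data, 0, grid=GRID)
        cs0 = conditional_survival(samples, data, 0, 0, grid=GRID).draws
        cs1 = conditional_survival(samples, data, 0, 1, grid=GRID).draws
        expect = (exp_summary.pi_r * (1 - cs1 / cs0)).mean(axis=0)
        # t=0: both curves equal 1, the measure is exactly 0
        assert c.estimate[0] == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(c.estimate[1:], expect[1:], atol=1e-12)

    def test_ppar_hand_values(self, fixture):
        # CS0=0.8, CS1=0.6, pi=0.5: 0.1/0.3 = 1/3; boundary pi=1, CS1=0: CS0
        num = 0.5 * (0.8 - 0.6)
        assert num / (num + 1 - 0.8) == pytest.approx(1 / 3, abs=1e-15)
        cs0 = 0.7
        assert 1.0 * (cs0 - 0) / (1.0 * (cs0 - 0) + 1 - cs0) == pytest.approx(
            cs0, abs=1e-15)

    def test_ppar_zero_when_levels_equal_and_at_origin(self, rng):
        data = toy_dataset(rng, n=10)
        null = toy_samples(rng, n_cov=2, M=5, theta=[0.0, 0.0])
        c = ppar(null, data, 0, grid=GRID)
        assert np.allclose(c.estimate, 0.0, atol=1e-14)

    def test_ppar_matches_per_draw_formula(self, fixture):
        samples, data = fixture
        pi_r = ExposureSummary.from_data(data, 0).pi_r
        cs0 = conditional_survival(samples, data, 0, 0, grid=GRID).draws
        cs1 = conditional_survival(samples, data, 0, 1, grid=GRID).draws
        num = pi_r * (cs0 - cs1)
        den = num + 1 - cs0
        expect = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
        c = ppar(samples, data, 0, grid=GRID)
        assert np.allclose(c.estimate, expect.mean(axis=0), atol=1e-12)


class TestMonotoneEffects:
    def test_stronger_coefficient_increases_every_measure(self, rng):
        data = toy_dataset(rng, n=12)
        grid = np.linspace(0.0, 3.0, 12)
        prev = None
        for theta_k in (0.2, 0.6, 1.1):
            samples = toy_samples(rng.__class__(np.random.PCG64(5)),
                                  n_cov=2, M=6, theta=[theta_k, 0.1])
            vals = [fn(samples, data, 0, grid=grid).estimate
                    for fn in (ppce, ppas, ppar, ppme)]
            if prev is not None:
                for new, old in zip(vals, prev):
                    assert np.all(new >= old - 1e-12)
            prev = vals

    def test_harmful_exposure_gives_positive_effects(self, rng):
        data = toy_dataset(rng, n=12)
        samples = toy_samples(rng, n_cov=2, M=6, theta=[0.8, 0.0])
        grid = np.linspace(0.0, 3.0, 10)
        for fn in (ppce, ppas, ppar, ppme):
            c = fn(samples, data, 0, grid=grid)
            assert np.all(c.estimate[1:] > 0)

    def test_ppme_decays_at_long_horizon(self, rng):
        data = toy_dataset(rng, n=12)
        samples = toy_samples(rng, n_cov=2, M=6, theta=[0.8, 0.0])
        tmed = np.median(data.times)
        c = ppme(samples, data, 0, grid=np.array([0.0, tmed, 50 * tmed]))
        assert c.estimate[1] > c.estimate[2]
        assert c.estimate[2] < 0.05


class TestRMST:
    def test_unit_survival_gives_horizon(self, rng):
        # effectively-null hazard: survival stays at 1 on [0, t*]
        data = toy_dataset(rng, n=6)
        samples = toy_samples(rng, n_cov=2, M=3, theta=[0.0, 0.0])
        samples.baseline_draws[:] = [1e8, 1.0, 1.0]  # huge scale, zero hazard
        est, lo, hi = rmst(samples, data, 2.0, 0, 0)
        assert est == pytest.approx(2.0, rel=1e-6)

    def test_exponential_closed_form(self, rng):
        # MS is exp(-0.5 t) when every subject has unit-exponential baseline
        # scaled by theta=log(0.5) at z=1... simplest: null covariates,
        # exponential baseline with rate 0.5 (eta=2)
        data = toy_dataset(rng, n=6)
        samples = toy_samples(rng, n_cov=2, M=3, theta=[0.0, 0.0])
        samples.baseline_draws[:] = [2.0, 1.0, 1.0]
        est, _, _ = rmst(samples, data, 2.0, 0, 0)
        lam = 0.5
        assert est == pytest.approx((1 - np.exp(-lam * 2.0)) / lam, rel=1e-4)

    def test_grid_refinement_converges(self, rng):
        data = toy_dataset(rng, n=8)
        samples = toy_samples(rng, n_cov=2, M=4)
        a = rmst(samples, data, 3.0, 0, 1, n_grid=1000)[0]
        b = rmst(samples, data, 3.0, 0, 1, n_grid=2000)[0]
        assert abs(a - b) < 1e-5 * 3.0

    def test_exposed_rmst_below_unexposed_under_harm(self, rng):
        data = toy_dataset(rng, n=10)
        samples = toy_samples(rng, n_cov=2, M=5, theta=[0.7, 0.2])
        for t_star in (1.0, 2.5, 4.0):
            r1 = rmst(samples, data, t_star, 0, 1)[0]
            r0 = rmst(samples, data, t_star, 0, 0)[0]
            assert r1 <= r0

    def test_horizon_vector_and_validation(self, rng):
        data = toy_dataset(rng, n=6)
        samples = toy_samples(rng, n_cov=2, M=3)
        tab = rmst(samples, data, np.array([1.0, 2.0]), 0, 0)
        assert list(tab["t_star"]) == [1.0, 2.0]
        assert (tab["estimate"].diff().dropna() > 0).all()
        with pytest.raises(ValueError):
            rmst(samples, data, -1.0, 0, 0)


class TestExposureSummary:
    def test_counts_and_prevalence(self, rng):
        data = toy_dataset(rng, n=15)
        s = ExposureSummary.from_data(data, 0)
        assert s.n_0 + s.n_1 == 15
        assert s.pi_r == pytest.approx(data.Z[:, 0].mean())
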