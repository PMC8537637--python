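"""Population PK model: closed forms against independent numerical oracles,
covariate/ random-effect structure, and the dose-linearity invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from mipdsim.pk_model import (
    EVALUATION_DAY,
    CovariateVector,
    DosingRegimen,
    RandomEffects,
    concentration_at,
    individual_parameters,
    partial_auc,
    simulate_observation,
)


def _typical_cov(mayo=2, steroid=False, extensive=False, ffm=50.0, wt=75.0):
    return CovariateVector(1, wt, ffm, "M", mayo, steroid, extensive)


def _random_case(rng):
    ke = rng.uniform(0.02, 0.3, 3)
    v = rng.uniform(2.0, 8.0)
    amounts = tuple(rng.uniform(100.0, 1000.0, 3))
    return DosingRegimen.induction(amounts), ke, v


def _ode_concentration(regimen, ke_occ, v, t_eval):
    """Independent oracle: integrate dC/dt = -ke(t) C with bolus jumps,
    segment by segment up to each requested time."""
    times = list(regimen.times)

    def at(t):
        c = 0.0
        for k, tk in enumerate(times):
            if t < tk:
                break
            c += regimen.amounts[k] / v
            seg_end = min(t, times[k + 1]) if k + 1 < len(times) else t
            if seg_end > tk:
                sol = solve_ivp(lambda s, y, kek=ke_occ[k]: [-kek * y[0]],
                                (tk, seg_end), [c], rtol=1e-11, atol=1e-13)
                c = sol.y[0][-1]
        return c

    return np.array([at(float(t)) for t in np.atleast_1d(t_eval)])


class TestIndividualParameters:
    def test_typical_subject_identity(self, poppk):
        ke, v = individual_parameters(poppk, _typical_cov(ffm=poppk.ffm_ref),
                                      RandomEffects.none())
        assert v == pytest.approx(poppk.v_typ)
        assert ke == pytest.approx(poppk.cl_typ / poppk.v_typ)

    def test_eta_ke_doubles_elimination(self, poppk):
        re = RandomEffects(np.log(2.0), 0.0, (0.0, 0.0, 0.0))
        ke, v = individual_parameters(poppk, _typical_cov(ffm=poppk.ffm_ref), re)
        assert v == pytest.approx(poppk.v_typ)
        assert ke == pytest.approx(2.0 * poppk.cl_typ / poppk.v_typ)

    def test_kappa_applies_per_occasion(self, poppk):
        re = RandomEffects(0.0, 0.0, (np.log(2.0), 0.0, 0.0))
        ke, _ = individual_parameters(poppk, _typical_cov(ffm=poppk.ffm_ref), re)
        assert ke[0] == pytest.approx(2.0 * ke[1])
        assert ke[1] == ke[2]

    def test_mayo3_raises_ke_and_lowers_auc(self, poppk):
        """Severe baseline disease clears faster, hence lower exposure at
        equal dose (the direction behind 1979 < 2455 mg*day/L)."""
        reg = DosingRegimen.induction(350.0)
        aucs = {}
        for mayo in (2, 3):
            ke, v = individual_parameters(poppk, _typical_cov(mayo=mayo),
                                          RandomEffects.none())
            aucs[mayo] = partial_auc(reg, ke, v)
        assert poppk.theta_mayo3_cl > 1
        assert aucs[3] < aucs[2]

    def test_invalid_covariates_rejected(self):
        with pytest.raises(ValueError):
            CovariateVector(1, -70.0, 50.0, "M", 2, False, False)
        with pytest.raises(ValueError):
            CovariateVector(1, 70.0, 80.0, "M", 2, False, False)  # ffm > wt
        with pytest.raises(ValueError):
            CovariateVector(1, 70.0, 50.0, "M", 4, False, False)


class TestRegimen:
    def test_validation(self):
        with pytest.raises(ValueError):
            DosingRegimen(times=(0.0, 14.0, 7.0), amounts=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            DosingRegimen(times=(0.0, 14.0), amounts=(1.0, -1.0))
        with pytest.raises(ValueError):
            DosingRegimen(times=(-1.0,), amounts=(1.0,))

    def test_induction_defaults(self):
        reg = DosingRegimen.induction(350.0)
        assert reg.times == (0.0, 14.0, 42.0)
        assert reg.n_occasions == 3


class TestConcentration:
    def test_zero_doses_zero_everywhere(self):
        reg = DosingRegimen.induction(0.0)
        ke = np.array([0.1, 0.1, 0.1])
        t = np.linspace(0.0, 84.0, 50)
        assert np.all(concentration_at(t, reg, ke, 5.0) == 0.0)

    def test_single_bolus_closed_form(self):
        reg = DosingRegimen(times=(0.0,), amounts=(400.0,))
        ke, v = np.array([0.12]), 6.0
        for t in (0.0, 3.0, 30.0):
            assert concentration_at(t, reg, ke, v) == pytest.approx(
                400.0 / v * np.exp(-0.12 * t), rel=1e-12)

    def test_before_first_dose_is_zero(self):
        reg = DosingRegimen(times=(10.0, 20.0), amounts=(100.0, 100.0))
        assert concentration_at(5.0, reg, np.array([0.1, 0.1]), 5.0) == 0.0

    def test_matches_ode_oracle(self):
        rng = np.random.default_rng(42)
        t_eval = np.array([1.0, 13.9, 14.1, 41.0, 43.0, 60.0, 84.0])
        for _ in range(20):
            reg, ke, v = _random_case(rng)
            ours = concentration_at(t_eval, reg, ke, v)
            oracle = _ode_concentration(reg, ke, v, t_eval)
            np.testing.assert_allclose(ours, oracle, rtol=1e-6)

    def test_superposition_of_single_doses(self):
        """With constant ke a multi-dose profile equals the sum of
        single-dose profiles."""
        ke, v = np.array([0.09] * 3), 5.0
        reg = DosingRegimen.induction((200.0, 300.0, 400.0))
        t = np.linspace(0.0, 84.0, 101)
        total = concentration_at(t, reg, ke, v)
        parts = sum(
            concentration_at(t, DosingRegimen(times=(tk,), amounts=(dk,)),
                             np.array([0.09]), v)
            for tk, dk in zip(reg.times, reg.amounts))
        np.testing.assert_allclose(total, parts, rtol=1e-12, atol=1e-15)


class TestPartialAuc:
    def test_zero_doses(self):
        reg = DosingRegimen.induction(0.0)
        assert partial_auc(reg, np.array([0.1] * 3), 5.0) == 0.0

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            reg, ke, v = _random_case(rng)
            ours = partial_auc(reg, ke, v)
            segs = list(reg.times) + [EVALUATION_DAY]
            oracle = 0.0
            for a, b in zip(segs[:-1], segs[1:]):
                # stop infinitesimally before b: the closed form at b already
                # includes the bolus administered there
                t = np.linspace(a, np.nextafter(b, a), 4000)
                c = concentration_at(t, reg, ke, v)
                oracle += np.trapezoid(c, t)
            assert ours == pytest.approx(oracle, rel=1e-4)

    def test_dose_doubling_doubles_auc_exactly(self):
        rng = np.random.default_rng(44)
        reg, ke, v = _random_case(rng)
        assert partial_auc(reg.scaled(2.0), ke, v) == 2.0 * partial_auc(reg, ke, v)

    @given(scale=st.floats(1.05, 3.0))
    def test_auc_decreases_with_faster_elimination(self, scale):
        ke = np.array([0.08, 0.1, 0.12])
        reg = DosingRegimen.induction(350.0)
        assert partial_auc(reg, ke * scale, 5.0) < partial_auc(reg, ke, 5.0)

    @given(extra=st.floats(1.0, 500.0), idx=st.integers(0, 2))
    def test_auc_increases_with_any_dose_amount(self, extra, idx):
        ke = np.array([0.08, 0.1, 0.12])
        amounts = [200.0, 300.0, 400.0]
        base = partial_auc(DosingRegimen.induction(tuple(amounts)), ke, 5.0)
        amounts[idx] += extra
        bigger = partial_auc(DosingRegimen.induction(tuple(amounts)), ke, 5.0)
        assert bigger > base

    def test_t_end_before_last_dose_rejected(self):
        reg = DosingRegimen.induction(350.0)
        with pytest.raises(ValueError):
            partial_auc(reg, np.array([0.1] * 3), 5.0, t_end=30.0)


class TestObservation:
    def test_sigma_zero_returns_prediction(self, rng):
        reg = DosingRegimen.induction(350.0)
        ke, v = np.array([0.1] * 3), 5.0
        obs = simulate_observation(14.0, reg, ke, v, 0.0, rng)
        assert obs.value == pytest.approx(concentration_at(14.0, reg, ke, v))

    def test_fixed_seed_reproducible(self):
        reg = DosingRegimen.induction(350.0)
        ke, v = np.array([0.1] * 3), 5.0
        a = simulate_observation(14.0, reg, ke, v, 0.25,
                                 np.random.default_rng(5))
        b = simulate_observation(14.0, reg, ke, v, 0.25,
                                 np.random.default_rng(5))
        assert a == b

    def test_unbiased_in_expectation(self, rng):
        reg = DosingRegimen.induction(350.0)
        ke, v = np.array([0.1] * 3), 5.0
        pred = concentration_at(14.0, reg, ke, v)
        n = 10_000
        vals = np.array([simulate_observation(14.0, reg, ke, v, 0.2, rng).value
                         for _ in range(n)])
        se = 0.2 * pred / np.sqrt(n)
        assert abs(vals.mean() - pred) < 3 * se
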