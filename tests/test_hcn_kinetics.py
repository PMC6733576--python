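"""HCN gate kinetics: rate functions, gate integration, Boltzmann/HH fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcnax.hcn_kinetics import (
    CAMP_0MM,
    CAMP_1MM,
    ActivationPoint,
    RateParams,
    TauPoint,
    alpha_rate,
    beta_rate,
    boltzmann,
    effective_slope,
    fit_boltzmann,
    fit_hh,
    gate_step,
    steady_state,
    time_constant,
)


class TestRates:
    @pytest.mark.parametrize("func, v, expected", [
        (alpha_rate, -102.1, 6.907),              # at the midpoint both rates equal A
        (alpha_rate, -150.0, 89.35915188793813),  # 6.907·exp(47.9/18.71)
        (beta_rate, -102.1, 6.907),
        (beta_rate, -70.0, 30.25785507559776),    # 6.907·exp(32.1/21.73)
    ])
    def test_rate_values_0mm(self, func, v, expected):
        assert func(v, CAMP_0MM) == pytest.approx(expected, rel=1e-12)

    def test_alpha_decreasing_beta_increasing(self):
        v = np.linspace(-160, -40, 200)
        assert np.all(np.diff(alpha_rate(v, CAMP_0MM)) < 0)
        assert np.all(np.diff(beta_rate(v, CAMP_0MM)) > 0)

    def test_mirror_symmetry_with_equal_scales(self):
        p = RateParams(a=3.0, v_half=-90.0, v_alpha=15.0, v_beta=15.0)
        v = np.linspace(-140, -40, 50)
        assert beta_rate(v, p) == pytest.approx(
            alpha_rate(2 * p.v_half - v, p), rel=1e-12)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            alpha_rate(np.nan, CAMP_0MM)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RateParams(a=-1.0, v_half=-100.0, v_alpha=10.0, v_beta=10.0)


class TestSteadyStateAndTau:
    def test_midpoint_is_half(self):
        assert steady_state(CAMP_0MM.v_half, CAMP_0MM) == pytest.approx(0.5)
        assert steady_state(CAMP_1MM.v_half, CAMP_1MM) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        v = np.linspace(-250, 50, 400)
        m = steady_state(v, CAMP_0MM)
        assert np.all(np.diff(m) < 0)
        assert steady_state(-1e3, CAMP_0MM) == pytest.approx(1.0)
        assert steady_state(1e3, CAMP_0MM) == pytest.approx(0.0)

    def test_value_at_minus80(self):
        # 1/(1 + e^{22.1·(1/18.71 + 1/21.73)})
        assert steady_state(-80.0, CAMP_0MM) == pytest.approx(0.0999110157,
                                                              rel=1e-8)

    def test_tau_at_midpoint_is_half_inverse_peak_rate(self):
        # alpha = beta = A there; per-second A gives ms via the 1e3 factor
        assert time_constant(CAMP_0MM.v_half, CAMP_0MM) == pytest.approx(
            1e3 / (2 * CAMP_0MM.a))

    def test_tau_value_at_minus70(self):
        assert time_constant(-70.0, CAMP_0MM) == pytest.approx(31.745987,
                                                               rel=1e-6)

    def test_tau_single_interior_maximum_and_edge_decay(self):
        v = np.linspace(-250, 50, 600)
        tau = time_constant(v, CAMP_0MM)
        sign_changes = np.sum(np.diff(np.sign(np.diff(tau))) != 0)
        assert sign_changes == 1
        assert tau[0] < tau.max() / 100 and tau[-1] < tau.max() / 100

    def test_per_ms_unit_switch(self):
        p_ms = RateParams(a=6.907, v_half=-102.1, v_alpha=18.71,
                          v_beta=21.73, rate_unit="per_ms")
        assert time_constant(p_ms.v_half, p_ms) == pytest.approx(
            1.0 / (2 * 6.907))


class TestGateStep:
    def test_fixed_point(self):
        m_inf = float(steady_state(-90.0, CAMP_0MM))
        assert gate_step(m_inf, -90.0, 5.0, CAMP_0MM) == pytest.approx(m_inf)

    def test_large_dt_reaches_steady_state(self):
        out = gate_step(0.0, -120.0, 1e7, CAMP_0MM)
        assert out == pytest.approx(float(steady_state(-120.0, CAMP_0MM)))

    def test_semigroup_two_half_steps(self):
        one = gate_step(0.2, -95.0, 3.0, CAMP_0MM)
        two = gate_step(gate_step(0.2, -95.0, 1.5, CAMP_0MM),
                        -95.0, 1.5, CAMP_0MM)
        assert two == pytest.approx(one, abs=1e-14)

    def test_bounds_preserved_for_any_dt(self):
        for m0 in (0.0, 0.3, 1.0):
            for dt in (1e-3, 1.0, 1e4):
                out = gate_step(m0, -110.0, dt, CAMP_0MM)
                assert 0.0 <= out <= 1.0

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            gate_step(0.5, -90.0, 0.0, CAMP_0MM)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(v=st.floats(-150, -50), m0=st.floats(0, 1),
           dt=st.floats(0.01, 5.0))
    def test_matches_fine_euler_oracle(self, v, m0, dt):
        """Exact update agrees with brute-force explicit Euler at dt=1e-4."""
        a = float(alpha_rate(v, CAMP_0MM)) * 1e-3   # per ms
        b = float(beta_rate(v, CAMP_0MM)) * 1e-3
        m = m0
        n = int(round(dt / 1e-4))
        for _ in range(n):
            m += 1e-4 * (a * (1 - m) - b * m)
        assert gate_step(m0, v, n * 1e-4, CAMP_0MM) == pytest.approx(
            m, abs=1e-6)


class TestBoltzmann:
    def test_midpoint_and_unit_slope_offset(self):
        assert boltzmann(-100.0, -100.0, 9.0) == pytest.approx(0.5)
        assert boltzmann(-109.0, -100.0, 9.0) == pytest.approx(
            1 / (1 + np.exp(-1)))

    def test_matches_steady_state_with_matched_slope(self):
        k = effective_slope(CAMP_0MM)
        v = np.linspace(-160, -40, 300)
        assert np.max(np.abs(boltzmann(v, CAMP_0MM.v_half, k)
                             - steady_state(v, CAMP_0MM))) < 1e-12

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            boltzmann(-90.0, -100.0, -1.0)


class TestFitBoltzmann:
    def test_exact_recovery(self):
        v = np.arange(-150.0, -60.0, 10.0)
        pts = [ActivationPoint(vv, float(boltzmann(vv, -103.3, 9.0)))
               for vv in v]
        fit = fit_boltzmann(pts)
        assert fit.v_half == pytest.approx(-103.3, abs=1e-6)
        assert fit.k == pytest.approx(9.0, abs=1e-6)
        assert fit.rss < 1e-20

    def test_degenerate_flat_data_raises(self):
        pts = [ActivationPoint(v, 0.5) for v in (-150.0, -120.0, -90.0, -70.0)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_boltzmann(pts)

    def test_too_few_points_raises(self):
        pts = [ActivationPoint(v, float(boltzmann(v, -100, 9)))
               for v in (-140.0, -100.0, -60.0)]
        with pytest.raises(ValueError):
            fit_boltzmann(pts)


def _hh_datasets(p, act_grid, ta_grid, td_grid):
    act = [ActivationPoint(v, float(steady_state(v, p))) for v in act_grid]
    ta = [TauPoint(v, float(time_constant(v, p)), kind="activation")
          for v in ta_grid]
    td = [TauPoint(v, float(time_constant(v, p)), kind="deactivation")
          for v in td_grid]
    return act, ta, td


ACT_GRID = np.arange(-150.0, -69.0, 10.0)
TA_GRID = np.arange(-150.0, -89.0, 10.0)
TD_GRID = np.arange(-110.0, -49.0, 10.0)


class TestFitHH:
    @pytest.mark.parametrize("p", [CAMP_0MM, CAMP_1MM],
                             ids=["0mM_cAMP", "1mM_cAMP"])
    def test_exact_recovery_of_published_sets(self, p):
        act, ta, td = _hh_datasets(p, ACT_GRID, TA_GRID, TD_GRID)
        res = fit_hh(act, ta, td, seed=0)
        q = res.params
        assert res.converged
        for got, true in [(q.a, p.a), (q.v_half, p.v_half),
                          (q.v_alpha, p.v_alpha), (q.v_beta, p.v_beta)]:
            assert abs(got - true) / abs(true) < 1e-3
        assert np.all(res.ci68[np.isfinite(res.ci68)] >= 0)

    def test_randomized_exact_recovery(self, rng):
        for _ in range(4):
            p = RateParams(a=float(rng.uniform(2, 15)),
                           v_half=float(rng.uniform(-115, -85)),
                           v_alpha=float(rng.uniform(10, 40)),
                           v_beta=float(rng.uniform(10, 40)))
            act, ta, td = _hh_datasets(p, ACT_GRID, TA_GRID, TD_GRID)
            res = fit_hh(act, ta, td, seed=1, n_starts=4)
            q = res.params
            assert q.v_half == pytest.approx(p.v_half, abs=0.01)
            assert q.a == pytest.approx(p.a, rel=1e-3)

    def test_doubling_weights_preserves_optimum_and_scales_objective(self):
        act, ta, td = _hh_datasets(CAMP_0MM, ACT_GRID, TA_GRID, TD_GRID)
        # perturb one point so the objective is non-zero at the optimum
        act[3] = ActivationPoint(act[3].v, act[3].activation + 0.05)
        w = (1.0, 1e-4, 1e-4)
        r1 = fit_hh(act, ta, td, seed=0, n_starts=3, weights=w)
        r2 = fit_hh(act, ta, td, seed=0, n_starts=3,
                    weights=tuple(2 * x for x in w))
        assert r2.params.v_half == pytest.approx(r1.params.v_half, abs=1e-5)
        assert r2.weighted_sse == pytest.approx(2 * r1.weighted_sse, rel=1e-6)

    def test_empty_dataset_rejected(self):
        act, ta, td = _hh_datasets(CAMP_0MM, ACT_GRID, TA_GRID, TD_GRID)
        with pytest.raises(ValueError):
            fit_hh([], ta, td)

    def test_scaled_ci_coverage_under_noise(self):
        """Variance-scaled 68% CIs cover the generating voltage parameters
        in roughly 68% of noisy replicates."""
        rng = np.random.default_rng(5)
        p = CAMP_0MM
        act_t = steady_state(ACT_GRID, p)
        ta_t = time_constant(TA_GRID, p)
        td_t = time_constant(TD_GRID, p)
        n_rep = 200
        hits = np.zeros(3)
        for _ in range(n_rep):
            act = [ActivationPoint(v, float(y + 0.03 * rng.standard_normal()))
                   for v, y in zip(ACT_GRID, act_t)]
            ta = [TauPoint(v, float(max(y * (1 + 0.05 * rng.standard_normal()),
                                        0.5)), kind="activation")
                  for v, y in zip(TA_GRID, ta_t)]
            td = [TauPoint(v, float(max(y * (1 + 0.05 * rng.standard_normal()),
                                        0.5)), kind="deactivation")
                  for v, y in zip(TD_GRID, td_t)]
            res = fit_hh(act, ta, td, n_starts=1)
            q, ci = res.params, res.ci68_scaled
            hits += [abs(q.v_half - p.v_half) <= ci[1],
                     abs(q.v_alpha - p.v_alpha) <= ci[2],
                     abs(q.v_beta - p.v_beta) <= ci[3]]
        coverage = hits / n_rep
        assert np.all(coverage >= 0.58) and np.all(coverage <= 0.78)
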