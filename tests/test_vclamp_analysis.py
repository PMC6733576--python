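"""Voltage-clamp analysis: tails, exponentials, ramps, Hill fits, peaks."""

import numpy as np
import pytest

from hcnax.hcn_kinetics import RateParams, boltzmann, fit_boltzmann, \
    steady_state, time_constant
from hcnax.synthetic_data import VClampProtocol, gen_dose_response, \
    gen_vclamp_dataset
from hcnax.vclamp_analysis import (
    DoseResponsePoint,
    RampIV,
    Sweep,
    estimate_endogenous_camp,
    extract_tail_activation,
    fit_hill,
    fit_monoexp,
    hill_curve,
    peak_halfwidth,
    reversal_from_ramps,
)


class TestTailExtraction:
    def test_points_match_windowed_gate_oracle_exactly(self):
        """Extracted points equal the closed-form window-averaged gate."""
        p = RateParams(6.907, -103.3, 18.0, 18.0)
        prot = VClampProtocol()
        sweeps, _ = gen_vclamp_dataset(p, prot, noise_frac=0.0, seed=0)
        pts = extract_tail_activation(sweeps)
        # closed form: during the tail the gate decays from m_cond toward
        # m_inf(tail) with tau(tail); the window mean is affine in m_cond
        tau = float(time_constant(prot.tail_v, p))
        minf = float(steady_state(prot.tail_v, p))
        t0 = prot.step_start + prot.step_duration
        tgrid = np.arange(0.0, prot.step_start + prot.step_duration
                          + prot.tail_duration, prot.dt)
        win = (tgrid >= t0 + 0.5) & (tgrid < t0 + 2.5)
        decay = np.mean(np.exp(-(tgrid[win] - t0) / tau))
        m_conds = np.array([float(steady_state(v, p)) for v in prot.steps])
        amps = minf + (m_conds - minf) * decay
        expected = amps / amps.max()
        got = np.array([q.activation for q in pts])
        assert got == pytest.approx(expected, abs=1e-8)

    def test_most_activated_step_normalizes_to_one(self):
        p = RateParams(6.907, -103.3, 18.0, 18.0)
        sweeps, _ = gen_vclamp_dataset(p, noise_frac=0.0, seed=0)
        pts = extract_tail_activation(sweeps)
        by_v = {q.v: q.activation for q in pts}
        assert by_v[-150.0] == pytest.approx(1.0)

    def test_noise_free_fit_recovers_generating_midpoint(self):
        p = RateParams(6.907, -103.3, 18.0, 18.0)
        sweeps, _ = gen_vclamp_dataset(p, noise_frac=0.0, seed=0)
        fit = fit_boltzmann(extract_tail_activation(sweeps))
        # residual bias from window deactivation and the <1 plateau is
        # well under the experimental SEM (0.8 mV)
        assert fit.v_half == pytest.approx(-103.3, abs=0.3)
        assert fit.k == pytest.approx(9.0, abs=0.15)

    def test_missing_meta_raises(self):
        t = np.arange(0.0, 10.0, 0.1)
        sw = Sweep(t, np.zeros_like(t), np.full_like(t, -70.0))
        with pytest.raises(ValueError, match="meta"):
            extract_tail_activation([sw])

    def test_zero_tail_amplitude_raises(self):
        t = np.arange(0.0, 50.0, 0.1)
        sweeps = [Sweep(t, np.zeros_like(t), np.full_like(t, -70.0),
                        meta={"step_mV": v, "tail_start_ms": 20.0,
                              "step_start_ms": 5.0})
                  for v in (-80.0, -100.0, -120.0, -140.0)]
        with pytest.raises(ValueError, match="normalize"):
            extract_tail_activation(sweeps)


class TestMonoExp:
    def test_exact_exponential_recovery(self):
        t = np.arange(0.0, 300.0, 0.5)
        y = 120.0 * np.exp(-t / 50.0) - 30.0
        fit = fit_monoexp(t, None, y)
        assert fit.ok
        assert fit.tau == pytest.approx(50.0, rel=1e-8)
        assert fit.offset == pytest.approx(-30.0, abs=1e-6)

    def test_constant_trace_flagged(self):
        t = np.arange(0.0, 100.0, 1.0)
        fit = fit_monoexp(t, None, np.full_like(t, 5.0))
        assert not fit.ok

    def test_noisy_recovery_within_tolerance(self, rng):
        t = np.arange(0.0, 400.0, 0.5)
        y = 80.0 * np.exp(-t / 35.0) + 10.0 + rng.normal(0, 1.0, t.size)
        fit = fit_monoexp(t, None, y)
        assert fit.ok and fit.tau == pytest.approx(35.0, rel=0.05)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexp(np.arange(5.0), None, np.arange(5.0))


def _line_ramp(slope, v_rev, act_v):
    v = np.linspace(-120.0, -20.0, 40)
    return RampIV(v, slope * (v - v_rev), act_v)


class TestReversal:
    def test_common_intersection(self):
        ramps = [_line_ramp(s, -36.0, a)
                 for s, a in ((0.5, -80), (1.5, -110), (3.0, -140))]
        assert reversal_from_ramps(ramps) == pytest.approx(-36.0, abs=1e-9)

    def test_mean_of_distinct_pairwise_intersections(self):
        # lines y = s(x - x0) chosen so the three pairwise crossings are
        # -20, -24, -28 mV
        v = np.linspace(-120.0, -10.0, 60)
        l1 = RampIV(v, 1.0 * v + 20.0, -80.0)            # crosses l2 at -20
        l2 = RampIV(v, 2.0 * v + 40.0, -110.0)
        # l3 slope 3: l1∩l3 at -28 → 3·(-28)+c = -28+20 → c = 76
        l3 = RampIV(v, 3.0 * v + 76.0, -140.0)           # l2∩l3 at -36? check
        x12 = -20.0
        x13 = (76.0 - 20.0) / (1.0 - 3.0)
        x23 = (76.0 - 40.0) / (2.0 - 3.0)
        expected = np.mean([x12, x13, x23])
        assert reversal_from_ramps([l1, l2, l3]) == pytest.approx(expected)

    def test_matches_closed_form_oracle_and_order_invariance(self, rng):
        for _ in range(10):
            slopes = rng.uniform(0.5, 5.0, 3)
            icpts = rng.uniform(-50.0, 50.0, 3)
            v = np.linspace(-120.0, -10.0, 30)
            ramps = [RampIV(v, s * v + c, a)
                     for s, c, a in zip(slopes, icpts, (-80, -110, -140))]
            xs = []
            for i in range(3):
                for j in range(i + 1, 3):
                    xs.append((icpts[j] - icpts[i]) / (slopes[i] - slopes[j]))
            expected = np.mean(xs)
            assert reversal_from_ramps(ramps) == pytest.approx(expected,
                                                               rel=1e-9)
            shuffled = [ramps[2], ramps[0], ramps[1]]
            assert reversal_from_ramps(shuffled) == pytest.approx(expected,
                                                                  rel=1e-9)

    def test_near_parallel_pair_raises_with_names(self):
        ramps = [_line_ramp(1.0, -36.0, -80),
                 _line_ramp(1.0 + 1e-12, -40.0, -110),
                 _line_ramp(3.0, -36.0, -140)]
        with pytest.raises(ValueError, match="0 and 1"):
            reversal_from_ramps(ramps)

    def test_requires_exactly_three(self):
        with pytest.raises(ValueError):
            reversal_from_ramps([_line_ramp(1.0, -36.0, -80)])


class TestHillFit:
    def test_exact_recovery(self):
        concs = (3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
        pts = [DoseResponsePoint(c, float(hill_curve(c, 40.0, 18.0, 1.0)))
               for c in concs]
        fit = fit_hill(pts)
        assert fit.ec50 == pytest.approx(40.0, rel=1e-6)
        assert fit.s_max == pytest.approx(18.0, rel=1e-6)
        assert fit.h == pytest.approx(1.0, rel=1e-6)
        # half-maximal shift at EC50 by construction
        assert fit(fit.ec50) == pytest.approx(fit.s_max / 2)

    def test_concentration_rescaling_equivariance(self):
        concs = np.array([3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        pts = [DoseResponsePoint(c, float(hill_curve(c, 40.0, 18.0, 1.3)))
               for c in concs]
        pts10 = [DoseResponsePoint(10 * c, p.shift)
                 for c, p in zip(concs, pts)]
        f1, f2 = fit_hill(pts), fit_hill(pts10)
        assert f2.ec50 == pytest.approx(10 * f1.ec50, rel=1e-6)
        assert f2.s_max == pytest.approx(f1.s_max, rel=1e-6)
        assert f2.h == pytest.approx(f1.h, rel=1e-6)

    def test_fixed_hill_coefficient(self):
        pts, _ = gen_dose_response(40.4, None, 1.0, sem=0.0)
        fit = fit_hill(pts, fix_h=1.0)
        assert fit.h == 1.0
        assert fit.ec50 == pytest.approx(40.4, rel=1e-6)

    def test_median_ec50_recovery_over_replicates(self):
        ec50s = []
        for seed in range(100):
            pts, _ = gen_dose_response(seed=seed)
            ec50s.append(fit_hill(pts).ec50)
        assert np.median(ec50s) == pytest.approx(40.4, rel=0.15)

    def test_too_few_concentrations(self):
        pts = [DoseResponsePoint(c, 1.0) for c in (10.0, 100.0)]
        with pytest.raises(ValueError):
            fit_hill(pts)


class TestEndogenousEstimate:
    def test_half_maximal_shift_degenerates_to_ec50(self):
        from hcnax.vclamp_analysis import HillFit
        fit = HillFit(ec50=40.0, s_max=18.0, h=1.0, covariance=np.zeros((3, 3)))
        est = estimate_endogenous_camp(fit, 9.0, 0.0)
        assert est.conc_point == pytest.approx(40.0)
        assert est.ci68_low == pytest.approx(40.0)
        assert est.ci68_high == pytest.approx(40.0)

    def test_widening_sem_never_narrows_ci(self):
        pts, _ = gen_dose_response(seed=11)
        fit = fit_hill(pts)
        widths = []
        for sem in (0.5, 1.2, 2.5):
            est = estimate_endogenous_camp(fit, 4.8, sem)
            widths.append(est.ci68_high - est.ci68_low)
        assert widths[0] <= widths[1] <= widths[2]

    def test_point_matches_bisection_oracle(self, rng):
        from scipy.optimize import brentq
        from hcnax.vclamp_analysis import HillFit
        for _ in range(10):
            ec50 = float(rng.uniform(5, 200))
            s_max = float(rng.uniform(5, 30))
            h = float(rng.uniform(0.5, 2.5))
            fit = HillFit(ec50=ec50, s_max=s_max, h=h,
                          covariance=np.zeros((3, 3)))
            shift = float(rng.uniform(0.1, 0.9)) * s_max
            est = estimate_endogenous_camp(fit, shift, 0.5)
            oracle = brentq(lambda c: fit(c) - shift, 1e-6, 1e9)
            assert est.conc_point == pytest.approx(oracle, rel=1e-8)
            assert est.ci68_low <= est.conc_point <= est.ci68_high

    def test_shift_outside_range_rejected(self):
        from hcnax.vclamp_analysis import HillFit
        fit = HillFit(ec50=40.0, s_max=18.0, h=1.0,
                      covariance=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            estimate_endogenous_camp(fit, 19.0, 1.0)


class TestPeakHalfwidth:
    def test_symmetric_triangle(self):
        t = np.linspace(0.0, 4.0, 4001)
        y = np.clip(10.0 * (1 - np.abs(t - 2.0)), 0, None)
        amp, hw = peak_halfwidth(t, y)
        assert amp == pytest.approx(10.0, rel=1e-3)
        assert hw == pytest.approx(1.0, abs=2e-3)

    def test_gaussian_closed_form(self):
        t = np.linspace(0.0, 20.0, 8001)
        sigma = 1.3
        _, hw = peak_halfwidth(t, 5.0 * np.exp(-0.5 * ((t - 10) / sigma) ** 2))
        assert hw == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)),
                                   rel=1e-4)

    def test_negative_polarity(self):
        t = np.linspace(0.0, 10.0, 2001)
        y = -8.0 * np.exp(-0.5 * ((t - 5) / 0.7) ** 2)
        amp, hw = peak_halfwidth(t, y)
        assert amp == pytest.approx(-8.0, rel=1e-3)
        assert hw > 0

    def test_matches_dense_resampling_oracle(self, rng):
        for _ in range(5):
            center = rng.uniform(4, 6)
            sig = rng.uniform(0.3, 1.5)
            amp0 = rng.uniform(2, 20)
            t = np.linspace(0.0, 10.0, 501)       # coarse grid
            y = amp0 * np.exp(-0.5 * ((t - center) / sig) ** 2)
            _, hw = peak_halfwidth(t, y)
            td = np.linspace(0.0, 10.0, 200001)   # dense oracle
            yd = amp0 * np.exp(-0.5 * ((td - center) / sig) ** 2)
            above = td[yd >= amp0 / 2]
            assert hw == pytest.approx(above[-1] - above[0], rel=5e-3)

    def test_no_crossing_raises(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.raises(ValueError):
            peak_halfwidth(t, np.linspace(0, 1, 100))  # monotone ramp
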