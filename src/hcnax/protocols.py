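"""In-silico measurement protocols on the mossy-fiber cable model.

Every protocol mirrors its bench counterpart: input resistance and membrane
time constant from a −10 pA / 300 ms step, sag ratio from the peak and
steady-state deflection of a hyperpolarizing response, conduction velocity
from AP peak delays between interior boutons, train fidelity over a
frequency ladder with a −40 mV failure threshold, and the velocity /
NaV-availability curve as a function of the resting potential (set by
uniformly shifting the K-leak reversal, so each point is a true steady
state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cable_model import AxonModel, Stimulus, build_model, init_steady_state, \
    integrate
from .vclamp_analysis import fit_monoexp, peak_halfwidth

__all__ = [
    "InputResistanceResult",
    "SagResult",
    "VelocityResult",
    "TrainResult",
    "DEFAULT_STIM",
    "TRAIN_FREQUENCIES",
    "measure_input_resistance",
    "measure_sag",
    "measure_velocity",
    "run_train",
    "max_failure_free_frequency",
    "velocity_vs_resting",
]

#: suprathreshold stimulus used for AP/velocity protocols (at the WM end,
#: emulating white-matter stimulation)
DEFAULT_STIM = {"site": "wm_end", "duration": 0.2, "amplitude": 2000.0}

#: frequency ladder (Hz) of the high-frequency train protocol
TRAIN_FREQUENCIES = (100, 200, 333, 500, 750, 1000, 1111, 1666)

#: peak threshold (mV) below which a stimulus counts as a propagation failure
FAILURE_THRESHOLD = -40.0


@dataclass(frozen=True)
class InputResistanceResult:
    r_in: float          # MΩ
    tau_m: float         # ms
    v_rest: float        # mV
    v_steady: float      # mV
    steady: bool = True  # False if the response had not plateaued


@dataclass(frozen=True)
class SagResult:
    v_rest: float
    v_peak: float
    v_steady: float
    sag_ratio: float
    distinct_peak: bool = True


@dataclass(frozen=True)
class VelocityResult:
    velocity: float      # m/s
    site_a: int
    site_b: int
    t_peak_a: float      # ms
    t_peak_b: float
    distance: float      # µm


@dataclass(frozen=True)
class TrainResult:
    frequency: float
    n_stimuli: int
    failures: int
    delays: np.ndarray        # ms, stimulus-to-peak, NaN for failures
    amplitudes: np.ndarray    # mV, NaN for failures
    half_durations: np.ndarray


def _equilibrated(model: AxonModel) -> AxonModel:
    m = model.copy()
    if not m.equilibrated:
        init_steady_state(m)
    return m


def _refine_peak(t: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """3-point quadratic refinement of a sampled peak (time, value)."""
    if idx <= 0 or idx >= len(t) - 1:
        return float(t[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(t[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    dt = t[idx + 1] - t[idx]
    return float(t[idx] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def measure_input_resistance(
    model_or_trace,
    i_step: float = -10.0,
    t_step: float = 300.0,
    *,
    step_window: tuple[float, float] | None = None,
    dt: float = 0.1,
    record_site=("bouton", 8),
) -> InputResistanceResult:
    """Apparent input resistance and membrane time constant.

    From a model: inject ``i_step`` pA for ``t_step`` ms at a central bouton
    and read the voltage there (r_in from the voltage at the end of the
    step, tau_m from a mono-exponential fit of the initial relaxation).
    From a trace: pass ``(t, v)`` arrays plus ``step_window=(t0, t1)``.
    """
    if isinstance(model_or_trace, AxonModel):
        m = _equilibrated(model_or_trace)
        site = m.site_index(record_site)
        v_rest = float(m.vm[site])
        onset = 10.0
        sim = integrate(
            m, [Stimulus(site, onset, t_step, i_step)],
            dt=dt, t_end=onset + t_step + 50.0,
            record=[site], record_currents=False,
        )
        t, v = sim.t, sim.vm[0]
        t0, t1 = onset, onset + t_step
    else:
        t, v = (np.asarray(a, float) for a in model_or_trace)
        if step_window is None:
            raise ValueError("step_window required for trace input")
        t0, t1 = step_window
        v_rest = float(np.mean(v[t < t0])) if np.any(t < t0) else float(v[0])

    in_step = (t >= t0) & (t < t1)
    if not in_step.any():
        raise ValueError("step window outside trace")
    tail = in_step & (t >= t1 - min(50.0, 0.2 * (t1 - t0)))
    v_steady = float(np.mean(v[tail]))
    # steadiness check: drift over the last 50 ms of the step
    slope = np.polyfit(t[tail], v[tail], 1)[0]
    steady = abs(slope) * 50.0 < 0.05 * max(abs(v_steady - v_rest), 1e-9)

    r_in = (v_steady - v_rest) / i_step * 1e3   # mV/pA → MΩ
    fit = fit_monoexp(t[in_step], None, v[in_step])
    tau_m = fit.tau if fit.ok else float("nan")
    return InputResistanceResult(r_in=float(r_in), tau_m=float(tau_m),
                                 v_rest=v_rest, v_steady=v_steady,
                                 steady=bool(steady))


def measure_sag(t, v, step_window: tuple[float, float], *,
                convention: str = "steady_over_peak") -> SagResult:
    """Sag ratio of a hyperpolarizing voltage response.

    Default convention: steady-state deflection divided by peak deflection,
    so a response that relaxes halfway back gives 0.5 and a sag-free
    response gives ~1.  ``convention="one_minus"`` returns the complement.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    t0, t1 = step_window
    pre = t < t0
    v_rest = float(np.mean(v[pre])) if pre.any() else float(v[0])
    in_step = (t >= t0) & (t < t1)
    if not in_step.any():
        raise ValueError("step window outside trace")
    vs, ts = v[in_step], t[in_step]
    ipk = int(np.argmin(vs))
    v_peak = float(vs[ipk])
    v_steady = float(np.mean(vs[ts >= t1 - 0.1 * (t1 - t0)]))
    peak_defl = v_peak - v_rest
    steady_defl = v_steady - v_rest
    distinct = ipk < 0.9 * len(vs) and (v_peak < v_steady - 1e-9)
    if peak_defl == 0:
        raise ValueError("no hyperpolarizing deflection")
    ratio = steady_defl / peak_defl if distinct else 1.0
    if convention == "one_minus":
        ratio = 1.0 - ratio
    return SagResult(v_rest=v_rest, v_peak=v_peak, v_steady=v_steady,
                     sag_ratio=float(ratio), distinct_peak=bool(distinct))


def measure_velocity(
    model: AxonModel,
    stim: dict | None = None,
    site_a=("bouton", 5),
    site_b=("bouton", 12),
    *,
    dt: float = 0.0125,
    t_end: float = 15.0,
) -> VelocityResult:
    """Conduction velocity from the AP peak delay between two boutons.

    Peak times are refined by 3-point quadratic interpolation so velocity
    is insensitive to the dt grid.  Raises if either site fails to produce
    an AP (> 0 mV peak).
    """
    cfg = dict(DEFAULT_STIM, **(stim or {}))
    m = _equilibrated(model)
    ia, ib = m.site_index(site_a), m.site_index(site_b)
    sim = integrate(
        m, [Stimulus(cfg["site"], 1.0, cfg["duration"], cfg["amplitude"])],
        dt=dt, t_end=t_end, record=[ia, ib], record_currents=False,
    )
    peaks = []
    for row in sim.vm:
        idx = int(np.argmax(row))
        if row[idx] <= 0.0:
            raise RuntimeError(
                f"no AP at recording site (peak {row[idx]:.1f} mV)")
        peaks.append(_refine_peak(sim.t, row, idx)[0])
    ta, tb = peaks
    dist = abs(float(m.position[ib] - m.position[ia]))
    delay = tb - ta
    if delay <= 0:
        raise RuntimeError("non-orthodromic peak order")
    velocity = dist / delay * 1e-3   # µm/ms → m/s
    return VelocityResult(velocity=velocity, site_a=ia, site_b=ib,
                          t_peak_a=ta, t_peak_b=tb, distance=dist)


def run_train(
    model: AxonModel,
    frequency: float,
    n: int = 20,
    stim: dict | None = None,
    *,
    record_site=("bouton", 12),
    dt: float = 0.0125,
) -> TrainResult:
    """Stimulus-train fidelity at a distal bouton.

    APs whose peak stays at or below −40 mV count as failures; delays,
    amplitudes and half-durations are reported for the successes only
    (NaN elsewhere).
    """
    if not 0 < frequency <= 2000:
        raise ValueError("frequency must be in (0, 2000] Hz")
    from scipy.signal import find_peaks

    cfg = dict(DEFAULT_STIM, **(stim or {}))
    m = _equilibrated(model)
    site = m.site_index(record_site)
    v_rest = float(m.vm[site])
    period = 1000.0 / frequency
    onset0 = 1.0
    stims = [Stimulus(cfg["site"], onset0 + k * period, cfg["duration"],
                      cfg["amplitude"]) for k in range(n)]
    t_end = onset0 + n * period + 5.0
    sim = integrate(m, stims, dt=dt, t_end=t_end,
                    record=[site], record_currents=False)
    t, v = sim.t, sim.vm[0]

    # detect AP peaks over the whole trace, then match them to stimuli by
    # latency (propagation may exceed the inter-stimulus interval)
    min_dist = max(1, int(0.5 * period / dt))
    idx_peaks, _ = find_peaks(v, height=FAILURE_THRESHOLD, prominence=15.0,
                              distance=min_dist)
    peak_times = np.array([_refine_peak(t, v, int(j))[0] for j in idx_peaks])
    peak_vals = np.array([_refine_peak(t, v, int(j))[1] for j in idx_peaks])

    delays = np.full(n, np.nan)
    amps = np.full(n, np.nan)
    hwidths = np.full(n, np.nan)
    if peak_times.size:
        latency = peak_times[0] - onset0   # first stimulus sets the latency
        used = np.zeros(peak_times.size, bool)
        for k in range(n):
            expect = onset0 + k * period + latency
            cand = np.nonzero(~used)[0]
            if cand.size == 0:
                break
            j = cand[np.argmin(np.abs(peak_times[cand] - expect))]
            if abs(peak_times[j] - expect) > 0.6 * period:
                continue
            used[j] = True
            delays[k] = peak_times[j] - (onset0 + k * period)
            amps[k] = peak_vals[j] - v_rest
            w = (t >= peak_times[j] - 0.6 * period) & \
                (t <= peak_times[j] + 0.6 * period)
            try:
                _, hwidths[k] = peak_halfwidth(t[w], v[w], polarity="pos",
                                               baseline=v_rest)
            except ValueError:
                hwidths[k] = np.nan
    failures = int(np.isnan(delays).sum())
    return TrainResult(frequency=float(frequency), n_stimuli=n,
                       failures=failures, delays=delays, amplitudes=amps,
                       half_durations=hwidths)


def max_failure_free_frequency(model: AxonModel, *,
                               frequencies=TRAIN_FREQUENCIES, n: int = 20,
                               **kw) -> float:
    """Highest ladder frequency transmitted without failures."""
    best = 0.0
    for f in sorted(frequencies):
        res = run_train(model, f, n=n, **kw)
        if res.failures == 0:
            best = float(f)
    return best


def velocity_vs_resting(
    model: AxonModel,
    rest_targets,
    *,
    e_k_bounds: tuple[float, float] = (-130.0, -40.0),
    tol: float = 0.05,
) -> list[dict]:
    """Velocity and NaV availability as a function of the resting potential.

    The target resting potential is reached by uniformly shifting the
    K-leak reversal (bisection on e_K), so every point compares true steady
    states.  Returns one dict per reachable target with keys
    ``rest_target``, ``rest``, ``e_k``, ``velocity``, ``availability``,
    plus ``reached=False`` stubs for unreachable targets.
    """
    base = model
    out = []

    def rest_for_ek(e_k: float) -> tuple[float, AxonModel]:
        mem = replace(base.membrane, e_k=e_k)
        m = build_model(base.variant, geometry=base.geometry, membrane=mem,
                        densities=base.densities, kinetics=base.kinetics,
                        hcn_params=base.hcn_params)
        init_steady_state(m)
        return float(m.vm[m.site_index(("bouton", 8))]), m

    lo, hi = e_k_bounds
    r_lo, _ = rest_for_ek(lo)
    r_hi, _ = rest_for_ek(hi)
    for target in rest_targets:
        if not (r_lo - tol <= target <= r_hi + tol):
            out.append({"rest_target": float(target), "reached": False})
            continue
        a, b = lo, hi
        fa = r_lo - target
        m_mid = None
        for _ in range(60):
            mid = 0.5 * (a + b)
            r_mid, m_mid = rest_for_ek(mid)
            if abs(r_mid - target) < tol:
                break
            if (r_mid - target) * fa < 0:
                b = mid
            else:
                a, fa = mid, r_mid - target
        rest = float(m_mid.vm[m_mid.site_index(("bouton", 8))])
        availability = float(m_mid.kinetics.h_inf(rest))
        try:
            vel = measure_velocity(m_mid).velocity
        except RuntimeError:
            out.append({"rest_target": float(target), "rest": rest,
                        "reached": False})
            continue
        out.append({"rest_target": float(target), "rest": rest,
                    "e_k": float(m_mid.membrane.e_k), "velocity": vel,
                    "availability": availability, "reached": True})
    return out
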