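"""Seeded generators for every input class the analysis pipelines consume.

Each generator emulates the statistical structure of one experiment class
(tail-current step families, per-cell midpoint scatter, Hill-distributed
dose-response shifts, two-electrode CAP recordings with a programmed
velocity time-course, sag responses) and emits a
:class:`GeneratorManifest` with the exact parameters and ground truth, so
downstream recovery can be scored without external references and the
dataset can be regenerated bit-exactly.

Default scatter levels are calibrated to the recorded populations: per-cell
midpoint SD 4.8 mV (= SEM 0.8 mV × √36 for the 0 mM condition), sweep noise
2% of the largest I_h amplitude, dose-response SEM 1.2 mV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cap_analysis import SweepPair
from .hcn_kinetics import RateParams, steady_state, time_constant
from .vclamp_analysis import DoseResponsePoint, Sweep, hill_curve

__all__ = [
    "NoiseSpec",
    "GeneratorManifest",
    "VClampProtocol",
    "s_max_from_anchor",
    "gen_vclamp_dataset",
    "gen_cell_population",
    "gen_dose_response",
    "gen_cap_recording",
    "gen_sag_trace",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise level (trace units) and its seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class GeneratorManifest:
    """Everything needed to regenerate a dataset and score recovery."""

    generator: str
    parameters: dict
    seed: int
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=_jsonable, indent=2)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


@dataclass(frozen=True)
class VClampProtocol:
    """Step protocol of the I_h activation experiment (Fig-7 style)."""

    holding: float = -70.0
    step_min: float = -150.0
    step_max: float = -70.0
    step_increment: float = 10.0
    tail_v: float = -70.0
    step_start: float = 20.0        # ms
    step_duration: float = 1500.0   # long enough for slow gating to settle
    tail_duration: float = 300.0
    dt: float = 0.1                 # sample interval, ms (10 kHz)

    @property
    def steps(self) -> np.ndarray:
        return np.arange(self.step_max, self.step_min - 1e-9,
                         -abs(self.step_increment))


def _gate_trace(t, phases, p: RateParams, m0: float):
    """Piecewise-exact gate trajectory over (t_start, V) phases."""
    m = np.empty_like(t)
    m_cur = m0
    for k, (t0, v) in enumerate(phases):
        t1 = phases[k + 1][0] if k + 1 < len(phases) else t[-1] + 1.0
        sel = (t >= t0) & (t < t1)
        minf = float(steady_state(v, p))
        tau = float(time_constant(v, p))
        m[sel] = minf + (m_cur - minf) * np.exp(-(t[sel] - t0) / tau)
        m_cur = minf + (m_cur - minf) * np.exp(-(t1 - t0) / tau)
    return m


def gen_vclamp_dataset(
    p: RateParams,
    protocol: VClampProtocol = VClampProtocol(),
    *,
    g_max: float = 2.0,          # nS
    e_hcn: float = -23.3,
    noise_frac: float = 0.02,    # SD as a fraction of max |I_h|
    seed: int = 0,
) -> tuple[list[Sweep], GeneratorManifest]:
    """Family of I_h step sweeps generated from the HH gate.

    Currents are ``g_max · m(t) · (V − e_hcn)`` with the gate following its
    exact piecewise-exponential trajectory; Gaussian noise with SD equal to
    ``noise_frac`` of the largest noise-free |I_h| is added throughout.
    """
    rng = np.random.default_rng(seed)
    pr = protocol
    t = np.arange(0.0, pr.step_start + pr.step_duration + pr.tail_duration,
                  pr.dt)
    tail_start = pr.step_start + pr.step_duration
    m_hold = float(steady_state(pr.holding, p))
    clean, vcmds = [], []
    for v_step in pr.steps:
        phases = [(0.0, pr.holding), (pr.step_start, v_step),
                  (tail_start, pr.tail_v)]
        m = _gate_trace(t, phases, p, m_hold)
        v_cmd = np.full_like(t, pr.holding)
        v_cmd[(t >= pr.step_start) & (t < tail_start)] = v_step
        v_cmd[t >= tail_start] = pr.tail_v
        clean.append(g_max * m * (v_cmd - e_hcn))
        vcmds.append(v_cmd)
    sd = noise_frac * max(np.max(np.abs(c)) for c in clean)
    sweeps = []
    for v_step, i_clean, v_cmd in zip(pr.steps, clean, vcmds):
        i = i_clean + rng.normal(0.0, sd, size=t.size) if sd > 0 else i_clean
        sweeps.append(Sweep(t, i, v_cmd, meta={
            "step_mV": float(v_step), "holding_mV": pr.holding,
            "tail_mV": pr.tail_v, "step_start_ms": pr.step_start,
            "tail_start_ms": tail_start,
        }))
    manifest = GeneratorManifest(
        generator="vclamp_dataset",
        parameters={"protocol": asdict(pr), "g_max": g_max, "e_hcn": e_hcn,
                    "noise_frac": noise_frac, "noise_sd": sd},
        seed=seed,
        truth={"a": p.a, "v_half": p.v_half, "v_alpha": p.v_alpha,
               "v_beta": p.v_beta, "rate_unit": p.rate_unit},
    )
    return sweeps, manifest


def gen_cell_population(
    true_v_half: float = -103.3,
    cell_sd: float = 4.8,
    n_cells: int = 36,
    *,
    slope: float = 9.0,
    a: float = 6.907,
    protocol: VClampProtocol = VClampProtocol(),
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[list[list[Sweep]], GeneratorManifest]:
    """Per-cell tail-current datasets with scattered Boltzmann midpoints.

    Per-cell midpoints are Normal(true_v_half, cell_sd); each cell's gate
    has a symmetric rate pair (Valpha = Vbeta = 2·slope), so its
    steady-state curve is a Boltzmann with the requested slope factor.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    midpoints = true_v_half + cell_sd * rng.standard_normal(n_cells)
    cells = []
    for i, vh in enumerate(midpoints):
        p = RateParams(a=a, v_half=float(vh), v_alpha=2 * slope,
                       v_beta=2 * slope, label=f"cell{i:02d}")
        sweeps, _ = gen_vclamp_dataset(
            p, protocol, noise_frac=noise_frac,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        cells.append(sweeps)
    manifest = GeneratorManifest(
        generator="cell_population",
        parameters={"true_v_half": true_v_half, "cell_sd": cell_sd,
                    "n_cells": n_cells, "slope": slope,
                    "noise_frac": noise_frac},
        seed=seed,
        truth={"midpoints": midpoints},
    )
    return cells, manifest


def s_max_from_anchor(shift_at: float, conc_at: float, ec50: float,
                      h: float = 1.0) -> float:
    """Maximal Hill shift implied by one anchored (conc, shift) pair."""
    ch = conc_at ** h
    return shift_at * (ch + ec50 ** h) / ch


def gen_dose_response(
    ec50: float = 40.4,
    s_max: float | None = None,
    h: float = 1.0,
    concs=(30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0),
    *,
    sem: float = 1.2,
    seed: int = 0,
) -> tuple[list[DoseResponsePoint], GeneratorManifest]:
    """Mean ΔV½ shifts on a Hill curve with Gaussian scatter.

    ``s_max`` defaults to the value anchored so the 1 mM point equals a
    17 mV shift (≈ 17.69 mV for h = 1, EC50 40.4 µM).
    """
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be > 0")
    if s_max is None:
        s_max = s_max_from_anchor(17.0, 1000.0, ec50, h)
    rng = np.random.default_rng(seed)
    mean = hill_curve(np.asarray(concs, float), ec50, s_max, h)
    noisy = mean + (sem * rng.standard_normal(len(concs)) if sem > 0 else 0.0)
    points = [DoseResponsePoint(conc=float(c), shift=float(s), sem=sem, n=10)
              for c, s in zip(concs, noisy)]
    manifest = GeneratorManifest(
        generator="dose_response",
        parameters={"concs": list(concs), "sem": sem},
        seed=seed,
        truth={"ec50": ec50, "s_max": s_max, "h": h},
    )
    return points, manifest


def _cap_waveform(t, t_arrival, width: float = 0.6):
    """Biphasic difference-of-Gaussians CAP waveform (arbitrary units)."""
    x = t - t_arrival
    return (np.exp(-0.5 * (x / width) ** 2)
            - 0.6 * np.exp(-0.5 * ((x - 0.9 * width) / (1.4 * width)) ** 2))


def gen_cap_recording(
    baseline_velocity: float = 0.30,        # m/s
    effect_pct: float = -8.0,
    onset_min: float = 0.0,
    tau_min: float = 3.0,
    rundown_pct_per_20min: float = 0.0,
    *,
    distances: tuple[float, float] = (300.0, 1200.0),   # µm from stimulus
    timestamps=None,                        # min
    noise: NoiseSpec = NoiseSpec(),
    sweep_ms: float = 12.0,
    dt: float = 0.01,
    seed: int = 0,
) -> tuple[list[SweepPair], GeneratorManifest]:
    """Two-electrode CAP experiment with a programmed velocity time-course.

    The instantaneous velocity follows an exponential drug onset of
    ``effect_pct`` (time constant ``tau_min``) on top of a linear rundown;
    each electrode sees the same waveform delayed by distance/velocity.
    """
    if baseline_velocity <= 0:
        raise ValueError("baseline velocity must be > 0")
    d1, d2 = distances
    if not 0 < d1 < d2:
        raise ValueError("need 0 < proximal distance < distal distance")
    if timestamps is None:
        timestamps = np.arange(-10.0, 30.0 + 1e-9, 1.0)
    rng = np.random.default_rng(seed if noise.sd > 0 else 0)
    t = np.arange(0.0, sweep_ms, dt)
    pairs, v_true = [], []
    for ts in np.asarray(timestamps, float):
        drug = 0.0
        if ts > onset_min:
            drug = (effect_pct / 100.0) * (1.0 - np.exp(-(ts - onset_min)
                                                        / tau_min))
        rundown = (rundown_pct_per_20min / 100.0) * max(ts, 0.0) / 20.0
        v = baseline_velocity * (1.0 + drug) * (1.0 - rundown)
        v_true.append(v)
        v_um_ms = v * 1e3
        vp = _cap_waveform(t, d1 / v_um_ms)
        vd = _cap_waveform(t, d2 / v_um_ms)
        if noise.sd > 0:
            vp = vp + rng.normal(0, noise.sd, t.size)
            vd = vd + rng.normal(0, noise.sd, t.size)
        pairs.append(SweepPair(t=t, v_prox=vp, v_dist=vd,
                               distance_delta=d2 - d1, timestamp=float(ts)))
    manifest = GeneratorManifest(
        generator="cap_recording",
        parameters={"baseline_velocity": baseline_velocity,
                    "effect_pct": effect_pct, "onset_min": onset_min,
                    "tau_min": tau_min,
                    "rundown_pct_per_20min": rundown_pct_per_20min,
                    "distances": list(distances), "noise_sd": noise.sd},
        seed=seed,
        truth={"velocity_by_timestamp": np.asarray(v_true),
               "timestamps": np.asarray(timestamps, float)},
    )
    return pairs, manifest


def gen_sag_trace(
    rest: float = -80.0,
    r_in: float = 800.0,         # MΩ
    tau: float = 20.0,           # ms, fast (charging) time constant
    *,
    sag_ratio: float = 1.0,      # programmed steady/peak deflection ratio
    sag_tau: float = 60.0,       # ms, slow (sag relaxation) time constant
    i_step: float = -10.0,       # pA
    pre_ms: float = 100.0,
    step_ms: float = 500.0,
    post_ms: float = 200.0,
    dt: float = 0.5,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GeneratorManifest]:
    """Current-clamp step response with an optional programmed sag.

    The steady deflection is R_in·I; with ``sag_ratio < 1`` the response
    first reaches a deeper peak deflection (steady/sag_ratio) and relaxes
    back with ``sag_tau``.  Returns ``(t, v, manifest)``.
    """
    if not 0 < sag_ratio <= 1:
        raise ValueError("sag_ratio must be in (0, 1]")
    steady = r_in * i_step * 1e-3                 # MΩ·pA → mV
    peak = steady / sag_ratio
    t = np.arange(0.0, pre_ms + step_ms + post_ms, dt)
    v = np.full_like(t, rest)
    ts = t - pre_ms
    in_step = (ts >= 0) & (ts < step_ms)
    x = ts[in_step]
    v[in_step] = rest + peak * (1 - np.exp(-x / tau)) \
        - (peak - steady) * (1 - np.exp(-x / sag_tau))
    after = ts >= step_ms
    v_end = v[in_step][-1] if in_step.any() else rest
    v[after] = rest + (v_end - rest) * np.exp(-(ts[after] - step_ms) / tau)
    # achieved extremum of the clean trace (fast and slow phases overlap,
    # so the realized peak is slightly shallower than the programmed one)
    v_peak_clean = float(v[in_step].min())
    achieved_ratio = (v_end - rest) / (v_peak_clean - rest)
    if noise.sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise.sd, t.size)
    manifest = GeneratorManifest(
        generator="sag_trace",
        parameters={"rest": rest, "r_in": r_in, "tau": tau,
                    "sag_tau": sag_tau, "i_step": i_step,
                    "noise_sd": noise.sd,
                    "step_window_ms": [pre_ms, pre_ms + step_ms]},
        seed=seed,
        truth={"steady_deflection": steady, "peak_deflection": peak,
               "sag_ratio": sag_ratio,
               "achieved_peak": v_peak_clean,
               "achieved_steady": float(v_end),
               "achieved_sag_ratio": float(achieved_ratio)},
    )
    return t, v, manifest
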