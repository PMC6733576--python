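"""Voltage-clamp analysis for I_h and Na-current recordings.

Covers the measurement pipeline around the HCN kinetics model:

* tail-current activation-curve extraction from step families,
* mono-exponential fits of activation/deactivation kinetics,
* reversal potential from fast voltage ramps (three-line intersection),
* Hill dose-response fit of the cAMP-induced midpoint shift,
* endogenous-cAMP estimation from the fit's 68% confidence band,
* peak amplitude / half-duration metrics for subtracted currents.

Sweeps are plain time-series containers (uniform time base); CSV I/O helpers
mirror the column conventions used by the synthetic generators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .hcn_kinetics import ActivationPoint

__all__ = [
    "Sweep",
    "RampIV",
    "DoseResponsePoint",
    "HillFit",
    "EndogenousEstimate",
    "MonoExpFit",
    "extract_tail_activation",
    "fit_monoexp",
    "reversal_from_ramps",
    "hill_curve",
    "fit_hill",
    "estimate_endogenous_camp",
    "peak_halfwidth",
]


@dataclass(frozen=True)
class Sweep:
    """One voltage-clamp sweep on a uniform time base.

    ``t`` in ms, ``i`` in pA, ``v_cmd`` the command-voltage trace in mV.
    ``meta`` carries protocol labels (holding/step/tail voltages, drug).
    """

    t: np.ndarray
    i: np.ndarray
    v_cmd: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, i, v = (np.asarray(x, float) for x in (self.t, self.i, self.v_cmd))
        if not (t.shape == i.shape == v.shape):
            raise ValueError("t, i, v_cmd must have equal length")
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time base must be uniform")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "v_cmd", v)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t, "i_pA": self.i, "v_mV": self.v_cmd})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "Sweep":
        return cls(df["t_ms"].to_numpy(), df["i_pA"].to_numpy(),
                   df["v_mV"].to_numpy(), meta=dict(meta or {}))


@dataclass(frozen=True)
class RampIV:
    """Leak-subtracted I-V along a fast voltage ramp."""

    v: np.ndarray
    i: np.ndarray
    activation_v: float

    def __post_init__(self) -> None:
        v = np.asarray(self.v, float)
        dv = np.diff(v)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("ramp voltage must be strictly monotone")
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "i", np.asarray(self.i, float))


@dataclass(frozen=True)
class DoseResponsePoint:
    """Mean midpoint shift at one intracellular cAMP concentration."""

    conc: float          # µM
    shift: float         # mV, relative to 0 cAMP
    sem: float = 0.0     # mV
    n: int = 1

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValueError("concentration must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class HillFit:
    """Hill fit of midpoint shift vs cAMP concentration.

    shift(c) = s_max * c^h / (c^h + ec50^h); at c = ec50 the shift is
    s_max/2 by construction.
    """

    ec50: float
    s_max: float
    h: float
    covariance: np.ndarray = field(repr=False)

    def __call__(self, conc):
        return hill_curve(conc, self.ec50, self.s_max, self.h)


@dataclass(frozen=True)
class EndogenousEstimate:
    """Endogenous cAMP concentration inferred from a measured shift."""

    conc_point: float
    ci68_low: float
    ci68_high: float

    def __post_init__(self) -> None:
        if not (self.ci68_low <= self.conc_point <= self.ci68_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class MonoExpFit:
    tau: float
    amplitude: float
    offset: float
    ok: bool = True


# ---------------------------------------------------------------------------


def extract_tail_activation(
    sweeps: Sequence[Sweep],
    tail_window: tuple[float, float] | None = None,
    *,
    settle: float = 0.5,
    width: float = 2.0,
    baseline: str = "zero",
) -> list[ActivationPoint]:
    """Tail-current activation points from a conditioning-step family.

    Each sweep must carry ``meta`` keys ``step_mV`` (conditioning voltage)
    and ``tail_start_ms`` (end of the conditioning pulse).  The tail
    amplitude is the mean current over ``tail_window`` (default: 2 ms
    starting 0.5 ms after the step, skipping capacitive settling),
    normalized to the largest amplitude across sweeps — i.e. to the most
    activated conditioning step, without fitting a plateau.

    ``baseline="zero"`` (default) treats the sweeps as blocker-subtracted:
    zero current means no channel current, so the tail amplitude is
    proportional to the absolute open fraction reached during the step.
    ``baseline="pre_step"`` subtracts the pre-step holding current instead
    (raw, unsubtracted recordings); this under-reports activation when the
    holding potential itself activates the channel.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    if baseline not in ("zero", "pre_step"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    amps, volts = [], []
    for sw in sweeps:
        if "step_mV" not in sw.meta or "tail_start_ms" not in sw.meta:
            raise ValueError("sweep meta must contain step_mV and tail_start_ms")
        t0 = float(sw.meta["tail_start_ms"])
        if tail_window is None:
            win = (t0 + settle, t0 + settle + width)
        else:
            win = (t0 + tail_window[0], t0 + tail_window[1])
        mask = (sw.t >= win[0]) & (sw.t < win[1])
        if not mask.any():
            raise ValueError("tail window outside sweep")
        if baseline == "zero":
            base = 0.0
        else:
            pre = sw.i[sw.t < float(sw.meta.get("step_start_ms", t0))
                       ][: max(1, int(1.0 / sw.dt))]
            base = float(np.mean(pre))
        amps.append(float(np.mean(sw.i[mask])) - base)
        volts.append(float(sw.meta["step_mV"]))
    amps = np.asarray(amps)
    scale = amps[np.argmax(np.abs(amps))]
    if scale == 0:
        raise ValueError("zero maximal tail amplitude; cannot normalize")
    return [ActivationPoint(v=v, activation=float(a / scale))
            for v, a in zip(volts, amps)]


def fit_monoexp(sweep_or_t, window=None, y=None) -> MonoExpFit:
    """Fit ``a*exp(-t/tau) + c`` to a trace segment.

    Accepts either a :class:`Sweep` plus a (t0, t1) window, or explicit
    ``(t, window, y)`` arrays.  A non-decaying (flat or non-exponential)
    segment yields ``ok=False`` rather than a spurious time constant.
    """
    if isinstance(sweep_or_t, Sweep):
        t, yy = sweep_or_t.t, sweep_or_t.i
    else:
        t = np.asarray(sweep_or_t, float)
        yy = np.asarray(y, float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, yy = t[m], yy[m]
    if t.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    ts = t - t[0]
    c0 = yy[-1]
    a0 = yy[0] - c0
    if abs(a0) < 1e-12 * max(1.0, abs(c0)) or np.ptp(yy) == 0:
        return MonoExpFit(tau=np.nan, amplitude=0.0, offset=float(c0), ok=False)
    tau0 = max(ts[-1] / 5.0, ts[1])

    def _model(tt, a, tau, c):
        return a * np.exp(-np.clip(tt / tau, -700.0, 700.0)) + c

    try:
        with np.errstate(over="ignore"):
            popt, _ = curve_fit(_model, ts, yy, p0=[a0, tau0, c0],
                                maxfev=20000)
    except RuntimeError:
        return MonoExpFit(tau=np.nan, amplitude=np.nan, offset=np.nan, ok=False)
    a, tau, c = popt
    if tau <= 0 or not np.isfinite(tau):
        return MonoExpFit(tau=float(tau), amplitude=float(a), offset=float(c),
                          ok=False)
    return MonoExpFit(tau=float(tau), amplitude=float(a), offset=float(c))


def reversal_from_ramps(ramps: Sequence[RampIV], *,
                        slope_tol: float = 1e-9) -> float:
    """Reversal potential from three ramp I-V relations.

    Fits a line to each I-V, intersects the three lines pairwise, and
    returns the mean of the three intersection voltages.  Near-parallel
    pairs (slope difference below ``slope_tol``) raise with the offending
    pair named.
    """
    ramps = list(ramps)
    if len(ramps) != 3:
        raise ValueError("exactly three ramps are required")
    lines = []
    for r in ramps:
        slope, icpt = np.polyfit(r.v, r.i, 1)
        lines.append((float(slope), float(icpt)))
    xs = []
    for (ia, ib) in itertools.combinations(range(3), 2):
        (s1, c1), (s2, c2) = lines[ia], lines[ib]
        if abs(s1 - s2) < slope_tol:
            raise ValueError(
                f"ramps {ia} and {ib} are near-parallel "
                f"(slope difference {abs(s1 - s2):.3g})"
            )
        xs.append((c2 - c1) / (s1 - s2))
    return float(np.mean(xs))


def hill_curve(conc, ec50: float, s_max: float, h: float):
    """Hill dose-response s_max * c^h / (c^h + ec50^h)."""
    c = np.asarray(conc, float)
    ch = np.power(c, h)
    return s_max * ch / (ch + ec50 ** h)


def fit_hill(points: Sequence[DoseResponsePoint], *,
             fix_h: float | None = None) -> HillFit:
    """Weighted least-squares Hill fit of shift vs concentration.

    Weights are 1/sem² where SEMs are present (unit weights otherwise).
    ``fix_h`` pins the Hill coefficient (e.g. to 1) and fits only
    (ec50, s_max); the returned covariance is padded with zeros for h.
    """
    pts = list(points)
    n_free = 2 if fix_h is not None else 3
    if len({p.conc for p in pts}) < max(3, n_free):
        raise ValueError("need at least 3 distinct concentrations "
                         "(and no fewer than the number of free parameters)")
    c = np.array([p.conc for p in pts])
    y = np.array([p.shift for p in pts])
    sems = np.array([p.sem for p in pts])
    sigma = sems if np.all(sems > 0) else None

    ec0 = float(np.exp(np.interp(0.5 * y.max(), y[np.argsort(c)],
                                 np.log(np.sort(c)))))
    s0 = float(y.max())
    if fix_h is None:
        popt, pcov = curve_fit(
            lambda cc, lec, s, hh: hill_curve(cc, np.exp(lec), s, hh),
            c, y, p0=[np.log(ec0), s0, 1.0], sigma=sigma,
            absolute_sigma=sigma is not None, maxfev=40000,
        )
        lec, s_max, h = popt
        # delta method: var(ec50) = ec50^2 var(log ec50)
        Jt = np.diag([math.exp(lec), 1.0, 1.0])
        cov = Jt @ pcov @ Jt
    else:
        popt, pcov = curve_fit(
            lambda cc, lec, s: hill_curve(cc, np.exp(lec), s, fix_h),
            c, y, p0=[np.log(ec0), s0], sigma=sigma,
            absolute_sigma=sigma is not None, maxfev=40000,
        )
        lec, s_max = popt
        h = fix_h
        Jt = np.diag([math.exp(lec), 1.0])
        cov2 = Jt @ pcov @ Jt
        cov = np.zeros((3, 3))
        cov[:2, :2] = cov2
    return HillFit(ec50=float(math.exp(lec)), s_max=float(s_max),
                   h=float(h), covariance=np.asarray(cov))


def estimate_endogenous_camp(
    fit: HillFit,
    shift: float,
    shift_sem: float,
    *,
    grid: tuple[float, float, int] = (1e-1, 1e5, 400),
) -> EndogenousEstimate:
    """Concentration whose Hill-curve shift matches an observed shift.

    The point estimate inverts the mean Hill curve.  The 68% interval spans
    the extreme grid concentrations where the fit's 68% confidence band
    (first-order propagation of the parameter covariance over a log-spaced
    grid) overlaps ``shift ± shift_sem``.  If the overlap reaches a grid
    edge the bound is reported at that edge (open-ended).
    """
    if not (0 < shift < fit.s_max):
        raise ValueError("shift must lie strictly between 0 and s_max")
    point = fit.ec50 * (shift / (fit.s_max - shift)) ** (1.0 / fit.h)

    lo, hi, npts = grid
    c = np.logspace(math.log10(lo), math.log10(hi), int(npts))
    mean = fit(c)
    # gradient of the Hill curve wrt (ec50, s_max, h)
    ec, s, h = fit.ec50, fit.s_max, fit.h
    ch, ech = np.power(c, h), ec ** h
    denom = (ch + ech) ** 2
    d_ec = -s * ch * h * ec ** (h - 1.0) / denom
    d_s = ch / (ch + ech)
    d_h = s * ech * ch * (np.log(c) - math.log(ec)) / denom
    G = np.stack([d_ec, d_s, d_h], axis=1)
    band_sd = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G,
                                           fit.covariance, G), 0.0))
    overlap = (mean - band_sd <= shift + shift_sem) & \
              (mean + band_sd >= shift - shift_sem)
    if not overlap.any():
        lo_b = hi_b = point
    else:
        idx = np.nonzero(overlap)[0]
        lo_b, hi_b = float(c[idx[0]]), float(c[idx[-1]])
    lo_b = min(lo_b, point)
    hi_b = max(hi_b, point)
    return EndogenousEstimate(conc_point=float(point),
                              ci68_low=lo_b, ci68_high=hi_b)


def peak_halfwidth(t, y, *, polarity: str = "auto",
                   baseline: float | None = None) -> tuple[float, float]:
    """Peak amplitude and half-duration of a single-peaked trace.

    Amplitude is baseline-to-extremum (baseline defaults to the first
    sample); half-duration is the width at 50% amplitude with linear
    interpolation between samples.  Raises if the trace never crosses the
    half-amplitude level on both flanks.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    base = float(y[0]) if baseline is None else float(baseline)
    dev = y - base
    if polarity == "auto":
        polarity = "pos" if abs(dev.max()) >= abs(dev.min()) else "neg"
    sig = dev if polarity == "pos" else -dev
    ipk = int(np.argmax(sig))
    amp = float(sig[ipk])
    if amp <= 0:
        raise ValueError("no peak above baseline")
    half = amp / 2.0

    def _cross(side):
        rng = range(ipk, 0, -1) if side == "left" else range(ipk, len(t) - 1)
        for j in rng:
            k = j - 1 if side == "left" else j + 1
            if (sig[j] - half) * (sig[k] - half) <= 0 and sig[j] != sig[k]:
                frac = (half - sig[j]) / (sig[k] - sig[j])
                return t[j] + frac * (t[k] - t[j])
        raise ValueError(f"no half-amplitude crossing on the {side} flank")

    width = float(_cross("right") - _cross("left"))
    signed_amp = amp if polarity == "pos" else -amp
    return signed_amp, width
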