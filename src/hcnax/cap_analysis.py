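"""Compound-action-potential (CAP) analysis.

Two extracellular electrodes at different distances along a fiber bundle
record the same propagating volley; conduction velocity is the electrode
separation divided by the delay between the CAP peaks.  Drug experiments
are summarized as baseline-normalized velocity time-courses and windowed
percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "SweepPair",
    "TimecourseResult",
    "PeakDelayResult",
    "WINDOW_PRESETS",
    "smooth_trace",
    "peak_delay",
    "normalize_timecourse",
    "window_change",
]

#: named analysis windows (min): baseline, the standard effect window, and
#: the early window used for fast-onset effects
WINDOW_PRESETS = {
    "baseline": (-5.0, 0.0),
    "effect": (10.0, 15.0),
    "fast": (1.0, 6.0),
}

#: post-stimulus interval (ms) excluded from peak search (stimulus artifact)
ARTIFACT_WINDOW_MS = 0.3


@dataclass(frozen=True)
class SweepPair:
    """Simultaneous proximal/distal CAP sweeps on a shared time grid."""

    t: np.ndarray             # ms
    v_prox: np.ndarray
    v_dist: np.ndarray
    distance_delta: float     # µm between the electrodes along the path
    timestamp: float = 0.0    # min relative to drug onset

    def __post_init__(self) -> None:
        t, vp, vd = (np.asarray(a, float)
                     for a in (self.t, self.v_prox, self.v_dist))
        if not (t.shape == vp.shape == vd.shape):
            raise ValueError("t, v_prox, v_dist must share a grid")
        if self.distance_delta <= 0:
            raise ValueError("distance_delta must be > 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v_prox", vp)
        object.__setattr__(self, "v_dist", vd)


@dataclass(frozen=True)
class TimecourseResult:
    times: np.ndarray
    velocity_norm: np.ndarray
    baseline_window: tuple[float, float]


@dataclass(frozen=True)
class PeakDelayResult:
    delay: float              # ms
    velocity: float           # m/s
    t_peak_prox: float
    t_peak_dist: float
    ambiguous: bool = False


def smooth_trace(t, v, lam: float | None = None):
    """Cubic smoothing-spline estimate of a noisy trace on its own grid.

    ``lam`` is the roughness penalty: 0 interpolates the data exactly,
    ``None`` selects the penalty by generalized cross-validation.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if t.size < 20:
        raise ValueError("need at least 20 samples to smooth")
    if lam is not None and lam == 0:
        return v.copy()
    spl = make_smoothing_spline(t, v, lam=lam)
    return spl(t)


def _dominant_peak(t, v, polarity):
    sig = v if polarity == "pos" else -v
    ipk = int(np.argmax(sig))
    # ambiguity: a second local maximum within 20% of the dominant amplitude
    interior = np.nonzero((sig[1:-1] >= sig[:-2]) & (sig[1:-1] > sig[2:]))[0] + 1
    amp = sig[ipk] - np.min(sig)
    rivals = [j for j in interior
              if j != ipk and sig[j] - np.min(sig) > 0.8 * amp]
    # quadratic sub-sample refinement
    if 0 < ipk < len(t) - 1:
        y0, y1, y2 = sig[ipk - 1], sig[ipk], sig[ipk + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        t_pk = t[ipk] + delta * (t[ipk + 1] - t[ipk])
    else:
        t_pk = t[ipk]
    return float(t_pk), bool(rivals)


def peak_delay(pair: SweepPair, *, polarity: str = "auto",
               artifact_ms: float = ARTIFACT_WINDOW_MS,
               stimulus_ms: float = 0.0,
               smoothing: float | None = 0.0) -> PeakDelayResult:
    """Peak delay between the two electrodes and the implied velocity.

    The first ``artifact_ms`` after the stimulus marker are excluded from
    the peak search.  ``smoothing`` is passed to :func:`smooth_trace`
    before peak picking (``None`` = GCV-selected penalty, 0 = raw traces);
    smoothing noisy recordings removes the peak-picking jitter that
    otherwise biases delay-derived velocities.  Swapping the electrodes
    flips the delay's sign; a second comparable local extremum flags the
    result as ambiguous.
    """
    mask = pair.t >= stimulus_ms + artifact_ms
    t = pair.t[mask]
    vp, vd = pair.v_prox[mask], pair.v_dist[mask]
    if smoothing is None or smoothing > 0:
        vp = smooth_trace(t, vp, lam=smoothing)
        vd = smooth_trace(t, vd, lam=smoothing)
    if polarity == "auto":
        dev = vp - np.median(vp)
        polarity = "pos" if abs(dev.max()) >= abs(dev.min()) else "neg"
    tp, amb_p = _dominant_peak(t, vp, polarity)
    td, amb_d = _dominant_peak(t, vd, polarity)
    delay = td - tp
    velocity = pair.distance_delta / delay * 1e-3 if delay != 0 else np.inf
    return PeakDelayResult(delay=float(delay), velocity=float(velocity),
                           t_peak_prox=tp, t_peak_dist=td,
                           ambiguous=amb_p or amb_d)


def normalize_timecourse(times, velocities,
                         baseline_window=WINDOW_PRESETS["baseline"],
                         ) -> TimecourseResult:
    """Divide a velocity time-course by its baseline-window mean."""
    times = np.asarray(times, float)
    velocities = np.asarray(velocities, float)
    t0, t1 = baseline_window
    base = (times >= t0) & (times <= t1)
    if base.sum() < 2:
        raise ValueError("baseline window must contain at least 2 points")
    scale = float(np.mean(velocities[base]))
    if scale == 0:
        raise ValueError("zero baseline velocity")
    return TimecourseResult(times=times, velocity_norm=velocities / scale,
                            baseline_window=(float(t0), float(t1)))


def window_change(tc: TimecourseResult,
                  window=WINDOW_PRESETS["effect"]) -> float:
    """Percent velocity change over a window, 100·(window mean − 1)."""
    t0, t1 = window
    sel = (tc.times >= t0) & (tc.times <= t1)
    if not sel.any():
        raise ValueError("empty analysis window")
    return float(100.0 * (np.mean(tc.velocity_norm[sel]) - 1.0))
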