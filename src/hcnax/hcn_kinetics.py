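"""Hodgkin-Huxley kinetics of the axonal HCN (h-current) activation gate.

The gate is a single first-order activation variable ``m`` obeying

    dm/dt = alpha(V) (1 - m) - beta(V) m

with voltage-dependent rates

    alpha(V) = A exp(-(V - V1/2) / Valpha)
    beta(V)  = A exp(+(V - V1/2) / Vbeta)

so that the steady state m_inf(V) = alpha/(alpha+beta) is a falling Boltzmann
with midpoint ``V1/2`` and effective slope k = (1/Valpha + 1/Vbeta)^-1, and
the time constant tau(V) = 1/(alpha+beta) is bell-shaped with its peak near
the midpoint.

Two calibrated parameter sets are shipped, one per intracellular cAMP
condition (0 mM and 1 mM); cAMP enters only through these discrete sets.

Units: voltages in mV.  The peak rate ``A`` is interpreted as per *second*
by default (giving tau(V1/2) ~ 72 ms, in the tens-of-milliseconds range of
measured I_h kinetics); a ``rate_unit`` switch selects a per-millisecond
reading.  ``time_constant`` always returns milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "RateParams",
    "BoltzmannFit",
    "ActivationPoint",
    "TauPoint",
    "HHFitResult",
    "CAMP_0MM",
    "CAMP_1MM",
    "alpha_rate",
    "beta_rate",
    "steady_state",
    "time_constant",
    "gate_step",
    "boltzmann",
    "effective_slope",
    "fit_boltzmann",
    "fit_hh",
]


@dataclass(frozen=True)
class RateParams:
    """Rate-function parameters of the HCN activation gate for one condition.

    Attributes
    ----------
    a : float
        Peak rate at the midpoint (both rates equal ``a`` at ``v_half``).
        Interpreted in ``rate_unit``.
    v_half : float
        Midpoint voltage (mV); ``steady_state(v_half) == 0.5`` identically.
    v_alpha, v_beta : float
        Voltage scales (mV) of the forward and backward rates; both > 0.
    label : str
        Condition tag, e.g. ``"0mM_cAMP"``.
    rate_unit : {"per_s", "per_ms"}
        Unit of ``a``; ``time_constant`` converts to ms accordingly.
    """

    a: float
    v_half: float
    v_alpha: float
    v_beta: float
    label: str = ""
    rate_unit: Literal["per_s", "per_ms"] = "per_s"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.v_alpha > 0 and self.v_beta > 0):
            raise ValueError("RateParams requires a > 0, v_alpha > 0, v_beta > 0")
        if self.rate_unit not in ("per_s", "per_ms"):
            raise ValueError(f"unknown rate_unit {self.rate_unit!r}")

    def with_label(self, label: str) -> "RateParams":
        return replace(self, label=label)


#: Calibrated gate parameters with cAMP-free intracellular solution.
CAMP_0MM = RateParams(a=6.907, v_half=-102.1, v_alpha=18.71, v_beta=21.73,
                      label="0mM_cAMP")
#: Calibrated gate parameters with 1 mM intracellular cAMP.
CAMP_1MM = RateParams(a=7.570, v_half=-87.31, v_alpha=31.46, v_beta=10.84,
                      label="1mM_cAMP")


def _check_v(v):
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    return v


def alpha_rate(v, p: RateParams):
    """Forward (opening) rate alpha(V) = A exp(-(V - V1/2)/Valpha).

    Strictly decreasing in V: hyperpolarization opens the gate.
    """
    v = _check_v(v)
    return p.a * np.exp(-(v - p.v_half) / p.v_alpha)


def beta_rate(v, p: RateParams):
    """Backward (closing) rate beta(V) = A exp(+(V - V1/2)/Vbeta)."""
    v = _check_v(v)
    return p.a * np.exp((v - p.v_half) / p.v_beta)


def steady_state(v, p: RateParams):
    """Steady-state open fraction m_inf(V) = alpha/(alpha+beta).

    Algebraically equal to 1/(1 + exp((V - V1/2)(1/Valpha + 1/Vbeta))),
    i.e. a falling Boltzmann with slope factor ``effective_slope(p)``.
    """
    v = _check_v(v)
    x = (v - p.v_half) * (1.0 / p.v_alpha + 1.0 / p.v_beta)
    return 1.0 / (1.0 + np.exp(x))


def effective_slope(p: RateParams) -> float:
    """Boltzmann slope factor k (mV) of the steady-state curve."""
    return 1.0 / (1.0 / p.v_alpha + 1.0 / p.v_beta)


def time_constant(v, p: RateParams):
    """Gate time constant tau(V) = 1/(alpha + beta), in milliseconds."""
    tau = 1.0 / (alpha_rate(v, p) + beta_rate(v, p))
    if p.rate_unit == "per_s":
        tau = tau * 1e3
    return tau


def gate_step(m, v, dt: float, p: RateParams):
    """Advance the gate by ``dt`` ms at fixed voltage, exactly.

    The gate ODE is linear at fixed V, so the update

        m' = m_inf + (m - m_inf) exp(-dt/tau)

    is exact for any step size and keeps m in [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("gate value must lie in [0, 1]")
    minf = steady_state(v, p)
    tau = time_constant(v, p)
    return minf + (m - minf) * np.exp(-dt / tau)


def boltzmann(v, v_half: float, k: float):
    """Falling Boltzmann 1/(1 + exp((V - V1/2)/k)); k > 0."""
    if k <= 0:
        raise ValueError("slope factor k must be > 0")
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v - v_half) / k))


# ---------------------------------------------------------------------------
# data points and fits


@dataclass(frozen=True)
class ActivationPoint:
    """One normalized tail-current activation point."""

    v: float                 # conditioning voltage, mV
    activation: float        # normalized tail amplitude, ~[0, 1]
    sem: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.activation):
            raise ValueError("activation must be finite")


@dataclass(frozen=True)
class TauPoint:
    """One measured gate time constant."""

    v: float                 # mV
    tau: float               # ms
    sem: float = 0.0
    kind: Literal["activation", "deactivation"] = "activation"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class BoltzmannFit:
    """Least-squares Boltzmann fit of an activation curve."""

    v_half: float
    k: float
    covariance: np.ndarray = field(repr=False)
    rss: float = 0.0

    def __call__(self, v):
        return boltzmann(v, self.v_half, self.k)


@dataclass(frozen=True)
class HHFitResult:
    """Result of the weighted global HH fit.

    ``ci68`` holds per-parameter 68% half-widths for (A, V1/2, Valpha,
    Vbeta), from the square roots of the diagonal of the inverse Hessian of
    the weighted SSE at the optimum (the convention the printed parameter
    CIs follow — no residual-variance scaling); NaN where the Hessian is
    singular.  ``ci68_scaled`` additionally scales the covariance by the
    reduced weighted SSE, the standard nonlinear-least-squares estimate
    whose nominal 68% coverage holds under the data's actual noise level.
    """

    params: RateParams
    ci68: np.ndarray = field(repr=False)
    weighted_sse: float = 0.0
    converged: bool = True
    ci68_scaled: np.ndarray | None = field(default=None, repr=False)


def fit_boltzmann(points: Sequence[ActivationPoint]) -> BoltzmannFit:
    """Fit a falling Boltzmann to activation points.

    Raises ``ValueError`` on fewer than 4 points or on a degenerate input
    (activations that never cross the transition).
    """
    pts = list(points)
    if len(pts) < 4:
        raise ValueError("need at least 4 activation points")
    v = np.array([q.v for q in pts], dtype=float)
    y = np.array([q.activation for q in pts], dtype=float)
    if np.ptp(y) < 0.2:
        raise ValueError(
            "degenerate activation data: dynamic range "
            f"{np.ptp(y):.3g} < 0.2, no transition to fit"
        )
    # initial midpoint from the half-crossing of the (monotonized) curve
    order = np.argsort(v)
    vs, ys = v[order], y[order]
    half = 0.5 * (ys.min() + ys.max())
    cross = np.nonzero(np.diff(np.sign(ys - half)))[0]
    v0 = vs[cross[0]] if cross.size else float(np.median(vs))
    k0 = max(np.ptp(vs) / 10.0, 1.0)
    popt, pcov = curve_fit(
        lambda vv, vh, kk: 1.0 / (1.0 + np.exp((vv - vh) / kk)),
        v, y, p0=[v0, k0], maxfev=20000,
    )
    if popt[1] < 0:  # rising-sign degeneracy; re-fit from a flipped start
        popt, pcov = curve_fit(
            lambda vv, vh, kk: 1.0 / (1.0 + np.exp((vv - vh) / kk)),
            v, y, p0=[v0, abs(k0)], maxfev=20000,
        )
    if popt[1] <= 0:
        raise ValueError("Boltzmann fit converged to non-positive slope")
    resid = y - boltzmann(v, *popt)
    return BoltzmannFit(v_half=float(popt[0]), k=float(popt[1]),
                        covariance=np.asarray(pcov), rss=float(resid @ resid))


def _hh_residuals(theta, act_v, act_y, ta_v, ta_y, td_v, td_y,
                  w_act, w_ta, w_td, rate_unit):
    a, vh, va, vb = theta
    p = RateParams(a=a, v_half=vh, v_alpha=va, v_beta=vb, rate_unit=rate_unit)
    r = []
    if act_v.size:
        r.append(np.sqrt(w_act) * (steady_state(act_v, p) - act_y))
    if ta_v.size:
        r.append(np.sqrt(w_ta) * (time_constant(ta_v, p) - ta_y))
    if td_v.size:
        r.append(np.sqrt(w_td) * (time_constant(td_v, p) - td_y))
    return np.concatenate(r)


def fit_hh(
    act: Sequence[ActivationPoint],
    tau_act: Sequence[TauPoint],
    tau_deact: Sequence[TauPoint],
    *,
    rate_unit: Literal["per_s", "per_ms"] = "per_s",
    n_starts: int = 10,
    seed: int = 0,
    label: str = "",
    weights: tuple[float, float, float] | None = None,
) -> HHFitResult:
    """Global weighted HH fit of (A, V1/2, Valpha, Vbeta).

    Simultaneously fits m_inf to the activation curve and tau to the
    activation and deactivation time constants.  Each of the three datasets
    is weighted by the inverse square of its maximum value, so the three
    contribute on comparable scales regardless of units.  68% confidence
    half-widths come from the inverse Hessian (Gauss-Newton approximation
    2 J^T W J of the weighted SSE) at the optimum; ``n_starts`` randomized
    restarts around data-driven initial guesses guard against local minima.
    """
    if not (len(act) and len(tau_act) and len(tau_deact)):
        raise ValueError("all three datasets must be non-empty")
    act_v = np.array([q.v for q in act])
    act_y = np.array([q.activation for q in act])
    ta_v = np.array([q.v for q in tau_act])
    ta_y = np.array([q.tau for q in tau_act])
    td_v = np.array([q.v for q in tau_deact])
    td_y = np.array([q.tau for q in tau_deact])

    if weights is None:
        w_act = 1.0 / np.max(np.abs(act_y)) ** 2
        w_ta = 1.0 / np.max(ta_y) ** 2
        w_td = 1.0 / np.max(td_y) ** 2
    else:
        w_act, w_ta, w_td = weights

    tau_all = np.concatenate([ta_y, td_y])
    tau_unit = 1e3 if rate_unit == "per_s" else 1.0  # tau data are in ms
    a0 = tau_unit / (2.0 * tau_all.max())
    # midpoint guess: half-crossing of the activation curve
    order = np.argsort(act_v)
    vs, ys = act_v[order], act_y[order]
    cross = np.nonzero(np.diff(np.sign(ys - 0.5 * (ys.min() + ys.max()))))[0]
    vh0 = vs[cross[0]] if cross.size else float(np.median(vs))

    rng = np.random.default_rng(seed)
    args = (act_v, act_y, ta_v, ta_y, td_v, td_y, w_act, w_ta, w_td, rate_unit)
    best = None
    lb = [1e-12, -300.0, 0.5, 0.5]
    ub = [1e6, 50.0, 500.0, 500.0]
    for i in range(max(1, n_starts)):
        if i == 0:
            x0 = np.array([a0, vh0, 20.0, 20.0])
        else:
            x0 = np.array([
                a0 * float(np.exp(rng.normal(0, 0.7))),
                vh0 + float(rng.normal(0, 8.0)),
                float(np.exp(rng.normal(np.log(20.0), 0.5))),
                float(np.exp(rng.normal(np.log(20.0), 0.5))),
            ])
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                _hh_residuals, x0, args=args, bounds=(lb, ub),
                method="trf", xtol=1e-12, ftol=1e-14, gtol=1e-14,
                max_nfev=10000,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("HH fit failed from every start")

    a, vh, va, vb = best.x
    params = RateParams(a=float(a), v_half=float(vh), v_alpha=float(va),
                        v_beta=float(vb), label=label, rate_unit=rate_unit)
    wsse = float(2.0 * best.cost)  # least_squares cost is 0.5 * sum r^2
    # Hessian of the weighted SSE ~ 2 J^T J (J already carries sqrt-weights)
    J = best.jac
    H = 2.0 * (J.T @ J)
    ci_scaled = np.full(4, np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        ci = np.where(diag >= 0, np.sqrt(np.maximum(diag, 0.0)), np.nan)
        if np.linalg.cond(H) > 1e12:
            ci = np.full(4, np.nan)
        else:
            ndof = max(J.shape[0] - 4, 1)
            s2 = wsse / ndof
            # cov of the weighted LS estimator is s² (JᵀWJ)⁻¹ = 2 s² H⁻¹
            ci_scaled = np.sqrt(np.maximum(2.0 * s2 * diag, 0.0))
    except np.linalg.LinAlgError:
        ci = np.full(4, np.nan)
    converged = bool(best.status > 0)
    return HHFitResult(params=params, ci68=ci, weighted_sse=wsse,
                       converged=converged, ci68_scaled=ci_scaled)
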