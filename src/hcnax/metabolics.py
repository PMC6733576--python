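"""ATP accounting from simulated Na influx.

Every Na ion entering through NaV channels, the Na leak, or the Na
component of the HCN conductance must be pumped back out by the Na/K
ATPase at a stoichiometry of 3 Na per ATP.  The module converts
time-integrated inward Na charge into ATP counts, normalized per mm of the
repeating bouton+internode chain (the characteristic structure of the
fiber; the white-matter cylinder is excluded by default, switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable_model import AxonModel, SimResult, Stimulus, hcn_split, integrate

__all__ = [
    "EnergyReport",
    "ELEMENTARY_CHARGE",
    "NA_PER_ATP",
    "NA_PATHWAYS",
    "na_influx",
    "atp_from_na",
    "resting_na_current",
    "resting_cost",
    "ap_cost",
    "cost_share",
    "energy_report",
]

ELEMENTARY_CHARGE = 1.602176634e-19   # C
NA_PER_ATP = 3.0                      # Na/K-ATPase stoichiometry
NA_PATHWAYS = ("nav", "leak_na", "hcn_na")


@dataclass(frozen=True)
class EnergyReport:
    """Na-charge decomposition and its ATP equivalents."""

    na_charge_by_pathway: dict            # pC over the analysis window
    atp_rest_per_mm_s: float              # ATP · mm⁻¹ · s⁻¹
    atp_per_ap_per_mm: float              # ATP · mm⁻¹ per AP
    window: tuple = (0.0, 0.0)            # ms
    length_basis: float = 0.0             # µm


def _chain_mask(sim_or_model, include_wm: bool) -> np.ndarray:
    region = sim_or_model.region
    return np.ones(region.size, bool) if include_wm else region != "wm"


def _length_basis(model: AxonModel, include_wm: bool) -> float:
    L = model.geometry.chain_length
    if include_wm:
        L += model.geometry.wm_len
    return L


def na_influx(sim: SimResult, window: tuple[float, float] | None = None,
              *, include_wm: bool = False) -> dict[str, float]:
    """Time-integrated inward Na charge (pC) per pathway.

    With ``window=None`` the run-long accumulated per-segment charges are
    used; otherwise the recorded current densities are integrated over the
    window (requires ``record='all'`` with currents).  Influx is reported
    positive (inward membrane current is negative by convention).
    """
    for p in NA_PATHWAYS:
        if window is None:
            if p not in sim.charge:
                raise KeyError(f"pathway {p!r} missing from simulation")
        elif p not in sim.currents:
            raise KeyError(f"pathway {p!r} currents were not recorded")
    mask = _chain_mask(sim, include_wm)
    out = {}
    if window is None:
        for p in NA_PATHWAYS:
            out[p] = float(-np.sum(sim.charge[p][mask]))
    else:
        t0, t1 = window
        sel = (sim.t >= t0) & (sim.t <= t1)
        if sim.rec_idx.size != sim.area.size:
            raise ValueError("windowed influx needs all segments recorded")
        rec_mask = mask[sim.rec_idx]
        for p in NA_PATHWAYS:
            dens = sim.currents[p][rec_mask][:, sel]          # pA/µm²
            areas = sim.area[sim.rec_idx][rec_mask][:, None]
            q = np.trapezoid(dens * areas, sim.t[sel], axis=1) * 1e-3  # pC
            out[p] = float(-np.sum(q))
    return out


def atp_from_na(charge_pc: float) -> float:
    """ATP molecules needed to extrude ``charge_pc`` pC of Na influx."""
    if charge_pc < 0:
        raise ValueError("Na charge must be >= 0")
    return charge_pc * 1e-12 / ELEMENTARY_CHARGE / NA_PER_ATP


def resting_na_current(model: AxonModel, *, include_wm: bool = False,
                       split_convention: str = "printed",
                       ) -> dict[str, float]:
    """Steady-state inward Na current (pA, positive) per pathway.

    Evaluated analytically from the equilibrated state; raises if the model
    has not been brought to steady state.
    """
    if not model.equilibrated:
        raise RuntimeError("model must be equilibrated (init_steady_state)")
    mem = model.membrane
    mask = _chain_mask(model, include_wm)
    g = model.open_conductances()
    v = model.vm
    if model.g_hcn.any():
        try:
            frac_na, _ = hcn_split(1.0, mem.e_na, mem.e_k, mem.e_hcn,
                                   convention=split_convention)
        except ValueError:
            frac_na, _ = hcn_split(1.0, mem.e_na, mem.e_k, mem.e_hcn,
                                   convention="thermodynamic")
    else:
        frac_na = 1.0
    cur = {
        "nav": g["nav"] * (v - mem.e_na),
        "leak_na": g["leak_na"] * (v - mem.e_na),
        "hcn_na": frac_na * g["hcn"] * (v - mem.e_na),
    }
    return {p: float(-np.sum(i[mask])) for p, i in cur.items()}


def resting_cost(model: AxonModel, *, include_wm: bool = False,
                 by_pathway: bool = False):
    """Resting ATP consumption, ATP · mm⁻¹ · s⁻¹.

    1 pA of standing inward Na current integrates to 1 pC of charge per
    second; the chain-length normalization uses the 15-unit bouton +
    internode repeat (645 µm) unless ``include_wm``.
    """
    cur = resting_na_current(model, include_wm=include_wm)
    L_mm = _length_basis(model, include_wm) * 1e-3
    atp = {p: atp_from_na(max(q, 0.0)) / L_mm for p, q in cur.items()}
    total = float(sum(atp.values()))
    return (total, atp) if by_pathway else total


def ap_cost(model: AxonModel, *, stim: dict | None = None,
            dt: float = 0.0125, post_peak: float = 10.0,
            include_wm: bool = False, require_ap: bool = True) -> float:
    """ATP per action potential per mm of axon.

    Runs a single-AP protocol from steady state, integrates Na influx from
    stimulus onset to 10 ms after the last bouton's peak, and subtracts the
    resting influx over an equal window.
    """
    from .protocols import DEFAULT_STIM  # local import avoids a cycle
    if not model.equilibrated:
        raise RuntimeError("model must be equilibrated (init_steady_state)")
    cfg = dict(DEFAULT_STIM, **(stim or {}))
    m = model.copy()
    onset = 1.0
    last = m.bouton_center(m.geometry.n_units)
    t_end = onset + 20.0 + post_peak
    sim = integrate(m, [Stimulus(cfg["site"], onset, cfg["duration"],
                                 cfg["amplitude"])],
                    dt=dt, t_end=t_end, record=[last], record_currents=False)
    v = sim.vm[0]
    ipk = int(np.argmax(v))
    fired = v[ipk] > 0.0
    if require_ap and not fired:
        raise RuntimeError(f"no AP elicited (peak {v[ipk]:.1f} mV)")
    t_peak = sim.t[ipk] if fired else onset
    window = (onset, min(float(t_peak) + post_peak, float(sim.t[-1])))

    # run-long accumulated charges cover [0, t_end]; correct to the window
    # by subtracting the resting rate outside it as well as inside
    influx = na_influx(sim, None, include_wm=include_wm)
    rest_rate = resting_na_current(model, include_wm=include_wm)  # pA = pC/s
    total_pc = sum(influx.values())
    rest_pc_run = sum(rest_rate.values()) * (sim.t[-1] - sim.t[0]) * 1e-3
    net_pc = total_pc - rest_pc_run
    L_mm = _length_basis(model, include_wm) * 1e-3
    return atp_from_na(max(net_pc, 0.0)) / L_mm


def cost_share(model_with: AxonModel, model_without: AxonModel,
               frequency: float, *, ap_cost_value: float | None = None,
               include_wm: bool = False) -> float:
    """Fraction of the energy budget attributable to HCN at a firing rate.

    share(f) = (rest_with − rest_without) / (rest_without + f · ap_cost),
    strictly decreasing in f: at rest the HCN surcharge dominates, at high
    rates AP costs swamp it.
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    rest_w = resting_cost(model_with, include_wm=include_wm)
    rest_wo = resting_cost(model_without, include_wm=include_wm)
    if ap_cost_value is None:
        ap_cost_value = ap_cost(model_with, include_wm=include_wm)
    return (rest_w - rest_wo) / (rest_wo + frequency * ap_cost_value)


def energy_report(model: AxonModel, *, include_wm: bool = False,
                  stim: dict | None = None) -> EnergyReport:
    """Resting and per-AP energy summary for one model variant."""
    cur = resting_na_current(model, include_wm=include_wm)
    total = resting_cost(model, include_wm=include_wm)
    try:
        per_ap = ap_cost(model, stim=stim, include_wm=include_wm)
    except RuntimeError:
        per_ap = float("nan")
    return EnergyReport(
        na_charge_by_pathway={p: max(q, 0.0) for p, q in cur.items()},
        atp_rest_per_mm_s=total, atp_per_ap_per_mm=per_ap,
        window=(0.0, 1000.0),
        length_basis=_length_basis(model, include_wm),
    )
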