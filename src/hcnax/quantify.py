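"""Immunogold particle-density and channel-density arithmetic.

Small, exact utilities: particles per membrane area, background labeling as
a percentage of specific labeling, and the conversion from a conductance
density to a channel density via the unitary conductance (1.7 pS for HCN2).
Raw values are kept at full precision; report rounding (1 decimal for
densities, 2 for channels/µm²) is applied only in the display helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ParticleCount",
    "HCN2_UNITARY_CONDUCTANCE",
    "particle_density",
    "background_fraction",
    "channels_per_area",
    "density_table",
]

#: single-channel conductance of HCN2, pS
HCN2_UNITARY_CONDUCTANCE = 1.7


@dataclass(frozen=True)
class ParticleCount:
    """Immunogold particles counted on one membrane compartment."""

    n: int
    area: float          # µm²
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("particle count must be >= 0")
        if self.area <= 0:
            raise ValueError("membrane area must be > 0")


def particle_density(c: ParticleCount) -> float:
    """Labeling density, particles/µm²."""
    return c.n / c.area


def background_fraction(bg: float, specific: float) -> float:
    """Background labeling as a percentage of the specific density."""
    if specific <= 0:
        raise ValueError("specific density must be > 0")
    if bg < 0:
        raise ValueError("background density must be >= 0")
    return 100.0 * bg / specific


def channels_per_area(g_density: float,
                      unitary_g: float = HCN2_UNITARY_CONDUCTANCE) -> float:
    """Channel density (channels/µm²) from conductance density (pS/µm²)."""
    if unitary_g <= 0:
        raise ValueError("unitary conductance must be > 0")
    if g_density < 0:
        raise ValueError("conductance density must be >= 0")
    return g_density / unitary_g


def density_table(counts) -> pd.DataFrame:
    """Densities for a list of :class:`ParticleCount`, with display rounding."""
    rows = [{"label": c.label, "n": c.n, "area_um2": c.area,
             "density_per_um2": particle_density(c),
             "density_display": round(particle_density(c), 1)}
            for c in counts]
    return pd.DataFrame(rows)
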