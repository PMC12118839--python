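"""Gross carbonate production from corals, coralline algae and *Halimeda*.

Per transect, gross production (kg CaCO3 m-2 y-1) is

    gross = r * (x + ca + h)

where ``r`` is rugosity and the three terms are the calcification of
corals, crustose coralline algae (CCA) and the calcareous green alga
*Halimeda*.  The coral term sums, over coral taxa j present on the tape,

    x = sum_j  m_j * px_j * d_j * g_j * 10

with ``m`` the morphology adjustment coefficient, ``px`` the planar
proportion of the taxon, ``d`` its skeletal density (g cm-3), ``g`` its
linear extension rate (cm y-1), and 10 the g cm-2 -> kg m-2 conversion.
*Porites* growth is depth-dependent (linear above 6 m, exponential at and
below 6 m); other taxa use fixed table rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lookup import (
    LookupTables,
    PORITES_BREAK_DEPTH_M,
    PORITES_EXP_COEFFS,
    PORITES_LINEAR_COEFFS,
)
from .survey import BenthicTransect, benthic_proportions


@dataclass(frozen=True)
class CalcificationResult:
    """Per-transect gross-production breakdown, kg CaCO3 m-2 y-1 planar."""

    x: float  # corals
    ca: float  # coralline algae
    h: float  # Halimeda
    gross: float  # r * (x + ca + h)
    per_species: dict[str, float]


def porites_growth_rate(depth_m: float) -> float:
    """Depth-dependent *Porites* linear extension rate, cm y-1.

    Above the 6-m breakpoint the rate declines linearly with depth,
    (13.37 - 0.21*depth)/10; at and below 6 m it decays exponentially,
    16.2*exp(-0.032*depth)/10.  The /10 converts the mm y-1 regressions to
    cm y-1.  The two branches deliberately disagree by ~0.13 cm y-1 at the
    breakpoint; both are applied exactly as published.
    """
    if depth_m < 0:
        raise ValueError("depth must be >= 0")
    if depth_m < PORITES_BREAK_DEPTH_M:
        a, b = PORITES_LINEAR_COEFFS
        return (a - b * depth_m) / 10.0
    a, b = PORITES_EXP_COEFFS
    return a * math.exp(-b * depth_m) / 10.0


def resolve_coral_params(
    taxon: str, depth_m: float, tables: LookupTables
) -> tuple[float, float, float]:
    """Resolve (m, d, g) for a coral taxon at a given MSL depth.

    Species entries are preferred, then genus; growth entries flagged as
    the *Porites* depth model are evaluated at ``depth_m``.
    """
    m = tables.morphology_coeff(taxon)
    d = tables.skeletal_density(taxon)
    kind, value = tables.growth_entry(taxon)
    g = porites_growth_rate(depth_m) if kind == "porites_depth_model" else value
    return m, d, g


def coral_production(
    t: BenthicTransect, tables: LookupTables
) -> tuple[float, dict[str, float]]:
    """Coral calcification term x (planar, kg CaCO3 m-2 y-1) and the
    per-taxon contributions."""
    _, coral_props = benthic_proportions(t)
    per_species: dict[str, float] = {}
    for taxon, px in coral_props.items():
        m, d, g = resolve_coral_params(taxon, t.depth_m, tables)
        per_species[taxon] = m * px * d * g * 10.0
    return sum(per_species.values()), per_species


def cca_production(t: BenthicTransect, tables: LookupTables) -> float:
    """Coralline-algae calcification: rate (g cm-2 y-1) * proportion * 10."""
    props, _ = benthic_proportions(t)
    return tables.cca_rate * props["coralline_algae"] * 10.0


def halimeda_production(t: BenthicTransect, tables: LookupTables) -> float:
    """*Halimeda* calcification: rate (kg m-2 y-1) * proportion.

    The default rate is the 20-m literature value; it is applied wherever
    *Halimeda* occurs (in the source surveys that was only the deepest
    stations) and is overridable via the tables.
    """
    props, _ = benthic_proportions(t)
    return tables.halimeda_rate * props["halimeda"]


def gross_production(t: BenthicTransect, tables: LookupTables) -> CalcificationResult:
    """Gross carbonate production of one transect: r * (x + ca + h)."""
    x, per_species = coral_production(t, tables)
    ca = cca_production(t, tables)
    h = halimeda_production(t, tables)
    return CalcificationResult(
        x=x, ca=ca, h=h, gross=t.rugosity * (x + ca + h), per_species=per_species
    )
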