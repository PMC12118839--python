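"""Biological erosion: parrotfishes, sea urchins, macro- and microborers.

Total bioerosion for transect i at station (site x depth) k is

    bioerosion_i = parrotfish_k + urchin_i + macroboring_i + microboring_i

with the parrotfish term estimated at the station level (mean over its
belt transects) and broadcast to the station's benthic transects, the
urchin term from the quadrat paired with the transect, and the boring
terms from the transect's substrate availability.

Unit conventions baked into the constants:

* parrotfish: bite volume (cm3 per bite) x scar proportion x bite rate
  (bites d-1) x mean skeletal density (g cm-3), x365 d y-1, x0.001 g->kg,
  /125 m2 belt area;
* urchins: per-individual g d-1 power laws in test diameter (mm),
  x0.365 (g d-1 -> kg y-1), x0.57 re-ingested-sediment correction,
  /0.25 m2 quadrat area;
* borers: fixed areal rates 0.21 (macro) and 0.20 (micro) kg m-2 y-1
  scaled by rugosity and by the planar proportion of available substrate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .lookup import LookupTables
from .survey import (
    BenthicTransect,
    FishBeltTransect,
    UrchinQuadrat,
    benthic_proportions,
)

#: (a, b) of the per-individual g d-1 power law a * diameter_mm ** b.
URCHIN_POWER_LAWS = {
    "diadematidae": (3e-6, 3.2887),
    "echinometra": (3e-4, 1.9671),
    "other_eroding": (3e-5, 2.6414),
}
URCHIN_DAY_TO_YEAR = 0.365  # g d-1 -> kg y-1
URCHIN_REINGESTION = 0.57  # fraction not re-ingested during grazing

MACROBORING_RATE = 0.21  # kg m-2 y-1 on fully available substrate
MICROBORING_RATE = 0.20

#: Substrate categories available to borers.  CCA is included for
#: macroborers (a crust does not protect the underlying carbonate) but
#: excluded for microborers (its net rate already nets out microboring,
#: as does the corals').
MACRO_AVAILABLE = ("carbonate_substrate", "rubble", "turf_macroalgae", "coralline_algae")
MICRO_AVAILABLE = ("carbonate_substrate", "rubble", "turf_macroalgae")


@dataclass
class ParrotfishParams:
    """Constants of the parrotfish grazing-erosion model."""

    bitetime_h: float = 10.0  # grazing hours per day
    bite_vol_coeffs: tuple[float, float] = (1.3172, 0.0624)
    scar_coeffs: tuple[float, float] = (-2.46142, 0.08864)
    rate_coeffs: tuple[float, float, float, float] = (4.31, -0.355, 0.045, 60.0)


@dataclass(frozen=True)
class BioerosionResult:
    """Per-transect erosion breakdown, kg CaCO3 m-2 y-1 (all >= 0)."""

    parrotfish: float
    urchin: float
    macro: float
    micro: float
    total: float
    urchin_per_group: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Parrotfish
# ---------------------------------------------------------------------------


def bite_volume(length_cm: float, params: ParrotfishParams | None = None) -> float:
    """Volume of a single parrotfish bite (cm3) from fork length (cm)."""
    if length_cm <= 0:
        raise ValueError("fork length must be > 0")
    c0, c1 = (params or ParrotfishParams()).bite_vol_coeffs
    return math.exp(c0 + c1 * length_cm) / 1000.0


def scar_proportion(length_cm: float, params: ParrotfishParams | None = None) -> float:
    """Proportion of bites that leave a grazing scar (logistic in length)."""
    if length_cm <= 0:
        raise ValueError("fork length must be > 0")
    c0, c1 = (params or ParrotfishParams()).scar_coeffs
    return 1.0 / (1.0 + math.exp(-(c0 + c1 * length_cm)))


def bite_rate(
    length_cm: float, brc: float, params: ParrotfishParams | None = None
) -> float:
    """Bite rate (bites d-1) from fork length and the species bite-rate
    constant, applied exactly as published:

        60 * | (4.31 + brc - 0.355) - 0.045 * bitetime * length |
    """
    if length_cm <= 0:
        raise ValueError("fork length must be > 0")
    p = params or ParrotfishParams()
    a, b, c, minutes = p.rate_coeffs
    return minutes * abs((a + brc + b) - c * p.bitetime_h * length_cm)


def site_mean_skeletal_density(
    transects: list[BenthicTransect], tables: LookupTables
) -> float:
    """Coral-cover-weighted mean skeletal density D_k (g cm-3) over the
    station's transects.  With no coral observed, falls back to the
    unweighted mean of all species-level table densities."""
    if not transects:
        raise ValueError("need at least one transect")
    weight_sum = 0.0
    dens_sum = 0.0
    for t in transects:
        _, coral_props = benthic_proportions(t)
        for taxon, px in coral_props.items():
            dens_sum += tables.skeletal_density(taxon) * px
            weight_sum += px
    if weight_sum == 0:
        warnings.warn(
            "no coral observed at station; using unweighted table-mean "
            "skeletal density",
            stacklevel=2,
        )
        return float(tables.all_densities().mean())
    return dens_sum / weight_sum


def parrotfish_erosion_transect(
    belt: FishBeltTransect,
    density_k: float,
    tables: LookupTables,
    params: ParrotfishParams | None = None,
) -> float:
    """Erosion of one belt transect, kg CaCO3 m-2 y-1.

    Sums vol * sp * br * D_k over individuals, converts days to years and
    g to kg, and normalizes by the 25 x 5 m belt area.
    """
    params = params or ParrotfishParams()
    total_g_day = 0.0
    for fish in belt.fishes:
        brc = tables.brc(fish.species)
        total_g_day += (
            bite_volume(fish.fork_length_cm, params)
            * scar_proportion(fish.fork_length_cm, params)
            * bite_rate(fish.fork_length_cm, brc, params)
            * density_k
        )
    return total_g_day * 365.0 * 0.001 / belt.area_m2


def parrotfish_erosion(
    belts: list[FishBeltTransect],
    density_k: float,
    tables: LookupTables,
    params: ParrotfishParams | None = None,
    expected_belts: int = 6,
) -> float:
    """Station-level parrotfish erosion: mean over the station's belts.

    The census design uses six belts per station; the mean generalizes to
    however many are present (with a warning when that is not six).
    An empty belt list contributes zero erosion.
    """
    if not belts:
        return 0.0
    if len(belts) != expected_belts:
        warnings.warn(
            f"station has {len(belts)} parrotfish belts, design expects "
            f"{expected_belts}; averaging over those present",
            stacklevel=2,
        )
    rates = [
        parrotfish_erosion_transect(b, density_k, tables, params) for b in belts
    ]
    return sum(rates) / len(rates)


# ---------------------------------------------------------------------------
# Sea urchins
# ---------------------------------------------------------------------------


def urchin_erosion_individual(group: str, diameter_mm: float) -> float:
    """Per-individual erosion, kg CaCO3 y-1, from the group power law.

    Non-eroding species (e.g. *Tripneustes gratilla*) return 0.
    """
    if diameter_mm <= 0:
        raise ValueError("test diameter must be > 0")
    if group == "non_eroding":
        return 0.0
    try:
        a, b = URCHIN_POWER_LAWS[group]
    except KeyError:
        raise KeyError(f"unknown urchin group {group!r}") from None
    return a * diameter_mm**b * URCHIN_DAY_TO_YEAR * URCHIN_REINGESTION


def urchin_erosion_quadrat(q: UrchinQuadrat) -> tuple[float, dict[str, float]]:
    """Quadrat erosion, kg CaCO3 m-2 y-1: summed individual rates divided
    by quadrat area (0.25 m2 by design).  Also returns per-group totals."""
    per_group = {g: 0.0 for g in URCHIN_POWER_LAWS}
    for u in q.urchins:
        rate = urchin_erosion_individual(u.group, u.test_diameter_mm)
        if u.group in per_group:
            per_group[u.group] += rate
    per_group = {g: r / q.area_m2 for g, r in per_group.items()}
    return sum(per_group.values()), per_group


# ---------------------------------------------------------------------------
# Endolithic borers
# ---------------------------------------------------------------------------


def macroboring(t: BenthicTransect) -> float:
    """Macroborer erosion r * 0.21 * pmacro, kg CaCO3 m-2 y-1."""
    props, _ = benthic_proportions(t)
    pmacro = sum(props[c] for c in MACRO_AVAILABLE)
    return t.rugosity * MACROBORING_RATE * pmacro


def microboring(t: BenthicTransect) -> float:
    """Microborer erosion r * 0.20 * pmicro, kg CaCO3 m-2 y-1."""
    props, _ = benthic_proportions(t)
    pmicro = sum(props[c] for c in MICRO_AVAILABLE)
    return t.rugosity * MICROBORING_RATE * pmicro


# ---------------------------------------------------------------------------
# Total
# ---------------------------------------------------------------------------


def total_bioerosion(
    t: BenthicTransect,
    quadrat: UrchinQuadrat,
    parrotfish_rate_k: float,
) -> BioerosionResult:
    """Total erosion of one transect given its paired quadrat and the
    station's parrotfish rate (broadcast to all transects at the station)."""
    urchin, per_group = urchin_erosion_quadrat(quadrat)
    macro = macroboring(t)
    micro = microboring(t)
    return BioerosionResult(
        parrotfish=parrotfish_rate_k,
        urchin=urchin,
        macro=macro,
        micro=micro,
        total=parrotfish_rate_k + urchin + macro + micro,
        urchin_per_group=per_group,
    )
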