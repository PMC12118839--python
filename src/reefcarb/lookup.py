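"""Coefficient lookup tables with species -> genus fallback resolution.

The engine never hard-codes taxon-level values: coral morphology adjustment
coefficients, skeletal densities (g cm-3), linear extension rates (cm y-1)
and parrotfish bite-rate constants all ship as editable CSVs
(``reefcarb/data/``) seeded with representative Indo-Pacific values for the
common Hawaiian taxa, and can be replaced wholesale by the user.

Resolution order for a coral taxon is species entry, then genus entry
(first word of the binomial), then an optional ``default`` row; an
unresolvable taxon is a hard error naming the chain that was tried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

#: Linear extension model for *Porites* off Maui: linear in depth above the
#: 6-m breakpoint, exponential below; coefficients (a, b) per branch.
PORITES_LINEAR_COEFFS = (13.37, 0.21)
PORITES_EXP_COEFFS = (16.2, 0.032)
PORITES_BREAK_DEPTH_M = 6.0

#: Average calcification rate of crustose coralline algae, g cm-2 y-1.
CCA_RATE_DEFAULT = 0.036
#: Average calcification rate of *Halimeda*, kg m-2 y-1 (20-m value).
HALIMEDA_RATE_DEFAULT = 1.694


class LookupError_(KeyError):
    """A taxon could not be resolved through the fallback chain."""


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("reefcarb.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass
class LookupTables:
    """Morphology / density / growth / bite-rate coefficient tables.

    Each coral table is a DataFrame with columns ``taxon``, ``level``
    (species|genus|default), ``value`` and (for growth) ``kind``
    (fixed|porites_depth_model).
    """

    morphology: pd.DataFrame
    density: pd.DataFrame
    growth: pd.DataFrame
    parrotfish_brc: pd.DataFrame
    cca_rate: float = CCA_RATE_DEFAULT
    halimeda_rate: float = HALIMEDA_RATE_DEFAULT
    _resolution_log: list[str] = field(default_factory=list, repr=False)

    @classmethod
    def default(cls) -> "LookupTables":
        """Tables seeded from the packaged editable CSVs."""
        return cls(
            morphology=_load_packaged("coral_morphology.csv"),
            density=_load_packaged("skeletal_density.csv"),
            growth=_load_packaged("growth_rate.csv"),
            parrotfish_brc=_load_packaged("parrotfish_brc.csv"),
        )

    @classmethod
    def from_dir(cls, path: str | Path, **kwargs) -> "LookupTables":
        path = Path(path)
        return cls(
            morphology=pd.read_csv(path / "coral_morphology.csv"),
            density=pd.read_csv(path / "skeletal_density.csv"),
            growth=pd.read_csv(path / "growth_rate.csv"),
            parrotfish_brc=pd.read_csv(path / "parrotfish_brc.csv"),
            **kwargs,
        )

    # -- resolution ---------------------------------------------------------

    def _lookup_row(self, table: pd.DataFrame, taxon: str, what: str) -> pd.Series:
        tried = []
        hit = table[(table["taxon"] == taxon) & (table["level"] == "species")]
        tried.append(f"species:{taxon}")
        if hit.empty:
            genus = taxon.split()[0]
            hit = table[(table["taxon"] == genus) & (table["level"] == "genus")]
            tried.append(f"genus:{genus}")
            if not hit.empty:
                self._resolution_log.append(
                    f"{what}: {taxon} resolved at genus level ({genus})"
                )
        if hit.empty:
            hit = table[table["level"] == "default"]
            tried.append("default")
        if hit.empty:
            raise LookupError_(
                f"cannot resolve {what} for {taxon!r}; tried {tried}"
            )
        return hit.iloc[0]

    def morphology_coeff(self, taxon: str) -> float:
        return float(self._lookup_row(self.morphology, taxon, "morphology")["value"])

    def skeletal_density(self, taxon: str) -> float:
        return float(self._lookup_row(self.density, taxon, "density")["value"])

    def growth_entry(self, taxon: str) -> tuple[str, float | None]:
        """Return (kind, value): kind 'fixed' with its cm y-1 value, or
        'porites_depth_model' with value None (computed from depth)."""
        row = self._lookup_row(self.growth, taxon, "growth")
        kind = str(row["kind"])
        value = None if kind == "porites_depth_model" else float(row["value"])
        return kind, value

    def brc(self, species: str) -> float:
        return float(
            self._lookup_row(self.parrotfish_brc.rename(columns={"species": "taxon"}),
                             species, "bite-rate constant")["brc"]
        )

    def all_densities(self) -> pd.Series:
        """Species-level densities, used as the no-coral fallback mean."""
        sp = self.density[self.density["level"] == "species"]
        return sp.set_index("taxon")["value"].astype(float)
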