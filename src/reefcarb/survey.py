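"""Field-survey data model and readers.

The census design pairs three record types collected at each site x depth
station on the reef slope:

* benthic line-intercept transects -- the substrate category under every
  centimetre of a tape contoured over the reef surface (tape 2), laid under
  a 2-m linear tape (tape 1); the ratio of the two tape lengths is the
  transect rugosity;
* 0.25-m2 sea-urchin quadrats, each centred on a benthic transect, with
  every urchin identified to species and its test diameter measured in mm;
* 25 x 5 m parrotfish belt transects with species and fork length (cm).

All readers consume plain delimited text (one row per intercept / urchin /
fish) and validate the closed benthic vocabulary and type invariants before
anything downstream runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of benthic categories recorded on the intercept tape.
BENTHIC_CATEGORIES = frozenset(
    {
        "coral",
        "coralline_algae",
        "halimeda",
        "carbonate_substrate",
        "rubble",
        "turf_macroalgae",
        "sand",
        "other_noncarbonate",
    }
)

#: Functional sea-urchin groups used by the erosion rate models.
URCHIN_GROUPS = frozenset(
    {"diadematidae", "echinometra", "other_eroding", "non_eroding"}
)


class SurveyValidationError(ValueError):
    """Raised when a survey record violates a design invariant."""


@dataclass(frozen=True)
class Intercept:
    position_cm: int
    category: str
    taxon: str | None = None


@dataclass
class BenthicTransect:
    """One 2-m line-intercept transect contoured over the reef surface."""

    transect_id: str
    site_id: str
    depth_m: float
    planar_length_m: float
    contour_length_m: float
    intercepts: list[Intercept] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.planar_length_m <= 0:
            raise SurveyValidationError(
                f"{self.transect_id}: planar length must be > 0"
            )
        if self.contour_length_m < self.planar_length_m:
            raise SurveyValidationError(
                f"{self.transect_id}: contour length {self.contour_length_m} "
                f"< planar length {self.planar_length_m} (tape-reading error)"
            )
        n_cm = int(round(self.contour_length_m * 100))
        positions = sorted(i.position_cm for i in self.intercepts)
        if positions != list(range(n_cm)):
            raise SurveyValidationError(
                f"{self.transect_id}: intercepts must tile every cm of the "
                f"{n_cm}-cm contour tape exactly once"
            )
        for i in self.intercepts:
            if i.category not in BENTHIC_CATEGORIES:
                raise SurveyValidationError(
                    f"{self.transect_id}: unknown benthic category "
                    f"{i.category!r} at {i.position_cm} cm"
                )

    @property
    def rugosity(self) -> float:
        return rugosity(self.contour_length_m, self.planar_length_m)


@dataclass(frozen=True)
class UrchinRecord:
    species: str
    group: str
    test_diameter_mm: float


@dataclass
class UrchinQuadrat:
    """One 0.25-m2 sea-urchin quadrat."""

    quadrat_id: str
    site_id: str
    depth_m: float
    area_m2: float = 0.25
    urchins: list[UrchinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise SurveyValidationError(f"{self.quadrat_id}: area must be > 0")
        for u in self.urchins:
            if u.test_diameter_mm <= 0:
                raise SurveyValidationError(
                    f"{self.quadrat_id}: test diameter must be > 0 "
                    f"(got {u.test_diameter_mm} for {u.species})"
                )
            if u.group not in URCHIN_GROUPS:
                raise SurveyValidationError(
                    f"{self.quadrat_id}: unknown urchin group {u.group!r}"
                )


@dataclass(frozen=True)
class FishRecord:
    species: str
    fork_length_cm: float


@dataclass
class FishBeltTransect:
    """One 25 x 5 m parrotfish belt transect."""

    belt_id: str
    site_id: str
    depth_m: float
    length_m: float = 25.0
    width_m: float = 5.0
    fishes: list[FishRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_m * self.width_m <= 0:
            raise SurveyValidationError(f"{self.belt_id}: belt area must be > 0")
        for f in self.fishes:
            if f.fork_length_cm <= 0:
                raise SurveyValidationError(
                    f"{self.belt_id}: fork length must be > 0 "
                    f"(got {f.fork_length_cm} for {f.species})"
                )

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


@dataclass
class SurveyDataset:
    """All field records for one campaign, keyed by site x depth."""

    transects: dict[str, BenthicTransect] = field(default_factory=dict)
    quadrats: dict[str, UrchinQuadrat] = field(default_factory=dict)
    belts: dict[str, FishBeltTransect] = field(default_factory=dict)
    #: transect_id -> quadrat_id for the quadrat centred on that transect
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.pairing.values())) != len(self.pairing):
            raise SurveyValidationError("pairing must be one-to-one")
        for t_id, q_id in self.pairing.items():
            if t_id not in self.transects or q_id not in self.quadrats:
                raise SurveyValidationError(
                    f"pairing refers to unknown records: {t_id} -> {q_id}"
                )

    def station_keys(self) -> list[tuple[str, float]]:
        keys = {(t.site_id, t.depth_m) for t in self.transects.values()}
        keys |= {(q.site_id, q.depth_m) for q in self.quadrats.values()}
        keys |= {(b.site_id, b.depth_m) for b in self.belts.values()}
        return sorted(keys)

    def transects_at(self, site_id: str, depth_m: float) -> list[BenthicTransect]:
        return [
            t
            for t in self.transects.values()
            if t.site_id == site_id and t.depth_m == depth_m
        ]

    def belts_at(self, site_id: str, depth_m: float) -> list[FishBeltTransect]:
        return [
            b
            for b in self.belts.values()
            if b.site_id == site_id and b.depth_m == depth_m
        ]

    def counts(self) -> dict[str, int]:
        return {
            "transects": len(self.transects),
            "quadrats": len(self.quadrats),
            "belts": len(self.belts),
        }

    def validation_report(self) -> dict:
        """JSON-serializable record counts overall and per station."""
        per_station = {}
        for site_id, depth_m in self.station_keys():
            per_station[f"{site_id}@{depth_m:g}m"] = {
                "transects": len(self.transects_at(site_id, depth_m)),
                "quadrats": sum(
                    1
                    for q in self.quadrats.values()
                    if q.site_id == site_id and q.depth_m == depth_m
                ),
                "belts": len(self.belts_at(site_id, depth_m)),
            }
        return {"totals": self.counts(), "stations": per_station}


# ---------------------------------------------------------------------------
# Scalar survey operations
# ---------------------------------------------------------------------------


def rugosity(contour_length_m: float, planar_length_m: float) -> float:
    """Topographic-complexity index: contoured tape length over linear length.

    Always >= 1; a perfectly flat reef gives exactly 1.
    """
    if planar_length_m <= 0 or contour_length_m <= 0:
        raise ValueError("tape lengths must be > 0")
    if contour_length_m < planar_length_m:
        raise ValueError(
            "contour length < planar length: tape-reading inconsistency"
        )
    return contour_length_m / planar_length_m


def benthic_proportions(t: BenthicTransect) -> tuple[dict[str, float], dict[str, float]]:
    """Planar proportions of each benthic category and of each coral taxon.

    Proportions are relative to the contoured tape length (the surveyed
    surface), so that each category's cm count divided by total contour cm
    partitions to 1.

    Returns
    -------
    (by_category, coral_by_taxon)
        ``by_category`` maps every vocabulary category (zeros included) to
        its proportion; ``coral_by_taxon`` maps coral taxon labels to their
        proportions.
    """
    if not t.intercepts:
        raise ValueError(f"{t.transect_id}: empty intercept list")
    n = len(t.intercepts)
    by_cat = {c: 0 for c in BENTHIC_CATEGORIES}
    by_taxon: dict[str, int] = {}
    for i in t.intercepts:
        by_cat[i.category] += 1
        if i.category == "coral":
            taxon = i.taxon or "coral_unidentified"
            by_taxon[taxon] = by_taxon.get(taxon, 0) + 1
    props = {c: k / n for c, k in sorted(by_cat.items())}
    coral_props = {s: k / n for s, k in sorted(by_taxon.items())}
    return props, coral_props


def standardize_depth(
    raw_depth_m: float, tide_offset_m: float | None, assume_msl: bool = False
) -> float:
    """Convert a raw field depth to depth below mean sea level.

    The per-station tidal offset is subtracted from the raw depth; a
    negative result is clamped to 0 with a warning (the station cannot sit
    above MSL).
    """
    if tide_offset_m is None:
        if not assume_msl:
            raise ValueError(
                "no tide offset supplied; pass assume_msl=True to treat raw "
                "depths as MSL depths"
            )
        tide_offset_m = 0.0
    depth = raw_depth_m - tide_offset_m
    if depth < 0:
        warnings.warn(
            f"depth {raw_depth_m} m with tide offset {tide_offset_m} m is "
            "negative below MSL; clamped to 0",
            stacklevel=2,
        )
        depth = 0.0
    return depth


def cv_replicate_curve(
    counts: Sequence[float],
    max_n: int | None = None,
    tol: float = 0.05,
    k: int = 2,
) -> tuple[pd.DataFrame, int | None]:
    """Coefficient-of-variation curve used to choose the replicate number.

    CV(n) = sd / mean over the first ``n`` counts, for n = 3..max_n.  The
    plateau is the smallest n at which successive CVs change by less than
    ``tol`` for ``k`` consecutive steps, i.e. where adding quadrats no
    longer changes the precision appreciably.

    Returns the (n, CV) table (CV is NaN where the prefix mean is zero) and
    the plateau n, or ``None`` if no plateau is reached.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 replicate counts")
    if max_n is None:
        max_n = counts.size
    max_n = min(max_n, counts.size)
    rows = []
    for n in range(3, max_n + 1):
        prefix = counts[:n]
        mean = prefix.mean()
        if mean == 0:
            rows.append((n, np.nan))
        else:
            rows.append((n, prefix.std(ddof=1) / mean))
    curve = pd.DataFrame(rows, columns=["n", "cv"])
    plateau = None
    cv = curve["cv"].to_numpy()
    diffs = np.abs(np.diff(cv))
    for i in range(len(diffs) - k + 1):
        window = diffs[i : i + k]
        if np.all(np.isfinite(window)) and np.all(window < tol):
            plateau = int(curve["n"].iloc[i])
            break
    return curve, plateau


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BENTHIC_COLS = [
    "transect_id",
    "site_id",
    "depth_m",
    "planar_length_m",
    "contour_length_m",
    "position_cm",
    "category",
    "taxon",
]
_URCHIN_COLS = [
    "quadrat_id",
    "site_id",
    "depth_m",
    "area_m2",
    "species",
    "group",
    "test_diameter_mm",
]
_FISH_COLS = [
    "belt_id",
    "site_id",
    "depth_m",
    "length_m",
    "width_m",
    "species",
    "fork_length_cm",
]


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing so write_survey(read_survey(x)) is bit-exact
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise SurveyValidationError(f"{path}: empty survey file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing required columns {missing}")
    return df


def classify_urchin(species: str, group_table: Mapping[str, str] | None = None) -> str:
    """Map an urchin species label to its functional erosion group.

    An explicit species table takes priority; otherwise the genus rules
    apply: *Diadema* and *Echinothrix* are diadematids, *Echinometra* is its
    own group, *Tripneustes gratilla* does not erode, and every other
    surveyed urchin counts as "other eroding".
    """
    if group_table and species in group_table:
        return group_table[species]
    genus = species.split()[0].lower() if species else ""
    if genus in {"diadema", "echinothrix"}:
        return "diadematidae"
    if genus == "echinometra":
        return "echinometra"
    if species.strip().lower() == "tripneustes gratilla":
        return "non_eroding"
    return "other_eroding"


def read_survey(
    benthic_path: str | Path,
    urchin_path: str | Path,
    fish_path: str | Path,
    urchin_group_table: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Read and validate the three survey tables into one dataset.

    Empty ``species`` cells in the urchin/fish tables mark stations that
    were surveyed but held no animals, so the record (quadrat/belt) exists
    with zero individuals.  Transects and quadrats sharing an id stem are
    paired (the quadrat centred over the transect).
    """
    bdf = _read_table(benthic_path, _BENTHIC_COLS[:-1])
    udf = _read_table(urchin_path, [c for c in _URCHIN_COLS if c != "species"])
    fdf = _read_table(fish_path, [c for c in _FISH_COLS if c != "species"])
    return _build_dataset(bdf, udf, fdf, urchin_group_table, str(urchin_path))


def read_survey_excel(
    workbook_path: str | Path,
    sheets: tuple[str, str, str] = ("benthic", "urchins", "fish"),
    urchin_group_table: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Read a survey from one Excel workbook (three sheets, same columns
    as the CSV tables).  Requires ``openpyxl``."""
    frames = pd.read_excel(Path(workbook_path), sheet_name=list(sheets))
    bdf, udf, fdf = (frames[s] for s in sheets)
    for df, cols in (
        (bdf, _BENTHIC_COLS[:-1]),
        (udf, [c for c in _URCHIN_COLS if c != "species"]),
        (fdf, [c for c in _FISH_COLS if c != "species"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SurveyValidationError(
                f"{workbook_path}: missing required columns {missing}"
            )
        if df.empty:
            raise SurveyValidationError(f"{workbook_path}: empty survey sheet")
    return _build_dataset(bdf, udf, fdf, urchin_group_table, str(workbook_path))


def _build_dataset(
    bdf: pd.DataFrame,
    udf: pd.DataFrame,
    fdf: pd.DataFrame,
    urchin_group_table: Mapping[str, str] | None,
    urchin_source: str,
) -> SurveyDataset:
    transects: dict[str, BenthicTransect] = {}
    for tid, grp in bdf.groupby("transect_id", sort=True):
        head = grp.iloc[0]
        intercepts = [
            Intercept(
                int(r.position_cm),
                str(r.category),
                None if pd.isna(r.taxon) else str(r.taxon),
            )
            for r in grp.itertuples()
        ]
        transects[str(tid)] = BenthicTransect(
            transect_id=str(tid),
            site_id=str(head.site_id),
            depth_m=float(head.depth_m),
            planar_length_m=float(head.planar_length_m),
            contour_length_m=float(head.contour_length_m),
            intercepts=intercepts,
        )

    quadrats: dict[str, UrchinQuadrat] = {}
    for qid, grp in udf.groupby("quadrat_id", sort=True):
        head = grp.iloc[0]
        urchins = []
        for idx, r in zip(grp.index, grp.itertuples()):
            species = getattr(r, "species", None)
            if species is None or (isinstance(species, float) and np.isnan(species)):
                continue  # empty-quadrat marker row
            species = str(species)
            group = getattr(r, "group", None)
            if group is None or (isinstance(group, float) and np.isnan(group)):
                group = classify_urchin(species, urchin_group_table)
            diameter = float(r.test_diameter_mm)
            if diameter <= 0:
                raise SurveyValidationError(
                    f"{urchin_source} row {idx}: test diameter must be > 0 "
                    f"(got {diameter})"
                )
            urchins.append(UrchinRecord(species, str(group), diameter))
        quadrats[str(qid)] = UrchinQuadrat(
            quadrat_id=str(qid),
            site_id=str(head.site_id),
            depth_m=float(head.depth_m),
            area_m2=float(head.area_m2),
            urchins=urchins,
        )

    belts: dict[str, FishBeltTransect] = {}
    for bid, grp in fdf.groupby("belt_id", sort=True):
        head = grp.iloc[0]
        fishes = []
        for r in grp.itertuples():
            species = getattr(r, "species", None)
            if species is None or (isinstance(species, float) and np.isnan(species)):
                continue
            fishes.append(FishRecord(str(species), float(r.fork_length_cm)))
        belts[str(bid)] = FishBeltTransect(
            belt_id=str(bid),
            site_id=str(head.site_id),
            depth_m=float(head.depth_m),
            length_m=float(head.length_m),
            width_m=float(head.width_m),
            fishes=fishes,
        )

    pairing = {tid: tid for tid in transects if tid in quadrats}
    return SurveyDataset(
        transects=transects, quadrats=quadrats, belts=belts, pairing=pairing
    )


def write_survey(
    dataset: SurveyDataset,
    benthic_path: str | Path,
    urchin_path: str | Path,
    fish_path: str | Path,
) -> None:
    """Write the dataset back to the three normalized CSV tables."""
    brows = []
    for t in dataset.transects.values():
        for i in t.intercepts:
            brows.append(
                (
                    t.transect_id,
                    t.site_id,
                    t.depth_m,
                    t.planar_length_m,
                    t.contour_length_m,
                    i.position_cm,
                    i.category,
                    i.taxon,
                )
            )
    pd.DataFrame(brows, columns=_BENTHIC_COLS).to_csv(benthic_path, index=False)

    urows = []
    for q in dataset.quadrats.values():
        if not q.urchins:
            urows.append(
                (q.quadrat_id, q.site_id, q.depth_m, q.area_m2, None, None, None)
            )
        for u in q.urchins:
            urows.append(
                (
                    q.quadrat_id,
                    q.site_id,
                    q.depth_m,
                    q.area_m2,
                    u.species,
                    u.group,
                    u.test_diameter_mm,
                )
            )
    pd.DataFrame(urows, columns=_URCHIN_COLS).to_csv(urchin_path, index=False)

    frows = []
    for b in dataset.belts.values():
        if not b.fishes:
            frows.append(
                (b.belt_id, b.site_id, b.depth_m, b.length_m, b.width_m, None, None)
            )
        for f in b.fishes:
            frows.append(
                (
                    b.belt_id,
                    b.site_id,
                    b.depth_m,
                    b.length_m,
                    b.width_m,
                    f.species,
                    f.fork_length_cm,
                )
            )
    pd.DataFrame(frows, columns=_FISH_COLS).to_csv(fish_path, index=False)
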