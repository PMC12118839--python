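"""Seeded generators for survey datasets and cover rasters with known truth.

The default configuration emulates the census design the package targets:
two sites, stations at 2/3/6/9/17 m, 15 paired benthic transects and
urchin quadrats plus 6 parrotfish belts per station.  Urchin counts are
negative-binomial (quadrat standard errors in such surveys imply
overdispersion relative to Poisson) with per-depth, per-group means
matching a high-urchin-density Hawaiian reef (*Echinometra* dominant,
collapsing with depth); benthic composition is Dirichlet per depth with
coral means following the surveyed cover profile; rugosity is a shifted
lognormal bounded below by 1; parrotfish are sparse.

Benthic tapes are tiled deterministically (largest-remainder
apportionment of the contour centimetres) so that realized proportions
equal the drawn ones exactly, isolating downstream numerics from
multinomial noise; all generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage, stats

from .raster import RasterGrid
from .survey import (
    BenthicTransect,
    FishBeltTransect,
    FishRecord,
    Intercept,
    SurveyDataset,
    UrchinQuadrat,
    UrchinRecord,
    classify_urchin,
)

BENTHIC_ORDER = (
    "coral",
    "coralline_algae",
    "halimeda",
    "carbonate_substrate",
    "rubble",
    "turf_macroalgae",
    "sand",
    "other_noncarbonate",
)

#: Expected urchin counts per 0.25-m2 quadrat by depth and group,
#: emulating an extreme-density west-Hawaii urchin assemblage.
DEFAULT_URCHIN_MEANS: dict[float, dict[str, float]] = {
    2.0: {"diadematidae": 0.87, "echinometra": 15.13, "other_eroding": 0.30, "non_eroding": 0.10},
    3.0: {"diadematidae": 1.17, "echinometra": 12.17, "other_eroding": 0.90, "non_eroding": 0.10},
    6.0: {"diadematidae": 0.40, "echinometra": 15.57, "other_eroding": 2.07, "non_eroding": 0.20},
    9.0: {"diadematidae": 0.17, "echinometra": 10.37, "other_eroding": 1.07, "non_eroding": 0.50},
    17.0: {"diadematidae": 0.33, "echinometra": 1.73, "other_eroding": 0.27, "non_eroding": 0.23},
}

#: Mean live coral cover (percent) by depth used to centre the Dirichlet.
DEFAULT_LCC_MEANS: dict[float, float] = {
    2.0: 23.23,
    3.0: 28.16,
    6.0: 31.16,
    9.0: 34.65,
    17.0: 25.11,
}

#: (mean, sd) of test diameter in mm per urchin group (truncated normal).
DEFAULT_URCHIN_SIZES: dict[str, tuple[float, float]] = {
    "diadematidae": (60.0, 15.0),
    "echinometra": (30.0, 8.0),
    "other_eroding": (40.0, 10.0),
    "non_eroding": (70.0, 10.0),
}

_GROUP_SPECIES = {
    "diadematidae": "Echinothrix calamaris",
    "echinometra": "Echinometra mathaei",
    "other_eroding": "Heterocentrotus mammillatus",
    "non_eroding": "Tripneustes gratilla",
}

DEFAULT_CORAL_MIX = {
    "Porites lobata": 0.80,
    "Porites compressa": 0.10,
    "Pocillopora meandrina": 0.05,
    "Montipora capitata": 0.05,
}

DEFAULT_FISH_MIX = {
    "Chlorurus spilurus": 0.6,
    "Scarus psittacus": 0.2,
    "Scarus rubroviolaceus": 0.1,
    "Calotomus carolinus": 0.1,
}


@dataclass
class SimulationConfig:
    """All knobs of the survey and raster generators; seed is mandatory."""

    seed: int
    sites: tuple[str, ...] = ("S1", "S2")
    depths: tuple[float, ...] = (2.0, 3.0, 6.0, 9.0, 17.0)
    n_replicates: int = 15  # paired transects + quadrats per station
    n_belts: int = 6
    urchin_means: Mapping[float, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_URCHIN_MEANS
    )
    urchin_dispersion: float = 5.0  # negative-binomial size parameter
    urchin_sizes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_URCHIN_SIZES
    )
    lcc_means: Mapping[float, float] = field(
        default_factory=lambda: DEFAULT_LCC_MEANS
    )
    benthic_concentration: float = 30.0  # Dirichlet total concentration
    coral_mix: Mapping[str, float] = field(default_factory=lambda: DEFAULT_CORAL_MIX)
    rugosity_mu: float = -1.2  # log-scale location of (rugosity - 1)
    rugosity_sigma: float = 0.4
    fish_rate: float = 1.0  # expected parrotfish per belt
    fish_mix: Mapping[str, float] = field(default_factory=lambda: DEFAULT_FISH_MIX)
    fish_length_mean: float = 18.0
    fish_length_sd: float = 5.0
    planar_length_m: float = 2.0
    # raster generator
    raster_shape: tuple[int, int] = (100, 100)
    raster_pixel_m: float = 2.0
    raster_corr_length_m: float = 10.0
    raster_beta: tuple[float, float] = (2.0, 5.0)
    raster_nodata_fraction: float = 0.0
    # known cover -> production relation used by recovery tests
    truth_beta: tuple[float, float] = (-4.0, 0.2)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_replicates < 1 or self.n_belts < 0:
            raise ValueError("design cell with zero replicates")
        for v in (self.urchin_dispersion, self.benthic_concentration, self.fish_length_sd):
            if v <= 0:
                raise ValueError("rate/scale parameters must be > 0")


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units to match proportions exactly."""
    quotas = proportions * total
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(quotas - floors))
    floors[order[:short]] += 1
    return floors


def _benthic_alphas(cfg: SimulationConfig, depth: float) -> np.ndarray:
    lcc = cfg.lcc_means[depth] / 100.0
    coral = lcc
    halimeda = 0.01 if depth >= 15 else 0.0
    cca = 0.015
    remainder = max(1.0 - coral - halimeda - cca, 0.05)
    weights = np.array([0.45, 0.20, 0.15, 0.15, 0.05])  # carb, rubble, turf, sand, other
    means = np.concatenate(
        [[coral, cca, halimeda], remainder * weights]
    )
    return means * cfg.benthic_concentration


def _dirichlet(rng: np.random.Generator, alphas: np.ndarray) -> np.ndarray:
    # allows zero alphas (structural zeros), unlike Generator.dirichlet
    draws = np.array([rng.gamma(a, 1.0) if a > 0 else 0.0 for a in alphas])
    return draws / draws.sum()


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    a = (lower - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))


def generate_survey(cfg: SimulationConfig) -> tuple[SurveyDataset, dict]:
    """Generate a full paired survey campaign plus its truth record."""
    rng = np.random.default_rng(cfg.seed)
    transects: dict[str, BenthicTransect] = {}
    quadrats: dict[str, UrchinQuadrat] = {}
    belts: dict[str, FishBeltTransect] = {}
    truth: dict = {"config_seed": cfg.seed, "stations": {}}

    coral_species = list(cfg.coral_mix)
    coral_probs = np.array([cfg.coral_mix[s] for s in coral_species], dtype=float)
    coral_probs /= coral_probs.sum()
    fish_species = list(cfg.fish_mix)
    fish_probs = np.array([cfg.fish_mix[s] for s in fish_species], dtype=float)
    fish_probs /= fish_probs.sum()

    for site in cfg.sites:
        for depth in cfg.depths:
            st_truth: dict = {"proportions": [], "rugosity": []}
            alphas = _benthic_alphas(cfg, depth)
            for rep in range(1, cfg.n_replicates + 1):
                tid = f"{site}-D{depth:g}-T{rep:02d}"
                props = _dirichlet(rng, alphas)
                rug = 1.0 + rng.lognormal(cfg.rugosity_mu, cfg.rugosity_sigma)
                contour_cm = int(round(cfg.planar_length_m * 100 * rug))
                contour_m = contour_cm / 100.0
                counts = _largest_remainder(props, contour_cm)
                intercepts: list[Intercept] = []
                pos = 0
                for cat, k in zip(BENTHIC_ORDER, counts):
                    if cat == "coral" and k > 0:
                        sp_counts = _largest_remainder(coral_probs, int(k))
                        for sp, ks in zip(coral_species, sp_counts):
                            for _ in range(ks):
                                intercepts.append(Intercept(pos, "coral", sp))
                                pos += 1
                    else:
                        for _ in range(int(k)):
                            intercepts.append(Intercept(pos, cat, None))
                            pos += 1
                transects[tid] = BenthicTransect(
                    transect_id=tid,
                    site_id=site,
                    depth_m=depth,
                    planar_length_m=cfg.planar_length_m,
                    contour_length_m=contour_m,
                    intercepts=intercepts,
                )
                st_truth["proportions"].append(
                    dict(zip(BENTHIC_ORDER, (counts / contour_cm).tolist()))
                )
                st_truth["rugosity"].append(contour_m / cfg.planar_length_m)

                urchins: list[UrchinRecord] = []
                for group, mu in cfg.urchin_means[depth].items():
                    if mu <= 0:
                        continue
                    k_disp = cfg.urchin_dispersion
                    count = rng.negative_binomial(k_disp, k_disp / (k_disp + mu))
                    if count == 0:
                        continue
                    mean, sd = cfg.urchin_sizes[group]
                    sizes = _truncnorm(rng, mean, sd, 5.0, count)
                    species = _GROUP_SPECIES[group]
                    urchins.extend(
                        UrchinRecord(species, classify_urchin(species), float(s))
                        for s in sizes
                    )
                quadrats[tid] = UrchinQuadrat(
                    quadrat_id=tid, site_id=site, depth_m=depth, urchins=urchins
                )

            for rep in range(1, cfg.n_belts + 1):
                bid = f"{site}-D{depth:g}-B{rep:02d}"
                n_fish = rng.poisson(cfg.fish_rate)
                fishes = []
                if n_fish:
                    picks = rng.choice(len(fish_species), size=n_fish, p=fish_probs)
                    lengths = _truncnorm(
                        rng, cfg.fish_length_mean, cfg.fish_length_sd, 5.0, n_fish
                    )
                    fishes = [
                        FishRecord(fish_species[i], float(l))
                        for i, l in zip(picks, lengths)
                    ]
                belts[bid] = FishBeltTransect(
                    belt_id=bid, site_id=site, depth_m=depth, fishes=fishes
                )
            truth["stations"][f"{site}-D{depth:g}"] = st_truth

    pairing = {tid: tid for tid in transects}
    dataset = SurveyDataset(
        transects=transects, quadrats=quadrats, belts=belts, pairing=pairing
    )
    truth["urchin_means"] = {str(k): dict(v) for k, v in cfg.urchin_means.items()}
    truth["truth_beta"] = list(cfg.truth_beta)
    return dataset, truth


def generate_lcc_raster(cfg: SimulationConfig) -> tuple[RasterGrid, dict]:
    """Spatially correlated percent-cover raster with known latent truth.

    A Gaussian random field (white noise smoothed to the configured
    correlation length, then re-standardized) is mapped through the normal
    CDF and a beta quantile so the marginal cover distribution is the
    configured beta scaled to 0-100.  The truth record carries the latent
    net-production field beta0 + beta1 * cover.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    field_ = rng.standard_normal(cfg.raster_shape)
    sigma_px = cfg.raster_corr_length_m / cfg.raster_pixel_m
    if sigma_px > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_px, mode="wrap")
        field_ = (field_ - field_.mean()) / field_.std()
    uniform = stats.norm.cdf(field_)
    a, b = cfg.raster_beta
    cover = 100.0 * stats.beta(a, b).ppf(uniform)
    nodata = -9999.0
    if cfg.raster_nodata_fraction > 0:
        mask = rng.uniform(size=cfg.raster_shape) < cfg.raster_nodata_fraction
        cover = np.where(mask, nodata, cover)
    grid = RasterGrid(data=cover, nodata=nodata, band="lcc_percent")
    beta0, beta1 = cfg.truth_beta
    latent_net = np.where(
        grid.mask, beta0 + beta1 * np.clip(cover, 0, 100), nodata
    )
    truth = {
        "truth_beta": [beta0, beta1],
        "latent_net": latent_net,
        "beta_params": [a, b],
    }
    return grid, truth


def tabletop_fixture() -> SurveyDataset:
    """Tiny hand-checkable dataset: 2 transects, 2 quadrats, 1 belt.

    Transect T1 (6 m, rugosity 1.25): 100 cm Porites lobata, 25 cm
    coralline algae, 75 cm carbonate substrate, 50 cm sand; its quadrat
    holds one 30-mm *Echinometra mathaei* and one 60-mm *Echinothrix
    calamaris*.  Transect T2 (3 m, flat): all sand, empty quadrat.  One
    belt at 6 m with a single 20-cm *Chlorurus spilurus*.  The full budget
    of this fixture is reproduced by hand in the test suite.
    """
    def block(cat: str, taxon: str | None, start: int, n: int) -> list[Intercept]:
        return [Intercept(start + i, cat, taxon) for i in range(n)]

    t1_intercepts = (
        block("coral", "Porites lobata", 0, 100)
        + block("coralline_algae", None, 100, 25)
        + block("carbonate_substrate", None, 125, 75)
        + block("sand", None, 200, 50)
    )
    t1 = BenthicTransect("T1", "S1", 6.0, 2.0, 2.5, t1_intercepts)
    t2 = BenthicTransect("T2", "S1", 3.0, 2.0, 2.0, block("sand", None, 0, 200))
    q1 = UrchinQuadrat(
        "T1",
        "S1",
        6.0,
        urchins=[
            UrchinRecord("Echinometra mathaei", "echinometra", 30.0),
            UrchinRecord("Echinothrix calamaris", "diadematidae", 60.0),
        ],
    )
    q2 = UrchinQuadrat("T2", "S1", 3.0, urchins=[])
    b1 = FishBeltTransect(
        "B1", "S1", 6.0, fishes=[FishRecord("Chlorurus spilurus", 20.0)]
    )
    return SurveyDataset(
        transects={"T1": t1, "T2": t2},
        quadrats={"T1": q1, "T2": q2},
        belts={"B1": b1},
        pairing={"T1": "T1", "T2": "T2"},
    )
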