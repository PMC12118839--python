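"""Scaling field budgets across the bay from a live-coral-cover raster.

The procedure mirrors standard remote-sensing upscaling practice: screen
the candidate field predictors (cover, depth, rugosity, algal substrate)
for collinearity at |r| >= 0.7, drop Cook's-distance outliers
(D_i > 3 * mean D), confirm with cross-validated PLSR that the signal is
essentially one component, select among candidate OLS models on a single
seeded 70:30 train/test split by test RMSE (dropping predictors with
p >= 0.05 and re-running), refit the winner on all non-outlier data, and
apply it pixelwise to the cover raster (optionally converting predicted
net production to accretion potential).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .budget import vertical_accretion
from .raster import RasterGrid


def collinearity_screen(
    features: pd.DataFrame,
    priority: list[str] | None = None,
    cutoff: float = 0.7,
) -> tuple[list[str], pd.DataFrame]:
    """Drop the lower-priority member of each |r| >= cutoff pair.

    ``priority`` orders features from most to least preferred (default:
    the column order); constant features have undefined correlations and
    are dropped with a warning.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    priority = priority or list(features.columns)
    kept = []
    for col in sorted(features.columns, key=priority.index):
        if features[col].nunique() <= 1:
            warnings.warn(
                f"feature {col!r} is constant; correlation undefined, dropped",
                stacklevel=2,
            )
            continue
        kept.append(col)
    corr = features[kept].corr()
    retained: list[str] = []
    for col in kept:  # already priority-sorted
        if all(abs(corr.loc[col, r]) < cutoff for r in retained):
            retained.append(col)
    return retained, corr


def cooks_outlier_filter(
    y: np.ndarray, X: pd.DataFrame, multiplier: float = 3.0
) -> np.ndarray:
    """Flag observations with Cook's distance above multiplier x mean.

    An OLS fit of y on X (with intercept) over the full data supplies the
    distances; flagged rows are excluded from downstream model fits.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations for Cook's distances")
    if n <= p + 2:
        warnings.warn(
            "minimal sample size for Cook's distance; flags are unstable",
            stacklevel=2,
        )
    design = sm.add_constant(np.asarray(X, dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, design).fit()
    cooks = fit.get_influence().cooks_distance[0]
    return cooks > multiplier * cooks.mean()


def plsr_component_selection(
    y: np.ndarray,
    X: pd.DataFrame,
    folds: int = 10,
    seed: int | None = 0,
    max_components: int | None = None,
    rule: str = "min",
) -> tuple[int, pd.DataFrame]:
    """Cross-validated PLSR prediction error per component count.

    ``rule="min"`` returns the count minimizing CV mean-squared error;
    ``rule="one_se"`` the smallest count within one standard error of that
    minimum (parsimony rule).  A flat curve (spread < 1% of the minimum)
    warns that the response looks like noise.
    """
    y = np.asarray(y, dtype=float)
    Xa = np.asarray(X, dtype=float)
    if Xa.shape[1] < 2:
        raise ValueError("need at least 2 features")
    max_components = max_components or Xa.shape[1]
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for ncomp in range(1, max_components + 1):
        errs = []
        for train, test in cv.split(Xa):
            pls = PLSRegression(n_components=ncomp)
            pls.fit(Xa[train], y[train])
            pred = pls.predict(Xa[test]).ravel()
            errs.append(np.mean((y[test] - pred) ** 2))
        rows.append(
            (ncomp, float(np.mean(errs)), float(np.std(errs) / np.sqrt(folds)))
        )
    table = pd.DataFrame(rows, columns=["n_components", "cv_mse", "cv_se"])
    i_min = table["cv_mse"].idxmin()
    if rule == "one_se":
        limit = table.loc[i_min, "cv_mse"] + table.loc[i_min, "cv_se"]
        best = int(table.loc[table["cv_mse"] <= limit, "n_components"].min())
    elif rule == "min":
        best = int(table.loc[i_min, "n_components"])
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    spread = table["cv_mse"].max() - table["cv_mse"].min()
    if spread < 0.01 * table["cv_mse"].min():
        warnings.warn(
            "PLSR cross-validation curve is flat; response may be noise",
            stacklevel=2,
        )
    return best, table


@dataclass
class ScalingModelReport:
    """Candidate-model metrics table plus the selected final fit."""

    candidates: pd.DataFrame  # model, rmse_test, r2_train, r2_test, r2_full
    selected: str
    coefficients: dict[str, float]
    split_seed: int
    train_index: np.ndarray = field(repr=False, default=None)
    test_index: np.ndarray = field(repr=False, default=None)


class ScalingRegression(BaseEstimator, RegressorMixin):
    """Train/test-selected OLS model of net production on field predictors.

    Parameters
    ----------
    candidate_sets : list of predictor-name lists to compare (default:
        nested sets over the screened predictors, largest first).
    test_size : held-out fraction of the single seeded split (default 0.3).
    p_drop : significance level above which a predictor is dropped from a
        candidate and the candidate re-run.
    random_state : split seed; required.

    After ``fit``, ``coef_``/``intercept_`` hold the winner refit on all
    rows (the caller removes outliers first), and ``report_`` holds the
    Table-style candidate metrics computed on the split.
    """

    def __init__(
        self,
        candidate_sets: list[list[str]] | None = None,
        test_size: float = 0.3,
        p_drop: float = 0.05,
        random_state: int | None = None,
    ):
        self.candidate_sets = candidate_sets
        self.test_size = test_size
        self.p_drop = p_drop
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if self.random_state is None:
            raise ValueError("random_state (split seed) is required")
        y = np.asarray(y, dtype=float)
        predictors = list(X.columns)
        candidates = self.candidate_sets
        if candidates is None:
            candidates = [predictors[: k + 1] for k in range(len(predictors))][::-1]
        if not candidates:
            raise ValueError("empty candidate list")

        rng = np.random.default_rng(self.random_state)
        n = len(X)
        perm = rng.permutation(n)
        n_test = int(round(self.test_size * n))
        test_idx, train_idx = perm[:n_test], perm[n_test:]

        rows = []
        fitted_sets: dict[str, list[str]] = {}
        for cand in candidates:
            used = self._drop_insignificant(X.iloc[train_idx], y[train_idx], cand)
            res = sm.OLS(
                y[train_idx],
                sm.add_constant(X.iloc[train_idx][used], has_constant="add"),
            ).fit()
            pred_test = res.predict(
                sm.add_constant(X.iloc[test_idx][used], has_constant="add")
            )
            pred_full = res.predict(sm.add_constant(X[used], has_constant="add"))
            name = " + ".join(cand)
            fitted_sets[name] = used
            rows.append(
                {
                    "model": name,
                    "predictors_used": " + ".join(used) if used else "(intercept)",
                    "rmse_test": float(
                        np.sqrt(np.mean((y[test_idx] - pred_test) ** 2))
                    ),
                    "r2_train": float(res.rsquared),
                    "r2_test": _r2(y[test_idx], pred_test),
                    "r2_full": _r2(y, pred_full),
                }
            )
        table = pd.DataFrame(rows)
        best = table.loc[table["rmse_test"].idxmin(), "model"]
        used = fitted_sets[best]

        final = sm.OLS(
            y, sm.add_constant(X[used], has_constant="add")
        ).fit()
        self.predictors_ = used
        self.intercept_ = float(final.params["const"])
        self.coef_ = np.array([final.params[c] for c in used])
        self.final_result_ = final
        self.report_ = ScalingModelReport(
            candidates=table,
            selected=best,
            coefficients={"const": self.intercept_}
            | {c: float(final.params[c]) for c in used},
            split_seed=self.random_state,
            train_index=train_idx,
            test_index=test_idx,
        )
        return self

    def _drop_insignificant(
        self, X: pd.DataFrame, y: np.ndarray, cand: list[str]
    ) -> list[str]:
        used = list(cand)
        while used:
            res = sm.OLS(
                y, sm.add_constant(X[used], has_constant="add")
            ).fit()
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] < self.p_drop:
                break
            used.remove(worst)
        return used

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X[self.predictors_], float) @ self.coef_


def fit_and_select(
    dataset: pd.DataFrame,
    candidate_sets: list[list[str]] | None = None,
    split_seed: int = 0,
    response: str = "net_production",
    predictors: tuple[str, ...] = ("lcc_percent", "rugosity", "depth_m"),
) -> ScalingRegression:
    """Run the full selection on a budget table (outliers already flagged
    in an ``outlier_flag`` column, or none assumed)."""
    if "outlier_flag" in dataset.columns:
        dataset = dataset[~dataset["outlier_flag"].astype(bool)]
    model = ScalingRegression(
        candidate_sets=candidate_sets, random_state=split_seed
    )
    return model.fit(dataset[list(predictors)], dataset[response])


def predict_raster(
    model: ScalingRegression,
    lcc_raster: RasterGrid,
    accretion: bool = False,
) -> tuple[RasterGrid, RasterGrid | None, dict]:
    """Pixelwise prediction of net production from a percent-cover raster.

    Only usable when the selected model is cover-only (the raster carries
    a single band).  Cover values outside [0, 100] are clamped and
    counted; nodata propagates untouched.  Returns the production grid,
    optionally the accretion grid, and summary statistics.
    """
    check_is_fitted(model, "coef_")
    if list(model.predictors_) != ["lcc_percent"]:
        raise ValueError(
            "raster prediction needs a cover-only model; selected "
            f"predictors are {model.predictors_}"
        )
    data = lcc_raster.data.astype(float)
    mask = lcc_raster.mask
    clamped = int(np.sum((data[mask] < 0) | (data[mask] > 100)))
    values = np.clip(data, 0.0, 100.0)
    pred = model.intercept_ + model.coef_[0] * values
    pred[~mask] = lcc_raster.nodata
    out = lcc_raster.like(pred, band="net_production")
    acc_grid = None
    if accretion:
        acc = vertical_accretion(pred)
        acc = np.where(mask, acc, lcc_raster.nodata)
        acc_grid = lcc_raster.like(acc, band="accretion_mm")
    stats = {
        "n_valid": int(mask.sum()),
        "n_clamped": clamped,
        "mean_net_production": float(pred[mask].mean()) if mask.any() else None,
        "percent_positive": (
            float(100.0 * (pred[mask] > 0).mean()) if mask.any() else None
        ),
    }
    return out, acc_grid, stats


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    pred = np.asarray(pred, dtype=float)
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)
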