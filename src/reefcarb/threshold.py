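"""Bayesian additive mixed model for the coral-cover threshold.

Transect net carbonate production y is modelled as

    y_is = Beta + f(LCC_is) + Depth_is + a_s + e_is

with f an O'Sullivan penalized spline (cubic B-splines whose
curvature-penalty null space contains all linear functions), Depth a
categorical fixed effect, a_s a Gaussian random intercept per site, and
Gaussian residuals.  In the mixed-model representation the spline splits
into a fixed linear part and i.i.d. Gaussian random coefficients, so the
whole model is a conjugate Gaussian hierarchy and is sampled exactly by a
Gibbs sampler: multivariate-normal block updates for all coefficients and
inverse-gamma updates for the three variances.  "Diffuse" priors are
normal(0, 1e6) on fixed effects and half-Cauchy(0, 25) on standard
deviations (via the inverse-gamma scale-mixture expansion, which keeps
every full conditional closed-form).

The quantity of interest is the live-coral-cover threshold: per posterior
draw, the fitted population-level curve at a given depth is evaluated on a
fine cover grid and the smallest cover at which it crosses from negative
to positive net production is recorded; draws whose curve never crosses
are censored at the grid boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# O'Sullivan basis
# ---------------------------------------------------------------------------


@dataclass
class OSullivanBasis:
    """Penalized cubic B-spline basis with curvature penalty.

    ``knots`` is the full (padded) knot vector, ``penalty`` the K x K
    integrated-squared-second-derivative matrix.  ``null_dim`` columns of
    the penalty eigenbasis span constants + linear functions (unpenalized).
    """

    knots: np.ndarray
    degree: int
    penalty: np.ndarray
    _transform: np.ndarray  # K x (K - null_dim), maps basis -> random part

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        """Full B-spline design matrix at ``x`` (extrapolating cubically
        outside the boundary knots)."""
        x = np.asarray(x, dtype=float)
        spl = BSpline(self.knots, np.eye(self.n_basis), self.degree)
        return spl(x)

    def random_design(self, x: np.ndarray) -> np.ndarray:
        """Design of the penalized (random-coefficient) spline components
        in the mixed-model representation; the unpenalized part is the
        intercept + linear term handled as fixed effects."""
        return self.design(x) @ self._transform


def osullivan_basis(
    x: np.ndarray,
    n_knots: int = 5,
    degree: int = 3,
    boundary: tuple[float, float] | None = None,
) -> OSullivanBasis:
    """Build the O'Sullivan penalized spline basis for covariate ``x``.

    ``n_knots`` interior knots are placed at quantiles of the distinct
    covariate values; the penalty is the exact integral of products of
    second derivatives over the boundary interval (Gauss-Legendre, exact
    for cubics), so coefficients of any straight line incur zero penalty.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < n_knots + 2:
        raise ValueError(
            f"need at least {n_knots + 2} distinct covariate values for "
            f"{n_knots} knots; got {distinct.size}"
        )
    if boundary is None:
        boundary = (float(distinct.min()), float(distinct.max()))
    a, b = boundary
    probs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.quantile(distinct, probs)
    interior = interior[(interior > a) & (interior < b)]
    t = np.concatenate(
        [np.full(degree + 1, a), np.sort(interior), np.full(degree + 1, b)]
    )
    n_basis = len(t) - degree - 1

    # exact penalty: integrate B_i'' B_j'' with 3-pt Gauss-Legendre per
    # inter-knot interval (integrand is piecewise quartic in general but
    # piecewise quadratic-by-quadratic products of degree <= 2+2=4;
    # 3-point GL is exact through degree 5)
    spl2 = BSpline(t, np.eye(n_basis), degree).derivative(2)
    breaks = np.unique(t)
    gl_x, gl_w = np.polynomial.legendre.leggauss(3)
    omega = np.zeros((n_basis, n_basis))
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = (hi - lo) / 2.0
        pts = (gl_x + 1.0) * half + lo
        vals = spl2(pts)  # (3, n_basis)
        omega += half * (vals.T * gl_w) @ vals
    omega = (omega + omega.T) / 2.0

    evals, evecs = np.linalg.eigh(omega)
    tol = evals.max() * 1e-10
    positive = evals > tol
    null_dim = int((~positive).sum())
    if null_dim != 2:
        raise RuntimeError(
            f"penalty null space has dimension {null_dim}, expected 2"
        )
    transform = evecs[:, positive] / np.sqrt(evals[positive])
    return OSullivanBasis(knots=t, degree=degree, penalty=omega, _transform=transform)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def gibbs_additive_model(
    y: np.ndarray,
    W: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    iterations: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    fixed_prior_var: float = 1e6,
    sd_prior_scale: float = 25.0,
    resid_var: float | None = None,
) -> dict[str, np.ndarray]:
    """One chain of the conjugate Gibbs sampler.

    ``W`` holds fixed effects (normal(0, fixed_prior_var) priors), ``Z``
    penalized spline coefficients (variance sig2_u), ``A`` site indicators
    (variance sig2_a); either of the latter may have zero columns, which
    drops that block.  ``resid_var`` fixes the residual variance instead of
    sampling it (used by exactness checks against closed-form posteriors).
    Standard deviations get half-Cauchy(0, sd_prior_scale) priors through
    the inverse-gamma mixture representation.
    """
    n = y.size
    p, q, s = W.shape[1], Z.shape[1], A.shape[1]
    C = np.hstack([W, Z, A])
    d = C.shape[1]
    CtC = C.T @ C
    Cty = C.T @ y
    A2 = sd_prior_scale**2

    sig2_e = float(np.var(y)) or 1.0
    if resid_var is not None:
        sig2_e = resid_var
    sig2_u = sig2_a = 1.0
    aux_e = aux_u = aux_a = 1.0

    kept_theta, kept_vars = [], []
    for it in range(iterations):
        prior_prec = np.concatenate(
            [
                np.full(p, 1.0 / fixed_prior_var),
                np.full(q, 1.0 / sig2_u),
                np.full(s, 1.0 / sig2_a),
            ]
        )
        P = CtC / sig2_e + np.diag(prior_prec)
        L = np.linalg.cholesky(P)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, Cty / sig2_e))
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(d))

        resid = y - C @ theta
        if resid_var is None:
            # floor keeps the coefficient update well-conditioned when the
            # data are (near) noise-free
            sig2_e = max(
                _inv_gamma(rng, 0.5 + n / 2.0, 1.0 / aux_e + resid @ resid / 2.0),
                1e-10,
            )
            aux_e = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / sig2_e)
        if q:
            u = theta[p : p + q]
            sig2_u = _inv_gamma(rng, 0.5 + q / 2.0, 1.0 / aux_u + u @ u / 2.0)
            aux_u = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / sig2_u)
        if s:
            a = theta[p + q :]
            sig2_a = _inv_gamma(rng, 0.5 + s / 2.0, 1.0 / aux_a + a @ a / 2.0)
            aux_a = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / sig2_a)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_theta.append(theta)
            kept_vars.append((sig2_e, sig2_u, sig2_a))
    return {
        "theta": np.asarray(kept_theta),
        "variances": np.asarray(kept_vars),
    }


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction factor for one scalar
    parameter; ``chains`` has shape (n_chains, n_draws)."""
    m, n = chains.shape
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdEstimate:
    """Cover threshold for positive net production at one depth (% LCC)."""

    depth_m: float
    threshold_lcc: float
    ci_lower: float
    ci_upper: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.ci_upper <= 100.0):
            raise ValueError("credible interval must lie in [0, 100]")


class CoralCoverThresholdModel(BaseEstimator):
    """Bayesian penalized-spline additive mixed model for net production
    against live coral cover.

    Parameters
    ----------
    n_knots : interior spline knots (default 5).
    chains, iterations, burn_in, thin : MCMC schedule per chain.
    fixed_prior_var : variance of the diffuse normal prior on fixed effects.
    sd_prior_scale : half-Cauchy scale for the three standard deviations.
    lcc_range : boundary interval of the spline (percent cover).
    random_state : seed; required for a reproducible fit.

    Fitted attributes (trailing underscore) hold the pooled posterior
    draws, per-parameter split-Rhat diagnostics, and the design metadata
    needed to evaluate posterior curves at new cover values.
    """

    def __init__(
        self,
        n_knots: int = 5,
        degree: int = 3,
        chains: int = 3,
        iterations: int = 20000,
        burn_in: int = 5000,
        thin: int = 5,
        fixed_prior_var: float = 1e6,
        sd_prior_scale: float = 25.0,
        lcc_range: tuple[float, float] = (0.0, 100.0),
        rhat_limit: float = 1.1,
        random_state: int | None = None,
    ):
        self.n_knots = n_knots
        self.degree = degree
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.fixed_prior_var = fixed_prior_var
        self.sd_prior_scale = sd_prior_scale
        self.lcc_range = lcc_range
        self.rhat_limit = rhat_limit
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        """Fit from a DataFrame X with columns ``lcc`` (percent cover),
        ``depth`` and ``site``, and response y (net production)."""
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.n_knots < 3:
            raise ValueError("need at least 3 knots")
        if self.random_state is None:
            raise ValueError("random_state is required for a reproducible fit")
        lcc = np.asarray(X["lcc"], dtype=float)
        depth = np.asarray(X["depth"])
        site = np.asarray(X["site"])
        y = np.asarray(y, dtype=float)
        if np.unique(site).size < 2:
            raise ValueError("need at least 2 sites for the random intercept")

        self.basis_ = osullivan_basis(
            lcc, self.n_knots, self.degree, boundary=self.lcc_range
        )
        self.depth_levels_ = np.unique(depth)
        self.site_levels_ = np.unique(site)
        depth_dummies = (
            depth[:, None] == self.depth_levels_[None, 1:]
        ).astype(float)
        W = np.column_stack([np.ones_like(lcc), lcc, depth_dummies])
        Z = self.basis_.random_design(lcc)
        A = (site[:, None] == self.site_levels_[None, :]).astype(float)
        self.n_fixed_ = W.shape[1]
        self.n_spline_ = Z.shape[1]

        seeds = np.random.SeedSequence(self.random_state).spawn(self.chains)
        per_chain = [
            gibbs_additive_model(
                y,
                W,
                Z,
                A,
                iterations=self.iterations,
                burn_in=self.burn_in,
                thin=self.thin,
                rng=np.random.default_rng(seed),
                fixed_prior_var=self.fixed_prior_var,
                sd_prior_scale=self.sd_prior_scale,
            )
            for seed in seeds
        ]
        theta_chains = np.stack([c["theta"] for c in per_chain])  # (m, n, d)
        var_chains = np.stack([c["variances"] for c in per_chain])
        self.draws_theta_ = theta_chains.reshape(-1, theta_chains.shape[-1])
        self.draws_variances_ = var_chains.reshape(-1, 3)
        self.rhat_ = {
            f"theta[{j}]": split_rhat(theta_chains[:, :, j])
            for j in range(theta_chains.shape[-1])
        }
        self.rhat_.update(
            {
                name: split_rhat(np.log(var_chains[:, :, j]))
                for j, name in enumerate(("sig2_e", "sig2_u", "sig2_a"))
            }
        )
        self.converged_ = all(r < self.rhat_limit for r in self.rhat_.values())
        if not self.converged_:
            warnings.warn(
                "split-Rhat >= %.2f for some parameters; thresholds from "
                "this fit are unreliable" % self.rhat_limit,
                ConvergenceWarning,
                stacklevel=2,
            )
        return self

    # -- posterior curves ----------------------------------------------------

    def _grid_design(self, depth_m, grid: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "draws_theta_")
        if depth_m not in self.depth_levels_:
            raise ValueError(
                f"depth {depth_m!r} not among fitted levels "
                f"{list(self.depth_levels_)}"
            )
        dd = (np.asarray(depth_m) == self.depth_levels_[1:]).astype(float)
        W = np.column_stack(
            [np.ones_like(grid), grid, np.tile(dd, (grid.size, 1))]
        )
        Z = self.basis_.random_design(grid)
        return np.hstack([W, Z])

    def posterior_curves(
        self, depth_m, grid: np.ndarray, chunk: int = 512
    ) -> np.ndarray:
        """Fitted curves at the average surveyed site, one row per draw.

        With few sites only the sum of the fixed intercept and the mean
        site intercept is identified by the data, so each curve carries
        the draw's mean site intercept; this is the bay-level curve the
        threshold is defined on.
        """
        G = self._grid_design(depth_m, grid)
        coefs = self.draws_theta_[:, : self.n_fixed_ + self.n_spline_]
        site_offset = self.draws_theta_[:, self.n_fixed_ + self.n_spline_ :].mean(
            axis=1
        )
        out = np.empty((coefs.shape[0], grid.size))
        for i in range(0, coefs.shape[0], chunk):
            out[i : i + chunk] = (
                coefs[i : i + chunk] @ G.T + site_offset[i : i + chunk, None]
            )
        return out

    def mean_curve(self, depth_m, grid: np.ndarray) -> np.ndarray:
        G = self._grid_design(depth_m, grid)
        coefs = self.draws_theta_[:, : self.n_fixed_ + self.n_spline_].mean(axis=0)
        offset = self.draws_theta_[:, self.n_fixed_ + self.n_spline_ :].mean()
        return G @ coefs + offset


def _first_upcrossing(curve: np.ndarray, grid: np.ndarray) -> tuple[float, bool]:
    """Smallest grid point where the curve crosses from <=0 to >0.

    Everywhere-positive curves censor at the lower boundary, everywhere-
    non-positive ones at the upper boundary.
    """
    pos = curve > 0
    up = pos[1:] & ~pos[:-1]
    idx = np.flatnonzero(up)
    if idx.size:
        return float(grid[idx[0] + 1]), False
    if pos.all():
        return float(grid[0]), True
    return float(grid[-1]), True


def coral_cover_threshold(
    fit: CoralCoverThresholdModel,
    depth_m,
    grid_step: float = 0.01,
) -> ThresholdEstimate:
    """Live-coral-cover threshold for positive net production at a depth.

    The point estimate is the zero upcrossing of the posterior-mean curve;
    the 95% credible interval comes from the 2.5/97.5 percentiles of the
    per-draw upcrossings (censored draws enter at the boundary).
    """
    check_is_fitted(fit, "draws_theta_")
    if not fit.converged_:
        warnings.warn(
            "fit did not converge; threshold is unreliable",
            ConvergenceWarning,
            stacklevel=2,
        )
    lo, hi = fit.lcc_range
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    curves = fit.posterior_curves(depth_m, grid)
    draws = np.empty(curves.shape[0])
    for i, c in enumerate(curves):
        draws[i], _ = _first_upcrossing(c, grid)
    point, censored = _first_upcrossing(fit.mean_curve(depth_m, grid), grid)
    ci_lo, ci_hi = np.percentile(draws, [2.5, 97.5])
    try:
        depth_val = float(depth_m)
    except (TypeError, ValueError):
        depth_val = float("nan")
    return ThresholdEstimate(
        depth_m=depth_val,
        threshold_lcc=point,
        ci_lower=float(min(ci_lo, point)),
        ci_upper=float(max(ci_hi, point)),
        censored=censored,
    )


def fit_threshold_model(
    data, config: dict | None = None
) -> CoralCoverThresholdModel:
    """Convenience wrapper: fit from a DataFrame with columns
    ``net_production``, ``lcc_percent``, ``depth_m``, ``site_id``."""
    config = config or {}
    model = CoralCoverThresholdModel(**config)
    X = data.rename(
        columns={"lcc_percent": "lcc", "depth_m": "depth", "site_id": "site"}
    )[["lcc", "depth", "site"]]
    return model.fit(X, data["net_production"])
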