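"""Phenotype preparation and clonal variance decomposition.

Raw survey scores are rank-normalized, field microsite variation is removed
with a two-dimensional thin-plate smoothing spline, and a one-random-effect
linear mixed model (genotype as the random effect, optional fixed
covariate) is fitted by REML to estimate broad-sense heritability
H2 = Vg / (Vg + Ve), its significance via a simulation-based exact
restricted likelihood-ratio test, and per-genotype BLUPs for QTL mapping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "normal_score_transform",
    "binarize_scores",
    "broad_sense_h2",
    "ThinPlateSpline",
    "fit_spatial_spline",
    "spatial_correct",
    "VarianceComponents",
    "ClonalFit",
    "fit_clonal_model",
    "exact_rlrt",
]


def normal_score_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Maps value i to ``Phi^{-1}((rank_i - 0.5) / n)`` with average ranks for
    ties, yielding scores with mean ~0 and SD ~1; monotone in the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("normal-score transform needs >= 2 distinct values")
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / ok.sum())
    return out


def binarize_scores(scores) -> np.ndarray:
    """Collapse a 0-5 severity scale to 0/1: scores >= 2.5 become 1."""
    x = np.asarray(scores, dtype=float)
    ok = ~np.isnan(x)
    if np.any((x[ok] < 0) | (x[ok] > 5)):
        raise ValueError("scores must lie within [0, 5]")
    out = np.where(x >= 2.5, 1.0, 0.0)
    out[~ok] = np.nan
    return out


def broad_sense_h2(v_g: float, v_e: float) -> float:
    """Clonal repeatability H2 = Vg / (Vg + Ve)."""
    if v_g < 0 or v_e <= 0:
        raise ValueError("require Vg >= 0 and Ve > 0")
    return v_g / (v_g + v_e)


# ---------------------------------------------------------------------------
# thin-plate spline surface
# ---------------------------------------------------------------------------


def _tps_kernel(d2: np.ndarray) -> np.ndarray:
    # r^2 log r = d2 * log(d2) / 2, with the limit 0 at r = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 0.5 * d2 * np.log(d2)
    k[~np.isfinite(k)] = 0.0
    return k


@dataclass
class ThinPlateSpline:
    """Classical 2-D thin-plate smoothing spline with optional GCV.

    Minimizes ``sum (y_i - f(x_i))^2 + n * lam * J(f)`` where J is the
    bending energy; the affine part is unpenalized, so planes are
    reproduced exactly at any lam.
    """

    coords: np.ndarray
    coef_radial: np.ndarray
    coef_affine: np.ndarray
    lam: float
    gcv_score: float
    fitted: np.ndarray
    edf: float

    @classmethod
    def fit(cls, coords, values, lam: float | str = "gcv") -> "ThinPlateSpline":
        xy = np.asarray(coords, dtype=float)
        y = np.asarray(values, dtype=float)
        n = len(y)
        if xy.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        if n < 10:
            raise ValueError("need at least 10 points for a surface fit")
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        if np.any(d2[~np.eye(n, dtype=bool)] == 0.0):
            raise ValueError("duplicate coordinates; deduplicate or jitter first")
        K = _tps_kernel(d2)
        P = np.column_stack([np.ones(n), xy])
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("collinear coordinates")
        Q, R = np.linalg.qr(P, mode="complete")
        Q1, Q2 = Q[:, :3], Q[:, 3:]
        B = Q2.T @ K @ Q2
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        z = U.T @ (Q2.T @ y)
        scale = max(np.abs(w).max(), 1e-12)

        def solve(lam_val: float):
            denom = w + n * lam_val
            # guard against indefiniteness from near-duplicate points
            denom = np.where(np.abs(denom) < 1e-10 * scale, 1e-10 * scale, denom)
            gamma = U @ (z / denom)
            c = Q2 @ gamma
            resid = n * lam_val * c
            tr_ia = n * lam_val * np.sum(1.0 / denom)
            gcv = n * float(resid @ resid) / max(tr_ia, 1e-12) ** 2
            return c, resid, gcv

        if lam == "gcv":
            grid = np.logspace(-9, 3, 40) * scale / n

            def obj(loglam):
                return solve(float(np.exp(loglam)))[2]

            scores = [obj(math.log(g)) for g in grid]
            i = int(np.argmin(scores))
            lo = math.log(grid[max(i - 1, 0)])
            hi = math.log(grid[min(i + 1, len(grid) - 1)])
            res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded")
            lam_val = float(np.exp(res.x))
        else:
            lam_val = float(lam)
            if lam_val < 0:
                raise ValueError("lam must be >= 0")
        c, resid, gcv = solve(max(lam_val, 1e-14 * scale / n))
        d = linalg.solve_triangular(R[:3, :3], Q1.T @ (y - K @ c))
        fitted = y - resid
        denom = w + n * lam_val
        edf = float(n - n * lam_val * np.sum(1.0 / np.where(denom == 0, np.inf, denom)))
        return cls(xy, c, d, lam_val, float(gcv), fitted, edf)

    def predict(self, coords) -> np.ndarray:
        xy = np.asarray(coords, dtype=float)
        d2 = ((xy[:, None, :] - self.coords[None, :, :]) ** 2).sum(-1)
        return _tps_kernel(d2) @ self.coef_radial + np.column_stack(
            [np.ones(len(xy)), xy]
        ) @ self.coef_affine

def fit_spatial_spline(
    coords, values, lam: float | str = "gcv"
) -> tuple[ThinPlateSpline, np.ndarray]:
    """Fit the microsite surface; returns (surface model, residuals)."""
    y = np.asarray(values, dtype=float)
    spl = ThinPlateSpline.fit(coords, y, lam=lam)
    return spl, y - spl.fitted


def spatial_correct(
    table: pd.DataFrame, trait: str, lam: float | str = "gcv"
) -> np.ndarray:
    """Remove the field surface: corrected = mean(raw) + spline residual.

    The rescaling keeps the corrected values on the original scale (their
    mean equals the raw mean).
    """
    for col in ("row", "col"):
        if col not in table or table[col].isna().any():
            raise ValueError("field coordinates required for spatial correction")
    y = table[trait].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    coords = table.loc[ok, ["row", "col"]].to_numpy(dtype=float)
    _, resid = fit_spatial_spline(coords, y[ok], lam=lam)
    out = np.full_like(y, np.nan)
    out[ok] = float(np.mean(y[ok])) + resid
    return out


# ---------------------------------------------------------------------------
# one-random-effect REML, BLUPs, exact RLRT
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    v_g: float
    v_e: float
    h2: float
    rlr_statistic: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        assert self.v_g >= 0 and self.v_e > 0
        assert abs(self.h2 - self.v_g / (self.v_g + self.v_e)) < 1e-12


@dataclass
class ClonalFit:
    """Fitted clonal mixed model, with enough state to re-simulate the null."""

    components: VarianceComponents
    blups: pd.Series
    beta: np.ndarray
    beta_null: np.ndarray
    loglik_full: float
    loglik_null: float
    v_e_null: float
    _X: np.ndarray
    _group_sizes: np.ndarray
    _group_index: np.ndarray
    singleton_only: bool = False


def _reml_profile(y: np.ndarray, X: np.ndarray, gidx: np.ndarray, sizes: np.ndarray):
    """Profiled REML for y = X beta + Z g + e with one grouping factor.

    Returns (lambda_hat, sigma2_hat, beta, restricted loglik at lambda_hat,
    restricted loglik at lambda = 0).  lambda = Vg / Ve.
    """
    n, p = X.shape
    q = len(sizes)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums of X columns and y
    GX = np.zeros((q, p))
    for j in range(p):
        GX[:, j] = np.bincount(gidx, weights=X[:, j], minlength=q)
    Gy = np.bincount(gidx, weights=y, minlength=q)

    def neg2_restricted(lam: float):
        shrink = lam / (1.0 + lam * sizes)  # per group
        XtWX = XtX - (GX * shrink[:, None]).T @ GX
        XtWy = Xty - (GX * shrink[:, None]).T @ Gy
        yWy = yty - float((shrink * Gy) @ Gy)
        try:
            cho = linalg.cho_factor(XtWX)
        except linalg.LinAlgError:
            return np.inf, None, None
        beta = linalg.cho_solve(cho, XtWy)
        rss = max(yWy - float(beta @ XtWy), 1e-300)
        sigma2 = rss / (n - p)
        logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        crit = (
            (n - p) * math.log(sigma2)
            + float(np.sum(np.log1p(lam * sizes)))
            + logdet_xwx
            + (n - p) * (1.0 + math.log(2 * math.pi))
        )
        return crit, sigma2, beta

    def obj(theta: float) -> float:
        return neg2_restricted(math.exp(theta))[0]

    res = optimize.minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded")
    crit0, sigma2_0, beta0 = neg2_restricted(0.0)
    lam_hat = float(math.exp(res.x))
    crit_hat = float(res.fun)
    if crit0 <= crit_hat:
        lam_hat, crit_hat = 0.0, crit0
    _, sigma2_hat, beta_hat = neg2_restricted(lam_hat)
    return lam_hat, sigma2_hat, beta_hat, -0.5 * crit_hat, -0.5 * crit0


def fit_clonal_model(
    table: pd.DataFrame, trait: str, covariate: str | None = None
) -> ClonalFit:
    """REML fit of ``y = mu (+ b * covariate) + genotype + error``.

    Returns variance components with H2 = Vg/(Vg+Ve), the restricted
    log-likelihoods of the full and the Vg = 0 null model, and per-genotype
    BLUPs (shrunken genotype-mean deviations); genotypes with no non-missing
    trait value are dropped.
    """
    cols = ["genotype_id", trait] + ([covariate] if covariate else [])
    sub = table[cols].dropna()
    if sub["genotype_id"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    y = sub[trait].to_numpy(dtype=float)
    groups, gidx = np.unique(sub["genotype_id"].to_numpy(), return_inverse=True)
    sizes = np.bincount(gidx).astype(float)
    singleton_only = bool(np.all(sizes < 2))
    if singleton_only:
        warnings.warn(
            "all genotypes are singletons; Vg is not identifiable", stacklevel=2
        )
    X = np.ones((len(y), 1))
    if covariate:
        X = np.column_stack([X, sub[covariate].to_numpy(dtype=float)])
    lam, sigma2, beta, ll_full, ll_null = _reml_profile(y, X, gidx, sizes)
    v_e = float(sigma2)
    v_g = float(lam * sigma2)
    comp = VarianceComponents(v_g, v_e, v_g / (v_g + v_e))
    resid = y - X @ beta
    gsum = np.bincount(gidx, weights=resid, minlength=len(groups))
    blup = lam * gsum / (1.0 + lam * sizes)
    # Ve under the Vg = 0 null (plain OLS), for parametric resimulation
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    r0 = y - X @ beta_ols
    v_e_null = float(r0 @ r0 / (len(y) - X.shape[1]))
    return ClonalFit(
        components=comp,
        blups=pd.Series(blup, index=groups, name=f"blup_{trait}"),
        beta=np.asarray(beta, dtype=float),
        beta_null=np.asarray(beta_ols, dtype=float),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        v_e_null=v_e_null,
        _X=X,
        _group_sizes=sizes,
        _group_index=gidx,
        singleton_only=singleton_only,
    )


def exact_rlrt(fit: ClonalFit, n_sim: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Simulation-based exact RLRT for the genotype variance component.

    The observed statistic is ``2 * (restricted loglik full - null)``,
    clipped at 0.  The null distribution is built parametrically: data are
    simulated under Vg = 0 with the fitted fixed effects and null residual
    variance, and both models are refitted per replicate.  The p-value uses
    the add-one convention ``(1 + #{sim >= obs}) / (1 + n_sim)``.
    """
    obs = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    rng = np.random.default_rng(seed)
    X = fit._X
    mu = X @ fit.beta_null
    sd = math.sqrt(fit.v_e_null)
    gidx = fit._group_index
    sizes = fit._group_sizes
    stats_null = np.empty(n_sim)
    for s in range(n_sim):
        ysim = mu + rng.normal(0.0, sd, size=len(mu))
        _, _, _, ll_f, ll_0 = _reml_profile(ysim, X, gidx, sizes)
        stats_null[s] = max(0.0, 2.0 * (ll_f - ll_0))
    p = (1.0 + float(np.sum(stats_null >= obs))) / (1.0 + n_sim)
    fit.components.rlr_statistic = obs
    fit.components.p_value = p
    return obs, p
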