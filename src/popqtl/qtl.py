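"""Genome scans for a two-class backcross.

Single-QTL interval mapping by the EM algorithm (normal and binary traits),
composite interval mapping with background marker covariates, genome-wide
permutation thresholds, percent variance explained for fitted QTL, allele
direction at peaks, and conversion of map peaks into fixed 1-Mb physical
intervals anchored on the top marker.

Genotype state is binary throughout: T (heterozygous, donor allele present)
versus D (homozygous recurrent parent).  Conditional genotype probabilities
on a cM grid come from a two-state hidden Markov chain with Haldane
transition fractions and a symmetric genotyping-error emission.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import GeneticMap, haldane_r

__all__ = [
    "GenotypeProbGrid",
    "Peak",
    "PhysicalInterval",
    "ScanResult",
    "genotype_probabilities",
    "scan_em_normal",
    "scan_binary",
    "cim",
    "permutation_threshold",
    "find_peaks",
    "fit_qtl_pve",
    "effect_direction",
    "peak_to_interval",
    "exclusive_subset_scan",
]

LN10 = math.log(10.0)
_PI_EPS = 1e-6  # penetrance clip, keeps binary LOD finite under separation


@dataclass
class GenotypeProbGrid:
    """P(genotype = T) per tree at marker and pseudomarker positions."""

    positions: pd.DataFrame  # columns: chrom, pos_cM, is_marker, marker
    prob_t: np.ndarray  # (n_individuals, n_positions)
    ids: np.ndarray

    def __post_init__(self) -> None:
        assert self.prob_t.shape == (len(self.ids), len(self.positions))
        assert np.all((self.prob_t >= 0) & (self.prob_t <= 1))

    def subset(self, mask: np.ndarray) -> "GenotypeProbGrid":
        return GenotypeProbGrid(self.positions, self.prob_t[mask], self.ids[mask])

    def marker_columns(self) -> np.ndarray:
        return np.flatnonzero(self.positions["is_marker"].to_numpy())


@dataclass
class Peak:
    chrom: int
    pos_cM: float
    lod: float
    p_value: float | None = None
    pve: float | None = None
    positive_allele: str | None = None


@dataclass
class PhysicalInterval:
    """1-based inclusive physical coordinates."""

    chrom: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end precedes start")


@dataclass
class ScanResult:
    positions: pd.DataFrame  # chrom, pos_cM, lod
    threshold: float | None = None
    perm_maxima: np.ndarray | None = None
    peaks: list[Peak] = field(default_factory=list)
    flagged_positions: list[int] = field(default_factory=list)

    @property
    def lod(self) -> np.ndarray:
        return self.positions["lod"].to_numpy()

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lod))


def genotype_probabilities(
    gmap: GeneticMap,
    geno: pd.DataFrame,
    step_cM: float = 1.0,
    error_rate: float = 1e-4,
) -> GenotypeProbGrid:
    """Forward-backward conditional genotype probabilities on a cM grid.

    Pseudomarkers are inserted every `step_cM`; at observed markers the
    emission puts mass 1 - error_rate on the observed class.  Missing calls
    are uninformative.
    """
    missing = [m for m in geno.columns if m not in set(gmap.table["marker"])]
    if missing:
        raise KeyError(f"markers absent from the map: {missing[:5]}")
    n = geno.shape[0]
    frames = []
    probs = []
    for c in gmap.chromosomes:
        sub = gmap.markers_on(c)
        length = gmap.chrom_length_cM[c]
        grid = np.arange(0.0, length + step_cM / 2, step_cM)
        pos = np.unique(np.concatenate([grid, sub["cM"].to_numpy()]))
        marker_at = {}
        for _, r in sub.iterrows():
            j = int(np.argmin(np.abs(pos - r["cM"])))
            marker_at[j] = r["marker"]
        # emissions: (n, n_pos, 2) collapsed to per-state likelihood factors
        em_t = np.ones((n, len(pos)))
        em_d = np.ones((n, len(pos)))
        for j, mname in marker_at.items():
            if mname not in geno.columns:
                continue
            v = geno[mname].to_numpy()
            is_t = v == "T"
            is_d = v == "D"
            em_t[:, j] = np.where(is_t, 1 - error_rate, np.where(is_d, error_rate, 1.0))
            em_d[:, j] = np.where(is_d, 1 - error_rate, np.where(is_t, error_rate, 1.0))
        r = haldane_r(np.diff(pos))
        # forward
        a_t = 0.5 * em_t[:, 0]
        a_d = 0.5 * em_d[:, 0]
        alphas_t = np.empty((n, len(pos)))
        alphas_d = np.empty((n, len(pos)))
        norm = a_t + a_d
        alphas_t[:, 0] = a_t / norm
        alphas_d[:, 0] = a_d / norm
        for j in range(1, len(pos)):
            rt = r[j - 1]
            pt = alphas_t[:, j - 1] * (1 - rt) + alphas_d[:, j - 1] * rt
            pdd = alphas_d[:, j - 1] * (1 - rt) + alphas_t[:, j - 1] * rt
            a_t = pt * em_t[:, j]
            a_d = pdd * em_d[:, j]
            norm = a_t + a_d
            alphas_t[:, j] = a_t / norm
            alphas_d[:, j] = a_d / norm
        # backward
        b_t = np.ones(n)
        b_d = np.ones(n)
        post = np.empty((n, len(pos)))
        post[:, -1] = alphas_t[:, -1] * b_t / (
            alphas_t[:, -1] * b_t + alphas_d[:, -1] * b_d
        )
        for j in range(len(pos) - 2, -1, -1):
            rt = r[j]
            nt = em_t[:, j + 1] * b_t
            nd = em_d[:, j + 1] * b_d
            b_t = (1 - rt) * nt + rt * nd
            b_d = (1 - rt) * nd + rt * nt
            norm = b_t + b_d
            b_t = b_t / norm
            b_d = b_d / norm
            denom = alphas_t[:, j] * b_t + alphas_d[:, j] * b_d
            post[:, j] = alphas_t[:, j] * b_t / denom
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos_cM": pos,
                    "is_marker": [j in marker_at for j in range(len(pos))],
                    "marker": [marker_at.get(j) for j in range(len(pos))],
                }
            )
        )
        probs.append(post)
    positions = pd.concat(frames, ignore_index=True)
    return GenotypeProbGrid(positions, np.hstack(probs), np.asarray(geno.index))


# ---------------------------------------------------------------------------
# EM scans
# ---------------------------------------------------------------------------


def _null_normal_loglik(y: np.ndarray, X: np.ndarray | None) -> float:
    n = len(y)
    if X is None:
        rss = float(np.sum((y - y.mean()) ** 2))
    else:
        Xd = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rss = float(np.sum((y - Xd @ beta) ** 2))
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _em_normal_vectorized(
    y: np.ndarray, w: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """EM over all positions at once (no covariates).

    Returns (loglik, mu_t, mu_d, sigma2, flagged position indices).
    """
    n, P = w.shape
    yc = y[:, None]
    sw = w.sum(0)
    sw = np.clip(sw, 1e-9, None)
    swc = np.clip((1.0 - w).sum(0), 1e-9, None)
    mu_t = (w * yc).sum(0) / sw
    mu_d = ((1 - w) * yc).sum(0) / swc
    sigma2 = np.full(P, max(float(np.var(y)), 1e-12))
    ll_old = np.full(P, -np.inf)
    active = np.ones(P, dtype=bool)
    flagged: list[int] = []
    for it in range(max_iter):
        dt = yc - mu_t[None, :]
        dd = yc - mu_d[None, :]
        inv2s = 0.5 / sigma2[None, :]
        ft = np.exp(-dt * dt * inv2s)
        fd = np.exp(-dd * dd * inv2s)
        num = w * ft
        den = num + (1 - w) * fd
        den = np.clip(den, 1e-300, None)
        p = num / den
        ll = np.log(den).sum(0) - 0.5 * n * np.log(2 * np.pi * sigma2)
        if it > 0:
            drop = ll < ll_old - 1e-6
            if np.any(drop):  # EM must not decrease the likelihood
                raise AssertionError("EM log-likelihood decreased")
            active = (ll - ll_old) > tol
        ll_old = ll
        if not np.any(active):
            break
        sp = np.clip(p.sum(0), 1e-9, None)
        spc = np.clip((1 - p).sum(0), 1e-9, None)
        mu_t = (p * yc).sum(0) / sp
        mu_d = ((1 - p) * yc).sum(0) / spc
        dt = yc - mu_t[None, :]
        dd = yc - mu_d[None, :]
        sigma2 = (p * dt * dt + (1 - p) * dd * dd).sum(0) / n
        sigma2 = np.clip(sigma2, 1e-12, None)
    else:
        flagged = list(np.flatnonzero(active))
    return ll_old, mu_t, mu_d, sigma2, flagged


def _em_normal_position(
    y: np.ndarray,
    w: np.ndarray,
    X: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[float, bool]:
    """EM at one position with fixed covariates X (n, k); returns (loglik, flag)."""
    n = len(y)
    k = X.shape[1]
    # params: mu_t, mu_d, alpha (k)
    beta0, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)
    mu_t = mu_d = float(beta0[0])
    alpha = beta0[1:]
    # nudge the means apart using the prior weights so EM can separate them
    resid0 = y - X @ alpha
    mu_t = float((w * resid0).sum() / max(w.sum(), 1e-9))
    mu_d = float(((1 - w) * resid0).sum() / max((1 - w).sum(), 1e-9))
    sigma2 = max(float(np.var(resid0)), 1e-12)
    ll_old = -np.inf
    for it in range(max_iter):
        eta = X @ alpha
        dt = y - eta - mu_t
        dd = y - eta - mu_d
        ft = np.exp(-0.5 * dt * dt / sigma2)
        fd = np.exp(-0.5 * dd * dd / sigma2)
        den = np.clip(w * ft + (1 - w) * fd, 1e-300, None)
        p = w * ft / den
        ll = float(np.log(den).sum() - 0.5 * n * math.log(2 * math.pi * sigma2))
        if ll < ll_old - 1e-6:
            raise AssertionError("EM log-likelihood decreased")
        if ll - ll_old <= tol:
            return ll, False
        ll_old = ll
        # M-step: weighted LS on the duplicated design [I(T), I(D), X]
        A = np.zeros((k + 2, k + 2))
        b = np.zeros(k + 2)
        sp = p.sum()
        spc = n - sp
        A[0, 0] = sp
        A[1, 1] = spc
        A[0, 2:] = p @ X
        A[2:, 0] = A[0, 2:]
        A[1, 2:] = (1 - p) @ X
        A[2:, 1] = A[1, 2:]
        A[2:, 2:] = X.T @ X
        b[0] = p @ y
        b[1] = (1 - p) @ y
        b[2:] = X.T @ y
        try:
            theta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            theta, *_ = np.linalg.lstsq(A, b, rcond=None)
        mu_t, mu_d, alpha = float(theta[0]), float(theta[1]), theta[2:]
        eta = X @ alpha
        dt = y - eta - mu_t
        dd = y - eta - mu_d
        sigma2 = max(float((p * dt * dt + (1 - p) * dd * dd).sum() / n), 1e-12)
    return ll_old, True


def scan_em_normal(
    grid: GenotypeProbGrid,
    y,
    covariates: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    position_covariates: list[np.ndarray | None] | None = None,
) -> ScanResult:
    """Single-QTL scan for a continuous trait by a 2-component normal mixture.

    At each grid position the mixture ``y_i ~ N(mu_g + x_i'alpha, sigma^2)``
    with mixing weights equal to the conditional genotype probabilities is
    fitted by EM; LOD = log10 of the likelihood ratio against the model
    without the genotype mean split (covariates retained).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(grid.ids):
        raise ValueError("trait vector does not match the probability grid")
    if covariates is not None and position_covariates is not None:
        raise ValueError("pass either global or per-position covariates, not both")
    flagged: list[int] = []
    if covariates is None and position_covariates is None:
        ll0 = _null_normal_loglik(y, None)
        ll, _, _, _, flagged = _em_normal_vectorized(y, grid.prob_t, tol, max_iter)
        lod = (ll - ll0) / LN10
    else:
        P = grid.prob_t.shape[1]
        lod = np.empty(P)
        for j in range(P):
            X = covariates if covariates is not None else position_covariates[j]
            w = grid.prob_t[:, j]
            if X is None:
                llj, _, _, _, fl = _em_normal_vectorized(y, w[:, None], tol, max_iter)
                llj = float(llj[0])
                flag = bool(fl)
                ll0 = _null_normal_loglik(y, None)
            else:
                X = np.atleast_2d(np.asarray(X, dtype=float))
                if X.shape[0] != len(y):
                    X = X.T
                llj, flag = _em_normal_position(y, w, X, tol, max_iter)
                ll0 = _null_normal_loglik(y, X)
            lod[j] = (llj - ll0) / LN10
            if flag:
                flagged.append(j)
    positions = grid.positions.copy()
    positions["lod"] = np.maximum(lod, 0.0)
    return ScanResult(positions, flagged_positions=flagged)


def scan_binary(
    grid: GenotypeProbGrid,
    y,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ScanResult:
    """Single-QTL scan for a binary trait via a two-penetrance mixture.

    P(y=1 | g) = pi_g, fitted by EM with genotype-probability weights; the
    null has a single penetrance.  Penetrances are clipped away from 0/1 so
    LOD stays finite under complete separation.
    """
    y = np.asarray(y, dtype=float)
    vals = np.unique(y[~np.isnan(y)])
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("binary trait must be coded 0/1")
    if len(vals) < 2:
        raise ValueError("degenerate trait: only one class present")
    n, P = grid.prob_t.shape
    w = grid.prob_t
    yc = y[:, None]
    pbar = float(y.mean())
    ll0 = n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
    pi_t = np.clip((w * yc).sum(0) / np.clip(w.sum(0), 1e-9, None), _PI_EPS, 1 - _PI_EPS)
    pi_d = np.clip(
        ((1 - w) * yc).sum(0) / np.clip((1 - w).sum(0), 1e-9, None), _PI_EPS, 1 - _PI_EPS
    )
    ll_old = np.full(P, -np.inf)
    flagged: list[int] = []
    for it in range(max_iter):
        ft = np.where(yc == 1, pi_t[None, :], 1 - pi_t[None, :])
        fd = np.where(yc == 1, pi_d[None, :], 1 - pi_d[None, :])
        den = np.clip(w * ft + (1 - w) * fd, 1e-300, None)
        p = w * ft / den
        ll = np.log(den).sum(0)
        if it > 0 and np.any(ll < ll_old - 1e-6):
            raise AssertionError("EM log-likelihood decreased")
        active = (ll - ll_old) > tol
        ll_old = ll
        if not np.any(active):
            break
        pi_t = np.clip((p * yc).sum(0) / np.clip(p.sum(0), 1e-9, None), _PI_EPS, 1 - _PI_EPS)
        pi_d = np.clip(
            ((1 - p) * yc).sum(0) / np.clip((1 - p).sum(0), 1e-9, None),
            _PI_EPS,
            1 - _PI_EPS,
        )
    else:
        flagged = list(np.flatnonzero(active))
    positions = grid.positions.copy()
    positions["lod"] = np.maximum((ll_old - ll0) / LN10, 0.0)
    return ScanResult(positions, flagged_positions=flagged)


# ---------------------------------------------------------------------------
# composite interval mapping
# ---------------------------------------------------------------------------


def _expected_code(grid: GenotypeProbGrid, j: int) -> np.ndarray:
    """Expected +/-1 genotype code at grid column j."""
    return 2.0 * grid.prob_t[:, j] - 1.0


def select_cim_covariates(
    grid: GenotypeProbGrid,
    y,
    n_covar: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[int]:
    """Forward selection of background marker covariates by single-marker LOD."""
    marker_cols = grid.marker_columns()
    if n_covar >= len(marker_cols):
        raise ValueError("n_covar must be smaller than the marker count")
    chosen: list[int] = []
    for _ in range(n_covar):
        X = (
            np.column_stack([_expected_code(grid, j) for j in chosen])
            if chosen
            else None
        )
        best_j, best_lod = -1, -np.inf
        for j in marker_cols:
            if j in chosen:
                continue
            w = grid.prob_t[:, j]
            sub = GenotypeProbGrid(
                grid.positions.iloc[[j]].reset_index(drop=True),
                w[:, None],
                grid.ids,
            )
            res = scan_em_normal(sub, y, covariates=X, tol=tol, max_iter=max_iter)
            if res.lod[0] > best_lod:
                best_lod, best_j = float(res.lod[0]), int(j)
        chosen.append(best_j)
    return chosen


def cim(
    grid: GenotypeProbGrid,
    y,
    n_covar: int = 3,
    window_cM: float = 10.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    covariate_cols: list[int] | None = None,
) -> ScanResult:
    """Composite interval mapping: EM scan with background marker covariates.

    Covariate markers are chosen by forward selection on single-marker LOD;
    at each scan position every covariate lying within `window_cM` of the
    position (same chromosome) is dropped, so a covariate never absorbs the
    signal it sits on.  ``n_covar=0`` reduces to the plain single-QTL scan.
    """
    y = np.asarray(y, dtype=float)
    if n_covar == 0:
        return scan_em_normal(grid, y, tol=tol, max_iter=max_iter)
    if covariate_cols is None:
        covariate_cols = select_cim_covariates(grid, y, n_covar, tol, max_iter)
    codes = {j: _expected_code(grid, j) for j in covariate_cols}
    pos = grid.positions
    per_position: list[np.ndarray | None] = []
    for i in range(len(pos)):
        keep = [
            j
            for j in covariate_cols
            if not (
                pos["chrom"].iloc[j] == pos["chrom"].iloc[i]
                and abs(pos["pos_cM"].iloc[j] - pos["pos_cM"].iloc[i]) <= window_cM
            )
        ]
        per_position.append(
            np.column_stack([codes[j] for j in keep]) if keep else None
        )
    return scan_em_normal(
        grid, y, position_covariates=per_position, tol=tol, max_iter=max_iter
    )


# ---------------------------------------------------------------------------
# permutations, peaks, PVE, effects, intervals
# ---------------------------------------------------------------------------


def permutation_threshold(
    scan_fn,
    y,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from trait permutations.

    `scan_fn(y_permuted)` must return a ScanResult.  The threshold is the
    empirical (1 - alpha) quantile (type-7) of per-permutation genome-wide
    maxima; the maxima are returned so peak p-values can use the add-one
    convention.
    """
    if n_perm < 20 / alpha:
        warnings.warn(
            f"n_perm={n_perm} is small for alpha={alpha}; threshold will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        maxima[b] = scan_fn(rng.permutation(y)).max_lod
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="linear"))
    return threshold, maxima


def find_peaks(
    scan: ScanResult,
    threshold: float,
    perm_maxima: np.ndarray | None = None,
) -> list[Peak]:
    """One peak per chromosome: its maximum-LOD position, kept if >= threshold."""
    peaks = []
    for c, sub in scan.positions.groupby("chrom"):
        i = sub["lod"].idxmax()
        lod = float(sub.loc[i, "lod"])
        if lod >= threshold:
            p = None
            if perm_maxima is not None:
                p = (1.0 + float(np.sum(perm_maxima >= lod))) / (1.0 + len(perm_maxima))
            peaks.append(Peak(int(c), float(sub.loc[i, "pos_cM"]), lod, p_value=p))
    scan.threshold = threshold
    scan.perm_maxima = perm_maxima
    scan.peaks = peaks
    return peaks


def _grid_column(grid: GenotypeProbGrid, chrom: int, pos_cM: float) -> int:
    pos = grid.positions
    sel = pos.index[pos["chrom"] == chrom]
    if len(sel) == 0:
        raise KeyError(f"chromosome {chrom} not on grid")
    sub = pos.loc[sel]
    return int(sel[np.argmin(np.abs(sub["pos_cM"].to_numpy() - pos_cM))])


def fit_qtl_pve(
    grid: GenotypeProbGrid, y, peaks: list[Peak]
) -> tuple[float, list[Peak]]:
    """Percent variance explained by a joint linear model on all peaks.

    Peaks closer than 1 cM on the same chromosome are merged (higher LOD
    wins).  Model PVE = 100 (RSS0 - RSS_full) / RSS0; per-peak PVE by
    drop-one refits against the same null RSS.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    merged: list[Peak] = []
    for pk in sorted(peaks, key=lambda p: -p.lod):
        if any(
            pk.chrom == m.chrom and abs(pk.pos_cM - m.pos_cM) < 1.0 for m in merged
        ):
            continue
        merged.append(pk)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = [_grid_column(grid, p.chrom, p.pos_cM) for p in merged]
    codes = np.column_stack([_expected_code(grid, j) for j in cols])

    def rss_of(Xc: np.ndarray | None) -> float:
        X = np.ones((n, 1)) if Xc is None else np.column_stack([np.ones(n), Xc])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0 = rss_of(None)
    rss_full = rss_of(codes)
    model_pve = 100.0 * (rss0 - rss_full) / rss0
    out = []
    for k, pk in enumerate(merged):
        if codes.shape[1] == 1:
            pve_k = model_pve
        else:
            rss_k = rss_of(np.delete(codes, k, axis=1))
            pve_k = 100.0 * (rss_k - rss_full) / rss0
        out.append(replace(pk, pve=float(np.clip(pve_k, 0.0, 100.0))))
    return float(np.clip(model_pve, 0.0, 100.0)), out


def effect_direction(
    grid: GenotypeProbGrid, y, peak: Peak
) -> tuple[str, dict[str, tuple[float, float]]]:
    """Probability-weighted class means at a peak and the susceptibility allele.

    Returns (positive allele "T"/"D"/"NA", {class: (mean, SE)}).  T denotes
    heterozygous carriers of the donor allele, D homozygous recurrent
    parent; the positive allele is the class with the larger mean.
    """
    y = np.asarray(y, dtype=float)
    j = _grid_column(grid, peak.chrom, peak.pos_cM)
    w = grid.prob_t[:, j]
    sw, swc = float(w.sum()), float((1 - w).sum())
    if sw < 1e-9 or swc < 1e-9:
        raise ValueError("degenerate class weights at peak")
    m_t = float((w * y).sum() / sw)
    m_d = float(((1 - w) * y).sum() / swc)
    var_t = float((w * (y - m_t) ** 2).sum() / sw)
    var_d = float(((1 - w) * (y - m_d) ** 2).sum() / swc)
    n_eff_t = sw**2 / max(float((w**2).sum()), 1e-12)
    n_eff_d = swc**2 / max(float(((1 - w) ** 2).sum()), 1e-12)
    means = {
        "T": (m_t, math.sqrt(var_t / max(n_eff_t, 1.0))),
        "D": (m_d, math.sqrt(var_d / max(n_eff_d, 1.0))),
    }
    if abs(m_t - m_d) < 1e-12:
        return "NA", means
    direction = "T" if m_t > m_d else "D"
    peak.positive_allele = direction
    return direction, means


def peak_to_interval(
    peak: Peak,
    scan: ScanResult,
    gmap: GeneticMap,
    half_width_bp: int = 500_000,
    max_snap_cM: float = 5.0,
) -> PhysicalInterval:
    """Fixed 1-Mb physical interval centred on the top genotyped marker.

    The peak (possibly a pseudomarker) snaps to the highest-LOD genotyped
    marker with a physical anchor within `max_snap_cM`; the interval is
    ``[anchor - half + 1, anchor + half]`` clipped to the chromosome.
    """
    markers = gmap.markers_on(peak.chrom)
    near = markers[np.abs(markers["cM"] - peak.pos_cM) <= max_snap_cM]
    if near.empty:
        raise ValueError(
            f"no anchored marker within {max_snap_cM} cM of peak at "
            f"chr{peak.chrom}:{peak.pos_cM} cM"
        )
    pos = scan.positions
    chrom_pos = pos[pos["chrom"] == peak.chrom]
    lods = []
    for _, mk in near.iterrows():
        i = int(np.argmin(np.abs(chrom_pos["pos_cM"].to_numpy() - mk["cM"])))
        lods.append(float(chrom_pos["lod"].iloc[i]))
    best = near.iloc[int(np.argmax(lods))]
    anchor = int(best["bp"])
    chrom_end = gmap.chrom_length_bp[peak.chrom]
    start = max(1, anchor - half_width_bp + 1)
    end = min(chrom_end, anchor + half_width_bp)
    return PhysicalInterval(peak.chrom, start, end)


def exclusive_subset_scan(
    grid: GenotypeProbGrid,
    y_a,
    y_b,
    scan_fn=scan_em_normal,
) -> tuple[ScanResult, ScanResult]:
    """Scans of each trait restricted to individuals free of the other.

    Trait A is re-scanned on individuals with B == 0 and vice versa,
    mirroring the exclusion of co-infected trees when two pathogens
    compete.  Subsets smaller than 50 individuals are computed with a
    warning.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    mask_a = y_b == 0
    mask_b = y_a == 0
    for name, m in (("A", mask_a), ("B", mask_b)):
        if m.sum() < 50:
            warnings.warn(
                f"subset for trait {name} has only {int(m.sum())} individuals",
                stacklevel=2,
            )

    def _scan(mask: np.ndarray, y: np.ndarray) -> ScanResult | None:
        if mask.sum() < 2:
            return None
        return scan_fn(grid.subset(mask), y[mask])

    return _scan(mask_a, y_a), _scan(mask_b, y_b)
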