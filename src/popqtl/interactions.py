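"""Competing-pathogen analysis: sequential ANOVA and Tukey mean grouping.

When two leaf pathogens share host tissue, the severity of one can depend
on the other.  The model here fits genotype first (as a fixed factor
absorbing host genetic differences) and then the competitor's severity
score as a categorical factor, with Type-I (sequential) sums of squares, so
the competitor effect is tested on top of genotype.  Tukey's honest
significant difference groups the severity means of the competitor levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.libqsturng import qsturng

__all__ = ["AnovaTable", "sequential_anova", "tukey_groups", "f_ratio"]


def f_ratio(mean_square: float, residual_mean_square: float) -> float:
    """F statistic as the ratio of a factor mean square to the residual."""
    if residual_mean_square <= 0:
        raise ValueError("residual mean square must be positive")
    return mean_square / residual_mean_square


@dataclass
class AnovaTable:
    """Sequential ANOVA table; identities MS = SS/df and F = MS/MS_res hold exactly."""

    table: pd.DataFrame  # rows: factors then Residuals; columns df, sum_sq, mean_sq, F, p

    def __post_init__(self) -> None:
        t = self.table
        ms_res = t.loc["Residuals", "mean_sq"]
        for name, row in t.iterrows():
            assert abs(row["mean_sq"] - row["sum_sq"] / row["df"]) <= 1e-9 * max(
                1.0, abs(row["mean_sq"])
            )
            if name != "Residuals":
                assert abs(row["F"] - row["mean_sq"] / ms_res) <= 1e-9 * max(
                    1.0, abs(row["F"])
                )


def _factor_projection_ss(y: np.ndarray, design_cols: list[np.ndarray]) -> float:
    X = np.column_stack(design_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2))


def sequential_anova(
    y, genotype_factor, score_factor
) -> AnovaTable:
    """Type-I ANOVA fitting genotype first, then the competitor score factor.

    Both predictors are categorical; F ratios test each factor's mean
    square against the residual.  Raises when the residual degrees of
    freedom are exhausted; a constant response is rejected up front.
    """
    y = np.asarray(y, dtype=float)
    g = pd.Categorical(np.asarray(genotype_factor))
    s = pd.Categorical(np.asarray(score_factor))
    if len(s.categories) < 2:
        raise ValueError("score factor needs at least 2 levels")
    if np.allclose(y, y[0]):
        raise ValueError("constant response: all sums of squares are zero")
    n = len(y)

    def dummies(cat: pd.Categorical) -> np.ndarray:
        return pd.get_dummies(cat, drop_first=True, dtype=float).to_numpy()

    ones = np.ones((n, 1))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    Xg = np.column_stack([ones, dummies(g)])
    rss_g = _factor_projection_ss(y, [Xg])
    Xgs = np.column_stack([Xg, dummies(s)])
    rss_gs = _factor_projection_ss(y, [Xgs])

    df_g = len(g.categories) - 1
    df_s = np.linalg.matrix_rank(Xgs) - np.linalg.matrix_rank(Xg)
    df_res = n - int(np.linalg.matrix_rank(Xgs))
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    ss_g = rss_null - rss_g
    ss_s = rss_g - rss_gs
    ms_res = rss_gs / df_res
    rows = []
    for name, ss, df in (
        ("Genotype", ss_g, df_g),
        ("Score", ss_s, int(df_s)),
    ):
        ms = ss / df
        F = ms / ms_res
        p = float(stats.f.sf(F, df, df_res))
        rows.append((name, df, ss, ms, F, p))
    rows.append(("Residuals", df_res, rss_gs, ms_res, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["factor", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("factor")
    return AnovaTable(table)


def _compact_letter_display(
    levels: list, not_different: set[tuple]
) -> dict:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter are not significantly different.
    """
    letter_sets: list[set] = []
    # one letter per level to start, merged wherever all pairs are compatible
    for lvl in levels:
        placed = False
        for grp in letter_sets:
            if all((min(lvl, o), max(lvl, o)) in not_different for o in grp):
                grp.add(lvl)
                placed = True
        if not placed:
            letter_sets.append({lvl})
    # absorb subsets
    letter_sets = [
        g
        for i, g in enumerate(letter_sets)
        if not any(g < h for j, h in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lvl: "" for lvl in levels}
    for letter, grp in zip(alphabet, letter_sets):
        for lvl in sorted(grp):
            out[lvl] += letter
    return out


def tukey_groups(y, score_factor, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over factor-level means with a compact letter display.

    Pairwise comparisons use studentized-range critical values on the
    pooled within-level variance; levels sharing a letter are not
    significantly different at `alpha`.  Levels with fewer than 2
    observations are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    s = pd.Series(np.asarray(score_factor))
    sizes = s.groupby(s).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping levels with < 2 observations: {small}", stacklevel=2)
        keep = ~s.isin(small)
        y, s = y[keep.to_numpy()], s[keep].reset_index(drop=True)
    levels = sorted(s.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 usable levels")
    means = {lvl: float(y[(s == lvl).to_numpy()].mean()) for lvl in levels}
    ns = {lvl: int((s == lvl).sum()) for lvl in levels}
    df_res = len(y) - len(levels)
    mse = (
        sum(float(np.sum((y[(s == lvl).to_numpy()] - means[lvl]) ** 2)) for lvl in levels)
        / df_res
    )
    q_crit = float(qsturng(1 - alpha, len(levels), df_res))
    not_different: set[tuple] = set()
    for a, b in combinations(levels, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se if se > 0 else np.inf
        if q < q_crit:
            not_different.add((min(a, b), max(a, b)))
    letters = _compact_letter_display(levels, not_different)
    return pd.DataFrame(
        {
            "level": levels,
            "n": [ns[l] for l in levels],
            "mean": [means[l] for l in levels],
            "group": [letters[l] for l in levels],
        }
    )
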