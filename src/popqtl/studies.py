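"""Reproducible validation studies for the pipeline's statistical engines.

Each function runs a self-contained simulation study at the package's
reference conditions - oracle agreement for the tandem clustering and the
EM scans, null calibration for the Monte Carlo enrichment test and the
permutation thresholds, power and recovery studies for planted signals -
and returns a scalar summary plus the problem size.  They back both the
test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd

from . import compgen, phenotype, qtl
from .simulate import (
    GenomeConfig,
    QTLSpec,
    SimConfig,
    TraitModel,
    SpatialConfig,
    make_map,
    simulate_backcross,
    simulate_cds_pairs,
    simulate_genome,
    simulate_phenotypes,
)

__all__ = [
    "tandem_oracle_agreement",
    "enrichment_calibration",
    "enrichment_power",
    "em_lod_oracle_max_diff",
    "permutation_type1_rate",
    "qtl_localization_rate",
    "h2_recovery_mae",
    "ng86_oracle_max_diff",
    "omega_recovery_error",
    "spline_surface_correlation",
]


# ---------------------------------------------------------------------------
# tandem clustering vs. a plain union-find oracle
# ---------------------------------------------------------------------------


def _union_find_oracle(catalog: pd.DataFrame, homology: pd.DataFrame,
                       log_cut: float = -180.0, window: int = 500_000):
    """Naive all-pairs filter + dict union-find, kept deliberately simple."""
    chrom = dict(zip(catalog["gene_id"], catalog["chrom"]))
    start = dict(zip(catalog["gene_id"], catalog["start"]))
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for q, s, e in zip(homology["query"], homology["subject"],
                       homology["log10_evalue"]):
        if q == s or q not in chrom or s not in chrom:
            continue
        if e >= log_cut or chrom[q] != chrom[s]:
            continue
        if abs(start[q] - start[s]) > window:
            continue
        parent[find(q)] = find(s)
    comps: dict[str, list[str]] = {}
    for g in list(parent):
        comps.setdefault(find(g), []).append(g)
    return sorted(sorted(c) for c in comps.values() if len(c) >= 2)


def tandem_oracle_agreement(n_catalogs: int = 50, max_genes: int = 500,
                            seed: int = 0) -> tuple[float, int]:
    """Fraction of random catalogs where clustering equals the oracle exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_catalogs):
        n = int(rng.integers(40, max_genes))
        rows = []
        for c in (1, 2, 3):
            k = max(n // 3, 5)
            starts = np.sort(rng.integers(0, 4_000_000, k))
            rows += [(f"g{c}_{i}", c, int(s), int(s) + 500, "+")
                     for i, s in enumerate(starts)]
        cat = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        cat = cat.sort_values(["chrom", "start"]).reset_index(drop=True)
        cat["index"] = cat.groupby("chrom").cumcount()
        ids = cat["gene_id"].to_numpy()
        m = 4 * len(ids)
        ai = rng.integers(0, len(ids), m)
        bi = rng.integers(0, len(ids), m)
        hom = pd.DataFrame(
            {"query": ids[ai], "subject": ids[bi],
             "log10_evalue": rng.uniform(-400, -50, m),
             "pident": 90.0, "length": 300}
        )
        hom = hom[hom["query"] != hom["subject"]]
        got = sorted(sorted(c.genes)
                     for c in compgen.detect_tandem_duplicates(cat, hom).clusters)
        agree += got == _union_find_oracle(cat, hom)
    return agree / n_catalogs, n_catalogs


# ---------------------------------------------------------------------------
# Monte Carlo enrichment: null calibration and power
# ---------------------------------------------------------------------------


def _genome_cfg(seed: int, factor: float, n_chrom: int = 10,
                genes_per_chrom: int = 2_000, rate: float = 0.05,
                n_intervals: int = 5, interval_genes: int = 120) -> SimConfig:
    intervals = tuple(
        (1 + (j % n_chrom), 300 + 150 * (j // n_chrom), interval_genes)
        for j in range(n_intervals)
    )
    return SimConfig(
        n_chrom=n_chrom, seed=seed,
        genome=GenomeConfig(genes_per_chrom=genes_per_chrom,
                            mean_intergenic_bp=8_000,
                            tandem_base_rate=rate,
                            tandem_enrichment_factor=factor,
                            intervals=intervals),
    )


def _enrichment_pvalue(cfg: SimConfig, n_iter: int, seed: int) -> float:
    cat, hom, truth = simulate_genome(cfg)
    clusters = compgen.detect_tandem_duplicates(cat, hom)
    ivs = [qtl.PhysicalInterval(c, s, e) for c, s, e in truth.interval_bp]
    res = compgen.monte_carlo_enrichment(
        cat, clusters.flags, intervals=ivs, n_iter=n_iter, seed=seed
    )
    return res.p_value


def enrichment_calibration(n_rep: int = 200, n_iter: int = 1_000,
                           alpha: float = 0.05, seed: int = 0) -> tuple[float, int]:
    """Type-I error of the enrichment test on homogeneous null genomes."""
    rejections = 0
    for i in range(n_rep):
        p = _enrichment_pvalue(_genome_cfg((seed * 100_003 + i) % 2_147_483_629, factor=1.0),
                               n_iter=n_iter, seed=seed + i)
        rejections += p <= alpha
    return rejections / n_rep, n_rep


def enrichment_power(n_rep: int = 100, factor: float = 3.0, n_iter: int = 1_000,
                     alpha: float = 0.05, seed: int = 1) -> tuple[float, int]:
    """Detection rate when the planted intervals carry `factor`-fold tandems."""
    hits = 0
    for i in range(n_rep):
        p = _enrichment_pvalue(_genome_cfg((seed * 200_003 + i) % 2_147_483_629, factor=factor),
                               n_iter=n_iter, seed=seed + i)
        hits += p < alpha
    return hits / n_rep, n_rep


# ---------------------------------------------------------------------------
# EM scan oracle and permutation calibration
# ---------------------------------------------------------------------------


def _informative_grid(codes: np.ndarray) -> qtl.GenotypeProbGrid:
    positions = pd.DataFrame(
        {"chrom": [1], "pos_cM": [0.0], "is_marker": [True], "marker": ["m0"]}
    )
    return qtl.GenotypeProbGrid(
        positions, (codes == 1).astype(float)[:, None],
        np.array([f"G{i}" for i in range(len(codes))]),
    )


def em_lod_oracle_max_diff(n_rep: int = 20, n: int = 200,
                           seed: int = 0) -> tuple[float, int]:
    """Max |EM LOD - closed form| at fully informative markers (normal + binary)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rep):
        codes = rng.integers(0, 2, n) * 2 - 1
        grid = _informative_grid(codes)
        y = 0.4 * codes + rng.standard_normal(n)
        res = qtl.scan_em_normal(grid, y)
        rss0 = float(np.sum((y - y.mean()) ** 2))
        rss1 = sum(float(np.sum((y[codes == s] - y[codes == s].mean()) ** 2))
                   for s in (-1, 1))
        worst = max(worst, abs(res.lod[0] - (n / 2) * math.log10(rss0 / rss1)))
        yb = (rng.random(n) < np.where(codes == 1, 0.65, 0.35)).astype(float)
        if len(np.unique(yb)) < 2:
            continue
        resb = qtl.scan_binary(grid, yb)
        g_stat = 0.0
        for s in (-1, 1):
            for v in (0.0, 1.0):
                obs = np.sum((codes == s) & (yb == v))
                exp = np.sum(codes == s) * np.mean(yb == v)
                if obs > 0:
                    g_stat += 2 * obs * math.log(obs / exp)
        worst = max(worst, abs(resb.lod[0] - g_stat / (2 * math.log(10))))
    return worst, n_rep


def _null_scan_setup(seed: int, n: int = 200):
    cfg = SimConfig(n_chrom=3, markers_per_chrom=6, chrom_length_cM=60.0,
                    n_genotypes=n, missing_rate=0.0, seed=seed,
                    trait_models={"t": TraitModel(h2=0.0)})
    m = make_map(cfg)
    g = simulate_backcross(m, cfg)
    grid = qtl.genotype_probabilities(m, g, step_cM=4.0)
    return grid


def permutation_type1_rate(n_rep: int = 200, n_perm: int = 200,
                           alpha: float = 0.05, seed: int = 0) -> tuple[float, int]:
    """Genome-wide type-I error of the permutation threshold on null traits."""
    grid = _null_scan_setup(seed)
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    import warnings as _warnings

    for i in range(n_rep):
        y = rng.standard_normal(len(grid.ids))
        res = qtl.scan_em_normal(grid, y)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            thr, _ = qtl.permutation_threshold(
                lambda yy: qtl.scan_em_normal(grid, yy), y,
                n_perm=n_perm, alpha=alpha, seed=seed + 10 + i,
            )
        rejections += res.max_lod > thr
    return rejections / n_rep, n_rep


def qtl_localization_rate(n_rep: int = 50, n: int = 400,
                          tolerance_cM: float = 10.0, seed: int = 0) -> tuple[float, int]:
    """Recovery of a planted QTL explaining ~20% of trait variance.

    The QTL effect of 1.0 on a 1:1 backcross contributes variance 0.25;
    with residual variance 1.0 and no polygenic background that is 20% of
    the total.
    """
    hits = 0
    for i in range(n_rep):
        cfg = SimConfig(n_chrom=5, markers_per_chrom=11, chrom_length_cM=100.0,
                        n_genotypes=n, ramets_per_genotype=1, missing_rate=0.0,
                        seed=(seed * 300_007 + i) % 2_147_483_629,
                        qtl_spec=(QTLSpec(3, 50.0, 1.0, "t"),),
                        trait_models={"t": TraitModel(h2=0.2, error_var=1.0)})
        m = make_map(cfg)
        g = simulate_backcross(m, cfg)
        ph, _ = simulate_phenotypes(g, m, cfg)
        y = ph.groupby("genotype_id")["t"].mean().reindex(g.index).to_numpy()
        grid = qtl.genotype_probabilities(m, g, step_cM=2.0)
        res = qtl.scan_em_normal(grid, y)
        best = res.positions.iloc[int(np.argmax(res.lod))]
        hits += (best["chrom"] == 3) and (abs(best["pos_cM"] - 50.0) <= tolerance_cM)
    return hits / n_rep, n_rep


# ---------------------------------------------------------------------------
# heritability recovery
# ---------------------------------------------------------------------------


def h2_recovery_mae(h2_values=(0.25, 0.4, 0.6), n_rep_total: int = 20,
                    n_genotypes: int = 500, seed: int = 0) -> tuple[float, int]:
    """Mean absolute error of REML H2 against the planted target."""
    errs = []
    reps = [n_rep_total // len(h2_values)] * len(h2_values)
    for j in range(n_rep_total - sum(reps)):
        reps[j] += 1
    for j, (h2, r) in enumerate(zip(h2_values, reps)):
        for k in range(r):
            cfg = SimConfig(n_chrom=2, markers_per_chrom=4,
                            n_genotypes=n_genotypes, ramets_per_genotype=2,
                            missing_rate=0.0, seed=(seed * 400_009 + 50 * j + k) % 2_147_483_629,
                            trait_models={"t": TraitModel(h2=h2, error_var=1.0)})
            m = make_map(cfg)
            ph, _ = simulate_phenotypes(simulate_backcross(m, cfg), m, cfg)
            fit = phenotype.fit_clonal_model(ph, "t")
            errs.append(abs(fit.components.h2 - h2))
    return float(np.mean(errs)), len(errs)


# ---------------------------------------------------------------------------
# NG86 oracle and omega recovery
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _naive_ng86(seq_a: str, seq_b: str):
    """Plain pathway-enumerating NG86, written independently of the estimator."""
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        for codon in (ca, cb):
            for p in range(3):
                for nt in "ACGT":
                    if nt == codon[p]:
                        continue
                    mut = codon[:p] + nt + codon[p + 1:]
                    if _translate(mut) == "*":
                        continue
                    if _translate(mut) == _translate(codon):
                        S += 1 / 6
                    else:
                        N += 1 / 6
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        clean, stopped = [], []
        for order in permutations(diff):
            cur, s_ct, n_ct, hit = ca, 0.0, 0.0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if _translate(nxt) == "*":
                    hit = True
                if _translate(nxt) == _translate(cur):
                    s_ct += 1
                else:
                    n_ct += 1
                cur = nxt
            (stopped if hit else clean).append((s_ct, n_ct))
        use = clean or stopped
        sd += sum(u[0] for u in use) / len(use)
        nd += sum(u[1] for u in use) / len(use)
    ps, pn = sd / S, nd / N
    if ps >= 0.75 or pn >= 0.75:
        return None
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)  # noqa: E731
    return jc(pn), jc(ps)


def ng86_oracle_max_diff(n_pairs: int = 100, n_codons: int = 50,
                         seed: int = 0) -> tuple[float, int]:
    """Max |Ka or Ks - naive enumeration oracle| over random codon pairs."""
    from .kaks_tables import NON_STOP_CODONS

    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_pairs:
        a = [str(c) for c in rng.choice(NON_STOP_CODONS, n_codons)]
        b = []
        for c in a:
            if rng.random() < 0.25:
                while True:
                    cand = c
                    for p in range(3):
                        if rng.random() < 0.5:
                            cand = cand[:p] + "ACGT"[rng.integers(4)] + cand[p + 1:]
                    if _translate(cand) != "*":
                        b.append(cand)
                        break
            else:
                b.append(c)
        seq_a, seq_b = "".join(a), "".join(b)
        res = compgen.kaks_ng86(seq_a, seq_b)
        oracle = _naive_ng86(seq_a, seq_b)
        if res.saturated or oracle is None:
            continue
        ka_o, ks_o = oracle
        worst = max(worst, abs(res.ka - ka_o), abs(res.ks - ks_o))
        done += 1
    return worst, n_pairs


def omega_recovery_error(omega: float = 1.35, n_codons: int = 900,
                         n_rep: int = 10, seed: int = 0) -> tuple[float, int]:
    """Mean absolute error of the estimated Ka/Ks against the simulated omega."""
    pairs, _ = simulate_cds_pairs(n_rep, [omega], n_codons=n_codons, seed=seed)
    errs = [abs(compgen.kaks_ng86(a, b).ratio - omega) for a, b in pairs]
    return float(np.mean(errs)), n_rep


# ---------------------------------------------------------------------------
# spatial spline recovery
# ---------------------------------------------------------------------------


def spline_surface_correlation(amplitude: float = 2.0, noise_sd: float = 1.0,
                               n_trees: int = 400, seed: int = 0) -> tuple[float, int]:
    """Correlation of the GCV thin-plate surface with the planted surface."""
    cfg = SimConfig(n_chrom=1, markers_per_chrom=3, n_genotypes=n_trees,
                    ramets_per_genotype=1, seed=seed,
                    spatial=SpatialConfig(amplitude=amplitude,
                                          correlation_length=8.0),
                    trait_models={"t": TraitModel(h2=0.0,
                                                  error_var=noise_sd ** 2)})
    m = make_map(cfg)
    ph, truth = simulate_phenotypes(simulate_backcross(m, cfg), m, cfg)
    coords = ph[["row", "col"]].to_numpy(dtype=float)
    spl, _ = phenotype.fit_spatial_spline(coords, ph["t"].to_numpy(), lam="gcv")
    corr = float(np.corrcoef(spl.fitted, truth.surface)[0, 1])
    return corr, n_trees
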