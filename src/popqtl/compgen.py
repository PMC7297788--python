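"""Tandem-duplicate detection, Monte Carlo interval enrichment, collinear
ortholog mapping, NG86 Ka/Ks and term enrichment.

A recent tandem duplication is a same-chromosome gene pair whose blastp
E-score is strictly below a stringent cutoff (default 1e-180) and whose
start coordinates lie within a fixed window (default 500 kb); clusters are
the single-linkage connected components of such links.  Enrichment of
tandem-flagged genes inside QTL intervals is tested against a Monte Carlo
null of random contiguous gene windows of matching size.

E-scores are carried as log10 values throughout so that scores far below
the double-precision underflow limit remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kaks_tables import CODON_TABLE, codon_sites, pathway_differences
from .qtl import PhysicalInterval

__all__ = [
    "TandemCluster",
    "TandemClusterSet",
    "EnrichmentResult",
    "KaKsResult",
    "detect_tandem_duplicates",
    "window_sensitivity",
    "genes_in_interval",
    "monte_carlo_enrichment",
    "collinear_orthologs",
    "map_interval",
    "kaks_ng86",
    "term_enrichment",
]

LOG10_E_CUTOFF_DEFAULT = -180.0


@dataclass
class TandemCluster:
    genes: list[str]
    chrom: int
    span_bp: int

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class TandemClusterSet:
    clusters: list[TandemCluster]
    flags: pd.Series  # per-gene tandem membership, indexed by gene_id
    rejected_cross_chrom: int = 0

    @property
    def n_tandem_genes(self) -> int:
        return int(self.flags.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [f"TC{i + 1:05d}" for i in range(len(self.clusters))],
                "chrom": [c.chrom for c in self.clusters],
                "size": [c.size for c in self.clusters],
                "span_bp": [c.span_bp for c in self.clusters],
                "genes": [",".join(c.genes) for c in self.clusters],
            }
        )


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    p_value: float
    n_iter: int
    seed: int
    per_interval: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _log10_cutoff(e_cutoff: float | None, log10_e_cutoff: float | None) -> float:
    if log10_e_cutoff is not None:
        return float(log10_e_cutoff)
    if e_cutoff is None:
        return LOG10_E_CUTOFF_DEFAULT
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive; pass log10_e_cutoff instead")
    return math.log10(e_cutoff)


def detect_tandem_duplicates(
    catalog: pd.DataFrame,
    homology: pd.DataFrame,
    e_cutoff: float | None = 1e-180,
    window_bp: int = 500_000,
    log10_e_cutoff: float | None = None,
) -> TandemClusterSet:
    """Single-linkage clusters of recent tandem duplicates.

    A pair is linked iff both genes are on the same chromosome, the E-score
    is strictly below the cutoff, and their start coordinates differ by at
    most `window_bp`.  Cross-chromosome pairs passing the E filter are
    counted but never linked.
    """
    cut = _log10_cutoff(e_cutoff, log10_e_cutoff)
    pos = catalog.set_index("gene_id")[["chrom", "start"]]
    h = homology[homology["log10_evalue"] < cut]
    h = h[h["query"] != h["subject"]]
    h = h[h["query"].isin(pos.index) & h["subject"].isin(pos.index)]
    qc = pos.loc[h["query"]].to_numpy()
    sc = pos.loc[h["subject"]].to_numpy()
    same = qc[:, 0] == sc[:, 0]
    near = np.abs(qc[:, 1] - sc[:, 1]) <= window_bp
    uf = _UnionFind()
    for q, s in zip(h.loc[same & near, "query"], h.loc[same & near, "subject"]):
        uf.union(q, s)
    groups: dict[str, list[str]] = {}
    for g in uf.parent:
        groups.setdefault(uf.find(g), []).append(g)
    clusters = []
    order = {g: i for i, g in enumerate(catalog["gene_id"])}
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(key=order.__getitem__)
        chrom = int(pos.loc[members[0], "chrom"])
        starts = pos.loc[members, "start"].to_numpy()
        ends = catalog.set_index("gene_id").loc[members, "end"].to_numpy()
        clusters.append(TandemCluster(members, chrom, int(ends.max() - starts.min())))
    clusters.sort(key=lambda c: order[c.genes[0]])
    flags = pd.Series(False, index=catalog["gene_id"], name="tandem")
    for c in clusters:
        flags.loc[c.genes] = True
    return TandemClusterSet(
        clusters, flags, rejected_cross_chrom=int(np.sum(same == False))  # noqa: E712
    )


def window_sensitivity(
    catalog: pd.DataFrame,
    homology: pd.DataFrame,
    windows: list[int],
    e_cutoff: float | None = 1e-180,
    log10_e_cutoff: float | None = None,
) -> pd.DataFrame:
    """Tandem-gene counts across candidate window sizes.

    Returns a frame with the cumulative count per window and the marginal
    (newly discovered) series used to pick the knee where discovery
    declines.  Counts are non-decreasing in window size.
    """
    if not windows:
        raise ValueError("empty window list")
    if sorted(windows) != list(windows):
        raise ValueError("windows must be sorted ascending")
    counts = [
        detect_tandem_duplicates(
            catalog, homology, e_cutoff, w, log10_e_cutoff
        ).n_tandem_genes
        for w in windows
    ]
    marginal = np.diff([0] + counts)
    return pd.DataFrame(
        {"window_bp": windows, "tandem_genes": counts, "newly_discovered": marginal}
    )


def genes_in_interval(catalog: pd.DataFrame, interval: PhysicalInterval) -> list[str]:
    """Genes whose midpoint falls inside the interval (edges inclusive)."""
    if interval.end < interval.start:
        raise ValueError("interval end precedes start")
    sub = catalog[catalog["chrom"] == interval.chrom]
    mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
    sel = (mid >= interval.start) & (mid <= interval.end)
    return sub.loc[sel, "gene_id"].tolist()


def monte_carlo_enrichment(
    catalog: pd.DataFrame,
    tandem_flags: pd.Series,
    intervals: list[PhysicalInterval] | None = None,
    interval_gene_counts: list[int] | None = None,
    observed: int | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte Carlo test for tandem-duplicate enrichment in QTL intervals.

    Per iteration, for each interval of k genes a random run of k
    contiguous genes is drawn genome-wide (chromosome picked with
    probability proportional to its number of valid starts) and its
    tandem-flagged genes counted; the statistic is the sum over intervals.
    Empirical p = (1 + #{sim >= obs}) / (1 + n_iter).
    """
    flags = tandem_flags.reindex(catalog["gene_id"]).fillna(False).to_numpy(dtype=bool)
    if intervals is not None:
        interval_gene_counts = []
        observed = 0
        per_obs = []
        fl = tandem_flags
        for iv in intervals:
            genes = genes_in_interval(catalog, iv)
            interval_gene_counts.append(len(genes))
            o = int(fl.reindex(genes).fillna(False).sum())
            per_obs.append(o)
            observed += o
    elif interval_gene_counts is None or observed is None:
        raise ValueError("pass intervals, or interval_gene_counts plus observed")
    else:
        per_obs = [None] * len(interval_gene_counts)

    chrom_sizes = catalog.groupby("chrom").size()
    # flags laid out chromosome-block by chromosome-block with prefix sums
    offsets = {}
    off = 0
    csum = np.concatenate([[0], np.cumsum(flags)])
    for c in chrom_sizes.index:
        offsets[c] = off
        off += int(chrom_sizes[c])
    rng = np.random.default_rng(seed)
    sims = np.zeros(n_iter, dtype=np.int64)
    per_interval = []
    for k, o_k in zip(interval_gene_counts, per_obs):
        valid = chrom_sizes[chrom_sizes >= k]
        if valid.empty:
            raise ValueError(f"no chromosome holds {k} contiguous genes")
        weights = (valid - k + 1).to_numpy(dtype=float)
        weights /= weights.sum()
        chroms = rng.choice(len(valid), size=n_iter, p=weights)
        n_starts = (valid - k + 1).to_numpy()
        starts = (rng.random(n_iter) * n_starts[chroms]).astype(np.int64)
        base = np.array([offsets[c] for c in valid.index])[chroms]
        counts_k = csum[base + starts + k] - csum[base + starts]
        sims += counts_k
        per_interval.append(
            {
                "k": int(k),
                "observed": o_k,
                "null_mean": float(counts_k.mean()),
                "p_value": None
                if o_k is None
                else (1.0 + float(np.sum(counts_k >= o_k))) / (1.0 + n_iter),
            }
        )
    p = (1.0 + float(np.sum(sims >= observed))) / (1.0 + n_iter)
    return EnrichmentResult(
        observed=int(observed),
        null_mean=float(sims.mean()),
        null_sd=float(sims.std()),
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        per_interval=per_interval,
    )


# ---------------------------------------------------------------------------
# collinear ortholog segments
# ---------------------------------------------------------------------------


def _reciprocal_best_hits(cross: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query and per subject (lowest E, then highest identity)."""
    ranked = cross.sort_values(
        ["log10_evalue", "pident"], ascending=[True, False]
    )
    best_q = ranked.drop_duplicates("query").set_index("query")["subject"]
    best_s = ranked.drop_duplicates("subject").set_index("subject")["query"]
    keep = [
        (q, s)
        for q, s in best_q.items()
        if best_s.get(s) == q
    ]
    idx = pd.MultiIndex.from_tuples(keep, names=["query", "subject"])
    ranked = ranked.set_index(["query", "subject"])
    return ranked.loc[ranked.index.isin(idx)].reset_index().drop_duplicates(
        subset=["query", "subject"]
    )


def collinear_orthologs(
    catalog_a: pd.DataFrame,
    catalog_b: pd.DataFrame,
    cross_homology: pd.DataFrame,
    min_chain: int = 5,
    max_gap: int = 10,
    log10_e_median_cutoff: float = LOG10_E_CUTOFF_DEFAULT,
) -> pd.DataFrame:
    """Chain reciprocal-best-hit anchors into collinear ortholog segments.

    Anchors are ordered by gene index in genome A; a dynamic program links
    anchors whose index steps in both genomes are at most `max_gap`, with a
    consistent orientation (strand).  Chains shorter than `min_chain` or
    with median log10 E-score >= the cutoff are discarded.  Returns one row
    per chain with bp spans in both genomes.
    """
    rbh = _reciprocal_best_hits(cross_homology)
    a = catalog_a.set_index("gene_id")
    b = catalog_b.set_index("gene_id")
    rbh = rbh[rbh["query"].isin(a.index) & rbh["subject"].isin(b.index)]
    anchors = pd.DataFrame(
        {
            "gene_a": rbh["query"].to_numpy(),
            "gene_b": rbh["subject"].to_numpy(),
            "chrom_a": a.loc[rbh["query"], "chrom"].to_numpy(),
            "idx_a": a.loc[rbh["query"], "index"].to_numpy(),
            "chrom_b": b.loc[rbh["subject"], "chrom"].to_numpy(),
            "idx_b": b.loc[rbh["subject"], "index"].to_numpy(),
            "log10_evalue": rbh["log10_evalue"].to_numpy(),
        }
    )
    chains = []
    for (_, _), grp in anchors.groupby(["chrom_a", "chrom_b"]):
        grp = grp.sort_values("idx_a").reset_index(drop=True)
        n = len(grp)
        ia = grp["idx_a"].to_numpy()
        ib = grp["idx_b"].to_numpy()
        used = np.zeros(n, dtype=bool)
        for direction in (1, -1):
            score = np.ones(n, dtype=int)
            back = np.full(n, -1)
            for j in range(n):
                for i in range(j - 1, -1, -1):
                    if ia[j] - ia[i] > max_gap:
                        break
                    da = ia[j] - ia[i]
                    db = direction * (ib[j] - ib[i])
                    if 0 < da <= max_gap and 0 < db <= max_gap:
                        if score[i] + 1 > score[j]:
                            score[j] = score[i] + 1
                            back[j] = i
            for j in np.argsort(-score):
                if used[j] or score[j] < min_chain:
                    continue
                path = []
                k = j
                while k != -1 and not used[k]:
                    path.append(k)
                    k = back[k]
                if len(path) < min_chain:
                    continue
                path = path[::-1]
                used[path] = True
                seg = grp.iloc[path]
                med_e = float(np.median(seg["log10_evalue"]))
                if med_e >= log10_e_median_cutoff:
                    continue
                a_rows = a.loc[seg["gene_a"]]
                b_rows = b.loc[seg["gene_b"]]
                chains.append(
                    {
                        "chrom_a": int(seg["chrom_a"].iloc[0]),
                        "a_start": int(a_rows["start"].min()),
                        "a_end": int(a_rows["end"].max()),
                        "chrom_b": int(seg["chrom_b"].iloc[0]),
                        "b_start": int(b_rows["start"].min()),
                        "b_end": int(b_rows["end"].max()),
                        "strand": "+" if direction == 1 else "-",
                        "n_anchors": len(path),
                        "median_log10_evalue": med_e,
                    }
                )
    cols = [
        "chrom_a",
        "a_start",
        "a_end",
        "chrom_b",
        "b_start",
        "b_end",
        "strand",
        "n_anchors",
        "median_log10_evalue",
    ]
    return pd.DataFrame(chains, columns=cols)


def map_interval(
    chains: pd.DataFrame, interval: PhysicalInterval
) -> list[PhysicalInterval]:
    """Map a genome-A interval onto genome B via overlapping chains.

    Returns the B-side spans of every chain overlapping the query; an empty
    list means the interval is unmapped.
    """
    hits = chains[
        (chains["chrom_a"] == interval.chrom)
        & (chains["a_end"] >= interval.start)
        & (chains["a_start"] <= interval.end)
    ]
    return [
        PhysicalInterval(int(r["chrom_b"]), int(r["b_start"]), int(r["b_end"]))
        for _, r in hits.iterrows()
    ]


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # nan when Ks == 0 or saturated
    positive_selection: bool | None  # None when the ratio is undefined
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion saturates the Jukes-Cantor correction")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(seq_a: str, seq_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for one codon-aligned, in-frame pair.

    Site counts are averaged over the two sequences; multi-hit codons use
    pathway averaging; both proportions receive the Jukes-Cantor
    correction.  Ks = 0 leaves the ratio undefined (NaN, flag None);
    saturation (p >= 3/4) flags the result instead of raising.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length is not a multiple of 3")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if CODON_TABLE.get(ca, "*") == "*" or CODON_TABLE.get(cb, "*") == "*":
            raise ValueError(f"internal stop or invalid codon at position {i}")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        ds, dn = pathway_differences(ca, cb)
        sd += ds
        nd += dn
    S = 0.5 * (s_a + s_b)
    N = 0.5 * (n_a + n_b)
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return KaKsResult(
            math.nan, math.nan, math.nan, None, S, N, sd, nd, saturated=True
        )
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if ks == 0.0:
        return KaKsResult(ka, ks, math.nan, None, S, N, sd, nd)
    ratio = ka / ks
    return KaKsResult(ka, ks, ratio, ratio > 1.0, S, N, sd, nd)


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------


def term_enrichment(
    interval_genes: list[str],
    catalog: pd.DataFrame,
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term over-representation inside QTL intervals.

    `term_map` columns: gene_id, term_id (term_type optional).  Per term a
    hypergeometric upper-tail p compares the term's count among interval
    genes with the genome; significance uses a Bonferroni threshold
    alpha / n_terms_tested, reported in ``result.attrs``.
    """
    genome_genes = set(catalog["gene_id"])
    tm = term_map[term_map["gene_id"].isin(genome_genes)]
    inside = set(interval_genes) & genome_genes
    M = len(genome_genes)
    n_draw = len(inside)
    rows = []
    for term, grp in tm.groupby("term_id"):
        carriers = set(grp["gene_id"])
        K = len(carriers)
        k = len(carriers & inside)
        p = float(stats.hypergeom.sf(k - 1, M, K, n_draw))
        rows.append((term, K, k, p))
    out = pd.DataFrame(rows, columns=["term_id", "genome_count", "interval_count", "p_value"])
    n_tested = len(out)
    threshold = alpha / n_tested if n_tested else math.nan
    out["enriched"] = out["p_value"] < threshold
    out = out.sort_values("p_value").reset_index(drop=True)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_terms_tested"] = n_tested
    out.attrs["alpha"] = alpha
    return out
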