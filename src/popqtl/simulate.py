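"""Synthetic data with planted truth for the pseudo-backcross pipeline.

Everything the downstream stages consume can be generated here: a
19-chromosome genetic map, 1:1-segregating backcross genotypes, clonally
replicated phenotypes with planted QTL and a smooth spatial microsite
surface, a gene catalog with seeded tandem-duplicate clusters plus the
matching within-genome homology table, and codon-aligned CDS pairs with
known Ka/Ks.  Every generator is deterministic under a fixed seed and
returns a :class:`TruthRecord` describing what was planted, so recovery can
be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .kaks_tables import CODON_TABLE, NON_STOP_CODONS, codon_sites

__all__ = [
    "QTLSpec",
    "TraitModel",
    "SpatialConfig",
    "GenomeConfig",
    "SimConfig",
    "TruthRecord",
    "GeneticMap",
    "make_map",
    "haldane_r",
    "simulate_backcross",
    "simulate_phenotypes",
    "simulate_genome",
    "simulate_cds_pairs",
]

# Genome-wide map-to-physical scale: a ~2,600 cM map spread over a ~420 Mb
# assembly gives ~160 kb per cM, the rate used to anchor markers in bp.
BP_PER_CM = 160_000.0


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: class means differ by `effect` at this map position."""

    chrom: int
    pos_cM: float
    effect: float
    trait: str


@dataclass(frozen=True)
class TraitModel:
    """Distributional family for one simulated trait.

    `h2` is the target broad-sense heritability of the latent genotype
    values; `error_var` is the ramet-level residual variance on the latent
    scale.  `n_classes` applies to the ordinal family only.
    """

    family: Literal["normal", "ordinal", "binary", "count"] = "normal"
    h2: float = 0.4
    error_var: float = 1.0
    n_classes: int = 4
    count_mean: float = 5.0


@dataclass(frozen=True)
class SpatialConfig:
    amplitude: float = 0.0
    correlation_length: float = 8.0  # grid units


@dataclass(frozen=True)
class GenomeConfig:
    genes_per_chrom: int = 400
    mean_gene_bp: int = 2_500
    # None: space genes to tile the mapped chromosome length (cM * 160 kb)
    mean_intergenic_bp: int | None = None
    tandem_base_rate: float = 0.05
    tandem_enrichment_factor: float = 1.0
    mean_cluster_size: float = 2.5
    # enriched intervals in gene-index space: (chrom, first gene index, n genes)
    intervals: tuple[tuple[int, int, int], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    n_chrom: int = 19
    markers_per_chrom: int = 20
    chrom_length_cM: float = 138.0  # ~2,617 cM over 19 chromosomes
    n_genotypes: int = 692
    ramets_per_genotype: int = 2
    missing_rate: float = 0.01
    qtl_spec: tuple[QTLSpec, ...] = ()
    trait_models: dict[str, TraitModel] = field(default_factory=dict)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom <= 0 or self.markers_per_chrom <= 0:
            raise ValueError("chromosome and marker counts must be positive")
        if self.n_genotypes <= 0 or self.ramets_per_genotype <= 0:
            raise ValueError("genotype and ramet counts must be positive")
        if not 0.0 <= self.genome.tandem_base_rate <= 1.0:
            raise ValueError("tandem_base_rate must lie in [0, 1]")
        for q in self.qtl_spec:
            if not math.isfinite(q.effect):
                raise ValueError(f"non-finite QTL effect for trait {q.trait!r}")
        for name, tm in self.trait_models.items():
            if not 0.0 <= tm.h2 < 1.0:
                raise ValueError(f"target H2 for {name!r} must be in [0, 1)")


@dataclass
class TruthRecord:
    """Planted truth from a generator call; only relevant fields are set."""

    qtl: list[QTLSpec] = field(default_factory=list)
    genetic_values: dict[str, np.ndarray] = field(default_factory=dict)
    true_h2: dict[str, float] = field(default_factory=dict)
    surface: np.ndarray | None = None
    tandem_clusters: list[list[str]] = field(default_factory=list)
    interval_bp: list[tuple[int, int, int]] = field(default_factory=list)
    omegas: list[float] = field(default_factory=list)


@dataclass
class GeneticMap:
    """Ordered markers with cM positions and physical (bp) anchors."""

    table: pd.DataFrame  # columns: marker, chrom, cM, bp
    chrom_length_cM: dict[int, float]
    chrom_length_bp: dict[int, int]

    def __post_init__(self) -> None:
        for c, sub in self.table.groupby("chrom"):
            if not np.all(np.diff(sub["cM"].to_numpy()) > 0):
                raise ValueError(f"cM positions not strictly increasing on chrom {c}")
            if not np.all(np.diff(sub["bp"].to_numpy()) > 0):
                raise ValueError(f"bp anchors not monotone on chrom {c}")

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.chrom_length_cM)

    def markers_on(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from map distance, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def make_map(cfg: SimConfig) -> GeneticMap:
    """Evenly spaced markers per chromosome with monotone random bp anchors."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    len_cm: dict[int, float] = {}
    len_bp: dict[int, int] = {}
    for c in range(1, cfg.n_chrom + 1):
        m = cfg.markers_per_chrom
        if m == 1:
            pos = np.array([0.0])
        else:
            pos = np.linspace(0.0, cfg.chrom_length_cM, m)
        chrom_bp = max(int(round(cfg.chrom_length_cM * BP_PER_CM)), 2 * m)
        # anchors: sorted uniform draws, bumped to be strictly increasing
        anchors = np.sort(rng.uniform(1, chrom_bp, size=m)).astype(np.int64)
        anchors = np.maximum.accumulate(anchors + np.arange(m))
        anchors = np.clip(anchors, 1, chrom_bp)
        anchors = np.maximum.accumulate(anchors)  # clip can only hit the top end
        for i, (p, a) in enumerate(zip(pos, anchors)):
            rows.append((f"C{c:02d}M{i + 1:03d}", c, float(p), int(a)))
        len_cm[c] = float(cfg.chrom_length_cM)
        len_bp[c] = chrom_bp
    table = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"])
    return GeneticMap(table, len_cm, len_bp)


def simulate_backcross(gmap: GeneticMap, cfg: SimConfig) -> pd.DataFrame:
    """Two-class (T/D) backcross genotypes by a Markov chain along each chromosome.

    T marks progeny heterozygous for the recurrent and donor alleles, D
    homozygous for the recurrent parent; both classes segregate 1:1.
    Adjacent-marker transitions use the Haldane recombination fraction.
    Returns a genotype-by-marker DataFrame of "T"/"D" with NaN for missing.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_genotypes
    cols: dict[str, np.ndarray] = {}
    for c in gmap.chromosomes:
        sub = gmap.markers_on(c)
        d = np.diff(sub["cM"].to_numpy())
        r = haldane_r(d)
        state = rng.integers(0, 2, size=n)  # 1 = T, 0 = D
        cols[sub["marker"].iloc[0]] = state.copy()
        for k, rk in enumerate(r):
            flips = rng.random(n) < rk
            state = np.where(flips, 1 - state, state)
            cols[sub["marker"].iloc[k + 1]] = state.copy()
    ids = [f"G{i + 1:04d}" for i in range(n)]
    geno = pd.DataFrame(
        {m: np.where(v == 1, "T", "D") for m, v in cols.items()}, index=ids
    )
    geno = geno[gmap.table["marker"].tolist()]
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno = geno.mask(mask)
    geno.index.name = "genotype_id"
    return geno


def _nearest_marker(gmap: GeneticMap, chrom: int, pos_cM: float) -> str:
    sub = gmap.markers_on(chrom)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    i = int(np.argmin(np.abs(sub["cM"].to_numpy() - pos_cM)))
    return str(sub["marker"].iloc[i])


def _spatial_surface(
    rows: np.ndarray, cols: np.ndarray, cfg: SpatialConfig, rng: np.random.Generator
) -> np.ndarray:
    """Smooth microsite surface: a few low-frequency sinusoids, SD = amplitude."""
    if cfg.amplitude == 0.0:
        return np.zeros(rows.shape, dtype=float)
    lam = max(cfg.correlation_length, 1.0)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    z = (
        0.6 * np.sin(2 * np.pi * rows / (2 * lam) + phases[0])
        + 0.4 * np.cos(2 * np.pi * cols / (2 * lam) + phases[1])
        + 0.3 * np.sin(2 * np.pi * (rows + cols) / (3.4 * lam) + phases[2])
    )
    sd = z.std()
    if sd < 1e-12:
        return np.zeros(rows.shape, dtype=float)
    return cfg.amplitude * (z - z.mean()) / sd


def simulate_phenotypes(
    geno: pd.DataFrame, gmap: GeneticMap, cfg: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Clonal phenotypes with planted QTL, polygenic effect and spatial surface.

    The latent value of tree j of genotype i is
    ``mu + sum_q effect_q * s_iq / 2 + u_i + surface(row_j, col_j) + e_ij``
    with s in {+1 (T), -1 (D)} and the polygenic variance of u sized so the
    total genotype variance divided by (genotype + residual) variance equals
    the trait's target H2.  Ordinal, binary and count traits discretize the
    latent value (thresholds / log-link).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_g = geno.shape[0]
    n_trees = n_g * cfg.ramets_per_genotype
    tree_geno = np.repeat(np.arange(n_g), cfg.ramets_per_genotype)
    tree_ids = [
        f"{gid}_r{r + 1}"
        for gid in geno.index
        for r in range(cfg.ramets_per_genotype)
    ]

    # field layout: a near-square grid, trees placed in randomized order
    ncol = int(math.ceil(math.sqrt(n_trees)))
    order = rng.permutation(n_trees)
    rows_f = (order // ncol).astype(float)
    cols_f = (order % ncol).astype(float)
    surface = _spatial_surface(rows_f, cols_f, cfg.spatial, rng)

    table = pd.DataFrame(
        {
            "tree_id": tree_ids,
            "genotype_id": np.asarray(geno.index)[tree_geno],
            "row": rows_f,
            "col": cols_f,
        }
    )
    truth = TruthRecord(qtl=list(cfg.qtl_spec), surface=surface)

    # genotype codes at QTL-carrying markers: +1 for T, -1 for D (0 if missing)
    code_cache: dict[str, np.ndarray] = {}

    def marker_code(marker: str) -> np.ndarray:
        if marker not in code_cache:
            v = geno[marker]
            code_cache[marker] = np.where(v == "T", 1.0, np.where(v == "D", -1.0, 0.0))
        return code_cache[marker]

    for trait, tm in cfg.trait_models.items():
        g_qtl = np.zeros(n_g)
        for q in cfg.qtl_spec:
            if q.trait != trait:
                continue
            marker = _nearest_marker(gmap, q.chrom, q.pos_cM)
            g_qtl += 0.5 * q.effect * marker_code(marker)
        v_qtl = float(np.var(g_qtl))
        v_e = tm.error_var
        v_g_target = tm.h2 / (1.0 - tm.h2) * v_e
        v_poly = max(v_g_target - v_qtl, 0.0)
        u = rng.normal(0.0, math.sqrt(v_poly), size=n_g) if v_poly > 0 else np.zeros(n_g)
        g = g_qtl + u
        truth.genetic_values[trait] = g
        truth.true_h2[trait] = float(np.var(g) / (np.var(g) + v_e)) if v_e > 0 else 1.0

        eps = rng.normal(0.0, math.sqrt(v_e), size=n_trees)
        latent = g[tree_geno] + surface + eps
        if tm.family == "normal":
            y = latent
        elif tm.family == "ordinal":
            qs = np.quantile(latent, np.linspace(0, 1, tm.n_classes + 1)[1:-1])
            y = np.searchsorted(qs, latent).astype(float)
        elif tm.family == "binary":
            y = (latent >= np.median(latent)).astype(float)
        elif tm.family == "count":
            b0 = math.log(tm.count_mean) - np.var(latent) / 2.0
            lam_scale = 0.5  # damp latent scale so counts stay moderate
            y = rng.poisson(np.exp(b0 + lam_scale * latent)).astype(float)
        else:  # pragma: no cover - guarded by TraitModel Literal
            raise ValueError(f"unknown trait family {tm.family!r}")
        table[trait] = y

    # stem diameter: available as a productivity covariate
    table["stem_diameter"] = rng.normal(30.0, 5.0, size=n_trees)
    return table, truth


# ---------------------------------------------------------------------------
# gene catalog + homology table with seeded tandem clusters
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Gene catalog and within-genome homology table with seeded tandem clusters.

    Tandem clusters are runs of adjacent genes; their within-cluster pair
    E-scores are strictly below the detection cutoff (log10 E < -185) while
    background pairs sit above it, so the planted membership is recoverable
    exactly.  Genes inside a designated interval start clusters at
    ``tandem_base_rate * tandem_enrichment_factor``; elsewhere at the base
    rate.  Returns (catalog, homology, truth).
    """
    cfg.validate()
    g = cfg.genome
    if g.genes_per_chrom < 2:
        raise ValueError("need at least 2 genes per chromosome")
    if g.mean_intergenic_bp is None:
        chrom_bp = cfg.chrom_length_cM * BP_PER_CM
        intergenic = max(int(chrom_bp / g.genes_per_chrom) - g.mean_gene_bp, 500)
    else:
        intergenic = g.mean_intergenic_bp
    mean_pitch = g.mean_gene_bp + intergenic
    if 500_000 < 2 * mean_pitch:
        raise ValueError("tandem window smaller than twice the mean gene spacing")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

    records = []
    for c in range(1, cfg.n_chrom + 1):
        lengths = rng.integers(800, 2 * g.mean_gene_bp - 800, size=g.genes_per_chrom)
        gaps = rng.exponential(intergenic, size=g.genes_per_chrom).astype(
            np.int64
        ) + 1
        start = np.int64(1)
        for i in range(g.genes_per_chrom):
            start = start + gaps[i]
            end = start + lengths[i]
            records.append(
                (
                    f"Pg{c:02d}G{i + 1:05d}",
                    c,
                    int(start),
                    int(end),
                    "+" if rng.random() < 0.5 else "-",
                    i,
                )
            )
            start = end
    catalog = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "index"]
    )

    in_interval = np.zeros(len(catalog), dtype=bool)
    interval_bp: list[tuple[int, int, int]] = []
    for chrom, first, n_genes in g.intervals:
        sel = (catalog["chrom"] == chrom) & (
            catalog["index"].between(first, first + n_genes - 1)
        )
        if not sel.any():
            raise ValueError(f"interval ({chrom}, {first}, {n_genes}) is off-catalog")
        in_interval |= sel.to_numpy()
        sub = catalog[sel]
        interval_bp.append((chrom, int(sub["start"].min()), int(sub["end"].max())))

    # seed clusters: walk genes in order; a cluster occupies consecutive genes
    mean_size = max(g.mean_cluster_size, 2.0)
    p_geom = 1.0 / (mean_size - 1.0)
    clusters: list[list[str]] = []
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in catalog.groupby("chrom")}
    chrom_mask = {c: in_interval[(catalog["chrom"] == c).to_numpy()] for c in by_chrom}
    for c, sub in by_chrom.items():
        n_genes_c = len(sub)
        gene_ids_c = sub["gene_id"].to_numpy()
        enriched_c = chrom_mask[c]
        u = rng.random(n_genes_c)
        sizes_draw = 1 + rng.geometric(p_geom, size=n_genes_c)
        i = 0
        while i < n_genes_c - 1:
            rate = g.tandem_base_rate
            if enriched_c[i]:
                rate = min(1.0, rate * g.tandem_enrichment_factor)
            p_start = min(1.0, rate / mean_size)
            if u[i] < p_start:
                size = min(int(sizes_draw[i]), n_genes_c - i)
                if size >= 2:
                    clusters.append(list(gene_ids_c[i : i + size]))
                    i += size
                    continue
            i += 1

    truth = TruthRecord(tandem_clusters=clusters, interval_bp=interval_bp)

    # homology: within-cluster pairs below the cutoff, background above
    pos = catalog.set_index("gene_id")
    rows_h: list[tuple[str, str, float, float, int]] = []
    for members in clusters:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                rows_h.append(
                    (
                        members[a],
                        members[b],
                        float(rng.uniform(-300.0, -185.0)),
                        float(rng.uniform(85.0, 99.5)),
                        int(rng.integers(200, 600)),
                    )
                )
    # background: random pairs with E-scores above (weaker than) the cutoff
    n_bg = max(len(catalog) // 10, 5)
    gene_ids = catalog["gene_id"].to_numpy()
    ai = rng.integers(0, len(gene_ids), size=n_bg)
    bi = rng.integers(0, len(gene_ids), size=n_bg)
    for a, b in zip(ai, bi):
        if a == b:
            continue
        rows_h.append(
            (
                gene_ids[a],
                gene_ids[b],
                float(rng.uniform(-170.0, -5.0)),
                float(rng.uniform(30.0, 80.0)),
                int(rng.integers(100, 400)),
            )
        )
    # decoys exercising the linking rules: strong cross-chromosome pairs and
    # strong same-chromosome pairs far beyond any plausible window
    if cfg.n_chrom >= 2:
        for _ in range(3):
            a = gene_ids[rng.integers(0, g.genes_per_chrom)]
            b = gene_ids[g.genes_per_chrom + rng.integers(0, g.genes_per_chrom)]
            rows_h.append((a, b, float(rng.uniform(-280.0, -185.0)), 90.0, 400))
    for c, sub in by_chrom.items():
        far = sub[sub["start"] > int(sub["start"].iloc[0]) + 2_000_000]
        if len(far) and len(sub) > 4:
            a = sub["gene_id"].iloc[0]
            b = far["gene_id"].iloc[-1]
            if abs(int(pos.loc[a, "start"]) - int(pos.loc[b, "start"])) > 1_500_000:
                rows_h.append((a, b, float(rng.uniform(-280.0, -185.0)), 90.0, 400))
    homology = pd.DataFrame(
        rows_h, columns=["query", "subject", "log10_evalue", "pident", "length"]
    ).drop_duplicates(subset=["query", "subject"])
    return catalog, homology, truth


# ---------------------------------------------------------------------------
# codon-aligned CDS pairs with known omega
# ---------------------------------------------------------------------------


def _codon_mutations(codon: str) -> list[tuple[str, bool]]:
    """All single-nucleotide non-stop mutants of a codon, with synonymy flag."""
    out = []
    aa = CODON_TABLE[codon]
    for p in range(3):
        for nt in "ACGT":
            if nt == codon[p]:
                continue
            mut = codon[:p] + nt + codon[p + 1 :]
            if CODON_TABLE[mut] == "*":
                continue
            out.append((mut, CODON_TABLE[mut] == aa))
    return out


def simulate_cds_pairs(
    n: int,
    omegas: Sequence[float],
    n_codons: int = 300,
    ks_target: float = 0.2,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Codon-aligned sequence pairs whose NG86 Ka/Ks is close to each omega.

    Substitution counts are sized from the target Ks (and Ka = omega * Ks)
    through the Jukes-Cantor forward map on NG86 site counts, then sprinkled
    as synonymous / nonsynonymous single-nucleotide codon changes.
    """
    if len(omegas) not in (1, n):
        raise ValueError("omegas must have length 1 or n")
    if any(w <= 0 for w in omegas):
        raise ValueError("omega targets must be positive")
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    pairs: list[tuple[str, str]] = []
    truth = TruthRecord()
    omg = list(omegas) * (n if len(omegas) == 1 else 1)
    for k in range(n):
        omega = float(omg[k])
        anc = "".join(rng.choice(NON_STOP_CODONS, size=n_codons))
        s_sites = sum(codon_sites(anc[i : i + 3])[0] for i in range(0, 3 * n_codons, 3))
        n_sites = sum(codon_sites(anc[i : i + 3])[1] for i in range(0, 3 * n_codons, 3))
        p_s = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
        p_n = 0.75 * (1.0 - math.exp(-4.0 * omega * ks_target / 3.0))
        if p_s >= 0.75 or p_n >= 0.75:
            raise ValueError("requested divergence saturates the Jukes-Cantor map")
        n_syn = int(round(p_s * s_sites))
        n_non = int(round(p_n * n_sites))
        codons = [anc[i : i + 3] for i in range(0, 3 * n_codons, 3)]
        # at most one change per codon, so the observed difference
        # proportions equal the targets and NG86 + Jukes-Cantor maps them
        # straight back to (Ka, Ks)
        order = rng.permutation(n_codons)
        cursor = 0
        for want_syn, count in ((True, n_syn), (False, n_non)):
            placed = 0
            while placed < count and cursor < n_codons:
                j = int(order[cursor])
                cursor += 1
                options = [m for m, syn in _codon_mutations(codons[j]) if syn == want_syn]
                if not options:
                    continue
                codons[j] = options[int(rng.integers(0, len(options)))]
                placed += 1
            if placed < count:
                raise ValueError(
                    "alignment too short for the requested divergence"
                )
        pairs.append((anc, "".join(codons)))
        truth.omegas.append(omega)
    return pairs, truth
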