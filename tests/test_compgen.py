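"""Tandem clustering, enrichment null, collinearity, Ka/Ks, term enrichment."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from popqtl.compgen import (
    collinear_orthologs,
    detect_tandem_duplicates,
    genes_in_interval,
    kaks_ng86,
    map_interval,
    monte_carlo_enrichment,
    term_enrichment,
    window_sensitivity,
)
from popqtl.kaks_tables import NON_STOP_CODONS, codon_sites
from popqtl.qtl import PhysicalInterval
from popqtl.simulate import GenomeConfig, SimConfig, simulate_genome


def _catalog(rows):
    cat = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    cat = cat.sort_values(["chrom", "start"]).reset_index(drop=True)
    cat["index"] = cat.groupby("chrom").cumcount()
    return cat


def _homology(pairs):
    return pd.DataFrame(
        [(q, s, e, 90.0, 300) for q, s, e in pairs],
        columns=["query", "subject", "log10_evalue", "pident", "length"],
    )


def _brute_force_clusters(catalog, homology, log_cut=-180.0, window=500_000):
    """All-pairs filter + networkx components; the independent oracle."""
    import networkx as nx

    pos = catalog.set_index("gene_id")[["chrom", "start"]]
    g = nx.Graph()
    for _, r in homology.iterrows():
        a, b = r["query"], r["subject"]
        if a == b or a not in pos.index or b not in pos.index:
            continue
        if r["log10_evalue"] >= log_cut:
            continue
        if pos.loc[a, "chrom"] != pos.loc[b, "chrom"]:
            continue
        if abs(int(pos.loc[a, "start"]) - int(pos.loc[b, "start"])) > window:
            continue
        g.add_edge(a, b)
    return sorted(sorted(c) for c in nx.connected_components(g) if len(c) >= 2)


class TestTandemDetection:
    def test_pair_within_window_clusters(self):
        cat = _catalog([("a", 1, 100, 200, "+"), ("b", 1, 400_100, 400_200, "+")])
        hom = _homology([("a", "b", -200.0)])
        cs = detect_tandem_duplicates(cat, hom)
        assert len(cs.clusters) == 1 and cs.clusters[0].size == 2

    def test_pair_beyond_window_ignored(self):
        cat = _catalog([("a", 1, 100, 200, "+"), ("b", 1, 600_100, 600_200, "+")])
        cs = detect_tandem_duplicates(cat, _homology([("a", "b", -200.0)]))
        assert not cs.clusters

    def test_cutoff_is_strict(self):
        cat = _catalog([("a", 1, 100, 200, "+"), ("b", 1, 200_000, 200_100, "+")])
        cs = detect_tandem_duplicates(cat, _homology([("a", "b", -180.0)]))
        assert not cs.clusters  # E exactly at the cutoff is excluded

    def test_chain_single_linkage(self):
        cat = _catalog(
            [
                ("a", 1, 0, 100, "+"),
                ("b", 1, 300_000, 300_100, "+"),
                ("c", 1, 600_000, 600_100, "+"),
            ]
        )
        hom = _homology([("a", "b", -250.0), ("b", "c", -250.0), ("a", "c", -250.0)])
        cs = detect_tandem_duplicates(cat, hom)
        assert [c.genes for c in cs.clusters] == [["a", "b", "c"]]
        assert _brute_force_clusters(cat, hom) == [["a", "b", "c"]]

    def test_cross_chromosome_never_linked(self):
        cat = _catalog([("a", 1, 100, 200, "+"), ("b", 2, 150, 250, "+")])
        cs = detect_tandem_duplicates(cat, _homology([("a", "b", -300.0)]))
        assert not cs.clusters
        assert cs.rejected_cross_chrom == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        rows = []
        for c in (1, 2):
            starts = np.sort(rng.integers(0, 3_000_000, n // 2))
            for i, s in enumerate(starts):
                rows.append((f"g{c}_{i}", c, int(s), int(s) + 500, "+"))
        cat = _catalog(rows)
        ids = cat["gene_id"].to_numpy()
        pairs = []
        for _ in range(4 * n):
            a, b = rng.choice(ids, 2, replace=False)
            pairs.append((a, b, float(rng.uniform(-400, -50))))
        hom = _homology(pairs)
        cs = detect_tandem_duplicates(cat, hom)
        assert sorted(sorted(c.genes) for c in cs.clusters) == _brute_force_clusters(
            cat, hom
        )

    def test_recovers_seeded_truth_exactly(self):
        cfg = SimConfig(n_chrom=3, seed=77,
                        genome=GenomeConfig(genes_per_chrom=400,
                                            mean_intergenic_bp=8000,
                                            tandem_base_rate=0.08))
        cat, hom, truth = simulate_genome(cfg)
        cs = detect_tandem_duplicates(cat, hom)
        assert sorted(sorted(c) for c in truth.tandem_clusters) == sorted(
            sorted(c.genes) for c in cs.clusters
        )


@pytest.fixture(scope="module")
def fixture():
    cfg = SimConfig(n_chrom=2, seed=78,
                    genome=GenomeConfig(genes_per_chrom=400,
                                        mean_intergenic_bp=8000,
                                        tandem_base_rate=0.1))
    cat, hom, _ = simulate_genome(cfg)
    return cat, hom


class TestWindowSensitivity:
    def test_zero_window_zero_genes(self, fixture):
        cat, hom = fixture
        out = window_sensitivity(cat, hom, [0])
        assert out["tandem_genes"].iloc[0] == 0

    def test_monotone_in_window(self, fixture):
        cat, hom = fixture
        out = window_sensitivity(cat, hom, [10_000, 50_000, 200_000, 500_000])
        assert out["tandem_genes"].is_monotonic_increasing

    def test_plateau_beyond_cluster_span(self, fixture):
        cat, hom = fixture
        # seeded clusters span well under 200 kb at ~10 kb gene pitch
        out = window_sensitivity(cat, hom, [200_000, 500_000, 1_000_000])
        assert out["tandem_genes"].nunique() == 1
        assert (out["newly_discovered"].iloc[1:] == 0).all()

    def test_empty_window_list_rejected(self, fixture):
        cat, hom = fixture
        with pytest.raises(ValueError):
            window_sensitivity(cat, hom, [])


class TestGenesInInterval:
    def test_whole_chromosome(self):
        cat = _catalog([(f"g{i}", 1, i * 1000, i * 1000 + 500, "+") for i in range(1, 9)])
        got = genes_in_interval(cat, PhysicalInterval(1, 1, 10_000))
        assert got == list(cat["gene_id"])

    def test_midpoint_edge_inclusive(self):
        cat = _catalog([("g", 1, 900, 1100, "+")])  # midpoint 1000
        assert genes_in_interval(cat, PhysicalInterval(1, 1000, 2000)) == ["g"]
        assert genes_in_interval(cat, PhysicalInterval(1, 500, 1000)) == ["g"]
        assert genes_in_interval(cat, PhysicalInterval(1, 1001, 2000)) == []

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            PhysicalInterval(1, 2000, 1000)


class TestMonteCarloEnrichment:
    def test_no_flags_p_one(self):
        cat = _catalog([(f"g{i}", 1, i * 1000, i * 1000 + 500, "+") for i in range(50)])
        flags = pd.Series(False, index=cat["gene_id"])
        res = monte_carlo_enrichment(
            cat, flags, interval_gene_counts=[5], observed=0, n_iter=500, seed=1
        )
        assert res.p_value == 1.0
        assert res.null_mean == 0.0

    def test_whole_genome_interval_degenerate(self):
        cat = _catalog([(f"g{i}", 1, i * 1000, i * 1000 + 500, "+") for i in range(40)])
        flags = pd.Series(np.arange(40) % 3 == 0, index=cat["gene_id"])
        obs = int(flags.sum())
        res = monte_carlo_enrichment(
            cat, flags, interval_gene_counts=[40], observed=obs, n_iter=200, seed=2
        )
        assert res.p_value == 1.0
        assert res.null_sd == 0.0

    def test_oversized_interval_rejected(self):
        cat = _catalog([(f"g{i}", 1, i * 1000, i * 1000 + 500, "+") for i in range(10)])
        flags = pd.Series(False, index=cat["gene_id"])
        with pytest.raises(ValueError):
            monte_carlo_enrichment(
                cat, flags, interval_gene_counts=[11], observed=0, n_iter=10, seed=0
            )

    def test_planted_enrichment_detected(self):
        cfg = SimConfig(n_chrom=4, seed=79,
                        genome=GenomeConfig(genes_per_chrom=2000,
                                            mean_intergenic_bp=8000,
                                            tandem_base_rate=0.05,
                                            tandem_enrichment_factor=3.0,
                                            intervals=((1, 200, 150), (2, 500, 150))))
        cat, hom, truth = simulate_genome(cfg)
        cs = detect_tandem_duplicates(cat, hom)
        ivs = [PhysicalInterval(c, s, e) for c, s, e in truth.interval_bp]
        res = monte_carlo_enrichment(cat, cs.flags, intervals=ivs, n_iter=1000, seed=3)
        assert res.p_value < 0.05
        assert res.observed > res.null_mean


class TestCollinearOrthologs:
    def _identity_setup(self, n=60, chroms=(1, 2)):
        rows_a, rows_b, pairs = [], [], []
        for c in chroms:
            for i in range(n):
                s = i * 10_000
                rows_a.append((f"A{c}_{i}", c, s, s + 2000, "+"))
                rows_b.append((f"B{c}_{i}", c, s, s + 2000, "+"))
                pairs.append((f"A{c}_{i}", f"B{c}_{i}", -250.0))
        return _catalog(rows_a), _catalog(rows_b), _homology(pairs)

    def test_identity_full_chains(self):
        cat_a, cat_b, hom = self._identity_setup()
        chains = collinear_orthologs(cat_a, cat_b, hom)
        assert len(chains) == 2
        assert set(chains["strand"]) == {"+"}
        assert (chains["n_anchors"] == 60).all()
        iv = PhysicalInterval(1, 100_000, 200_000)
        mapped = map_interval(chains, iv)
        assert len(mapped) == 1 and mapped[0].chrom == 1

    def test_inverted_block_reported_on_minus_strand(self):
        cat_a, cat_b, hom = self._identity_setup(n=40, chroms=(1,))
        # invert the B-side order of a 12-gene block
        pairs = []
        for i in range(40):
            j = 29 - (i - 18) if 18 <= i <= 29 else i
            pairs.append((f"A1_{i}", f"B1_{j}", -250.0))
        chains = collinear_orthologs(cat_a, cat_b, _homology(pairs))
        assert "-" in set(chains["strand"])

    def test_shuffled_order_no_chains(self):
        # at a realistic gene count a random order leaves no collinear run
        cat_a, cat_b, _ = self._identity_setup(n=1000, chroms=(1,))
        rng = np.random.default_rng(5)
        perm = rng.permutation(1000)
        pairs = [(f"A1_{i}", f"B1_{perm[i]}", -250.0) for i in range(1000)]
        chains = collinear_orthologs(cat_a, cat_b, _homology(pairs), min_chain=5)
        assert chains.empty

    def test_weak_median_escore_discarded(self):
        cat_a, cat_b, _ = self._identity_setup(n=20, chroms=(1,))
        pairs = [(f"A1_{i}", f"B1_{i}", -50.0) for i in range(20)]
        chains = collinear_orthologs(cat_a, cat_b, _homology(pairs))
        assert chains.empty

    def test_unmapped_interval_returns_empty(self):
        cat_a, cat_b, hom = self._identity_setup(n=20, chroms=(1,))
        chains = collinear_orthologs(cat_a, cat_b, hom)
        assert map_interval(chains, PhysicalInterval(9, 1, 100)) == []


# --- NG86 brute-force oracle (independent of the implementation) -----------

_BASES = "ACGT"


def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _oracle_sites(codon: str):
    syn = non = 0.0
    for p in range(3):
        for nt in _BASES:
            if nt == codon[p]:
                continue
            mut = codon[:p] + nt + codon[p + 1 :]
            if _aa(mut) == "*":
                continue
            if _aa(mut) == _aa(codon):
                syn += 1 / 3
            else:
                non += 1 / 3
    return syn, non


def _oracle_diffs(ca: str, cb: str):
    diff = [p for p in range(3) if ca[p] != cb[p]]
    if not diff:
        return 0.0, 0.0
    clean, stopped = [], []
    for order in permutations(diff):
        cur, s, n, hit = ca, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if _aa(nxt) == "*":
                hit = True
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        (stopped if hit else clean).append((s, n))
    use = clean or stopped
    return (
        sum(u[0] for u in use) / len(use),
        sum(u[1] for u in use) / len(use),
    )


def _oracle_kaks(seq_a: str, seq_b: str):
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = _oracle_sites(ca)
        sb, nb = _oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = _oracle_diffs(ca, cb)
        sd += ds
        nd += dn
    ps, pn = sd / S, nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)  # noqa: E731
    return jc(pn), jc(ps)


def _random_pair(rng, n_codons=50, p_mut=0.25):
    a = [str(c) for c in rng.choice(NON_STOP_CODONS, n_codons)]
    b = []
    for c in a:
        if rng.random() < p_mut:
            while True:
                cand = c
                for p in range(3):
                    if rng.random() < 0.5:
                        cand = cand[:p] + _BASES[rng.integers(4)] + cand[p + 1 :]
                if _aa(cand) != "*":
                    b.append(cand)
                    break
        else:
            b.append(c)
    return "".join(a), "".join(b)


class TestKaKs:
    def test_identical_sequences(self):
        r = kaks_ng86("ATGGCT", "ATGGCT")
        assert r.ka == 0.0 and r.ks == 0.0
        assert math.isnan(r.ratio) and r.positive_selection is None

    def test_single_synonymous_change(self):
        rng = np.random.default_rng(7)
        anc = "".join(rng.choice(NON_STOP_CODONS, 100))
        # GGA -> GGG is synonymous (Gly)
        seq_b = "GGG" + anc[3:]
        seq_a = "GGA" + anc[3:]
        r = kaks_ng86(seq_a, seq_b)
        ka_o, ks_o = _oracle_kaks(seq_a, seq_b)
        assert r.ka == 0.0 and r.ks > 0.0
        assert r.ks == pytest.approx(ks_o, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pathway_enumeration_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        seq_a, seq_b = _random_pair(rng)
        r = kaks_ng86(seq_a, seq_b)
        if r.saturated:
            return
        ka_o, ks_o = _oracle_kaks(seq_a, seq_b)
        assert r.ka == pytest.approx(ka_o, abs=1e-9)
        assert r.ks == pytest.approx(ks_o, abs=1e-9)

    def test_site_counts_sum_to_three_minus_stop_adjacency(self):
        for codon in NON_STOP_CODONS:
            s, n = codon_sites(codon)
            n_stop_adjacent = sum(
                _aa(codon[:p] + nt + codon[p + 1 :]) == "*"
                for p in range(3)
                for nt in _BASES
                if nt != codon[p]
            )
            assert s + n == pytest.approx(3.0 - n_stop_adjacent / 3.0, abs=1e-12)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            kaks_ng86("TAAGCT", "TAAGCT")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kaks_ng86("ATG", "ATGGCT")


class TestTermEnrichment:
    def _catalog_n(self, n):
        return _catalog([(f"g{i}", 1, i * 1000, i * 1000 + 500, "+") for i in range(n)])

    def test_concentrated_term_enriched(self):
        cat = self._catalog_n(1000)
        interval = [f"g{i}" for i in range(10)]
        terms = [("g%d" % i, "PF0001") for i in range(10)]
        terms += [(f"g{i}", "PF0002") for i in range(0, 1000, 10)]
        tm = pd.DataFrame(terms, columns=["gene_id", "term_id"])
        out = term_enrichment(interval, cat, tm)
        row = out[out["term_id"] == "PF0001"].iloc[0]
        assert row["enriched"]
        assert row["p_value"] < out.attrs["bonferroni_threshold"]

    def test_whole_genome_interval_all_p_one(self):
        cat = self._catalog_n(100)
        tm = pd.DataFrame(
            [(f"g{i}", "PF0001") for i in range(0, 100, 3)],
            columns=["gene_id", "term_id"],
        )
        out = term_enrichment(list(cat["gene_id"]), cat, tm)
        assert (out["p_value"] == 1.0).all()

    def test_uniform_term_rarely_enriched(self):
        cat = self._catalog_n(2000)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            carriers = rng.choice(cat["gene_id"], 200, replace=False)
            tm = pd.DataFrame({"gene_id": carriers, "term_id": "PF0001"})
            interval = [f"g{i}" for i in range(100)]
            out = term_enrichment(interval, cat, tm)
            hits += bool(out["enriched"].any())
        assert hits <= 1
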