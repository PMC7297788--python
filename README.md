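# popqtl

Quantitative-genetic and comparative-genomic analysis of a two-class
(pseudo-backcross) *Populus* mapping population, built as a reusable,
fully tested pipeline.  It is aimed at forest geneticists and quantitative
biologists working with clonally replicated field trials who want to go
from raw biotic-survey scores to QTL intervals and genome-structure
signatures (recent tandem duplications, Ka/Ks, term enrichment) without
any external data: a synthetic-data module generates every input with
planted truth.

## What it computes

**Phenotypes** (`popqtl.phenotype`).  Ordinal disease scores and insect
counts are rank-normalized with the inverse-normal transform
Φ⁻¹((rᵢ − ½)/n); field microsite variation is removed with a 2-D thin-plate
smoothing spline (GCV-chosen smoothing), with corrected values rescaled to
the survey mean.  A one-random-effect mixed model *y = μ (+ βx) + g + ε* is
fitted by REML to estimate clonal broad-sense heritability
*H² = σ²_g / (σ²_g + σ²_e)*, its significance by a simulation-based exact
restricted likelihood-ratio test, and genotype BLUPs for mapping.

**QTL mapping** (`popqtl.qtl`).  Conditional genotype probabilities on a cM
grid come from a two-state HMM with Haldane transitions.  Single-QTL scans
fit a two-component mixture by EM (normal traits: mixture of class means;
binary traits: two penetrances), LOD = log₁₀ likelihood ratio against the
no-QTL null.  Composite interval mapping adds forward-selected background
marker covariates, dropped within a 10 cM window of the scan position.
Genome-wide significance uses 1,000-permutation thresholds (α = 0.05);
fitted multi-QTL models report percent variance explained, and each peak is
converted into a fixed 1-Mb physical interval centred on the top anchored
marker.

**Comparative genomics** (`popqtl.compgen`).  Recent tandem duplicates are
same-chromosome gene pairs with blastp E < 1e−180 within 500 kb,
single-linkage clustered; interval enrichment is tested by Monte Carlo
resampling of random contiguous gene sets of matching size (10,000
iterations, add-one empirical p).  Collinear ortholog segments are chained
from reciprocal best hits; Ka/Ks uses the Nei–Gojobori (1986) estimator
with Jukes–Cantor correction; term (PFAM/GO) enrichment uses the
hypergeometric tail with a Bonferroni threshold.

**Pathogen competition** (`popqtl.interactions`).  Sequential (Type-I)
ANOVA fitting genotype before the competitor's severity score, plus Tukey
HSD letter groupings of score-level means.

## Worked example

```python
from popqtl.simulate import SimConfig, QTLSpec, TraitModel, make_map, \
    simulate_backcross, simulate_phenotypes
from popqtl.phenotype import fit_clonal_model
from popqtl import qtl

cfg = SimConfig(n_chrom=3, markers_per_chrom=6, chrom_length_cM=100,
                n_genotypes=300, missing_rate=0.0, seed=5,
                qtl_spec=(QTLSpec(2, 40.0, 1.0, "rust"),),
                trait_models={"rust": TraitModel(h2=0.3)})
gmap = make_map(cfg)
geno = simulate_backcross(gmap, cfg)
pheno, truth = simulate_phenotypes(geno, gmap, cfg)

fit = fit_clonal_model(pheno, "rust")
print(f"H2 = {fit.components.h2:.3f}")            # H2 = 0.327

grid = qtl.genotype_probabilities(gmap, geno, step_cM=2)
y = fit.blups.reindex(geno.index).to_numpy()
scan = qtl.scan_em_normal(grid, y)
thr, maxima = qtl.permutation_threshold(
    lambda yy: qtl.scan_em_normal(grid, yy), y, n_perm=1000, seed=1)
peaks = qtl.find_peaks(scan, thr, maxima)
print(f"threshold = {thr:.2f}")                   # threshold = 2.02
for p in peaks:
    print(f"chr{p.chrom} {p.pos_cM:.0f} cM LOD {p.lod:.1f} p {p.p_value:.4f}")
# chr2 38 cM LOD 26.9 p 0.0010
```

The planted QTL (chromosome 2 at 40 cM, class-mean difference 1.0 on a
trait with H² = 0.3) is recovered 2 cM from its true position with a LOD
far above the genome-wide permutation threshold; the heritability estimate
matches the planted value within sampling error.

A full pipeline run (simulate → pheno → scan → intervals → tandem →
enrich → kaks → anova) is driven by one YAML config:

```bash
popqtl all --config config.yaml --outdir out
```

and writes TSV/CSV/GFF3/BED/JSON artifacts plus a deterministic
`report.json` (same config and seeds ⇒ byte-identical report).

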