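# Methods

This note documents the models behind each stage, the defaults that
matter, what the synthetic data do and do not emulate, and the numerical
choices a maintainer would want recorded.

## Synthetic study system

The generator (`popqtl.simulate`) emulates a clonally replicated
pseudo-backcross trial: an interspecific F1 crossed back to the recurrent
species, so maternally informative markers segregate 1:1 into a
heterozygous class (T, donor allele present) and a homozygous recurrent
class (D).  Default dimensions mirror a realistic poplar design: 19
chromosomes of ~138 cM (≈2,600 cM total), ~160 kb per cM of physical
sequence (≈420 Mb genome), several hundred genotyped progeny with two
ramets each, and 1% missing genotype calls.

- **Map.**  Markers are evenly spaced in cM with random, strictly monotone
  bp anchors.  Recombination uses the Haldane map function
  r = (1 − e^(−2d/100))/2 — the natural choice for a no-interference
  Markov simulation, and consistent with the HMM used for scanning.
- **Phenotypes.**  Latent value = QTL effects (±effect/2 by class) +
  genotype-level polygenic effect + smooth spatial surface + ramet residual.
  The polygenic variance is sized so genotype variance / (genotype +
  residual) hits the trait's target H²; if the planted QTL alone exceed the
  target the polygenic term is clipped at zero and the realized H² is
  recorded in the truth record.  Ordinal scores are the latent value cut at
  equal-frequency thresholds (scores treated as discretized liabilities),
  binary traits threshold at the median, counts use a Poisson log link with
  a damped latent scale.  Zero-inflation and other survey pathologies are
  *not* emulated; trait-family parameters are configurable, not inferred.
- **Spatial surface.**  A sum of three low-frequency sinusoids with random
  phases, standardized to the requested amplitude (SD).  Smooth and
  spline-recoverable by construction; real microsite variation is rougher,
  so spline-recovery results here are an upper bound on field performance.
- **Genome.**  Genes tile each chromosome (spacing derived from the mapped
  length unless set explicitly).  Tandem clusters are runs of adjacent
  genes seeded at rate base_rate/mean_cluster_size with geometric sizes
  (mean 2.5), so the expected tandem-gene fraction equals the base rate;
  designated intervals multiply the rate by an enrichment factor.
  Within-cluster homology pairs get log10 E ∈ (−300, −185); background and
  decoy pairs (cross-chromosome, beyond-window) sit on the other side of
  the detection rules, which makes the planted membership recoverable
  exactly — deliberately so, since the clustering test is an oracle-identity
  check, not a robustness study.
- **CDS pairs.**  Substitution counts come from the target Ks (and
  Ka = ω·Ks) through the forward Jukes–Cantor map on NG86 site counts and
  are applied as at most one single-nucleotide change per codon, so the
  observed difference proportions equal their targets and the estimator
  maps them back to (Ka, Ks) almost exactly.  Multi-hit codons therefore do
  not arise from the generator (requesting more changes than codons raises
  an error); pathway averaging is exercised separately by enumeration
  oracles on hand-built multi-hit pairs.  Default Ks = 0.2 per synonymous
  site keeps ω ≤ 2 within the single-change capacity of an alignment.

## Phenotype stage

- **Normal scores.**  Φ⁻¹((rank − 0.5)/n) with average ranks for ties; the
  (r − 0.5)/n percentile convention is a deliberate choice (the transform
  itself does not fix one).  Constant input is an error.
- **Thin-plate spline.**  Classical 2-D TPS (radial basis r² log r plus an
  affine part, which reproduces planes exactly at any smoothing).  The
  penalized system is reduced to the null space of the polynomial part via
  QR, then eigendecomposed once so GCV can be evaluated cheaply; GCV is
  minimized on a 40-point log grid followed by bounded refinement.
  Duplicate coordinates make the system singular and are rejected —
  deduplicate or jitter upstream.  Spatial correction returns
  mean(raw) + residual, preserving the survey mean to ~1e−10.
  Default order of operations: transform, then spatial-correct (the
  alternative order is one function call away; both are monotone-compatible).
- **REML.**  One random effect allows the likelihood to be profiled on
  λ = Vg/Ve: group-wise Sherman–Morrison gives O(n) evaluation, and a
  bounded 1-D search on log λ ∈ [−12, 12] with an explicit λ = 0 boundary
  comparison replaces any matrix-sized optimization.  On balanced designs
  the result equals the ANOVA method-of-moments estimator to ~1e−6
  (asserted in tests, cross-checked against an independent mixed-model
  implementation).  BLUPs reduce to the one-way shrinkage form
  g̃ᵢ = λ Σⱼ rᵢⱼ / (1 + λ mᵢ).  A covariate enters as a fixed effect.
  All-singleton designs leave Vg unidentifiable and are flagged.
- **Exact RLRT.**  Statistic 2(ℓ_full − ℓ_null) on restricted likelihoods,
  clipped at zero (the null value lies on the boundary of the parameter
  space, so ~half the null mass is at 0).  The null distribution is
  simulated parametrically — data under Vg = 0 with the null model's fixed
  effects and residual variance, both models refitted per replicate —
  rather than via the spectral shortcut; slower but self-contained, with
  n_sim configurable (default 10,000).  p = (1 + #{sim ≥ obs})/(1 + n_sim).
- **Binarization.**  0–5 canker scores map to 1 iff score ≥ 2.5.

## QTL stage

- **Genotype probabilities.**  Two-state forward–backward over markers plus
  pseudomarkers (default step 1 cM; the calibration studies use 2–4 cM),
  Haldane transitions, symmetric genotyping-error emission ε = 1e−4,
  missing calls uninformative.
- **EM scans.**  At each position the mixture over the two genotype classes
  is fitted by EM with the conditional probabilities as mixing weights;
  tolerance 1e−6 on the log-likelihood, ≤200 iterations, initialized from
  the marker-regression (prior-weighted) estimates.  Per-iteration
  likelihood monotonicity is asserted; non-converged positions are flagged
  and keep their best iterate.  At fully informative markers the normal
  LOD equals (n/2) log₁₀(RSS₀/RSS₁) and the binary LOD equals the 2×2
  G statistic / (2 ln 10) to 1e−6 (oracle tests).  Binary penetrances are
  clipped to [1e−6, 1 − 1e−6] so separation keeps LOD finite.
- **CIM.**  Background covariates (default 3) are expected genotype codes
  at markers chosen by forward selection on single-marker LOD; at each scan
  position covariates within 10 cM on the same chromosome are dropped.
  With covariates the EM M-step solves a small weighted least-squares
  system per position; without covariates the whole genome is vectorized.
  Permutations re-select covariates per permuted trait (the conservative
  choice); both n_covar and the window are configuration.
- **Permutations.**  Plain shuffles of the genotype-level trait (clonal
  replicates are collapsed to BLUPs before scanning, so rows are
  exchangeable); threshold = type-7 empirical (1 − α) quantile of
  genome-wide maxima; peak p-values use the add-one convention.  n_perm
  below 20/α triggers a warning.
- **PVE.**  Joint OLS on expected genotype codes at all peaks (peaks < 1 cM
  apart merged, higher LOD kept); model PVE = 100(RSS₀ − RSS_full)/RSS₀,
  per-peak by drop-one against the same RSS₀.
- **Intervals.**  A peak snaps to the highest-LOD genotyped, anchored
  marker within 5 cM (error if none; the CLI exposes the radius for sparse
  maps) and becomes [anchor − 499,999, anchor + 500,000], 1-based
  inclusive, clipped at chromosome ends.  BED output converts to 0-based
  half-open; the conversion is round-trip tested.

## Comparative-genomics stage

- **E-scores** travel as log10 values end to end; BLAST's literal `0.0`
  parses to −∞ and printed exponents are parsed directly, so scores far
  below double-precision underflow (1e−320 and beyond) stay ordered.
- **Tandem clusters.**  Link two genes iff same chromosome, E strictly
  below 1e−180 (ties excluded), and start-to-start distance ≤ 500 kb;
  clusters are connected components (union-find), size ≥ 2.  Tandem
  *genes* (cluster members) are counted, so a cluster's size is its copy
  number.  Cross-chromosome pairs passing the E filter are counted but
  never linked.  The window-sensitivity curve reports cumulative and
  newly-discovered counts over a window ladder.
- **Monte Carlo enrichment.**  Windows are contiguous in gene-index space
  ("sets of contiguous genes"), chromosome chosen ∝ (genes − k + 1),
  uniform start, tandem flags precomputed globally (a sampled gene counts
  even if its cluster partners fall outside the window).  The test
  statistic is the summed count across all query intervals; per-interval
  p-values are a secondary output.  p = (1 + #{sim ≥ obs})/(1 + n_iter),
  default n_iter = 10,000 (calibration studies use 1,000).
- **Collinearity.**  Anchors are reciprocal best hits (lowest E, then
  highest identity).  A dynamic program chains anchors with index steps
  ≤ max_gap (default 10) in both genomes and a consistent orientation;
  chains need ≥ 5 anchors and median log10 E < −180.  This is a simplified
  chainer, not a reimplementation of a full synteny scorer: with a 10-gene
  gap allowance, random order on small (≲300-gene) chromosomes can produce
  short spurious chains, so null tests use realistic gene counts.
- **NG86 Ka/Ks.**  Per-codon site fractions (changes to stops dropped from
  both tallies, so stop-adjacent codons count slightly under 3 sites),
  pathway-averaged difference counts for multi-hit codons (stop-crossing
  pathways discarded unless none remain), Jukes–Cantor correction on both
  proportions.  Ks = 0 leaves the ratio undefined and the
  positive-selection flag None; p ≥ 3/4 flags saturation instead of
  raising.
- **Term enrichment.**  Hypergeometric upper tail per term against the
  genome, Bonferroni threshold α / #terms tested (the divisor is reported
  alongside the results, since it depends on the annotation actually
  supplied).

## Competing-pathogen ANOVA

Type-I (sequential) sums of squares, genotype fitted first, the
competitor's score as a 4-level factor (factor coding is what reproduces
the reference degrees of freedom; a linear score would have df = 1).
Genotype is fixed here, unlike the mixed model of the heritability stage —
the two answer different questions (testing a competitor effect net of
host genotype vs. partitioning variance).  Tukey HSD uses studentized-range
critical values on the pooled variance with an insert-and-absorb compact
letter display.

## Validation studies and their sizes

`popqtl.studies` fixes the reference conditions used by both the test
suite and `scripts/acceptance.py`; sizes are chosen so the whole battery
runs in minutes on one CPU while keeping Monte Carlo error well inside the
asserted bands:

| study | conditions |
|---|---|
| tandem oracle | 50 random catalogs, ≤500 genes, vs. plain union-find |
| enrichment calibration | 200 null genomes, 20,000 genes, rate 0.05, five 120-gene intervals, n_iter 1,000 |
| enrichment power | 100 genomes, 3× enrichment in intervals |
| EM LOD oracle | 20 informative-marker datasets, n = 200 |
| permutation type-I | 200 null traits, n_perm 200, 3-chromosome grid |
| QTL localization | 50 replicates, 20%-variance QTL, n = 400, ≤10 cM |
| H² recovery | planted H² ∈ {0.25, 0.4, 0.6}, 500 genotypes × 2 ramets, 20 fits |
| NG86 oracle | 100 random 50-codon pairs, tolerance 1e−9 |
| ω recovery | ω = 1.35, 900 codons |
| spline recovery | amplitude 2, noise SD 1, 400 trees, correlation > 0.8 |

## Known limitations

- Single-QTL and CIM scans only: no multiple-QTL model search, epistasis,
  or sex-chromosome handling; the map is taken as given.
- The mixed model has one unstructured random effect — no pedigree/kinship,
  no multi-trait covariance.
- Ordinal and count traits are scanned through their BLUPs on the latent
  scale rather than by family-specific scan likelihoods.
- The collinearity chainer approximates, and does not reproduce, MCScanX
  scoring; interval mapping across genomes reports chain spans, not
  base-level liftover.
- Synthetic data are idealized (smooth surfaces, exact 1:1 segregation,
  clean homology scores): passing tests demonstrate correctness of the
  machinery, not robustness to the messiness of real surveys and real
  annotation.
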