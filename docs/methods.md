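# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `rvpower`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Reference panel synthesis

**Base panel.** The starting point is a phased panel of `n_base = 379`
diploid individuals over a synthetic contig of 3 kb, half of which lies in
three evenly spaced "exon" blocks (an average-coding-length gene carries
roughly 1.5 kb of coding sequence). The base panel is produced by neutral
coalescent simulation (msprime; effective size 10⁴, population-scaled
per-bp rates θ = 2×10⁻³ and ρ = 10⁻³, chosen to give realistic nucleotide
diversity and within-gene LD decay for a European-ancestry-like sample).
Multi-allelic sites are dropped; alleles are coded 0 = major, 1 = minor.

**Expansion.** The panel is grown to `target_n = 12,514` individuals in
increments of 300 by sampling new haplotypes as imperfect mosaics of the
current panel under the Li & Stephens hidden-Markov copying model:
template switches between adjacent sites with probability
`1 − exp(−ρ·d/H)` (d = distance in bp, H = current haplotype count) and a
per-site copy-error rate `ε = θ/2/(H + θ)` with the HAPGEN2-convention
mutation parameter `θ = 0.08`. The same ε applies to every
currently-monomorphic exonic position, so each new haplotype introduces
`Poisson(ε · #free exonic bp)` brand-new singleton columns whose
frequencies can subsequently drift as later haplotypes copy them. This
single-θ treatment resolves the otherwise free split between copy error
and new mutation with one knob, and concentrates the simulated excess of
rare variation in coding sequence, which is where causal effects are
assigned and tests are run.

**SFS thinning.** Expansion overshoots the rare-variant density of real
exome data, so whole variant columns are removed by rejection sampling
until the retained spectrum matches a target. The bundled target is a
power-law spectrum on minor-allele count, `P(MAC = k) ∝ k^−1.6`, binned
into singleton/doubleton/…/common classes, with a retained density of 27
variants per kb of simulated region. The exponent makes ~44% of sites
singletons in the full panel; the density constant was calibrated once
against the design condition that a 3,000-individual sample at an
average-length locus segregates a median of ~38 exonic variants with
MAF < 1%, and then frozen. Thinning never edits genotypes inside retained
columns, so LD among retained sites is untouched. By default an
over-ambitious target is clipped to the feasible maximum; `strict=True`
turns that into an infeasibility error.

**Validation metrics.** `sfs()` bins the spectrum by MAF or minor-allele
count; `ld_profile()` reports mean pairwise r² within MAF strata by
inter-site distance. The suite checks that expansion changes common-variant
(MAF > 5%) mean r² by at most 0.05 per distance bin.

## Disease model and architectures

The trait is a common dichotomous disease with prevalence `K = 0.08`
(type-2-diabetes-like). Per-variant effects are per-allele relative risks
with additive dosage coding: genotype risk factors `1, RR, 2RR − 1`.
Penetrances are solved against the prevalence under Hardy-Weinberg:
`f0 = K / (p0 + p1·RR + p2·(2RR−1))`; combinations whose penetrances leave
(0, 1) raise an infeasibility error (this includes protective effects with
RR⁻¹ < 0.5, for which the additive homozygote coding breaks down —
draws like that are simply rejected and redrawn during locus sampling).

**Variance explained.** Each genotype class is given a unit-variance
normal liability whose mean reproduces its penetrance against the
population threshold `T = Φ⁻¹(1 − K)`: `μ_g = T − Φ⁻¹(1 − f_g)`. The
between-genotype variance `Vg = Σ p_g μ_g² − (Σ p_g μ_g)²` is reported as
`VE = Vg / (1 + Vg)`, i.e., as a fraction of total liability variance with
unit residual; users wanting raw `Vg` can invert the transform. Locus VE
is the sum of per-variant VEs (independence between causal variants is
assumed, consistent with their typically low frequencies).

**Architecture maps.** A `FreqRRMap` is a weight grid over MAF × RR bins
(24 log-spaced MAF bins on 2×10⁻⁵–0.5; 40 log-spaced RR bins on
1.02–5.0). The six bundled architectures use a log-normal conditional RR
distribution (spread 0.3 on log(RR−1)) whose mode follows
`1 + A·(maf/0.005)^−c`:

| id | coupling c | amplitude A | restriction | protective |
|----|-----------|-------------|-------------|------------|
| ar1 | 0.60 | 2.0 | none | 0 |
| ar2 | 0.45 | 1.2 | none | 0 |
| ar3 | 0.00 | 0.5 | none | 0 |
| ar4 | 0.60 | 2.0 | MAF < 1% | 0 |
| ar5 | 0.45 | 1.2 | MAF < 1% | 0 |
| ar6 | 0.45 | 1.2 | none | 0.5 |

The anchor puts the modal RR of a MAF 0.5% variant at 3.0 under strong
coupling (matching the classic single-variant power scenario) and keeps
common-variant RRs near the 1.1–1.3 range observed for complex-trait
loci. The RR ceiling of 5 keeps homozygote risk factors of ultra-rare
variants inside the multiplicative model's validity range at K = 0.08.
These grids are deliberately qualitative stand-ins for distributions that
would otherwise come from forward population-genetic simulation of
selection, which is out of scope; any custom grid can be supplied as a
TSV. Protective draws (ar6) invert the sampled RR.

**Causal-set sampling.** Effects accumulate at uniformly chosen exonic
variants (frequency taken from the full augmented panel): while the
cumulative VE is below 0.95× target, add a variant; when above 1.05×
target, remove one introduced effect uniformly at random; accept inside
the window unless more than 35 variants were introduced, in which case the
locus restarts from scratch. The cap, the window multipliers, and the
uniform removal rule are part of the study design. Defaults: 1,000
restarts maximum, 10⁴ add/remove steps per attempt before an internal
restart (guards a rare non-converging cycle when every available variant
overshoots the window).

## Cohort ascertainment

Cohort individuals are diploids formed from two fresh Li & Stephens
mosaics of the panel (same ρ and θ; no new columns, so the causal-site
annotation stays aligned). The target distributions are the conditionals
of the multiplicative risk model, `P(g | case) ∝ P(g)·risk(g)` and
`P(g | control) ∝ P(g)·(1 − risk(g))` with
`risk(g) = f0·∏_v RR_v(g_v)` and f0 solved so the population mean risk is
K (cross-variant independence at panel frequencies is used for the
solve; a Monte-Carlo test confirms the panel-mean risk lands on K with
the real LD included). Sampling is by thinning: each drawn individual is
accepted into the case pool with probability `risk/c` (c fixed at 1.1×
the first batch's maximum risk, at least 1) or into the control pool with
probability `1 − risk`, until both quotas fill. For risks strictly below
1 this reproduces exactly the same case and control genotype
distributions as assigning status by `Bernoulli(risk)` and retaining by
quota; in the rare tail where the multiplicative model would exceed unit
risk (about 10⁻⁵ of draws under the default architectures) the
acceptance probability saturates and the event is counted in the
dataset's diagnostics rather than aborting the replicate. `individual_risk`
itself keeps the strict contract and raises when any computed risk
reaches 1. Null loci skip ascertainment entirely — with no causal
variants, labels are exchangeable, so a null cohort is sampled
individuals with an arbitrary 1500/1500 split.

Sample-monomorphic columns are dropped from cohorts; observed MAF is
always recomputed from the genotype matrix. `causal_fraction_filter`
removes non-causal rare sites uniformly at random so the causal:total
ratio among retained MAF < 1% sites hits 0.25/0.5/0.75/1 (all causal
sites are always kept; a shortage of neutral sites yields the closest
achievable ratio rather than an error).

## Association tests

All gene-based tests see the sites with sample MAF strictly below the
threshold (default 1%; 0.5% and 5% supported), computed from cases and
controls combined; single-variant Fisher sees every site. Minor-allele
dosage coding is enforced per site.

Permutation tests (BURDEN, UNIQ, FRQWGT, VT, KBAC, C-ALPHA) exchange
case/control labels with the +1 correction `p = (1 + #{T* ≥ T})/(B + 1)`,
escalate adaptively (start 10³, ×10 whenever p < 10/B, cap 10⁶ by
default), and switch to exhaustive enumeration of case assignments
whenever `C(n, n_case) ≤ 5,000`, where the reported p is the exact
enumeration fraction. Statistics:

- **BURDEN** — total rare minor-allele count in cases (one-sided).
- **UNIQ** — minor-allele observations at sites whose minor alleles occur
  only in cases (case-uniqueness re-evaluated per permutation).
- **FRQWGT** — inverse-frequency weights `1/√(n·q(1−q))` with q estimated
  from controls (+1 pseudo-count) and recomputed per permutation; the
  statistic is the weighted case allele count.
- **VT** — the z-like burden statistic `(y−ȳ)ᵀs(T)/‖s(T)−s̄(T)‖` maximized
  over every distinct observed MAF threshold, re-scanned per permutation.
- **KBAC** — individuals grouped by multi-site rare genotype pattern;
  each non-null pattern weighted by the hypergeometric CDF of its case
  count; statistic = Σ w·(case rate − control rate) (one-sided).
- **C-ALPHA** — Σ over sites of `(y_i − n_i p0)² − n_i p0(1−p0)` with
  p0 = case fraction; permutation p of the sum (numeric mixture tails are
  left to SKAT).

Asymptotic tests:

- **CMC** — carrier indicator of any rare allele; likelihood-ratio test of
  the logistic regression on that single binary predictor, computed as the
  equivalent 2×2 G-test (1 df). Constant predictors return p = 1.
- **WILCOX-WSS** — Madsen-Browning control-weighted scores compared by the
  tie-corrected asymptotic Wilcoxon rank-sum test (two-sided).
- **SINGLE-FISHER** — two-sided (minimum-likelihood) Fisher's exact test
  on per-site allele-count tables; the locus summary is the minimum p and
  the attaining site's MAF.
- **SKAT** — `Q = (y−μ)ᵀGW²Gᵀ(y−μ)` with Beta(1, 25)-density MAF weights
  (flat weights available). The null is the chi-square mixture with
  eigenvalues of `σ²·(G̃W)ᵀ(G̃W)`; tails are computed by Imhof
  characteristic-function inversion, with the oscillatory part handled as
  a Fourier (QAWF) integral and a Liu moment-matched fallback. Because the
  permuted binary phenotype is sub-Gaussian, the mixture is additionally
  moment-corrected: the exact permutation mean and variance of Q (closed
  combinatorial formulas, verified against full enumeration in the suite)
  rescale Q before the tail lookup. Residual disagreement with the exact
  permutation null is at the level of the third moment (≈0.02–0.03
  absolute in the p body on 500-sample cohorts).
- **SKAT-O** — `Q_ρ = (1−ρ)Q_SKAT + ρQ_burden` on the grid
  ρ ∈ {0, 0.1², …, 0.5², 1}; each Q_ρ gets the moment-corrected mixture p;
  the minimum-p statistic's null is evaluated by the standard
  burden-direction decomposition (κ + τ(ρ)·χ²₁ with a cross-term variance
  adjustment) and one-dimensional numeric integration. The reported p is
  clipped to [min_ρ p_ρ, |grid|·min_ρ p_ρ]. Degenerate grids reproduce
  SKAT (ρ = 0) and the two-sided weighted-burden z-test (ρ = 1) exactly.
- **MiST** — stage 1: score z-test of the weighted-burden component;
  stage 2: variance-component score test of the genotype columns projected
  orthogonally to the burden score (moment-corrected mixture tail);
  combined by Fisher's method (χ², 4 df). Covariates are not modeled (the
  simulations contain none).

`run_test_battery` runs any subset on the identical filtered data with
independently spawned permutation seeds and converts per-test errors into
missing-with-reason rows.

## Evaluation

Power is the fraction of replicates with p strictly below α (ties count
as non-detections), with exact Clopper-Pearson intervals. FPR-corrected
thresholds are order statistics of null p-values (the largest cutoff with
empirical exceedance ≤ the target; requires ≥ 1/target null replicates).
Concordance is the squared Pearson correlation of −log₁₀ p over loci
where both tests report p ≤ 0.1. Composite selection is greedy forward
selection: add the candidate with the most novel signals (p·margin below
the included minimum and p < α; margins 100/10/1), then report min-p
sensitivity and, given nulls, the FPR-adjusted sensitivity using the
corrected threshold of the composite min-p statistic (novelty is counted
per locus-replicate). `discordance_profile` summarizes loci where one
test but not another reaches p < 0.01 by aggregate case:control ratio,
case-unique allele count, and top single-variant p.

**Analytic single-variant power** uses the prevalence-constrained model
for the expected case allele frequency and, by default, the population
frequency for controls (the unselected-controls convention of standard
power calculators; a screened-controls option conditions on disease-free
status and yields roughly twice the power in the anchor scenario). The
normal approximation to the two-sample allele test gives the analytic
value; the Monte-Carlo route simulates allele counts and applies Fisher's
exact test, which is conservative at extreme α because of discreteness.

## What the generator does and does not emulate

The synthetic panel reproduces: a rare-dominated exome-like SFS with a
calibrated per-locus rare-variant yield, plausible within-gene LD and its
preservation under expansion, and frequency-conditional effect-size
regimes spanning strong-to-weak selection coupling. It does not
reproduce: real gene length variation, mutation-rate or recombination
heterogeneity, demographic structure or non-European spectra, non-coding
variation, linked selection, genotyping or calling error, or covariate
structure. Passing tests therefore demonstrate the statistical machinery
and its calibration under the stated generative model, not performance on
any particular real dataset; in particular the architecture grids are
qualitative regimes, so absolute power percentages are specific to these
defaults while orderings and trends (power monotone in VE, sample size,
and causal fraction; unidirectional tests collapsing under bidirectional
effects) are the transferable findings.

## Numerical and scale choices

Test-suite and acceptance runs use scaled problem sizes chosen to keep
results statistically meaningful at interactive cost: 1,000 null cohorts
of 1.5K/1.5K with the adaptive permutation cap at 10³ for calibration
(the attainable level at B = 10³ is 50/1001 ≈ 0.04995); 100 loci for the
panel-yield median; 200 replicates at 500/500 for the SKAT/C-alpha
concordance; exhaustive 8-individual fixtures wherever enumeration is the
oracle. All randomness flows from explicit seeds (numpy `SeedSequence`
spawning; CRC-labeled per-stage children in `run_study`), and every
documented entry point is bit-reproducible given its seed. Exact Fisher
p-values at rare counts are discrete and hence conservative at nominal
α — the calibration check treats the single-variant test accordingly
(validity, not exact size).
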