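# Methods

This note documents the models and procedures implemented in
`thermoplast`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Thermal performance curve model

Performance (sprint speed, m/s) at body temperature T (°C) follows the
Kamykowski double-exponential

P(T) = a (1 − e^{−b(T − T_min)}) (1 − e^{−c(T_max − T)}),

with scale a (m/s), rise and fall rates b, c (1/°C), and zero-performance
temperatures T_min < T_max (°C). All predictions are clamped at zero;
outside [T_min, T_max] the raw product is negative and the clamped curve
is exactly 0. Critical-limit assays contribute anchor observations with
y = 0 at the measured CTmin/CTmax, treated as ordinary likelihood rows.

### Hierarchical model

Each of the five parameters is given a box (L, U) from data-driven
heuristics: T_min/T_max start at the anchor means with ±10 °C boxes, a at
the maximum observed speed with a (0.1·init, 10·init] box, and the rates
at 0.1 /°C inside (10⁻³, 10). On the unconstrained scale
η = logit((θ−L)/(U−L)):

- population locations μ_k ~ Normal(η(init_k), 1.5),
- population spreads σ_k ~ half-Normal(0, 0.5),
- individuals (non-centred) η_ik = μ_k + σ_k z_ik, z_ik ~ Normal(0, 1),
- observation noise σ_obs ~ half-Normal(0, sd(y)),
- likelihood y ~ Normal(mean curve, σ_obs).

The priors are weakly informative and centred on the bounds heuristics;
the half-Normal(0, 0.5) spread keeps individual variation plausible on the
logit scale without pinning it.

**Likelihood mean.** By default the likelihood mean is the *raw* (signed)
curve, not the clamped one, while every prediction, band and derived
quantity uses the clamped curve. Reason: with a clamped mean, a
zero-performance anchor penalises only curves positive at the anchor, so
nothing stops T_max drifting below CTmax across the data gap between the
hottest sprint temperature and the critical limit — in simulation this
inward drift reaches ~2 °C. With the raw mean, a curve whose T_max is
below the anchor predicts a negative value there and is penalised
symmetrically, restoring identifiability (recovery error drops below
0.5 °C). Fitting with the clamped mean remains available
(`MCMCConfig(clamp_likelihood_mean=True)`), and the untruncated Gaussian
noise on a non-negative response is a known approximation in both cases.

### Sampling and diagnostics

Each configured chain is an independent affine-invariant ensemble
(`emcee`, differential-evolution moves, ~2.5 walkers per free parameter),
initialised by scattering walkers around a posterior mode found by
L-BFGS. After discarding the warmup steps, the sampling steps are
flattened and evenly thinned to exactly the configured number of draws per
chain. Split R-hat and effective sample size are computed per
population-level quantity (arviz); any R-hat above 1.05 flags the result
(`converged=False`, warning) without discarding it. The divergence count
is reported as 0 — ensemble samplers have no divergences in the
Hamiltonian sense; R-hat/ESS carry the convergence information. At the
reduced default sampling the weakly identified fall rate c can flag; longer
chains clear it.

### Derived quantities

P_max and T_opt come from a two-stage grid search on the population-level
curve of each draw: a 50-point grid over [T_min, T_max] locates the coarse
argmax; a 100-point grid over one coarse step either side (clipped)
refines it. Against a derivative-root oracle the error is below one
fine-grid spacing (≈0.012 °C for a 30 °C span). Curve credible bands are
pointwise posterior quantiles (2.5/25/50/75/97.5%), nested by
construction.

### Identifiability limits

With sprint temperatures up to 37 °C and T_opt near 38 °C, the scale a is
partially extrapolated and sits on a ridge with b and c; in ~1 of 6
simulated datasets the posterior median of a lands 15–20% from truth even
though T_min/T_max recover within 0.5 °C. This is a property of the
emulated design (no performance data between 37 °C and CTmax), verified by
an independent least-squares oracle showing the same displacement and by
near-exact recovery when observation noise is removed.

## Permutation inference

*ANCOVA.* F compares the covariate-only model with the group+covariate
model, F = ((RSS_r − RSS_f)/q)/(RSS_f/(n−p)). The null distribution uses
Freedman–Lane: residuals of the reduced model are permuted and added back
to the reduced fit, preserving the covariate's contribution. The group
effect is tested adjusted for the covariate (Type II-like).

*Split-plot ANOVA.* Classical decomposition: the between-subject effect is
tested against subjects-within-groups; the within-subject effect and
interaction against the subject × within-level residual. Permutation
schemes: whole-subject profiles are relabelled across groups for the
between effect (equivalently, a subject-mean one-way permutation test,
which is how it is vectorised); within-subject labels are permuted inside
each subject — one shared permutation per iteration serving both the
within and interaction statistics. The within/interaction scheme is a
declared choice; the between-effect test is exact under subject
exchangeability (verified: null p-values are uniform).

*Reporting.* p = (b+1)/(m+1) counting ties as exceedances; when b = 0 the
result carries `below_floor` and the floor 1/m, reproducing the
"p < 2×10⁻⁵" convention at m = 50,000. Post hocs use |Δ group mean| per
within level with Holm's step-down correction. Holm/BH are delegated to
statsmodels behind this package's argument checking; Wilcoxon tests to
scipy with exact enumeration for n ≤ 12 without ties and tie-corrected
normal approximation otherwise.

## Co-expression modules

Counts are filtered (CPM > cpm_min, strictly, in ≥ ⌈min_frac·n⌉ samples),
scaled by median-of-ratios size factors (geometric-mean reference over
genes expressed in every sample; robust to a strongly co-varying minority,
where total-count scaling imprints a compositional component on the
background) and transformed to log2(scaled+1) — this package's
variance-stabilising step; module statistics downstream are
transform-agnostic. Sample outliers are
removed by average-linkage clustering on Euclidean distance, keeping the
largest branch below the cutoff. The top-n variable genes (variance, ties
by gene id) enter the network.

bicor follows the Tukey biweight definition with 9·MAD scaling and a
Pearson fallback (with warning) for zero-MAD vectors. The soft power is
the lowest β for which the signed Pearson adjacency ((1+r)/2)^β yields a
scale-free fit above the target: connectivities are binned into 10
equal-width bins and the signed index −sign(slope)·R² of
log10(frequency) ~ log10(mean k) must exceed 0.80 (the WGCNA
`scaleFreeFitIndex` convention). If no power passes, the best power is
returned flagged.

Module detection: signed bicor adjacency → topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) → average-linkage
tree of 1−TOM → static cut at the lowest height maximising the number of
branches of ≥ min_size/2 genes (seeds) → fuse seeds whose eigengenes
correlate ≥ 1−merge_height → one kME sweep assigning every gene to its
best-correlated module if kME > 0.6, else unassigned → final merge and
min_size filter. The kME sweep substitutes for the dynamic hybrid tree
cut (whose deepSplit tuning has no analogue here); the 0.6 membership
floor is ≈2.3 null standard deviations at 16 samples, conservative for
larger cohorts. On the default planted fixture the adjusted Rand index
against truth exceeds 0.95 across seeds.

Eigengenes are the first right singular vector of the standardised module
submatrix, sign-oriented to correlate positively with the module mean
profile. kME is bicor(gene, eigengene) over all genes × modules.
Module–trait association encodes each group as a one-vs-rest indicator,
r = bicor(eigengene, indicator), two-sided p from t = r√((n−2)/(1−r²)) on
n−2 df, BH across all module × trait cells jointly. Hub genes have
|kME| > 0.8 to their own module (strict).

The bootstrap stability score resamples sample columns with replacement
(draws with < 3 distinct samples are redrawn and logged), recomputes
eigengenes under the *original* assignments, takes each gene's kME to its
own module, and averages: first across genes within a bootstrap, then
across bootstraps. The mean is over own-module kME (signed, eigengenes
sign-oriented); the alternative grand mean over the full gene × module
matrix would mix in cross-module terms and was not used. The score
exceeds 0.8 at within-module correlation 0.8 and decreases monotonically
through 0.5 and 0.2 on the planted fixtures.

Fisher's exact module-overlap test builds the 2×2 table over a
caller-supplied universe (it must be explicit — overlap significance is
meaningless without it), OR = ad/bc, two-sided p by hypergeometric
enumeration (scipy).

## Regulatory windows

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on read. Gene-proximal windows are the gene body ± flank,
strand-independent and clipped to the chromosome (slop semantics).
Promoter windows are strand-aware around the biological TSS: [start−up,
start+down) on +, [end−down, end+up) on −. DPG classification requires
≥ 1 bp overlap with a differential peak (half-open: abutting intervals do
not overlap); no minimum-fraction rule. Footprint filtering keeps DEGs
with ≥ 1 footprint of any requested motif inside the promoter whose fold
change is strictly above the threshold on the raw-ratio scale (log2 input
is converted); the union over a motif family is reported. Interval queries
use interval trees and are tested against quadratic scans.

## Synthetic data

The thermal generator draws per-individual parameters as population values
plus independent Gaussian deviations on the natural scale (redrawn if the
curve would be invalid), one CTmin/CTmax anchor at the individual's own
limits with a uniform ramp-rate covariate, and sprint speeds at
15/20/25/30/35/37 °C with Gaussian noise (sd 0.05 m/s), clamped at zero
since speeds are non-negative. Default population curves peak at ~0.73 and
~0.84 m/s with T_opt in the high 30s — the scale of real gecko sprint
data. Default cohorts are 2 groups × 15 individuals.

The expression generator plants modules as shared latent factors: module
genes load √ρ on their factor plus √(1−ρ) noise, scaled by 1.8 so
co-regulated genes carry more variance than background (they must survive
top-variance selection, as in real transcriptomes); factors are
orthogonalised across modules so planted modules are mutually uncorrelated
exactly, and the first module's factor is shifted by the group effect
(default 2 latent SD) in the last group. The latent matrix maps through
exp(0.5·latent) onto log-normal baseline abundances and Poisson (or
negative binomial) counts at ~5×10⁵ reads/sample, 2 groups × 8 samples.
Default modules: 3 × 100 genes of 2,000.

The genome generator places strand-alternating, non-overlapping genes with
≥ 2·flank spacing (so ±5-kb windows are unambiguous), plants differential
peaks inside chosen gene windows plus uniform background peaks, and plants
strong-fold-change footprints inside chosen DEG promoters. Ground truth is
recomputed from the emitted intervals by a direct scan, so coincidental
background overlaps are part of the truth, not noise.

What the synthetic data do not emulate: read-level sequencing error,
compositional library artefacts beyond total-count scaling, gene length
bias, splicing, overlapping gene models, or realistic motif sequence
content. Passing tests demonstrate the statistics are implemented
correctly and are well calibrated under their assumptions — not that those
assumptions hold in any particular real dataset.

## Problem sizes and determinism

Tests and the acceptance script run deliberately reduced problems: 2 × 15
individuals with 2 chains × (500+500) iterations for curve recovery, 500
null replicates at m = 2,000 for calibration, 500-gene networks, 50
bootstraps. Every generator and sampler takes an explicit seed; the
pipeline derives per-stage seeds from the global seed by a stable string
hash, and two runs with the same config are byte-identical (verified by
SHA-256 digests of all outputs).

## Known limitations

- The Gaussian likelihood is untruncated although performance is
  non-negative; anchors make the effect negligible near the limits but a
  truncated or Tobit likelihood would be more principled.
- The calibration check at 500 replicates has ~2–4% probability of landing
  outside [0.03, 0.07] by Monte-Carlo chance even for an exact test.
- The scale parameter a is weakly identified when no test temperature
  reaches T_opt (see above).
- Module detection targets planted-block structure at a few hundred to a
  few thousand genes; it is not a blockwise engine for 20,000+ genes.
- The soft-power fit on the default 3-equal-module fixture rarely reaches
  R² > 0.8 — equal-size planted blocks are not scale-free; the hub-weighted
  fixture used in the tests is.
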