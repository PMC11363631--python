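# Methods

`smoltpipe` links strain-diagnostic genetic variants to the probability of
smoltification in Atlantic salmon (*Salmo salar*). It covers four stages:
calling genotypes at an amplicon SNP panel from per-sample read counts,
building the pedigree relationship structure, fitting a Bayesian
threshold (liability) animal model of binary smoltification status with
DIC-based backward model selection and prediction curves, and the
comparative-Ct (2^−ΔΔCt) qPCR expression workflow. A synthetic-data
module generates studies with the same statistical structure so every
stage is testable without sequencing data.

## Genotype calling

Each panel SNP is biallelic, with an anadromous allele (A) common in
sea-migrating populations and a landlocked allele (L) common in
freshwater-resident populations. Calls are made per sample per locus from
read counts (n_A, n_L, n_other):

* total depth < 50 → NO_CALL (`LOW_DEPTH`);
* n_other/depth > 0.10 → NO_CALL (`THIRD_ALLELE`);
* otherwise, with f = n_A/(n_A+n_L): f > 0.90 → AA, f < 0.10 → LL,
  0.25 ≤ f ≤ 0.75 → AL, and the gaps (0.10, 0.25) ∪ (0.75, 0.90) →
  NO_CALL (`AMBIGUOUS_FREQ`).

Boundary conventions: the depth floor is inclusive ("at least 50"), the
homozygous rule strict ("more than 90%"), the heterozygous band closed
("within 25–75%"). The gap zone is deliberately reported as a distinct
no-call reason rather than silently assigned, since frequencies there
usually indicate contamination or paralogy. Homo/het frequencies are
computed over the two panel alleles only, with the third-allele guard
applied separately on total depth. All thresholds are configurable
(`CallingRules`); the defaults are the published values. Group allele
frequencies are freq_L = (2·n_LL + n_AL)/(2·n_called) over called
genotypes only; a group with no calls reports a missing frequency, never
zero.

The mpileup parser consumes samtools-style pileup text (the upstream
mapping is out of scope): `.`/`,` count as the reference base, ACGT as
alternates, read-start/end markers and indel spans are skipped, and `*`,
`<`, `>`, `N` count as "other" coverage. Counts are strand-collapsed and
coordinates 1-based.

## Relatedness

The additive relationship matrix A is computed by the tabular method and
its inverse directly by Henderson's rules, with inbreeding coefficients
(from the tabular diagonal) entering the Mendelian-sampling variances, so
A⁻¹ is exact for inbred pedigrees too. Unknown parents are treated as
unrelated, non-inbred founders. Matrices are dense — at the intended
scale (≈700 offspring plus parents) dense linear algebra is faster and
simpler than sparse machinery — with a sparse triplet export for
interoperability. Correctness is checked two ways: A against gene-drop
Monte-Carlo expected IBD on small pedigrees, and A·A⁻¹ = I to 1e-8 on
random 200-individual multi-generation pedigrees.

## Threshold liability model

Smoltification status Y_i ∈ {0,1} (visual score 1–5 binarized at ≥3) is
modelled as a probit-linked Bernoulli draw of a latent liability

    l_i = α + β_G·G_i + β_W·W_i + β_S·S_i
        + β_GW·G_i W_i + β_GS·G_i S_i + β_WS·W_i S_i + a_i + e_i,

with e_i ~ N(0,1) fixed (the scale that identifies a threshold model),
genotype G an unordered three-level factor with AA as reference (two
indicator columns; the three prediction curves are free of any additive
constraint — additive dose coding is available as an option), weight W in
grams (centered internally for conditioning; predictions are reported on
the raw 0–350 g axis), sex S ∈ {0,1}, and breeding values
a ~ N(0, A σ²_a) through the pedigree. Priors: scaled inverse-χ²(ν, s²)
on σ²_a with weakly-informative defaults ν = 1, s² = 1 (both
configurable — an acknowledged source of divergence from any particular
published fit, since such details are rarely printed), and N(0, 10⁸) on
fixed effects to keep conjugate updates proper while behaving near-flat.

### Gibbs sampler

Fitting uses the classic data-augmentation scheme: (i) liabilities from
truncated normals around the current linear predictor (inverse-CDF
sampling with an accurate tail fallback); (ii) fixed effects from their
conjugate normal update; (iii) breeding values from the mixed-model
update with precision ZᵀZ + A⁻¹/σ²_a; (iv) σ²_a from its scaled
inverse-χ² full conditional. The breeding-value draw is performed in the
basis of a one-off generalized eigendecomposition of (ZᵀZ, A⁻¹): with
VᵀA⁻¹V = I and VᵀZᵀZV = diag(w), the conditional precision is
diag(w + 1/σ²_a), so each sweep costs two dense mat-vecs (O(q²)) after an
O(q³) setup that is reused across all candidate fits in model selection.
In the eigenbasis the quadratic form aᵀA⁻¹a needed by the variance update
is simply the squared coordinate norm.

The sampler draws from four independent RNG streams (liabilities, fixed
effects, breeding values, variance), all derived from the single
configured seed. Identical seeds give identical chains; and because the
liability/breeding-value/variance streams consume the same deviates
regardless of the fixed-effect dimension, fits of nested model
specifications under one seed are coupled (common random numbers), which
turns DIC differences between candidate models into paired, low-variance
comparisons.

Production defaults are 4 chains × 60,000 iterations (10,000 burn-in,
thinning 25) with a convergence gate of split-R̂ < 1.05 and ESS > 200 per
fixed effect; a warning is emitted whenever any fixed effect's ESS falls
below 100. The test-suite and acceptance runs use single shorter chains
(≈1,100–12,000 iterations depending on the check) — sizes chosen so the
Monte-Carlo error is small relative to each check's tolerance.

Setting `ainv=None` drops the random effect and yields plain Bayesian
probit regression, which is validated against maximum-likelihood probit
estimates.

### DIC and backward selection

Model fit is scored by DIC = D̄ + pD with pD = D̄ − D(θ̄), using the
conditional-on-(β, a) Bernoulli deviance with the latent liabilities
integrated out through the link (computed with log-CDF forms that never
overflow). The alternative convention — the Gaussian deviance of the
augmented liabilities — is available behind a flag (`on_liability=True`)
but is unusable for model comparison because the liability scale itself
shifts between models.

Backward selection starts from the full six-term fixed-effect structure
and repeatedly refits all single-term deletions that respect marginality
(an interaction must be removed before its main effects; if an
interaction survives, both main effects stay by construction). The best
deletion is accepted unless the reduced model's DIC is worse than the
incumbent's by more than a parsimony margin, default 3 DIC units. The
margin reflects the standard reading that DIC differences of a few units
are not decisive; it matters here because with a strict improve-only rule
a truly null term is retained whenever its spurious deviance gain exceeds
twice its parameter count — probability P(χ²_df > 2·df) ≈ 0.16 (1 df) or
0.14 (2 df) — which caps exact recovery of a generating model near 55%
regardless of sample size. With margin m the per-term retention
probability falls to P(χ²_df > 2·df + m), about 2.5–5% at m = 3. Setting
`margin=0` recovers the strict rule. Ties are broken by dropping the
highest-order term first, then lexicographically, so the selection path
is reproducible. Every candidate fit (model, DIC, accepted flag, any fit
failure) is recorded in a trace table.

A caveat worth knowing: with an individual-level random effect the
conditional DIC is a weak discriminator of null *fixed* effects (the
breeding values can absorb most of what a dropped covariate explained, so
DIC differences for null terms are fractions of a unit per degree of
freedom); strong effects still move DIC by tens to hundreds of units and
are never lost. This is a property of conditional DIC in flexible
hierarchical models, not of the implementation.

Each panel SNP is fitted separately with the same specification and the
per-locus DIC table is emitted; no cross-locus multiplicity correction is
applied, but the table lets users add one.

### Prediction curves

Predicted probability of smoltification versus weight is computed per
genotype as the posterior mean over draws of Φ(x(g, w, s)ᵀβ), with the
breeding value marginalized at zero (the curve for an average-pedigree
fish) and a 95% band from the 2.5/97.5 posterior percentiles of Φ(η).
A genotype absent from the training data is refused rather than
extrapolated.

## qPCR relative expression

Technical triplicates are screened before averaging. The conventional
"2 standard deviations" phrasing cannot operate within a triplicate — no
point of a sample of three can lie more than 2/√3 sample SDs from its own
mean — so the screen is applied in leave-one-out form: a replicate is an
outlier when it deviates from the mean of its sibling replicates by more
than max(2·SD(siblings), 0.5 cycles). The absolute floor (configurable)
is a conventional qPCR replicate tolerance and prevents flagging
ultra-tight triplicates on sub-noise differences. One replicate may be
removed per pass with a single re-check; fewer than two survivors mark
the sample unusable for that gene.

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator
sample's ΔCt; RQ = 2^−ΔΔCt with amplification efficiency fixed at 2
(measured primer efficiencies can be stored but do not enter the headline
computation). The default calibrator is the sample with the lowest ΔCt
(the highest expresser, so RQ ∈ (0, 1] with the calibrator at exactly 1);
calibrating on the lowest raw target Ct, or on an explicit sample, is
available by flag, since raw-Ct calibration ignores the reference gene.

Two-group comparisons are normality-gated: if either group has fewer than
8 samples the two-sided Mann–Whitney U is used directly; otherwise both
groups face Shapiro–Wilk at α = 0.05 and only a double pass earns the
two-tailed t-test (Student's equal-variance by default — Welch behind a
flag). Tests run on the RQ scale by default with a ΔCt-scale option. The
strain×timepoint grid emits, per gene and tissue, the two between-strain
tests (one per timepoint, annotated with letters) and the two
between-timepoint tests (one per strain, annotated with a star when
significant); comparisons touching a missing cell are skipped and logged.

## Synthetic data generator

The generator emulates a two-generation common-garden cross design:
36 families by default — 6 pure wild, 6 pure farmed, and 24 hybrid
(F1 in both parental orientations, F2, and both backcrosses; F2 and
backcross families get their own F1 parents built from founder pairs) —
with 669 offspring spread as evenly as possible across families.
Founder alleles at the 17-SNP panel are Bernoulli draws from per-strain
L-allele frequencies (defaults loosely shaped like the study system:
landlocked near-fixed for L, farmed mostly A, wild intermediate with the
Ssa04 locus L-rich); offspring genotypes follow Mendelian gene drop.

Phenotypes are forward draws of the liability model. Weights are
log-normal with mean 100 g and CV 30% — chosen, in the absence of any
published weight distribution, to span the 0–350 g axis on which
predictions are reported. Sexes are Bernoulli(1/2). Breeding values use
the founder-draw + Mendelian-sampling recursion (within-family variance
σ²_a/2), exact for pedigrees without inbreeding loops and O(n); an exact
MVN path through the Cholesky factor of A is kept as a cross-check for
small pedigrees. Read counts use a negative-binomial depth law (mean 500,
size 5 — wide enough that both no-calls and confident calls occur) with
binomial allele sampling at error rate 0.005 and an independent binomial
third-allele overlay. Ct tables place a constant-baseline reference gene
and fold-change-shifted target genes on 2 strains × 2 timepoints with 10
fish per group, a shared per-sample effect (SD 0.3 cycles) and
per-replicate technical noise (SD 0.15 cycles).

All five generator operations draw from independent streams spawned from
the single mandatory seed; identical seeds give byte-identical outputs.

What the generator does *not* emulate: genotyping batch effects, linkage
between panel SNPs, family-by-environment interaction, ordinal smolt
scores between the extremes (scores are emitted as 1 or 5), sex-linked
inheritance, or primer-efficiency differences between qPCR assays.
Passing tests therefore demonstrate the correctness of the algorithms
under the model's own assumptions, not robustness to these real-data
complications.

## Study conditions used in tests and the acceptance script

Parameter-recovery checks simulate n = 2,000 offspring in 50 families
with σ²_a = 0.5, β_W = 0.02 g⁻¹, genotype effects (AL, LL) =
(−0.4, −0.8) and α = −2 (which centers the liability at the 100 g mean
weight, giving balanced prevalence); the causal-locus frequency is set to
0.5 so all three genotypes are common. Coverage uses 50 replicates at
n = 1,000; selection recovery generates from the fixed effects {G, W}
alone (σ²_a = 0) at n = 1,500 and 20 replicates while still fitting the
full animal model. The acceptance script runs the same computations at
or slightly below these sizes and writes every quantity it measures.

## Numerical choices and degenerate inputs

* Φ and its inverse via `scipy.special.ndtr/ndtri/log_ndtr`; deviances
  never produce ±∞ even for saturated fits.
* Truncated-normal draws switch to `truncnorm.ppf` on the same uniforms
  when the interval mass underflows (|η| beyond ≈ 7.5), keeping RNG
  stream consumption fixed.
* σ²_a is floored at 1e-12 in the precision update; a non-finite state
  aborts the fit with a diagnostic rather than propagating NaNs.
* A singular fixed-effect precision (e.g. a constant column) raises
  immediately; a locus with fewer than two observed genotype classes is
  rejected as inestimable.
* Backward selection pre-filters to records complete under the *full*
  model so every candidate sees identical data and DICs are comparable.
* Zero-information groups (no called genotypes, empty expression cells)
  propagate as missing values or skipped comparisons, never as zeros.

## Known limitations

* Conditional DIC's weak penalty on null terms (above) means model
  selection leans on the parsimony margin; users wanting the strict rule
  can set `margin=0` and should expect occasional spurious interactions.
* σ²_a mixes slowly in threshold models (individual-level effects are
  only weakly separated from the unit residual); production-length
  chains or multiple chains are advisable for variance inference.
* The per-locus fits are marginal one-SNP models; no joint multi-locus
  modelling or multiplicity correction is built in.
* The ΔΔCt workflow assumes 100% amplification efficiency and a stable
  reference gene; both assumptions should be verified upstream.
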