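# Methods

## Data model and transformations

All analyses consume a `PairedDataset`: an RNA and a DNA pathway-per-species
table (features × samples), a species table (taxa × samples), a feature→taxon
map, and per-sample metadata (subject id, group label, optional covariates).
Abundances are non-negative; zeros encode dropout (non-observation), not
measured absence.

RNA and DNA are analysed as counts-per-million — each sample column rescaled
to 10⁶ — optionally log2-transformed after adding a pseudocount (default 1).
Taxa are compositional and are analysed as raw proportions, logits, or
centered log-ratios. The CLR of sample *j* uses only that sample's strictly
positive taxa: `clr_ij = ln x_ij − mean_i' ln x_i'j` over positive *i′*;
zero taxa become missing entries, and a logit at p ∈ {0, 1} is likewise
missing rather than ±∞. The CLR uses the natural log; downstream
correlations and regressions are invariant to the base up to coefficient
scaling.

Per feature, only samples with strictly positive untransformed RNA, DNA
*and* taxon abundance enter the model (the all-positive filter), and a
feature is tested only with ≥ 10 retained observations in both groups
(configurable). CLR zero-removal is per sample, which composes cleanly with
this filter: entries the filter would drop are the ones the CLR marks
missing.

## Partial-correlation diagnostics

For each feature, the partial correlation of RNA with one factor given the
other is the Pearson correlation of the two OLS residual vectors after
regressing the controlling factor (plus intercept) out of both. For a
single control this equals the closed form
`(r_xy − r_xz r_zy)/√((1−r_xz²)(1−r_zy²))`; the residual formulation
matches how the quantity is visualised (residual vs residual) and extends
to multiple controls. Features with fewer than 4 retained samples, or with
residual variance indistinguishable from rounding noise (relative
tolerance 1e-15), are skipped and counted. The screen tallies r into
(−1, −0.3], (−0.3, 0.3), [0.3, 1); the 0.3 cutpoint is configurable.

## Differential models

Three fixed-effect structures are compared throughout: intercept + DNA +
Taxa + group (+ covariates), and the two single-control versions. The group
label is coded 0/1 with the lexicographically first level as reference;
binary covariates are coded 0/1, continuous covariates pass through
unscaled.

**Mixed model.** For longitudinal designs each model optionally carries a
per-subject random intercept: y = Xβ + Zu + ε with u ~ N(0, σ_u² I),
ε ~ N(0, σ_e² I). Estimation profiles the restricted likelihood over the
variance ratio λ = σ_u²/σ_e²; per-subject blocks use the closed form
(I + λJ)⁻¹ = I − λ/(1 + n_s λ) J, so every likelihood evaluation is O(n).
The profile is scanned on {0} ∪ logspace(−4, 3, 29) and refined by bounded
scalar minimization (tolerance 1e-8); the boundary λ = 0 is kept whenever it
is within 1e-8 log-likelihood units of the best interior point, so designs
with no subject replication degenerate exactly to OLS. A fit is flagged
non-convergent when the residual variance collapses below 1e-12 (constant
response); such features fall back to the fixed-only model rather than
being dropped, keeping the BH family intact.

**Model selection.** Per feature, fixed-only vs mixed is compared by a
likelihood-ratio statistic on full-ML log-likelihoods (both profiled at
their own ML optima), floored at 0, with an asymptotic 1-df chi-squared
p-value. ML (not REML) likelihoods are used because the two models differ
in their random-effect structure only, and the asymptotic chi-squared
reference is an ML construction; the conservativeness of the 1-df reference
at the boundary (the true null mixture ½χ₀² + ½χ₁²) is accepted. The LRT
p-values are BH-adjusted across features; the mixed model is used where
that FDR is strictly below 0.05 (a tie at exactly 0.05 stays fixed-only).
Final mixed fits use REML, under which the Satterthwaite construction below
is defined.

**Satterthwaite degrees of freedom.** For a coefficient with sampling
variance v(θ) = [(X'V(θ)⁻¹X)⁻¹]_cc, θ = (σ_u², σ_e²),
df = 2v²/Var(v), where Var(v) = g'Ag with g the numeric gradient of v at
the REML estimate (central differences, one-sided at the σ_u² = 0 boundary)
and A the inverse negative numeric Hessian of the restricted log-likelihood
(relative step 1e-4). When the subject variance sits on the boundary or the
curvature is singular, df falls back to the residual df n − p with a flag.
The test suite cross-checks the fit on identical data against R's lmerTest
(variance components, fixed effects, standard errors, Satterthwaite df and
REML log-likelihood, agreeing to ~4 decimals) and against statsmodels
MixedLM.

**Multiple testing.** BH step-up: sort p ascending,
q_(i) = min_{j≥i} p_(j)·m/j clipped at 1, returned in input order. Power at
nominal FDR α counts truly-DE features with q < α over *all* truly-DE
features (features removed by filtering count as missed); realized FDR is
the null fraction among discoveries, defined as 0 when there are none.

**FDR–sensitivity AUC.** Features are ranked by p ascending (ties broken by
feature id; raw p rather than q, because BH is monotone in p and p breaks
the granularity ties BH introduces). For every cutoff depth d the realized
FDR(d) and sensitivity(d) are computed; the curve
S(x) = max{sensitivity(d) : FDR(d) ≤ x} (0 where no depth qualifies) is
integrated exactly over [0, 1] as a staircase. A perfect ranking gives 1.

## Synthetic paired-omics generator

The generator emulates the statistical structure of a paired shotgun
cohort, per sample j (subject s) and feature f on taxon i(f):

- taxon log abundance b_i + e_ij, b_i ~ N(0, 1), e_ij ~ N(0, 1) (natural
  log), columns closed to the library-size total;
- log2 DNA_fj = log2 taxa_i(f),j + copy_f + m_fj, copy_f ~ N(0, 0.5),
  measurement noise m_fj ~ N(0, 0.8) (log2);
- log2 RNA_fj = a_f + β_dna·log2 DNA_fj + β_taxa·clr_i(f),j + u_s + ε_fj,
  a_f ~ N(0, 3), u_s ~ N(0, σ_subject²), ε ~ N(0, σ_noise²);
- independent Bernoulli dropout zeros in all three tables (abundance-
  independent — downstream filtering removes zeros, so only the zero
  pattern matters); columns rescaled to CPM-like totals.

Defaults: 50 subjects × 2 timepoints, 20 taxa, 200 features, β_dna = 1,
β_taxa = 0.5, σ_subject = 0.5, σ_noise = 0.5, dropout 0.1, library 10⁶.

Two constants deserve comment. The DNA measurement noise (0.8 log2 units)
is what makes taxon abundance informative about RNA *beyond observed DNA*:
with near-noiseless DNA the taxon-linked RNA component is almost collinear
with DNA across samples and, being shared across features, is removed by
CPM normalization, so no partial-correlation signal survives. Substantial
DNA noise is also the realistic regime for sparse pathway-level shotgun
quantification. With it, β_taxa dials the RNA–taxa partial correlation
given DNA from ≈ 0.07 (β_taxa = 0) to ≈ 0.3–0.5 (β_taxa = 0.8),
monotonically. The feature-intercept spread (3 log2 units) reproduces the
several-orders-of-magnitude abundance skew of real pathway tables; it is
what makes the lowest injection bins genuinely weak signals (near-zero
log2 values exist only if low-abundance features exist).

What the generator does *not* emulate: read-level sampling noise,
abundance-dependent dropout, taxon-taxon interaction structure beyond
shared composition, batch effects, and non-Gaussian residuals. Passing
benchmarks therefore demonstrate correctness of the estimators and the
direction of the confounding effects, not performance guarantees on any
real cohort.

**Null assignment.** Group labels are independent Bernoulli(½) per sample;
a per-subject option assigns one draw per subject for strictly
between-subject phenotypes. The sample-level version is the default
reading of random assignment in a longitudinal table; both are exposed.

**Spike scenarios.** All modes mark round(0.1·F) random features as DE and
multiply their RNA by exp(c·j) in a per-feature random target group, with
strength j ∈ (0, 1] and c = 4·ln 2 (so j = 1 is a 4 log2-fold change,
spanning a realistic effect ladder). Additionally:

- *taxon-confounded*: a 50% random subset of taxa is multiplied by the same
  factor in one group. The shift is propagated through the generative
  equation: affected taxa's features gain DNA (×factor) and RNA
  (×factor^β_dna), and *every* feature's RNA responds to the CLR change of
  its taxon (×exp(β_taxa·Δclr), with Δclr computed exactly from the taxa
  tables before/after). Without the RNA-side propagation the DNA-controlling
  models would be spuriously misspecified; with it, the taxa-only model is
  the one that loses false-positive control — through its attenuated,
  renormalization-distorted taxa slope — which is the phenomenon the
  benchmark exists to show.
- *depth-confounded*: one group's RNA and DNA column totals are multiplied
  by (1 + j), a minimal sequencing-depth confound (removed again by CPM at
  analysis, by design).
- *feature-group*: DE status is assigned to whole contiguous blocks of
  features (default 20 blocks) until the 10% quota is met.

A known behavior worth stating: strong one-group spikes change that group's
column totals, and CPM renormalization then shifts *all* features in those
samples; because the RNA and DNA totals shift unequally, a per-sample
offset remains that is indistinguishable from a group effect within any
single feature's regression. Realized FDR of every model therefore rises
with spike strength in the scenario benchmark. This is a property of
compositional data, not of an estimator; the global-null benchmark (no
spikes) shows nominal FDR control, and the between-model orderings are
unaffected.

## Binned signal injection

The injection study works on the analysis scale (log2(CPM+1) RNA/DNA; taxa
raw, CLR-transformed at model time — positivity filtering is unchanged
because log2(x+1) > 0 iff x > 0). After a null group assignment, features
are screened by partial correlation (|r| > 0.3 under either controlling
direction); all positive RNA values across the matrix are sorted and split
into 10 equal-count bins (remainder to the lowest bins), so bin k's minimum
is never below bin k−1's maximum. Equal-count bins are the only splitting
rule that guarantees non-empty bins for arbitrary value distributions. For
each selected feature one group is chosen at random and every retained
sample in it receives an independent draw (with replacement) from bin k
added to its RNA value; a per-feature single-draw option exists. Draws use
one seeded stream in feature-id order, so results are independent of
iteration order. Library sizes are not recalibrated; the per-sample
relative change is available as a diagnostic. Non-selected features form
the null set; with the default generator the screen selects essentially
all features (the RNA–DNA|taxa direction is very strong), so the injection
benchmark is primarily a power/ladder instrument.

## Reproducibility split

Subjects are randomly halved (all of a subject's samples stay together;
odd counts differ by one), the chosen model runs in each half, and the
top-n lists (ranked by p, ties by FDR then feature id) are intersected for
each n in the grid. Under independent null rankings the expected overlap is
≈ n²/F for F features.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use cohorts of 24–100 samples
and 24–200 features, 10–20 benchmark replicates, 200 REML-recovery
replicates and 300 coverage features — sizes at which every check runs in
seconds to a few minutes on one CPU while keeping the binomial noise of
rate estimates within the asserted bands. Confidence-interval calibration
is evaluated on regression-scale simulations (the model's own sampling
assumptions, with taxa confounded with the group) because that is the
regime in which 95% coverage is the mathematically correct expectation;
generator-scale data adds pseudocount and renormalization distortions that
are properties of the data, not of the interval construction. Numerical
tolerances: design matrices are rejected when rank-deficient; BH and
partial correlations match independent oracles to 1e-10 or exactly;
optimizer and finite-difference steps are stated above.
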