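# Methods

## Synthetic cohorts

The generator draws per-probe methylation on the M scale (logit₂ of the beta
value) and maps back through beta = 2^M / (1 + 2^M). For probe j and sample i,

    M_ji = b_j + Σ_c λ_cj x_ci + batch_j(site_i) + δ_j · case_i + ε_ji,
    ε ~ N(0, noise_sd²),

additive effects on the logit scale keep beta inside [0, 1] while leaving the
working model (a linear regression on beta or M) approximately correct.

Defaults emulate a two-site case–control study: sites Berlin (112 cases / 136
controls) and Bonn (73 / 63), a desk-scale 20,000-probe array with 300 true
DMPs (full 632,997-probe runs are supported but optional), per-probe baselines
N(0, 1.5²) on the M scale, observation noise SD 0.5. The case effect is ±0.5
M-units per true DMP (random sign unless fixed); near beta = 0.5 that is a
beta-scale difference of roughly 0.08, inside the range of coefficients such
studies report, and large enough that a replication-powered design should
recover most of it — the calibration tests quantify exactly how much.

Covariates: age (years, N(34, 11²) clipped to 18–75), sex (~42% male),
smoking (~8%), and a 6-component blood cell-fraction simplex drawn from a
Dirichlet whose concentration mimics granulocyte-dominated whole blood. Each
covariate contributes through per-probe loadings drawn N(0, effect²), so some
probes are strongly confounded and most are barely touched. Site batch is an
additive M shift (+0.3 by default) on a random 20% of probes per site, giving
surrogate-variable estimation something real to find. Symptom severity
(Y-BOCS-like, cases only) is base 22 + 2.0 × standardized true-DMP burden +
N(0, 5²), so severity is genuinely downstream of the methylation signal;
cases at the first site carry a post-treatment score with a mean change of −8
(SD 5) and a ~50% medication rate.

What the generator does **not** emulate: probe type I/II chemistry bias,
genetic (mQTL) structure, spatial correlation along the genome, non-Gaussian
outliers, and missing values. Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not robustness to every
artifact of real array data.

## Per-probe association model

OLS of beta on status + age + sex + smoking + (k−1) cell fractions +
surrogate variables, fitted for all probes at once via a shared design
matrix; the status coefficient, its standard error, and a two-sided t test
with n − p degrees of freedom are reported. Regression is on the beta scale
by default (an M-scale option exists behind a flag). Constant probes are kept
with coefficient 0 and p = 1 and flagged, so probe indices stay aligned
across cohorts. p-values are floored at the smallest positive double so they
remain in (0, 1].

The 10% low-variability filter uses the standard deviation of beta across all
pooled samples; ties at the cutoff break by probe-id lexicographic order.

Surrogate variables are a simplified independent-surrogate-variable scheme:
each probe is regressed on status plus the known covariates, and the
surrogate components are independent components (FastICA; PCA selectable) of
the samples × probes residual matrix. Components are mean-zero and mutually
uncorrelated; the count (default 5 in the pipeline) is a configuration
parameter because no principled default exists without the real data.

Multiple-testing adjustment supports BH (default), Holm, Bonferroni and a
Storey q variant. The Storey q is π̂₀ × BH floored element-wise at the raw p
so that adjusted ≥ raw holds uniformly across methods — a deliberate
tightening of the textbook estimator to keep one monotonicity contract for
all four methods. The replication threshold method is a config field because
all three classical corrections are defensible at that stage.

## Two-stage selection and its FDR

Thresholds are inclusive (≤). Stage-2 adjustment is computed over the
discovery-pass probes only: replication tests only those hypotheses.
Direction consistency requires sign(coef₁)·sign(coef₂) > 0; an exactly zero
coefficient counts as discordant, since no reproducible direction exists.

The FDR estimator needs several conventions the formula alone does not fix:

- d₁ is the smallest discovery p above α₁; d₂ is the smallest stage-2
  **adjusted** p above c₂, matching the stage-2 decision rule (the decision
  statistic at stage 2 is the adjusted value). When no value lies above a
  threshold, d falls back to the threshold itself and the result is flagged.
- The doubly-null term is estimated by re-running both stages on case/control
  labels permuted within site (preserving the two-site structure under the
  null) and pooling hits over permutations. Surrogate variables are
  re-estimated per permutation by default (configurable off for speed, since
  SV re-estimation dominates the cost).
- FDR₁ is not pinned down by the two-stage formula; it is taken as the
  Storey-style stage-1 estimate π̂₀₁ · d₁ / P̂(p₁ ≤ d₁), symmetric with the
  stage-2 use of the Storey true-null proportion.
- π̂₀₂ is the Storey estimate (λ = 0.5) on the raw stage-2 p-values of the
  tested (discovery-pass) set.
- An empty stage-2 rejection set defines FDR = 0 with an explicit flag.

At modest probe counts the estimator is conservative: d₂ sits visibly above
c₂ when adjusted p-values are sparse near the threshold, inflating the
second term. The spacing shrinks as the probe count grows.

## Methylation profile scores

MPS_i = Σ_j β_j m_ji with raw (unstandardized) beta values, exactly linear in
the weights; a standardized variant exists behind a flag. Weights always come
from the discovery cohort — for the threshold-scan scores, the two-step
score, and the module scores alike — because that is the only leakage-free
choice when the replication cohort is the test set. The scan reports both
in-sample and out-of-sample AU-ROC but selects **only** on out-of-sample
values, ties broken toward fewer CpGs (parsimony). AU-ROC uses midranks, so
ties count one half, identical to O(n²) pair counting.

The default threshold list is 0.05, 0.01, 1e-4, 1e-5, 1e-10, 1e-20, 1e-30,
1e-40; any descending list is accepted. Thresholds selecting zero probes
produce a flagged row rather than an error.

## Co-methylation network

Unsigned adjacency |cor|^β (the unsigned form is the common default and
nothing in the design requires a signed network). Soft power: smallest
β ∈ 1..20 whose sign-corrected scale-free fit R² reaches 0.85, else the
argmax. TOM uses the standard shared-neighbor formula; 1 − TOM feeds
average-linkage clustering.

Module detection is a simplified single-height cut rather than the dynamic
hybrid tree cut: candidate heights are midpoints of the largest gaps between
consecutive merge distances, tried largest-gap first, and a multi-module cut
is accepted only when mean between-module minus mean within-module
dissimilarity exceeds a margin (0.05); otherwise the probes form one module.
Branches below `min_module_size` (default 30) are reported as `unassigned`,
always kept separate from real modules. Labels are computed in canonical
probe-id order, so they are invariant to input row and sample order.

Module eigenvectors are the first principal component of the probe-wise
standardized module submatrix, unit variance, sign aligned with the module's
mean methylation profile. Module–trait correlations are Pearson with
pairwise-complete observations (severity is missing for controls by design);
zero-variance cells return NaN with an `undefined` flag.

## Clinical correlates

Severity correlation is Pearson among cases with non-missing values.
The treatment-response model regresses the pre-to-post severity change
(negative = improvement, enforced at record construction) on baseline
severity, the baseline × MPS interaction, age, sex, medication. Continuous
predictors are standardized before the interaction is formed, which
decorrelates the product term from its parents. The default model also
includes the MPS main effect (hierarchical principle); a flag fits the
reduced model without it. The median split assigns ties to the low group,
requires ≥ 8 records per group, and fits `delta ~ baseline + mps + age + sex
+ medication` per group.

## Problem sizes in the test and acceptance runs

Calibration and recovery use 20 replicates at 20,000 probes / 300 true DMPs
with known covariates only (the simulation plants no confounding beyond
them, so surrogate variables are unnecessary there); null calibration uses a
single 50,000-probe cohort; the permutation-FDR self-consistency check uses
4,000-probe cohorts with 20 permutations; module recovery uses 120-probe
two-block designs. These sizes make the whole suite run in well under a
minute each while keeping every binomial/Poisson acceptance band meaningful.

## Known limitations

- The FDR estimator's conservatism at small probe counts (d₂ spacing) is
  inherent to the plug-in construction, not a bug; interpret estimates at
  desk scale as upper bounds.
- The simplified tree cut recovers well-separated modules; gradual module
  boundaries (where the dynamic hybrid algorithm shines) will land in
  `unassigned` more often.
- The ICA-based surrogate variables use a fixed random seed for
  reproducibility; different seeds can rotate near-degenerate components.
- Severity in the simulator couples to the *beta-scale* DMP burden; other
  coupling choices (M-scale, probe-weighted) would be equally defensible.
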