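# Methods

## Threshold model

Each physician's collapsed recommendations t ∈ {No < Unsure < Yes} on
cases with known risk r follow a proportional-odds model with cumulative
logits `logit P(t ≥ j | r) = α_j + β·r` for j ∈ {Unsure, Yes}. The model
assumes a single slope β for both cutpoints (proportional odds), responses
conditionally independent across cases given r, and risk as the only
covariate. The treatment threshold is defined behaviourally: the risk at
which P(Yes | r) = P(No | r). With P(No) = 1 − P(t ≥ Unsure) and
P(Yes) = P(t ≥ Yes) this has the closed form r\* = −(α_U + α_Y)/(2β),
which the test suite verifies against a bisection root of
P(Yes | r) − P(No | r) to 1e-9.

**Sign conventions.** The internal parameterization is P(t ≥ j). Standard
fitters often model P(t ≤ j) = F(c_j − βx); their cutpoints relate by
α_j = −c_j with the same β. Applying the threshold formula to unconverted
cutpoints silently negates the threshold, so the suite carries an explicit
conversion test against an independent cumulative-link fitter.

## Likelihood maximization

The likelihood is maximized in-package by BFGS on (α_U, γ, β) with
α_Y = α_U − exp(γ), which enforces the cutpoint ordering without
constraints. Analytic gradients; gradient-norm tolerance 1e-8; starts from
the empirical cumulative-proportion logits with slope 0 plus two
data-scaled slope starts, adding up to three jittered restarts on
non-convergence. Standard errors come from the numerically differentiated
observed information in the natural (α_U, α_Y, β) chart. Category
probabilities are floored at 1e-300 inside the log only (no parameter
clipping).

**Separation.** When the three categories occupy disjoint, ordered risk
ranges (either direction), or |β| exceeds 1e4 per unit risk, the MLE
diverges. Every point in the empirical gap between the largest sub-Yes
risk and the smallest Yes risk is then a maximum-likelihood balance point;
the estimator reports the gap midpoint with method `separation_midpoint`.
Such estimates carry a concordance index but no Nagelkerke R² — the
likelihood is degenerate at separation, so a pseudo-R² would be
uninformatively close to 1.

**Routing.** The dispatcher collapses the 7-point scale and routes:
no Yes → `never_treat` (threshold = (max risk + 1)/2); no No →
`always_treat` (threshold = min risk / 2, the mirror of the never-treat
rule, adopted because always-treat physicians demonstrably exist in the
left tail of the threshold distribution); only Unsure → `undefined`
(no imputation — these responses say nothing about the balance point);
No and Yes only → binary logistic (threshold −α/β, consistent with the
ordinal definition in the empty-Unsure limit); otherwise the ordinal fit.
Fits with β ≤ 0 are returned with a warning rather than an error: they
flag response sets inconsistent with risk-driven decision making, which is
a data-quality signal worth surfacing.

The fit accepts risks on any affine scale (the likelihood is
reparameterization-equivariant, so thresholds transform accordingly —
fitting on percent-scale risks returns 100× the proportion-scale
threshold); the (0, 1) range check is enforced at the I/O boundary and in
the simulators.

## Diagnostics

Nagelkerke R² = R²_CS / (1 − exp(2·ℓ₀/n)) with
R²_CS = 1 − exp(2(ℓ₀ − ℓ̂)/n), where ℓ₀ is the intercept-only
log-likelihood (closed form from category proportions). The concordance
index is computed over all case pairs with different collapsed categories:
the fraction in which the higher category has strictly higher risk, ties
counting ½; it equals ROC AUC for two categories and is undefined
(reported absent) with a single category.

## Synthetic-data generators

**Cases.** Continuous risk factors are drawn independently from normal
distributions truncated to eligibility bounds by rejection resampling
(clipping would pile mass on the bounds), with a 10,000-attempt cap per
value before an explicit failure naming the factor. Binary factors are
Bernoulli. The shipped example config is illustrative of an elevated-eye-
pressure cohort — means such as IOP 25 ± 3 mmHg truncated to [24, 32],
CCT 573 ± 38 µm — but is not any trial's published statistics. Factor
correlations are deliberately not modelled, and gender is carried but
unused by the risk model. The example risk model (logistic link; its
intercept chosen once so the simulated risk distribution is right-skewed
with mean ≈ 0.14, matching the approximately log-normal shape such
cohorts show) is likewise illustrative: real analyses must supply the
coefficients of a published, validated calculator via config. Both link
families (logistic and `1 − S0^exp(lp)` survival form) are supported
because published calculators use either.

**Physicians.** Each simulated physician has a latent threshold r\* drawn
from a beta distribution (default shapes 2.56 and 9.14, a right-skewed
population with mean ≈ 0.22 as observed among glaucoma specialists), a
discrimination β uniform on a configured range, and 7-level cutpoints
κ_j = −β·r\* + s_j with default offsets s = (3, 1.5, 0.5, −0.5, −1.5, −3).
The constraint s₃ = −s₆ makes the collapsed-scale balance point equal r\*
exactly (−(κ₃ + κ₆)/(2β) = r\*), so estimator recovery is testable against
known truth. Real response data never reveals this generative structure —
the symmetric spacing is a modelling choice, and the simulators do not
emulate fatigue, ordering effects, hedging asymmetries, or
between-physician correlation. Passing recovery tests therefore
demonstrates correctness of the estimator under the proportional-odds
assumption, not that human physicians satisfy it.

## Population analysis

Physicians reporting a pure intraocular-pressure treatment rule are
excluded (their recommendations are not functions of overall risk);
always- and never-treat flags are recorded but do not exclude, since the
degenerate rules still yield interpretable assigned thresholds. The
population beta fit uses maximum likelihood with both shape parameters
free and the support fixed to (0, 1); thresholds exactly on the boundary
are nudged inward by 1e-6 with a warning (the likelihood is unbounded
there). Standard errors come from the analytic observed information
(trigamma matrix). Assigned degenerate thresholds are included in the fit
by default, mirroring how reported population histograms include them; the
caller can exclude them for sensitivity analysis by filtering on the
method tag. Histograms default to bin width 0.05 on [0, 1], fine enough to
resolve a 10–20% modal interval.

## Pipeline and problem sizes

The pipeline expands one global seed into per-stage substreams
(`numpy.random.SeedSequence`), writes every artifact as CSV/JSON with
fixed numeric formatting, and records seeds, config hashes and artifact
hashes in a manifest; reruns are byte-identical. Validation problem sizes
were chosen to keep each check statistically decisive at interactive cost:
50,000 draws for beta-shape recovery (3-standard-error windows ≈ ±0.05
and ±0.17), 100 replicates × 500 cases for threshold recovery (mean
absolute error ≤ 0.02), and a 200-physician × 200-case end-to-end
recovery. The end-to-end check rates cases with risks uniform on
(0.005, 0.995): a risk range spanning the threshold population's support
keeps regression noise — not assigned degenerate thresholds — the dominant
error source, which is the property under test.

## Known limitations

- The proportional-odds assumption (one β across both cutpoints) is not
  tested against the data; a physician whose Unsure band widens with risk
  violates it.
- Thresholds for never/always-treat physicians are assignments, not
  estimates; their values depend on the case set shown.
- Each physician is fitted separately; no partial pooling, so per-physician
  estimates at small case counts are noisy and the refitted population
  beta absorbs that noise.
- The concordance index treats the three collapsed levels as exact; the
  information discarded by collapsing from 7 levels is not recovered.
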