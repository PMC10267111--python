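# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Data model

A cohort is a participant-by-variable table of three types:

* **ordinal** — rating-scale items scored 0–4 (24-item depression scale);
* **binary** — yes/no indicators (current suicidal ideation SI, plan SP,
  attempt SA), treated throughout as 2-category ordinals;
* **continuous** — positive biomarkers of the HPA axis (ACTH, cortisol).

All discrete variables are modelled as thresholded latent standard normals.
This latent-Gaussian (copula) assumption is what licenses polychoric and
polyserial correlations, and it is exactly the mechanism the synthetic
generator uses, which makes end-to-end parameter recovery a well-posed
test rather than an approximation check.

Inclusion follows the severity rule of the emulated protocol: a row is
analysed when its 24-item total is at least 8. Item 3 of the scale
(suicidal ideation) is excluded from the *network* because it duplicates
the SI indicator, but it still counts toward the inclusion total. The
default network therefore has 28 nodes in three communities: depression
(23 items), suicidality (SI, SP, SA) and biomarkers (ACTH, Cort).
Analysis is complete-case: rows missing any analysis variable are dropped
with a logged count, because row-resampling procedures downstream are
incompatible with multiply-imputed data.

## Correlation stage

Two-step estimators: thresholds are fixed at inverse-normal-CDF values of
the cumulative marginal proportions, then the latent correlation maximises
the bivariate-normal likelihood by bounded scalar optimisation on
(−0.999, 0.999) with tolerance 1e−6 on ρ. Bivariate-normal rectangle
probabilities are computed from an Owen's-T closed form of the bivariate
CDF (machine precision, verified against quadrature in the tests); cell
probabilities are floored at 1e−12 inside logs. Estimates that land at the
optimiser bound — typical of tables dominated by empty cells — are
returned flagged rather than rejected. Two-step (not joint) ML is the
reference-ecosystem default and is statistically adequate at cohort-scale
n; it is also what keeps ~400-pair matrices fast enough to re-estimate
hundreds of times inside bootstrap loops.

Continuous variables enter Pearson/polyserial estimation untransformed by
default. Because the default biomarkers are lognormal, their pairwise
estimates are attenuated relative to the latent correlation; a
`continuous_transform="rank"` switch applies a normal-scores
(nonparanormal) transform that removes the attenuation. The default stays
"none" because the emulated protocol is silent on the point; the tests
demonstrate both behaviours.

Pairwise estimates are assembled into a full matrix and repaired to
positive-semidefinite by eigenvalue clipping at 1e−6 with rescaling to
unit diagonal (a no-op on matrices that are already PSD).

## Network estimation

The graphical lasso (off-diagonal L1 penalty only) is solved by
scikit-learn's coordinate-descent/LARS core — dispatched by penalty regime,
warm-started along the path — over 100 logarithmically spaced penalties
from λ_max (the largest absolute off-diagonal of S, at which the graph is
provably empty) down to λ_max/100. Penalties at or above λ_max use the
exact closed-form diagonal solution. Duality-gap tolerance defaults to
1e−4.

Model selection minimises the EBIC with γ = 0.5 (the field's default; the
emulated protocol does not state it) and n equal to the number of rows used
for correlation estimation. Two scoring modes exist:

* **refit** (default) — each candidate support is scored by the EBIC of its
  support-constrained maximum likelihood, computed by iterative
  proportional fitting (edge-wise 2×2 marginal adjustments with Woodbury
  updates, warm-started from the lasso fit; parameter tolerance 1e−7). The
  returned network is that constrained MLE, i.e. a relaxed estimate whose
  edge weights carry no lasso shrinkage. This is the criterion's original
  formulation for graphical models, and it is what makes support recovery
  sharp (the penalised-likelihood shortcut tends to admit several tiny
  spurious edges because shrinkage of true edges is charged to sparser
  models) and bootstrap CIs approximately unbiased.
* **penalized** — the common shortcut in psychometric-network software:
  score the penalised fit's own likelihood and return its partial
  correlations.

EBIC ties are broken toward the larger penalty (sparser model). Path
points whose fit is not positive-definite are skipped; estimation fails
only if the whole path fails.

## Centrality and paths

Expected influence is one-step (signed sum of direct edge weights): the
emulated protocol's parenthetical definition describes a single summation.
Its wording ("in absolute value") actually describes strength, so both are
always computed and reported side by side. Bridge expected influence sums
a node's edges into other communities; community labels are supplied, not
detected. Shortest-path measures use the conventional distance transform
d = 1/|w|; tied shortest paths receive equal fractional credit, which
removes tie-order nondeterminism; disconnected pairs contribute nothing.
Focal-node predictive betweenness counts, for each other node, the
(fractionally credited) shortest paths between the focal node (default
ACTH) and every remaining node that pass through it. Centrality tables
carry raw values plus z-scores; betweenness and predictive betweenness are
validated against exhaustive path enumeration on small graphs.

## Resampling procedures

All procedures spawn per-replicate child seeds up front, so results are
reproducible bit-for-bit and independent of execution order. Replicates
whose estimation fails are excluded and counted, never imputed.

* **Nonparametric bootstrap** (default B = 1000): rows resampled with
  replacement; the full pipeline re-run per replicate; 2.5/97.5% quantile
  CIs per edge; an edge-pair difference is "significant" when the quantile
  interval of the difference excludes zero.
* **Case-dropping bootstrap**: drop proportions 0.05–0.75 in steps of
  0.05 (the grid is capped at 0.75, the emulated protocol's reported
  maximum); per proportion, subsets drawn without replacement and the
  Pearson correlation between subset and full-sample centrality recorded.
  The CS-coefficient is the largest tested proportion at which that
  correlation is ≥ 0.7 with probability ≥ 0.95 (the ecosystem's standard
  convention; the emulated protocol reports the statistic without defining
  it). Proportions leaving n ≤ p rows are skipped with a warning.
* **Predictive-betweenness bootstrap**: the focal-anchored counts across
  replicates, summarised by median and 2.5/97.5% quantiles.

## Network comparison

The permutation test pools both groups' rows, permutes labels preserving
group sizes, and re-estimates both networks per permutation. Statistics:
M = max over edges of |w₁ − w₂| (structure invariance) and S = |global
strength difference|. p-values use the add-one estimator
(1 + #{null ≥ observed})/(1 + P), which cannot return zero. Per-edge tests
are restricted to edges present in at least one observed network and
Holm-adjusted. Note the naming follows the reference test's convention —
M for edges, S for strength — and field names in the result object are
explicit (`observed_max_edge_diff`, `observed_strength_diff`) so the two
cannot be silently swapped.

## Synthetic cohorts

`make_ground_truth` draws a sparse precision matrix: random off-diagonal
support at a requested density, uniform weights in ±[0.15, 0.35], plus
designated fixed and bridge edges; positive-definiteness is enforced by
doubling a diagonal shift from 1e−3 until the smallest eigenvalue exceeds
1e−6 (support and signs are preserved; magnitudes shrink). The default
study truth has 29 variables (24 + 3 + 2), 15% within-community density,
a fully connected suicidality triad (SA–SP strongest), a strong ACTH–Cort
edge, strong insomnia and anxiety item pairs, and bridge edges placing
cortisol (to SA and to the retardation item), ACTH (to somatic symptoms)
and SI (to hopelessness) as bridge nodes; item 3 is tied to SI (partial
0.45) to reproduce the redundancy that motivates its exclusion.

`generate_cohort` samples the latent Gaussian from the implied correlation
matrix and maps each node to its observed scale. Defaults emulate the
study conditions: n = 898; ordinal cut points at cumulative probabilities
(.55, .83, .95, .99), giving right-skewed item distributions and a mean
24-item total near the mid-teens; binary thresholds set from target
prevalences 31.2/30.4/30.62%; biomarkers exp(μ + σZ) with (μ, σ) =
(3.2, 0.8) for ACTH and (2.6, 0.65) for cortisol, matching published
means with standard deviations near the mean (strong right skew — the
distributional form is an assumption, not an inference about any real
sample); and an independent binary "gender" label (59% the larger group),
so subgroup comparisons on default cohorts are true nulls.

Not emulated: item-content semantics, missing data, longitudinal
structure, genuine gender differences, and any non-Gaussian dependence
beyond the marginal transforms. Passing tests therefore certify the
statistical machinery under the latent-Gaussian mechanism, not robustness
to violations of it.

## Problem sizes used in the shipped checks

The test suite and the acceptance script scale resampling down to
desk-scale sizes as the package's own defaults for routine verification:
marginal-recovery checks at n = 50 000; polychoric/polyserial recovery at
n = 20 000; structure recovery on a 10-node chain at n = 2 000 over 20
seeds; bootstrap coverage with B = 50; the permutation-test calibration
with 100 repetitions of 200 permutations at n = 500 per group with a short
penalty path; and the full-protocol run at n = 898 with B = 30 bootstrap
replicates, 10 case-dropping subsamples per proportion, 50 permutations, a
12-point penalty path and a relaxed solver tolerance (1e−3, 50 iterations —
selection-grade accuracy, since edge weights come from the constrained
refit, not the penalised fit). Full-scale analyses (B = 1000, 1000 permutations) use the
same code paths via `StudyConfig`.

## Known limitations

* Pairwise two-step polychorics are not a joint MLE; the PSD repair can
  perturb entries when pairwise estimates are far from jointly consistent.
* EBIC n is the row count (no pairwise-n correction for the mixed matrix).
* Bootstrap CIs describe the sampling variability of the (relaxed) EBIC
  estimator, including model-selection variability; they are quantile, not
  bias-corrected, intervals.
* The CS-coefficient's own confidence interval is not a standard quantity
  and is not computed; the per-proportion correlation samples are exposed
  so users can summarise them as they see fit.
* The permutation comparison tests exchangeability of rows between groups;
  with grossly unequal group variances its per-edge tests inherit the
  usual caveats of resampling tests.
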