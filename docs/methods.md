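# Methods

This note documents the models, defaults and numerical choices behind
`pdopharm`, and what the synthetic-data tests do and do not establish
about real screens.

## Viability normalization

Plates carry test wells, 0.2% DMSO negative controls and 1 µM bortezomib
positive controls. The default normalization is two-anchor:

    viability% = 100 · (S − S̄_pos) / (S̄_neg − S̄_pos)

so the negative-control mean maps to 100% and the positive-control mean
to 0%. Values outside [0, 100] are preserved (they carry information for
the curve fit). A one-anchor alternative (`neg_only`,
`100 · S / S̄_neg`) is selectable in `RunConfig.normalization`, because
assays differ in whether the cytotoxic control defines the zero point;
the two-anchor form is the default since the screen explicitly carries a
positive control. A plate whose negative-control mean does not exceed
the positive-control mean is rejected as degenerate. Normalization is
invariant to rescaling all raw signals by a positive constant
(luminescence gain), which is property-tested.

## Dose–response model and IC50

Curves follow the four-parameter logistic (4PL)

    y(c) = bottom + (top − bottom) / (1 + (c / EC50)^h)

with viability in percent and concentration in molar. Fitting is
least-squares over all replicate wells (residual-level pooling — fitting
to per-dose means would discard the replicate error structure).
Initialization scans a coarse grid over log10(EC50) (30 points spanning
the tested range ± 1.5 decades) × hill ∈ {0.5, 1, 1.5, 2, 3, 4}; at each
grid point, top and bottom are profiled out by 2-parameter linear least
squares, since the 4PL is linear in its asymptotes given (EC50, h). The
grid winner seeds a Nelder–Mead refinement (derivative-free; ≤ 400
iterations, `xatol` 1e-8). If refinement fails to improve on the grid,
the grid-best parameters are kept and the fit is flagged. Fits whose
dynamic range (top − bottom) is under 10 viability points are also
flagged as degenerate (a flat line constrains neither EC50 nor hill);
flagged curves are still reported, and exclusion is left to downstream
choices. A test asserts that the fitter's residual sum of squares never
exceeds a dense brute-force profile grid's on random noisy instances.

The IC50 is the *absolute* 50%-viability crossing of the fitted curve —
not the relative-to-asymptote EC50 — because the screen defines
sensitivity as the concentration inhibiting half of the cells. When the
fitted curve stays above 50% across the tested range the IC50 is
censored to the highest tested concentration (`at_max`); when it stays
below, to the lowest (`at_min`). Censor statuses partition outcomes and
interior IC50s are clipped strictly inside the range.

## Tertile calls and the bound rule

Per drug, lines are ranked by IC50 ascending; ranks below ⌈n/3⌉ are
sensitive, below ⌈2n/3⌉ moderate, the rest resistant. Ceiling cutoffs
make the split deterministic for any n (76 lines → 26/25/25). Tied IC50
values all inherit the label of the lowest-ranked member of the tie —
the direction is arbitrary; what matters is determinism, and it is
logged as a convention. Because the split is rank-based, calls are
invariant under any strictly monotone transform of IC50.

When more than a tertile of the cohort is censored `at_max`, ranking is
uninformative inside the censored mass: all censored lines are called
resistant and the remainder is split into two equal-rank halves
(sensitive / moderate), and symmetrically for `at_min`. The "split into
two groups" step is underdetermined in prose descriptions of this rule;
equal-rank halves with a ⌈m/2⌉ lower block is our reading, flagged as an
interpretation. If both censored fractions exceed the tertile fraction
the drug's cohort is contradictory and an explicit ambiguity error is
raised rather than guessing.

Treatment-level rollup: a regimen is predicted effective iff it contains
at least one sensitive-called drug. Moderate calls do not count by
default (`moderate_counts_as_good` enables the alternative). The
continuous treatment score — (#sensitive + 0.5·#moderate) / #called —
exists to give the AUC a ranking variable; regimen drugs without calls
(e.g. liver-activated prodrugs the platform cannot evaluate) are
ignored, and a regimen with no called drug is excluded as untestable
with a logged count.

## Combination additivity

With a partner fixed at its IC30 the additive expectation under
Bliss-style independence is `predicted(c) = single-agent viability(c) ×
0.70`. The excess score is the mean of (predicted − observed) over the
dose grid: positive = stronger than additive. No Loewe/Chou–Talalay
indices are attempted; the comparison is deliberately the simple
fixed-dose product.

## Expression signature

Counts are normalized to log2(CPM + 1); CPM removes library-size
differences and the +1 keeps zeros finite. Differential expression
between pan-sensitive and pan-resistant lines (those sensitive,
respectively resistant, to all six microtubule drugs) uses a Welch
two-sample t on log2 expression with Benjamini–Hochberg q-values. This
is a deliberate, documented deviation from count-model (negative
binomial) DE machinery: it is self-contained, exactly testable, and the
screen's thresholds (q ≤ 0.01, |log2FC| ≥ 1) are applied unchanged. The
FC filter is two-sided because the signature contains both directions.

Surviving genes are Spearman-correlated (tie-corrected average ranks)
against the per-line **median log10 IC50 across the six drugs**; the
aggregation across drugs is a design choice (`aggregate="per_drug"`
averages six per-drug correlations instead). A gene enters the signature
iff |ρ| > 0.3 and the sign opposes its DE direction — a gene up in
sensitive lines must anticorrelate with IC50. Output invariants
(all three thresholds) are asserted on the emitted set, not assumed.

Clustering restricted to signature genes uses average-linkage
agglomeration on 1 − Pearson correlation between line profiles, cut at
k = 2; the cluster with the higher signed mean signature expression
(up-genes minus down-genes) is the sensitive-like class. The classifier
is a linear max-margin model (hinge loss + L2) trained by full-batch
subgradient descent with the 1/(λt) step schedule, zero initialization
and fixed epoch count — fully deterministic — on features standardized
with training-set mean/sd. Missing signature genes at prediction time
are imputed at the training mean (zero after standardization). Agreement
with a reference linear SVM on separated classes is tested.

## Survival and concordance

Kaplan–Meier curves and the two-group log-rank test are computed via
lifelines; tests pin them to hand-computed product-limit tables and
observed-minus-expected arithmetic on small mixed-censoring toys.

Concordance takes the **treatment** (one regimen round) as the unit of
analysis, matching how response records are kept; patient-level
clustering of repeated treatments is a known limitation. Outcomes map
CR/PR/SD → good, PD → poor; unknown outcomes are excluded listwise with
logged counts. The 2×2 table yields accuracy, sensitivity and
specificity; AUC is the rank-based area using the continuous treatment
score (an essentially binary predictor has no meaningful ROC, so the
score supplies the ranking — a documented choice rather than a claim
about any particular external dataset). CIs are percentile bootstrap
over treatment resamples (default B = 1000, 95%); interval endpoints are
exact order statistics of the resampled metric (`method="lower"` /
`"higher"` quantiles), so the reported interval is always realizable and
conservative. Pearson's chi-square is used without continuity
correction. Metrics undefined on the data (empty margin, single outcome
class) are reported as missing with warnings, never silently zeroed.

Small genomic-concordance arithmetic: `preservation_fraction` is the
percent set overlap relative to the parent tumor;
`signature_similarity` between mutational-signature contribution vectors
is cosine similarity (the metric is otherwise unspecified in common
usage; cosine is scale-free and bounded in [0, 1] for non-negative
vectors).

## Synthetic-data generators

The generators emulate the study conditions, not the biology:

* **Screen.** 7-point threefold series from 20 µM, triplicate wells,
  DMSO/bortezomib controls; per PDO × drug a true 4PL with top ~
  N(100, 3), bottom ~ U(0, 10), hill ~ U(0.8, 2.5), and log10 EC50 =
  drug potency (U(−7.3, −4.7)) + per-line sensitivity shift (N(0, 0.3))
  + a shared microtubule latent factor (weight 1 on the six microtubule
  drugs, which is what makes their responses co-vary) + residual
  N(0, 0.4). Noise is multiplicative lognormal with unit mean,
  CV-parameterized (default 10% — the assay's reproducibility is
  reported only qualitatively, so the noise level is a package choice
  exposed in `RunConfig.noise_cv`). Censoring arises naturally from
  EC50s beyond the tested range.
* **Expression.** Gamma–Poisson counts (dispersion 0.05 by default);
  library-size factors span exactly 2-fold by construction. Half the
  lines are planted sensitive; planted six-drug IC50s give the groups a
  10-fold separation with within-group spread (one decade per group) so
  per-drug tertile rankings are stable. Signature genes (half up, half
  down in sensitive lines) shift by `effect_log2fc` (default 2, i.e.
  4-fold) and are planted at detectable expression (log2 baseline ≥ 4):
  below ~16 mean counts Poisson shot noise swamps any fold change, and
  real response signatures come from robustly expressed genes.
* **Clinic.** Each treatment first receives a call profile (sampled
  regimen of 1–3 called drugs), then an outcome: good with probability
  0.71 given ≥ 1 sensitive drug; PD with probability 0.93 given no
  sensitive or moderate drug. Treatments whose best call is moderate sit
  between these regimes; their good-response probability is an explicit
  parameter, default 0.5. Convergence tests compare evaluated metrics to
  the analytic mixture implied by the generator's own parameters.
* **Survival.** Exponential event times with a group hazard ratio
  (default 3) and independent exponential censoring whose rate is solved
  from the target censored fraction (default 20%).

What passing these tests shows: the estimators recover planted structure
at the stated noise levels, the tests are calibrated under their nulls,
and the full pipeline is byte-deterministic for a fixed seed. What they
do not show: robustness to plate-position effects, batch effects in
expression, non-4PL dose–response shapes (e.g. biphasic), informative
censoring, or patient-level correlation of treatments — none of which
the generators emulate.

## Problem sizes and defaults

The default pipeline run simulates 20 lines on the 49-drug panel
(980 curve fits), 2000 genes × 20 lines for expression, 200 subjects per
survival arm and 300 treatments — sizes chosen so a full run completes
in about a minute while leaving every stage's statistics
well-determined; all are keyword-adjustable. All thresholds live in
`RunConfig` with the screen's standard values (tertile fraction 1/3,
DE FDR 0.01, FC 2, ρ 0.3, B = 1000, CI 95%, partner viability 0.70).
Every stage seed derives deterministically from `RunConfig.seed`.

## Known limitations

* The 4PL fit is unweighted least squares; heteroscedastic viability
  noise is handled only through replicate pooling.
* The bound-rule "two groups" split and the Spearman aggregation across
  the six drugs are interpretations (flagged above) with switchable
  alternatives.
* Drugs requiring in vivo activation (prodrugs), anti-angiogenics and
  hormonal modulators cannot be evaluated ex vivo; they are flagged
  untestable rather than predicted.
* Treatment-level bootstrap ignores within-patient correlation across
  rounds.
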