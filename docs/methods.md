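# Methods

`emrisk` implements an EMR-sequence risk-prediction pipeline for short-term
onset of alcohol and substance use disorder (ASUD) in patients diagnosed
with post-traumatic stress disorder (PTSD), together with a
perturbation-based *relative contribution* (RC) analysis that ranks clinical
and social-determinants-of-health (SDoH) features as risk (RC > 1) or
protective (RC < 1). Because the EMR data such studies draw on sit behind
data-use agreements, the package also ships a synthetic-population generator
with a known outcome mechanism; every statistical claim the test suite makes
is a claim about recovery of quantities that the generator planted.

## Cohort definition

A patient enters the cohort when they carry a PTSD diagnosis (ICD-9/10
codes 309.81, F43.10, F43.11, F43.12 by default; configurable). The **index
date** is the latest encounter strictly after the first PTSD diagnosis and
strictly before the first ASUD diagnosis, mimicking the patient's latest
pre-outcome status. A **case** has an ASUD record within the 90 days after
the index date; a **control** does not. Patients are excluded when PTSD and
ASUD are first coded on the same day, when ASUD precedes PTSD, or when any
ASUD record falls in the year before the index date.

Calendar conventions are fixed-day windows chosen for reproducibility:
"3 months" is the half-open interval (index, index + 90 d]; "1 year" is the
closed interval [index − 365 d, index]. A patient whose first ASUD falls
more than 90 days after the latest eligible encounter is a control by this
literal definition even though ASUD occurs later; the audit log records the
reason (`asud_after_window`) so such patients can be found.

Model inputs are the events of the 1-year lookback, packed per encounter:
diagnosis codes truncated to their 3-character ICD category (the same rule
is applied to ICD-9 codes, e.g. 309.81 → 309, since no GEM crosswalk is
shipped), medication codes taken verbatim, and laboratory results kept only
when flagged ABNORMAL/HIGH/LOW **and** belonging to a test whose abnormal
results occur at least `min_lab_frequency` times dataset-wide (default 100,
counted after the flag filter; the threshold is exclusive — exactly 100
occurrences is retained). Token multiplicity within a visit is preserved
because feature contributions later sum over occurrences. Records outside
the EMR observation span are treated as absent disease.

## SDoH encoding

Individual-level covariates (age at index in 10-year bands, sex, race) and
neighborhood-level indices (zip-keyed continuous values such as a
neighborhood socio-economic index, racial segregation, aridity, urbanicity,
transportation barriers) are all encoded as categorical tokens so that the
sequence models can embed them exactly like diagnosis codes. Continuous
indices are discretized into empirical quartile bins fitted on the zip
table (linear-interpolation quantiles; right-closed bins, so a value on an
edge falls in the lower bin; a constant index collapses to one bin with a
warning). The binning is a design choice of this package — how continuous
SDoH indices enter a token model is genuinely open — and the fitted edges
are persisted as JSON so inference reuses the training discretization.
Derivation of the indices themselves from census microdata is out of scope;
the zip table is a trusted input.

## Classifiers

Three recurrent architectures share one contract: token embeddings are
summed per visit (sum pooling preserves multiplicity), visits feed a
recurrent stack, and a logistic head reads out P(case).

* `rnn` — stacked tanh recurrence.
* `time_aware` — the same recurrence with the carried state decayed by
  `exp(-gap_days / time_decay_days)` before each step (default decay scale
  90 days), so long gaps between visits discount the memory.
* `retain_style` — reverse-time two-level attention: two recurrent nets run
  over the visit sequence in reverse; one yields a per-visit scalar
  attention (softmax over visits), the other per-dimension tanh gates; the
  attention-weighted, gated visit embeddings are pooled into a context
  vector. Named architectures of this kind are specified in the literature
  without full equations; we implement the canonical forms and do not claim
  numeric parity with any particular implementation.
* `logistic_baseline` — L2-regularized logistic regression on bag-of-tokens
  binary indicators (scikit-learn).

The networks run on a compact reverse-mode autodiff engine over NumPy
arrays (defined at the top of `models.py`) with an Adam optimizer; its
gradients are checked against finite differences in the test suite.
Structural defaults follow the reference configuration: embedding 128,
hidden 128, dropout 0.2, 8 stacked recurrent layers ("number of layers" is
read as stacked recurrent layers), vocabulary cap 30 000, early-stopping
patience 3 (training stops after 3 consecutive epochs without validation
AUROC improvement; the best-validation-epoch weights are restored).
Optimizer settings the reference configuration does not state are
conventional defaults: Adam, learning rate 1e-3, batch size 64, at most 50
epochs, classification threshold 0.5. The padding/unknown embedding row is
pinned to zero — this is what makes occlusion (below) remove exactly one
occurrence's signal. Everything is seeded end to end; identical config and
seed reproduce identical weights and trajectories.

`repeat_runs` repeats the split/train/evaluate cycle (re-splitting 8:1:1
and/or re-seeding) and reports per-run validation/test AUROC, precision,
recall and F1 with across-run mean and sample standard deviation, mirroring
the runs × metrics layout used for such studies. The default is 5 runs;
the run count is configurable (the source study describes both five-column
tables and ten repetitions).

## Relative contribution

For a trained model and patient, the contribution of one token occurrence
is the occlusion delta `P(case | original) − P(case | occurrence masked to
the padding id)`; the **feature contribution** (FC) is the sum of deltas
over the feature's occurrences within that patient, and 0 if absent.
Occlusion is the minimal deterministic reading of "perturbation-based"
attribution. Each patient's FC vector is then **normalized** by the sum of
absolute FCs over all of that patient's features, which removes dependence
on healthcare-utilization volume; the absolute-value denominator keeps the
normalizer positive while preserving signs (the natural-language definition
is ambiguous under negative contributions). Normalization is per patient
because utilization heterogeneity — its stated rationale — is a per-patient
phenomenon.

For each feature, with m cases and n controls (all labeled patients of the
group, zeros included):

    RC        = mean(FC | case) / mean(FC | control)
    Var(lnRC) = (sd_case/mean_case)²/m + (sd_control/mean_control)²/n
    95% CI    = exp(ln RC ± 1.96 · √Var(lnRC))
    p         = 2·(1 − Φ(|ln RC| / √Var(lnRC)))          (two-sided z-test)

with sample (n−1) standard deviations. Two-sided tests are used because
both risk and protective features are of interest. Bonferroni and
Benjamini–Hochberg FDR corrections are applied across tested features
(via statsmodels). Finally all RCs and CI bounds are multiplied by
1/RC(reference) so the reference feature — conventionally the
cohort-defining PTSD diagnosis group F43, present in nearly every record —
has scaled RC exactly 1; the common factor preserves all between-feature
ratios, and p-values are scale-free.

The ratio is only meaningful when the two group means share a sign: masking
a protective feature *raises* predicted risk, so protective features have
negative means in both groups and a positive ratio below 1. Features whose
group means have opposite signs (or a zero mean, or a single-patient group)
are flagged *indeterminate*, excluded from inference, and listed separately.
By default the report is computed on the union of validation and test
patients (configurable to the full cohort); which split published RC tables
use is generally unstated, and the held-out union avoids training-set
optimism while retaining sample size. A companion per-feature mean ± sd
summary of normalized FC is available for descriptive reporting of SDoH
features.

## Synthetic populations

The generator emulates the structure of a longitudinal EMR cohort:

* visits as a homogeneous Poisson process (default 8 visits/patient/year
  over 4 observed years — a plausible utilization rate for a chronic
  psychiatric cohort);
* an initial PTSD diagnosis uniform in the first half of the observation
  span, re-coded at later visits with probability 0.25 per visit (chronic
  conditions are recoded in real EMRs; this keeps the F43 reference feature
  frequent in lookback windows);
* per-visit random multisets of diagnosis (3-character ICD-like), medication
  and lab tokens (desk-scale vocabularies of 60/40/25 so that planted
  signals are recoverable at a few thousand patients), lab flags drawn
  ABNORMAL/HIGH/LOW/NORMAL with probabilities 0.30/0.20/0.15/0.35 to
  exercise the abnormality filter;
* one zip per patient from a 40-zip table whose index values are drawn from
  fixed normal distributions;
* an outcome drawn per post-diagnosis encounter window as a Bernoulli with
  logit = `baseline_logit` + Σ planted log-odds of the tokens present in
  the trailing 365 days (static SDoH tokens always count as present). On
  success the ASUD onset is placed uniformly within the next 90 days and
  recorded as a diagnosis event.

The default `baseline_logit = −3.5` yields a roughly balanced case/control
cohort (close to the near-1:1 balance reported for the real PTSD→ASUD
cohort this design emulates). All randomness flows from one root seed split
into independent sub-streams; identical config + seed reproduces the
population byte for byte. The ground truth records each patient's outcome
date, final-window linear predictor, and a per-window log of planted-token
presence, which lets tests fit the *generating* model directly (per-window
logistic regression) as an independent check.

What the generator deliberately does **not** emulate: realistic ICD/drug
ontologies and co-occurrence structure, coding errors, informative
missingness, drift over calendar time, or correlation between utilization
and demographics. Passing tests therefore demonstrate that the pipeline's
statistics recover planted generative structure — not that any particular
clinical finding would replicate on real EMR data.

One structural feature worth knowing about: because conversion is drawn per
encounter window, patients with more encounters are more likely to ever
convert, so even with no planted effects cases have slightly denser
histories than controls ("utilization bias", AUROC of the raw visit count
≈ 0.55–0.6 under the null). Real cohort studies show the same phenomenon,
and the per-patient FC normalization exists precisely to keep it out of the
RC statistic; classifier AUROC on null cohorts sits slightly above 0.5 on
average for this reason while remaining within the chance band.

## Problem sizes used by the checks

The acceptance checks run the full pipeline at desk scale, chosen as the
smallest sizes at which the estimators' behaviour is unambiguous:
parameter-recovery and null-control conditions use 3 000 patients per
replicate (20 replicates in tests, 10 in the acceptance script), with
contributions computed over the full cohort for recovery (the consistency
check benefits from all information) and over the held-out union for the
null. The discrimination comparison between the recurrent model and the
logistic baseline uses 6 000 patients per replicate: the generative model
is logistic on token indicators, so the baseline is Bayes-optimal there,
and the recurrent net needs more data than the baseline to approach it.
Recurrent models in these checks use a reduced desk configuration
(embedding 16, hidden 32, 1 layer, ≤ 40 epochs) rather than the 128/128/8
reference configuration, and `min_lab_frequency=50` rather than 100 to suit
the smaller event tables; all such deviations are per-call overrides, never
changed defaults.

## Known limitations

* Medication tokens are generic code strings; no name→ID dictionary
  (e.g. DrugBank) is shipped, so medication grouping fidelity on real data
  depends on the caller's preprocessing.
* The delta-method CI is a large-sample approximation; its empirical
  coverage at true RC = 1 is verified to sit in 93–97% at group sizes of
  100, but it degrades for features carried by very few patients.
* Indeterminate features (opposite-sign group means) are reported, not
  tested; a sign-agnostic effect measure is out of scope.
* Exact numeric parity with GPU-framework implementations of the named
  recurrent architectures is a non-goal; the architectures here are the
  canonical forms on a NumPy autodiff.
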