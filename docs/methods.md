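# Methods

## Problem and scope

`ccekit` implements a two-stage analysis of hospitalization expenditure for
a disease group of interest (by default diseases of the genitourinary
system, ICD-10 N00–N99, in patients aged 65 and over):

1. **Expenditure accounting.** Institution-level financial totals are
   apportioned onto individual admissions under the System of Health
   Accounts 2011 (SHA2011) convention, producing per-patient curative care
   expenditure (CCE) that can be aggregated along any dimension (disease
   chapter, GBD cause group, institution type, age band, care setting).
2. **Factor analysis.** Per-admission hospitalization expenditure is
   regressed on eight encounter factors with a small multilayer
   perceptron, and the trained network's connection weights are converted
   into factor importances with Garson's algorithm, averaged over random
   restarts.

The original provincial discharge database behind this design is not
publicly deposited, so the package ships a synthetic-data generator with
known ground truth; all statistical claims in the test suite are about the
pipeline's behaviour under that generator, not about any province's actual
figures (the worked-example tables in the README are fixed published
numbers used only to exercise the reporting arithmetic).

## Accounting model

For one institution, let `a_i` be the billed curative income of sampled
admission `i`, `a = Σ a_i`, and `a_p` the part of `a` billed on admissions
flagged as preventive services. With yearbook totals `ST_INC` (curative
income), `ST_ALL` (basic expenditure allowance) and `S_P_ALL`
(preventive-service allowance):

    share_i            = a_i / (a − a_p)                (0 for preventive records)
    income_i           = ST_INC · (1 − a_p/a) · share_i
    allowance_i        = (ST_ALL − S_P_ALL) · share_i
    CCE_i              = income_i + allowance_i

Design points:

* **Preventive share of `ST_INC`.** The yearbook does not split its income
  total into curative and preventive parts, so the preventive share is
  estimated by the sampled fraction `a_p/a`. This is the unique choice
  consistent with the sharing-coefficient denominator, and it is isolated
  in one place (`allocate_income`).
* **Degenerate institutions** (no sampled non-preventive income, or no
  sampled records at all) cannot be apportioned; their net allowance is
  returned in an explicit `unallocated` frame instead of being dropped.
* **Conservation.** Per institution, allocated income sums to
  `ST_INC·(1−a_p/a)` and allowance to `ST_ALL−S_P_ALL`; the suite checks
  this to 1e−6 RMB at 100 000 records.
* All arithmetic runs at float64 precision; rounding to two decimals
  happens only when tables are serialized.

## Regression model

* Inputs: the eight factors — length of stay, institution type, insurance
  type, surgery (yes/no), gender, institution level, age, admission
  season. Only inpatient admissions enter the model (outpatient visits
  have no stay and a different cost process).
* Outcome: natural log of per-admission curative income (cost data are
  strongly right-skewed; a `raw` option exists for ablation).
* Architecture: one hidden layer of 5 tanh units, linear output,
  squared-error loss with L2 penalty (default `alpha = 1e−4`), L-BFGS
  optimizer, at most 1500 iterations. The fit is scikit-learn's
  `MLPRegressor`; this package owns encoding, scaling, splitting, weight
  extraction and evaluation.
* Split protocol: shuffled 90/10 train/test, 5-fold cross-validation
  folds inside the training set. Standardization statistics (mean and
  sample SD per column) are computed on training rows only and applied
  unchanged to test rows.
* Encoding: for the *sensitivity* pipeline categorical factors are
  integer-coded with a fixed, documented level order ("ordinal"), giving
  exactly one input per factor. One-hot encoding is available and is the
  better choice for pure prediction, but it is unsuitable for
  connection-weight importance: summing Garson importances over a factor's
  k dummy columns systematically inflates many-level factors, because each
  dummy column retains initialization-scale weight mass regardless of its
  predictive value. We verified this directly — under one-hot encoding the
  summed importance of a 6-level nuisance factor exceeds that of a
  dominant continuous driver — so the importance analysis uses the
  8-input coding (which also matches how published per-variable
  sensitivity tables with exactly one row per factor must have been
  produced).

## Garson sensitivity analysis

For input `i`, hidden unit `h`, input→hidden weights `W` and
hidden→output weights `v`:

    Q_i ∝ Σ_h ( |W_ih| / Σ_k |W_kh| ) · |v_h|,   normalized so Σ_i Q_i = 1.

Biases are excluded (classical formulation); hidden units with all-zero
input weights are skipped; an all-zero network raises an error rather than
returning a vector. With a single hidden unit the formula reduces to
`|W_i| / Σ_k |W_k|`, independent of `v` — asserted as a test invariant,
along with scale invariance `garson(cW, cv) = garson(W, v)` and exact
agreement with an independent loop transcription of the formula.

A single fit's importances are noisy functions of the random weight
initialization. The pipeline therefore averages importances over `R`
independently re-initialized fits (seeds `base_seed … base_seed+R−1`) and
tabulates the running mean at increasing checkpoints (default 100 / 500 /
1000 / 2000). Convergence is declared when the element-wise drift between
consecutive checkpoints falls below 0.01, the order at which published
restart-averaged indices stabilize in their third decimal. Individual fit
failures are logged and skipped; more than 10% failures abort.

## Synthetic-data generator

What it emulates: a provincial one-year discharge census (default
1 377 681 admissions over 252 institutions of six types, matching the
scale of the motivating study), with a genitourinary ≥65 inpatient cohort
preset of 5 993 admissions. For inpatient records,

    log(income) = 9.0 + Σ_f β_f · z(x_f) [+ γ · z(los)·z(inst_type)] + N(0, σ)

where `z(x_f)` is the standardized factor (categoricals through fixed
ordinal scores) and `β_f` the configured standardized effect. Defaults:
`β(length_of_stay)=0.8`, then institution type 0.2, insurance type 0.15,
surgery 0.12, gender 0.11, institution level 0.10, admission season 0.03,
age 0.02 — a dominance ordering of stay > institution type > insurance
type with the remaining factors small; residual σ = 0.5 on the log scale
(incomes right-skewed, roughly a factor-e spread); intercept exp(9.0) ≈
8 100 RMB per hospitalization, outpatient intercept exp(5.7) ≈ 300 RMB.
The optional interaction `γ` exercises non-additive structure. Ledgers
set `ST_INC` to 1.25× the sampled income (the non-sampled remainder),
`ST_ALL = 0.12·ST_INC`, `S_P_ALL = 0.2·ST_ALL`.

What it does **not** emulate: real admission-date seasonality beyond the
season label, within-patient readmission correlation, survey weights of a
multistage cluster design, heteroscedastic billing noise, or miscoded
ICD-10 entries. Passing parameter-recovery tests therefore shows the
pipeline recovers a known dominance structure from data with the assumed
log-linear skeleton — not that any particular real-world ranking is
correct.

## Reproducibility experiments and problem sizes

`ccekit.experiments` fixes the canonical experiment sizes (chosen once as
a balance between Monte-Carlo error and a single-CPU run of the suite):

* **Conservation:** 100 000 records, 252 institutions, preventive
  fraction 3%.
* **Cohort fit quality:** n = 5993, defaults (max_iter 1500).
* **Dominant-factor recovery:** 100 independent cohorts of n = 6000;
  per cohort, importances averaged over 16 restarts with an L-BFGS
  iteration cap of 500 (the loss converges on the dominant structure well
  before the cap; restart averaging, not longer optimization, is the
  pipeline's noise control). Success = length of stay ranked first; the
  suite requires ≥95/100.
* **Restart convergence:** one cohort of n = 2000, checkpoints
  100/500/1000 restarts from a single seed stream, drift threshold 0.01.
* **Determinism:** the full simulate → account → report → sensitivity
  pipeline at 60 000 records run twice, every CSV compared byte-wise.

## Numerical and edge-case policy

* z-scoring uses the sample (n−1) SD; constant columns are dropped with a
  warning, never silently kept.
* Importance ranking breaks ties lexicographically by factor name.
* Unassigned ICD-10 codes in the gaps between chapter blocks fall to the
  preceding chapter, keeping the chapter map total; codes outside every
  GBD mapping range report `other_unclassified`, never an exception.
* Age bands are 0–14 / 15–64 / ≥65 with 65 inclusive in the top band.
* Empty genitourinary subsets yield an empty table plus a warning.

## Known limitations

* The generator's conditional log-normality is an assumption, not a fact
  about any real billing system; effect sizes are standardized and
  additive by default.
* Garson importances measure weight topology, not causal contribution;
  even under the ordinal coding they attenuate a dominant factor's true
  share of explained variance (a factor with ~85% of signal variance
  receives an importance near 0.26 against a 1/8 = 0.125 baseline).
* Per-institution apportionment assumes yearbook totals and the sampled
  records describe the same activity mix; a per-stratum variant is out of
  scope.
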