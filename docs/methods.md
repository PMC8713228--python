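# Methods

## The model

`clnmscore` implements a discriminant over categorical clinical risk
factors for predicting central-compartment (level VI) lymph node
metastasis (CLNM) in papillary thyroid cancer (PTC). The training data are
aggregated: a class-conditional frequency table giving, for each of six
risk factors — sex, age, tumor diameter, capsular invasion, multifocality,
tumor location (17 categories in total) — the number of metastatic (+) and
non-metastatic (−) patients per category, with class totals N₊ = 197 and
N₋ = 215 in the bundled retrospective distribution (412 PTC cases).

Conditional frequencies are the maximum-likelihood estimates
P(X_kj | Y_g) = n_kjg / N_g, where k indexes the factor, j its category
and g ∈ {+, −} the class. Each (factor, category, class) cell receives a
score

    s_kjg = (log10 P(X_kj | Y_g) + 1) × 10,

so P = 1 maps to 10 points, P = 0.1 to 0, and P < 0.1 goes negative. A
patient's class total is the sum of their six per-category scores,

    S_g = Σ_k s_{k, j(k), g},

and the predicted class is the one with the larger total. Because
S_g = 10 (lg P_g + 6) is an affine transform of the class log-likelihood
lg P_g = Σ_k log10 P(X_kj | Y_g), the rule is a prior-free
maximum-likelihood decision — a categorical naive Bayes with uniform class
priors. The factor-independence assumption is implicit in the product form
and is not tested against patient-level data (none are available in
aggregated form).

## Numerical conventions

**Display rounding.** Scores are printed at one decimal with ties rounded
away from zero. Every cell of the bundled published score table is
reproduced by this convention from the bundled frequency table (34 cells,
zero mismatches), so the alternative half-even convention was never needed.

**Summation precision.** `score_patient` defaults to `precision="display"`:
each per-category score is rounded to one decimal before summation. This is
the arithmetic a clinician performs with the printed table and the only
convention consistent with the published worked example — the example
patient's negative-class total is 30.2 when rounded cells are summed, while
full-precision summation gives 30.125, which displays as 30.1.
`precision="full"` sums the unrounded cells; in that mode the decision is
exactly the log-likelihood comparison, and the equivalence is verified on
all 320 enumerable profiles. The two modes can disagree only within ±0.05
points per factor of the decision boundary.

**Tie policy.** An exact tie S₊ = S₋ predicts *positive* by default — the
clinically conservative choice, since a missed metastasis is costlier than
an unnecessary dissection — and the result is flagged `tie_broken`. The
policy is configurable.

**Binning.** Tumor-diameter intervals are half-open with closed lower
edges: [0, 0.7), [0.7, 1.0), [1.0, 1.5), [1.5, 2.0), [2.0, ∞) cm, so every
diameter maps to exactly one category (1.6 cm falls in 1.5–2.0 cm, as the
worked example requires; exactly 0.7 cm falls in 0.7–1.0 cm). Age splits
at [0, 45) vs [45, ∞) years. Tumor location is a four-level vocabulary
(upper/middle/lower pole, isthmus); how a tumor spanning two thirds of the
gland should be assigned is not defined by the source material, so callers
must supply one of the four labels.

**Zero counts.** A zero cell makes the log undefined; fitting raises an
error naming the cell unless an additive smoothing constant α is supplied,
in which case P = (n + α)/(N_g + α·C_k) with C_k the factor's category
count. The bundled table has no zeros. As α → 0 on a strictly positive
table, smoothed scores converge to the unsmoothed fit (tested).

**Class priors.** The published rule carries no prior term; optionally,
`prior=p` adds 10·log10(p) and 10·log10(1−p) to the class totals, turning
the rule into a maximum-posterior classifier.

## Evaluation statistics

The per-class *coincidence rate* is per-class recall: 100·tp/(tp+fn) for
the positive class and 100·tn/(fp+tn) for the negative. The *mean
coincidence rate* is their unweighted (macro) average — deliberately not
overall accuracy: on the retrospective confusion matrix the macro mean is
71.8% while overall accuracy is 297/412 = 72.1%, and only the macro
reading matches the published summary. One published cell is internally
inconsistent: the prospective positive rate prints as 68.2% while its own
matrix gives 28/41 = 68.29% → 68.3% at one decimal; the package reports
the computed value and the fixture test asserts agreement within 0.1.

`derived_rates` computes per-category metastasis percentages
100·n₊/(n₊+n₋) directly from a frequency table (e.g. by tumor location:
35.1/48.8/55.9/42.1%), and `cohort_metastatic_rate` the overall prevalence
(47.8% retrospective).

## Synthetic cohorts and the enumeration oracle

No patient-level records accompany the aggregated tables, so the package
generates cohorts from the generative model the discriminant itself
assumes: class label ~ Bernoulli(prevalence), then each factor's category
drawn independently from that class's conditional frequencies. Default
prevalence is 197/412 (retrospective); 41/104 is available as the
prospective preset. Reproducibility contract: a fresh numpy generator
seeded from the spec draws one uniform vector for the labels, then one per
factor in scheme order; identical specs yield byte-identical cohorts.

What the generator deliberately does not emulate: between-factor
dependence given class (real risk factors are correlated — e.g. diameter
and capsular invasion), measurement error in ultrasound staging, and
covariates outside the six factors (Hashimoto's thyroiditis, TSH).
Consequently the simulated expected performance need not equal the
published real-data coincidence rates, and the tests never assert that it
does; under the bundled table and default settings the enumerated
expectations happen to come out near the real-data figures (≈67/78% per
class), which is reported by the `enumerate` CLI command as descriptive
output only.

`enumerate_expected_performance` is the exact oracle for this generative
model: it sums over all category combinations (2·2·5·2·2·4 = 320 for the
bundled scheme), weighting each by its class-conditional probability times
the class prior, and accumulates the exact expected confusion-cell
proportions — no sampling error. The combinatorial space is capped at 10⁶
combinations by default; larger schemes are refused rather than silently
truncated. Monte-Carlo rates from the sampler are tested to agree with the
enumeration within three binomial standard errors at n = 100,000, and the
fit → simulate → re-tabulate → refit loop recovers the generating score
table within 0.5 points per cell at the same n (both checks run in seconds;
the cohort sizes were chosen so binomial noise is well below the asserted
tolerances).

## Verification strategy

- All 34 score cells fitted from the bundled frequency table are compared
  against the independently bundled published table at display precision.
- The worked-example patient is pushed end-to-end through binning, scoring
  and classification.
- The full-precision decision rule is cross-checked against scikit-learn's
  `CategoricalNB` (α ≈ 0, uniform priors) fitted on a shared synthetic
  cohort: the two routes must agree on every untied patient.
- Hand-enumerable cases anchor the evaluation and enumeration code (a
  one-binary-factor model with P(A|+) = 0.9, P(A|−) = 0.1 has exact
  per-class rates of 90%).
- Property tests (hypothesis, derandomized) cover binning totality,
  permutation stability of the scheme, confusion-matrix counting against a
  brute-force loop, and macro-rate symmetries.

## Known limitations

- The published retrospective confusion matrix cannot be re-derived here:
  it requires the original patient-level records, which were never
  released. Only its printed arithmetic is checked.
- The independence assumption is untestable from the aggregated tables;
  simulated performance figures are conditional on it.
- Sex-specific metastasis rates quoted for the combined 516-patient
  population are not derivable from the bundled 412-case table and are
  not reproduced.
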