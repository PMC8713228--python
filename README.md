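# clnmscore

Clinical risk-factor scoring of **central-compartment lymph node
metastasis (CLNM)** in papillary thyroid cancer (PTC).

Preoperative ultrasound is insensitive to level-VI nodal disease, so the
decision to dissect the central compartment often rests on clinical risk
factors. `clnmscore` implements a maximum-likelihood discriminant over six
categorical factors — sex, age, tumor diameter, capsular invasion,
multifocality, tumor location — trained from an aggregated
class-conditional frequency table rather than patient-level records. Each
category receives an additive score

    s = (log10 P(X_kj | Y_g) + 1) × 10,

where P(X_kj | Y_g) is the fraction of class-g patients (g ∈ {+, −}) in
category j of factor k. A patient's class totals S₊ and S₋ are the sums of
their six per-category scores; the larger total wins. Since
S_g = 10(lg P_g + 6), this is the prior-free naive-Bayes
maximum-likelihood rule on the log scale.

The package bundles the published retrospective frequency distribution
(412 PTC cases, 197 metastatic) and the published score table, evaluates
per-class *coincidence rates* (recall) and their macro mean, and ships a
seeded synthetic-cohort generator plus an exact enumeration oracle for the
rule's expected performance under its own generative assumptions. See
`docs/methods.md` for the model, conventions, and limitations.

## Worked example

```python
from clnmscore import CLNMDiscriminant

model = CLNMDiscriminant.retrospective()   # bundled 412-case table
res = model.fit()
pred = res.predict_raw({
    "sex": "male", "age": 28, "tumor_diameter": 1.6,
    "capsular_invasion": "N", "multifocality": "N",
    "tumor_location": "lower pole",
})
print(round(pred.s_positive, 1), round(pred.s_negative, 1), pred.predicted.value)
```

prints

```
37.0 30.2 positive
```

The 28-year-old male with a unifocal 1.6 cm lower-pole tumor and no
capsular invasion totals 37.0 points under the metastatic class and 30.2
under the non-metastatic class, so the rule flags him as having CLNM.
`res.summary()` prints the full fitted score table (e.g. Male scores
4.3/2.4, multifocal disease −1.8/−3.8 under +/−).

The same workflow is available from the shell:

```sh
clnm-score demo                 # reproduce all bundled reference numbers
clnm-score fit --input freq.csv --output scores.csv
clnm-score simulate --n 1000 --seed 7 --output cohort.csv
clnm-score score --input cohort.csv --output scored.csv
clnm-score evaluate --input scored.csv
clnm-score enumerate            # exact expected coincidence rates
```

`clnm-score demo` re-fits the score table from the bundled frequencies,
checks every cell against the bundled published table, re-runs the worked
example, recomputes the coincidence-rate arithmetic of both published
confusion matrices, and the location-wise metastasis rates, flagging each
comparison PASS/FAIL.

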