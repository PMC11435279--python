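# crece

Scoring and criterion-validity analysis for **CRECE** (Cuestionario Rápido de
Evaluación Comunitaria en Español), a 22-item parent-completed Spanish
nutrition-risk screening questionnaire for 3–5-year-old children, validated
against a full nutrition assessment.

## Who this is for

Researchers developing or validating nutrition screening instruments who need
a reproducible pipeline for the two standard validation phases:

1. **Content validity** — an expert panel rates every item 1–4 on relevancy,
   clarity and simplicity. The item CVI per dimension is the proportion of
   experts rating 3–4; the combined CVI is the mean over the three
   dimensions, and items are *accepted* (≥ 0.80), *revised* (0.70–0.79) or
   *eliminated* (< 0.70).
2. **Criterion validity** — parent questionnaires are scored (22 items,
   total 0–48, banded low ≤ 15 < moderate ≤ 29 < high ≤ 48) and compared
   against a reference-standard nutrition assessment. The reference rates six
   points — BMI-for-age and MUAC-for-age z-scores (LMS method), medical
   history, 24-h recall, behavior, and a two-question food-security screen —
   and classifies a child *high* with ≥ 3 high points, else *moderate* with
   ≥ 3 moderate points, else *low*. The screening/reference pairs are
   cross-classified, collapsed to a 2×2 table (low = negative; moderate or
   high = positive), and summarized as

   sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
   PPV = TP/(TP+FP), NPV = TN/(TN+FN),

   with Wald standard errors, Wald and Clopper–Pearson intervals, and a
   χ² test of independence (optionally Yates-corrected).

Because the original study data cannot be shared, the package includes a
synthetic dyad-cohort generator with controlled prevalence and
screening/assessment misclassification, so every stage of the pipeline is
exercisable end to end. The bundled instrument configuration is a documented
reconstruction of the questionnaire's shape (the published item point values
are not available), and the bundled LMS table is synthetic.

## Worked example

Score the 39 published screening/assessment category pairs through the
pipeline:

```python
from crece import RiskCategory, ValidationReport, render_text_table

low, mod = RiskCategory.LOW, RiskCategory.MODERATE
pairs = [(low, low)] * 22 + [(low, mod)] + [(mod, low)] * 5 + [(mod, mod)] * 11
print(render_text_table(ValidationReport.from_pairs(pairs)))
```

prints

```
Screening vs. reference assessment

Screening          Ref low  Ref moderate  Ref high   Total
low risk             22 TN          1 FN         0      23
moderate risk         5 FP         11 TP         0      16
high risk                0             0         0       0
Total                   27            12         0      39

sensitivity: 91.67% (92%), SE 7.98
specificity: 81.48% (81%), SE 7.48
ppv: 68.75% (69%), SE 11.59
npv: 95.65% (96%), SE 4.25
chi-square (1 df, uncorrected): 18.37, p = 1.82e-05
```

Of the 12 children the reference assessment called at-risk, the screen
caught 11 (sensitivity 91.67%); of the 27 it called low-risk, the screen
agreed on 22 (specificity 81.48%). A positive screen is right 68.75% of the
time (PPV) and a negative screen 95.65% of the time (NPV); the association
between screen and reference is far from independence (p < 0.0001).

The same workflow is available from the shell:

```bash
crece simulate --seed 5 --n 50 --out cohort/
crece score cohort/screening_responses.csv --out scored.csv
crece assess cohort/assessment_components.csv --out assessed.csv
crece validate scored.csv assessed.csv --out report.json --text report.txt
```

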