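# oxiburden

Tools for asking whether intraoperative tissue deoxygenation predicts
postoperative renal impairment after coronary artery bypass grafting (CABG).

During cardiac surgery, near-infrared spectroscopy (NIRS) sensors can monitor
tissue oxygen saturation over the renal region (SrtO₂, flank), the cerebrum
(SctO₂, forehead) and the periphery (SptO₂, thenar muscle). `oxiburden`
quantifies each channel's intraoperative desaturation exposure as an
**area under the threshold** (AUT, %·min),

```
AUT(L) = ∫ max(L − S(t), 0) dt          over [incision, end of surgery]
```

for absolute levels L ∈ {90, 80, 70, 60}% and relative levels
L = (1 − f)·baseline with f ∈ {5, 10, 15}%, where the baseline is the mean
saturation over the 5 minutes before surgical incision. A renal-specific
differential burden integrates the positive excess of baseline-normalised
peripheral over renal saturation — the renal region sitting proportionally
deeper below its own baseline than the periphery does.

Postoperative **renal impairment** is a serum creatinine rise of strictly
more than 10% above the individual preoperative baseline within postoperative
days 1–7 (deliberately more sensitive than KDIGO/AKIN/RIFLE staging). Each
burden is evaluated as a predictor of that outcome via ROC analysis
(Mann–Whitney AUROC, Hanley–McNeil CI, Youden-J operating point), alongside
routed two-group comparisons (Shapiro–Wilk → t-test or Mann–Whitney U;
Fisher/chi-square for counts) and Spearman correlations.

Because real perioperative recordings are rarely shareable, the package
includes a **synthetic cohort generator** that emulates the target regime —
baseline plateaus with AR(1) noise, Poisson half-cosine desaturation
episodes, correlated left/right renal channels (Spearman ≈ 0.80), an on-pump
excess of renal-specific drift, and a logistic link from the realised
peripheral rel-10% burden to impairment — so the full pipeline runs and is
validated end to end with no external data.

Intended users: anaesthesiology / perioperative-outcomes researchers and
biostatisticians who want a reproducible, tested implementation of
threshold-burden analytics for irregular oximetry time series.

## Worked example

```python
import numpy as np
from oxiburden import (
    CohortSpec, generate_cohort, apply_exclusions,
    burden_panel, label_renal_impairment, roc_analysis,
)

cohort = generate_cohort(CohortSpec(seed=1))        # 41 patients
analysable, excluded = apply_exclusions(cohort)
panels = [burden_panel(r) for r in analysable]
labels = np.array([label_renal_impairment(r.creatinine).impaired
                   for r in analysable], dtype=int)

periph = np.array([p.burdens["peripheral_rel_10"].aut for p in panels])
roc = roc_analysis(periph, labels, predictor="peripheral_rel_10")
print(f"n={len(analysable)}, impaired={labels.sum()}")
print(f"AUROC {roc.auroc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
      f"p={roc.p_value:.3f}")
print(f"cutoff {roc.optimal_cutoff:.0f} %·min, "
      f"sens {roc.sensitivity:.2f}, spec {roc.specificity:.2f}")
```

prints

```
n=41, impaired=10
AUROC 0.690 (95% CI 0.488-0.892), p=0.065
cutoff 32 %·min, sens 1.00, spec 0.65
```

i.e. in this particular simulated cohort of 41 patients, 10 developed a
>10% creatinine rise, and the peripheral rel-10% desaturation burden ranked
impaired above non-impaired patients with probability 0.69; the Youden
cutoff of about 32 %·min catches every impaired patient at 65% specificity.
(A single n = 41 cohort is noisy; the designed large-sample AUROC under the
default generator is ≈ 0.75–0.77.)

The same analysis is available as a CLI:

```bash
oxiburden generate --out cohort_dir --seed 1       # write CSV cohort
oxiburden run --config config.yaml                 # full report bundle
oxiburden recover --replicates 200 --seed 1        # recovery study
```

where `config.yaml` names either `cohort: {input_dir: ...}` or
`cohort: {synthetic: {...}}` plus a `seed` and `output_dir`. The report
bundle contains cohort-characteristics, burden-by-outcome and burden-by-arm
comparison tables, the ROC table, an exclusion log, and a deterministic
`report.json` embedding the seed and config hash.

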