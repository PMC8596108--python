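# pdopharm

Pharmaco-phenotyping of patient-derived organoids (PDOs) for functional
precision oncology. PDOs grown from tumor tissue can be screened ex vivo
against a drug panel in days; the question this package addresses is how
to turn raw viability plates into per-drug sensitivity calls, per-patient
treatment predictions, and a transcriptomic signature that stratifies
survival — with every statistical step testable against synthetic data of
known truth.

The pipeline implements, end to end:

1. **Viability normalization.** Raw luminescence is anchored to plate
   controls: `viability% = 100 · (S − S̄_pos) / (S̄_neg − S̄_pos)`, where the
   negative control is 0.2% DMSO and the positive control 1 µM bortezomib.
2. **Dose–response modelling.** Each PDO × drug series (default: 7-point
   threefold dilution from 20 µM down to 27.4 nM, triplicate wells) is fit
   with the four-parameter logistic
   `y(c) = bottom + (top − bottom) / (1 + (c/EC₅₀)^h)` by profiled-grid
   initialization plus Nelder–Mead refinement. The **IC50** is the absolute
   50%-viability crossing; curves that never cross 50% in the tested range
   are censored to the range bound (`at_max` = resistant, `at_min` =
   hypersensitive).
3. **Tertile response calls.** Per drug, IC50 ranks split the cohort into
   sensitive / moderate / resistant thirds (cutoffs at ⌈n/3⌉ and ⌈2n/3⌉),
   with a bound rule when more than a third of the cohort is censored at a
   range bound.
4. **Combination additivity.** With one partner fixed at its IC30 (70%
   residual viability), the Bliss-style additive expectation is the
   pointwise product `predicted(c) = viability(c) · 0.70`; the excess score
   is the mean of (predicted − observed).
5. **Pharmaco-transcriptomic signature.** Genes differentially expressed
   between pan-sensitive and pan-resistant lines (six microtubule-targeting
   drugs; BH FDR ≤ 0.01, fold change ≥ 2) and Spearman-correlated
   (|ρ| > 0.3, sign-consistent) with the six-drug median log IC50 form the
   sensitivity signature, which drives hierarchical clustering, a
   Kaplan–Meier / log-rank survival split, and a linear max-margin
   classifier for external profiles.
6. **Clinical concordance.** A treatment is predicted effective iff its
   regimen contains ≥ 1 PDO-sensitive drug; against RECIST outcomes
   (CR/PR/SD = good, PD = poor) the package reports accuracy, sensitivity,
   specificity, rank-based AUC, 1000-rep percentile-bootstrap 95% CIs and
   Pearson's chi-square.

A synthetic-data module (`pdopharm.simulate`) generates screens,
expression matrices, treatment records and survival cohorts with planted
ground truth, so recovery, calibration and determinism are all tested
without external data.

## Worked example

```python
import numpy as np
from pdopharm import (default_panel, simulate_screen, normalize_viability,
                      fit_4pl, extract_ic50, classify_drug, Label)

panel = default_panel()[:4]                     # 4 drugs of the 49-drug panel
wells, truth = simulate_screen(panel, n_pdos=9, noise_cv=0.10, seed=7)

by_pdo = {}
for w in wells:
    by_pdo.setdefault(w.pdo_id, []).append(w)

records = {e.drug_id: [] for e in panel}
for pdo, pw in sorted(by_pdo.items()):
    for curve in normalize_viability(pw):       # raw signal -> viability%
        rec = extract_ic50(fit_4pl(curve), curve)
        records[curve.drug_id].append(rec)

rec = records["docetaxel"][0]
print(f"{rec.pdo_id} docetaxel IC50 = {rec.ic50*1e6:.3f} uM ({rec.censor.value})")
calls = classify_drug(records["docetaxel"])
n = {lab: sum(c.label is lab for c in calls) for lab in Label}
print("docetaxel calls:", {k.value: v for k, v in n.items()})
```

prints

```
PDO001 docetaxel IC50 = 0.124 uM (interior)
docetaxel calls: {'sensitive': 3, 'moderate': 3, 'resistant': 3}
```

i.e. PDO001's fitted curve crosses 50% viability at 0.124 µM, inside the
tested range (`interior`, so no censoring), and the nine-line cohort
splits into equal rank-thirds for this drug.

The same stages are available as a CLI over a shared artifact directory:

```sh
pdopharm simulate --seed 1 --out run/   # plates, counts, survival + truth
pdopharm fit      --out run/            # fits.tsv, ic50.tsv
pdopharm classify --out run/            # calls.tsv
pdopharm all      --seed 1 --out run/   # every stage in order
```

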