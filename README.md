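# hlikit — Hepatocyte Likeness Index

`hlikit` implements an image-based score for hepatocyte identity, the
**Hepatocyte Likeness Index (HLI)**, together with the plate-screen analysis
built on top of it. It is aimed at stem-cell and liver biologists running
high-content analysis (HCA) who need to quantify how close a cell population
— iPSC-derived hepatocytes (i-Heps), fetal hepatocytes, co-cultures — sits
to the physiological gold standard of freshly isolated adult hepatocytes,
and to screen culture substrates (niche factors such as collagen-1 or
laminins) for their ability to push cells toward that standard.

## The algorithm

Each cell is classified by a fixed three-stage gate sequence:

1. **nuclear morphology** — nuclear area and width inside acceptance
   intervals fit on the reference population;
2. **cell morphology** — cell area, cell width and symmetry (minor/major
   axis ratio of the second-moment ellipse) inside their intervals;
3. **albumin expression** — background-subtracted mean fluorescence
   intensity (MFI) at or above a cutoff calibrated by ROC analysis of
   reference vs negative cells, taking the threshold that maximizes
   Youden's J = TPR − FPR.

A cell failing a stage is not evaluated further (attrition is attributed to
its first failure). For a population of N cells of which n pass all three
stages,

    HLI = n / N  ∈ [0, 1]

so a healthy adult-hepatocyte population scores ≈ 1 and a negative control
such as fibroblasts scores ≈ 0. Morphology intervals are robust:
median ± 3·MADN (MADN = 1.4826 × MAD). Because roughly 30% of adult
hepatocyte nuclei are polyploid (a second nuclear-area mode at ~2× the
mononucleate mode), the nuclear-area gate is ploidy-aware: polyploid nuclei
are part of the healthy phenotype and pass.

A screen scores each well's HLI, aggregates replicate wells per condition
(mean ± SD), and calls a condition a **hit** when its mean HLI is above 0.2
*and* above the collagen-1 control mean; first-round hits are confirmed
only if they satisfy the same rule on every second-round plate.

Since no microscope data ships with the package, a synthetic
fluorescence-field generator (`hlikit.synthgen`) renders ground-truthed
multi-channel fields for five cell populations (adult, fetal, i-Hep,
fibroblast, GFP-labelled HUVEC) so the whole pipeline — nucleus-seeded
watershed segmentation, morphometry, calibration, gating, screening — can
be exercised and tested end to end.

## Worked example

```python
import numpy as np
import hlikit
from hlikit.classifier import apply_gates, compute_hli, fit_reference_profile

rng = np.random.default_rng(7)

def measure(preset, n):
    spec = hlikit.make_population_spec(preset, {"n_cells": n})
    return hlikit.sample_feature_table(spec, rng=rng)

profile = fit_reference_profile(measure("adult_hep", 500), measure("fibroblast", 500))
print(f"albumin cutoff: {profile.albumin_cutoff:.0f} AU "
      f"(ROC AUC {profile.calibration_meta['albumin_auc']:.3f})")
for preset in ("adult_hep", "fetal_hep", "ihep", "fibroblast"):
    res = compute_hli(apply_gates(measure(preset, 400), profile))
    print(f"HLI({preset:10s}) = {res.hli:.3f}   attrition {res.per_gate_attrition}")
```

prints

```
albumin cutoff: 1153 AU (ROC AUC 1.000)
HLI(adult_hep ) = 0.930   attrition {'nuclear': 27, 'cell': 0, 'albumin': 1}
HLI(fetal_hep ) = 0.240   attrition {'nuclear': 15, 'cell': 207, 'albumin': 82}
HLI(ihep      ) = 0.085   attrition {'nuclear': 53, 'cell': 238, 'albumin': 75}
HLI(fibroblast) = 0.000   attrition {'nuclear': 0, 'cell': 400, 'albumin': 0}
```

Albumin separates the reference from fibroblasts perfectly (AUC 1.0), an
independent adult draw scores near 1, fibroblasts fail en masse at the
cell-morphology stage (elongated shape), and i-Heps score low because their
enlarged, variable morphology and weak albumin exclude most cells — exactly
the ordering the index is designed to resolve. The example uses the fast
table-level measurement; `hlikit.pipeline.imaged_population_table` runs the
same thing through rendered images and watershed segmentation.

The `hli` command exposes the stages on the shell:

```bash
hli synth --preset adult_hep --n 500 --seed 7 --out field.tif
hli segment field.tif --out-prefix seg_
hli features field.tif --nuclei seg_nuclei.tif --cells seg_cells.tif --out cells.csv
hli calibrate --reference ref.csv --negatives neg.csv --out profile.json
hli score --table cells.csv --profile profile.json
hli screen --plate-map plate.json --tables-dir wells/ --profile profile.json --threshold 0.2
hli run --config config.yaml
```

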