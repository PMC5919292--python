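# Methods

This note records the model behind `hlikit`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The classification model

The HLI treats "hepatocyte identity" as a conjunction of three observable
properties, evaluated strictly in order:

1. a nucleus of normal hepatocyte size and width,
2. a cell body of normal hepatocyte size, width and symmetry,
3. albumin expression at the level of freshly isolated hepatocytes.

The sequential order is deliberate: it mirrors how an HCA operator curates
objects (nuclei first, then cell bodies, then marker intensity) and makes
the per-stage attrition counts interpretable — a fibroblast population
fails almost entirely at stage 2, an albumin-negative hepatocyte-shaped
population at stage 3. An all-stages-evaluated mode
(`apply_gates(..., short_circuit=False)`) is available when per-gate
diagnostics are wanted for every cell.

### Morphology gates

Each gated feature gets a closed acceptance interval
`median ± 3·MADN` fit on the reference population, where
`MADN = 1.4826 × MAD` is the normal-consistent robust scale. For Gaussian
features this accepts ≈ 99.7% of the reference, so a healthy population
scores near 1 without any tuning; robust statistics keep single debris
objects or segmentation faults from widening the gates. Boundary values
pass (closed intervals) so tie-breaking is deterministic.

**Ploidy-aware nuclear-area gate.** Adult hepatocytes are ~30% polyploid;
their nuclear-area distribution is a 1×/2× mixture, not a Gaussian. A
symmetric ±3·MADN interval fit on that mixture lands its upper bound inside
the 2× mode and would reject roughly a third of bona fide polyploid nuclei,
capping the HLI of the gold standard itself near 0.9. The nuclear-area gate
therefore takes its median and MADN from the mononucleate mode (cells below
1.5× the modal area, the same modal analysis used for ploidy calling) and
extends the upper bound to `2 × median + 3·MADN`. Polyploidy is part of the
healthy adult phenotype, so the gate must cover both modes; for unimodal
references the wider bound is harmless because no negative population is
separated from hepatocytes by nuclear area alone. A feature with zero
spread degenerates to a (median, median) gate and is flagged in
`calibration_meta`.

### Albumin cutoff

The cutoff is the Youden-optimal threshold (maximizing TPR − FPR) of the
empirical ROC of reference vs negative albumin MFI, with the classification
rule "positive when MFI ≥ threshold" and thresholds at every distinct
observed value. The trapezoid AUC of this curve equals the Mann–Whitney
U statistic divided by n₁·n₂ (asserted exactly in the tests against a
brute-force pair count and against scikit-learn). Ties in J break toward
the higher threshold; with perfectly separated populations the cutoff
therefore lands on the smallest observed reference MFI (≈ 1050–1150 AU for
the default adult-vs-fibroblast calibration at n = 500). That choice is the
most conservative threshold that still accepts every calibration reference
cell; it sits far above the negative population, and an independent adult
draw still passes at ≈ 99.9%. An AUC below 0.6 records a warning in
`calibration_meta` — the marker is then unfit for calibration.

### Score

`HLI = n_positive / n_total`, undefined (an error) for empty populations.
Wells with fewer than 20 cells are flagged low-count in the screen layer
and excluded from condition means, since proportions on tiny denominators
are unstable.

## Segmentation

Nuclei: Gaussian smoothing (σ = 1 px), Otsu threshold, Euclidean distance
transform smoothed at σ = 1 px, watershed from its regional maxima with a
minimum peak separation of half the expected nuclear diameter (derived from
the minimum-area parameter, default 20 µm²). Objects outside
[20, 600] µm² and objects touching the image border are removed; clipped
objects would bias morphometry. Cells: watershed from the nuclear seeds
over the Otsu foreground of the cytoplasm channel — in hepatocyte cultures
the albumin stain doubles as the segmentation channel. Every cell keeps its
seed nucleus label; nucleus-free foreground stays background; a blank or
constant channel yields an empty map rather than an error. Background per
channel is the median intensity outside all cells.

The smoothed-distance watershed keeps single elliptical nuclei intact
(their distance ridge has a unique regional maximum) while still splitting
touching nuclei whose centres are more than the peak separation apart; this
is what lets a 2×-area polyploid nucleus survive as one object instead of
being cut in half, which would silently delete the polyploidy signal.

## The synthetic generator

Cells are non-overlapping concentric ellipses (cell body + co-oriented
nucleus) placed by dart-throwing against an occupancy raster with a 2 µm
margin (≤ 1000 retries per cell, then an error advising a larger field).
Rendering paints each channel at the cell's true intensity over a uniform
background of 50 AU, with additive Gaussian read noise (σ = 5% of the mean
foreground intensity by default) and optional Poisson shot noise. Default
optics: 0.65 µm/pixel. Label maps returned by the renderer are the exact
rasterized ground truth. All sampling flows from one
`numpy.random.Generator`, so identical (spec, seed) pairs give bit-identical
images.

Preset magnitudes (means ± SD) encode the qualitative contrasts between
the five populations; the exact numbers are generator conventions:

| preset | cell area (µm²) | aspect | nuclear area (µm²) | polyploid | albumin (AU) |
|---|---|---|---|---|---|
| adult_hep | 1600 ± 300 | 0.85 ± 0.08 | 110 ± 20 | 0.30 | 2000 ± 300 |
| fetal_hep | 900 ± 250 | 0.65 ± 0.12 | 80 ± 15 | 0.03 | 1200 ± 300 |
| ihep | 3000 ± 900 | 0.85 ± 0.08 | 150 ± 45 | 0.10 | 900 ± 500 |
| fibroblast | 1600 ± 350 | 0.25 ± 0.08 | 110 ± 20 | 0 | 120 ± 60 |
| huvec_gfp | 800 ± 200 | 0.50 ± 0.10 | 90 ± 15 | 0 | 150 ± 70 |

Choices worth noting:

* **Polyploidy** is modelled as a second nuclear-area mode at exactly 2×
  the mononucleate mean with the same SD (binucleate/tetraploid model).
  This makes an area threshold at 1.5× the modal area the midpoint
  discriminator, which is what `call_polyploidy` uses by default.
* **Fibroblasts share the adult size parameters** on purpose: among the
  morphology features only symmetry (and albumin among intensities)
  separates the two classes, so feature-importance ranking has an
  unambiguous ground truth, and fibroblasts fail the gate sequence at the
  cell-morphology stage rather than trivially at every stage.
* **i-Heps are large and variable** (cell area 3000 ± 900, nuclei
  150 ± 45) with weak, variable albumin. Under an adult-calibrated profile
  the preset scores HLI ≈ 0.05–0.10, i.e. a realistic pre-optimization
  baseline for a substrate screen whose hits must clear 0.2.
* HUVEC GFP (1500 ± 300 AU) is painted on the nucleus, as for nuclear GFP
  labels; GFP MFI is accordingly measured over the nucleus mask, all other
  channels over the cell mask.

What the generator does **not** emulate: optics (no point-spread function,
no 3D, no vignetting or illumination gradients), confluent monolayers
(cells never touch, so watershed splitting of cell bodies is only exercised
for nuclei), intensity heterogeneity within a cell, debris and imaging
artefacts, and mixed-intensity fields where a dim population coexists with
a 10×-brighter one (a global Otsu threshold on the cytoplasm channel will
drop the dim cells there; co-culture scoring in the tests therefore runs at
feature-table level). Passing tests show the algorithm is correct under
these idealized conditions; they do not certify segmentation performance on
real micrographs.

## Screen analysis

Per-well HLI → per-condition mean ± SD over replicate wells → hit iff
`mean > 0.2` **and** `mean > control mean` (strict inequalities; the
control condition is never a hit). The conjunction keeps a noisy control
from masking hits while the absolute floor keeps a dead control plate from
promoting everything; the pure absolute rule is available via
`require_above_control=False`. Confirmation requires the same rule to hold
on every second-round plate. Raising the threshold can only remove hits
(monotone filter), and hit calls are invariant to well ordering and
condition relabeling — both property-tested.

## Problem sizes

The suite and the acceptance script use n = 500 cells per population for
calibration and HLI endpoints (split into fields of ≤ 250 cells at ~22%
packing), n = 2000 for ploidy fractions (nuclear segmentation only), and
feature-table-level wells of 80–150 cells for the 58-condition screen with
3 replicate wells per condition. At these sizes the binomial 99% CI on a
30% fraction is ±2.7 points and the whole acceptance run completes in
about a minute on one CPU.

## Known limitations

* Gate width depends on the calibration sample: with n = 500 reference
  cells the MADN estimate fluctuates enough that joint morphology coverage
  of an independent adult draw ranges ~0.93–0.99 across seeds. Larger
  references tighten this.
* The Youden cutoff under perfect separation is the sample minimum of the
  reference MFI — a high-variance statistic. With overlapping populations
  (where ROC calibration actually matters) it behaves conventionally.
* `symmetry` is a whole-cell ellipse ratio; it does not capture boundary
  roughness or branching, only elongation.
* Polyploidy is scored by nuclear area, not integrated DNA intensity or
  multi-nucleation counts; binucleate cells rendered as one 2× nucleus are
  indistinguishable from true tetraploid nuclei by construction.
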