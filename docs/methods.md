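# Methods

This note records the scientific and numerical choices behind `cxrnodule`:
what each stage computes, which parameters matter, what the synthetic
generators do and do not emulate, and where a design was genuinely open.

## Preprocessing

**Polarity correction.** Radiographs are sometimes stored inverse-grayscale
(air bright). The package decides polarity from the pixels alone: the mean
intensity of the four border strips (each 2 % of the corresponding image
dimension) is compared with the global median; if the border is brighter,
the image is inverted (`v → 1 − v`). The rationale: on a frontal CXR the
border is air, which renders dark at standard polarity. The rule is
parameter-light and idempotent — after one inversion the border is dark, so
a second pass is a no-op. Constant images are never inverted. This is a
stand-in for whatever combination of DICOM tags and manual screening a
clinical archive would use; DICOM metadata handling is deliberately out of
scope.

**Brightness normalization.** Exposure varies between machines and
technicians. The top 0.2 % of intensities (`clip_fraction = 0.002`, the
`1 − 0.002` quantile with linear interpolation of order statistics) is
clipped, and the histogram is affinely rescaled so the observed minimum
maps to 0 and the clip level to 1. Anchoring the lower end at the observed
minimum (rather than 0) makes the rescale a full-range stretch. A constant
image maps to constant 0. The quantile-interpolation tolerance (1e-6) is
the scale of disagreement one should expect between this and any other
interpolation convention.

**Gamma variant.** The power law `V_out = A·V_in^γ` with `A = 1`, `γ = 3`,
clipped to [0, 1]. With γ > 1 the dark lung fields spread over more of the
output range and bright soft tissue compresses, which is the reason a lung
detector may prefer it. The transform is monotone, fixes 0 and 1, and is
the identity at `A = γ = 1`.

**CLAHE variant.** Contrast-limited adaptive histogram equalization in the
classical tile formulation: the image is padded (edge replication) to a
multiple of the 8×8 tile grid; each tile's 256-bin histogram is clipped at
`clip_limit` × the uniform bin level (`clip_limit = 2`), the excess
redistributed uniformly; each tile maps intensity through its clipped CDF;
per-pixel output bilinearly interpolates the four surrounding tile
mappings. The clip limit is a *multiplier of the uniform histogram level*,
the common "clipLimit" convention; 256 bins match 8-bit clinical display.
In the degenerate limit (1×1 grid, unbounded clip) the transform equals
global histogram equalization, which the test suite verifies against an
independent cumulative-histogram implementation to within one bin width
(1/256). The implementation is authored here because the installed
alternatives use a different clip-limit convention and interpolation
scheme that break that exact limit law.

## Lung ROI

Segmentation is a pluggable contract (`GrayImage → LungMask`). The
deterministic fallback thresholds dark pixels (below the 0.35 intensity
quantile of the normalized image), removes components touching the border
(outside-air), drops components smaller than 1 % of the image, and keeps
the two largest (the lung fields). It is adequate for phantom geometry and
is *not* a clinical segmenter; a trained model can be slotted in through
the same contract.

The ROI is one combined box, not per-lung boxes: the tight bounding box of
all mask foreground already spans the mediastinal gap between the lungs,
which is the region naive masks cut off. The box is padded laterally by
2 % of its width per side and extended downward by 15 % of its height for
subdiaphragmatic coverage, then clipped to the image. The two fractions
are explicit stand-ins — there is no principled value for how far below
the diaphragm a nodule can hide — and ROI area is monotone in both, so
conservative users can simply raise them. Coordinates are 0-based,
half-open, origin top-left throughout; crops record their offset so
detections map back to source coordinates exactly.

## Toy detector

A multiscale difference-of-Gaussian blob finder: adjacent scales of a
geometric σ ladder (default 3…24 px) are differenced and divided by
`ratio − 1` for approximate scale normalization; local maxima of the 3-D
(scale, y, x) stack above a response floor become detections with box side
`2√2·σ` at the maximizing scale. Scores are responses normalized by the
maximum over the image set processed together, so the threshold ladder
acts on a stable [0, 1] scale. The floor is calibrated just above the
strongest response on nodule-free images (5 % margin). An optional
restriction mask (in the pipeline: the lung mask) suppresses maxima caused
by anatomy that is blob-like at coarse scales — the mediastinal band, the
body outline. The detector is deterministic and exists so ensembling and
evaluation can be tested end to end; it stands in for, and is interface-
compatible with, a trained detector whose outputs arrive via the JSONL
adapter.

## Ensemble

The fourth "model" is a set union: each member is thresholded at its own
operating point (default 0.01 for all three variants), the surviving
detections pooled, and boxes merged greedily in descending score order
(ties broken by box coordinates for determinism), absorbing any box with
IoU ≥ 0.5 with the cluster seed. Each cluster emits the seed's box with
the cluster's maximum score. Merging implements the *set* semantics — one
physical finding reported by several members counts once — and prevents
the union from trebling the false-positive count. Union can only add
findings, so ensemble sensitivity dominates every member's at the members'
own thresholds, and the FP count is subadditive; both properties are
asserted in tests on engineered disjoint-miss pseudo-models.

## FROC evaluation

A detection hits a nodule when the annotated center lies inside the
detection box — robust to box-size mismatch between detector and
annotation. Assignment is optimal (maximum number of hit nodules, ties
resolved toward larger total detection score, via linear sum assignment),
which provably agrees with exhaustive enumeration; a surplus detection on
an already-hit nodule is not a false positive (the standard free-response
convention), so false positives are exactly the detections containing no
nodule center. Sweeping the descending threshold ladder
0.1, 0.075, 0.05, 0.02, 0.01, 0.0075, 0.005, 0.0025, 0.001, 0.0001 gives
one (sensitivity, FP/image) point per threshold; both coordinates are
non-increasing in threshold by construction, and the curve constructor
asserts it. The summary area integrates sensitivity over FP/image on
[0, 10] — a range covering the operating points of practical CXR
detectors — by the trapezoid rule, extending the curve horizontally beyond
its last point and anchoring it horizontally at FP = 0 with the
highest-threshold sensitivity, then divides by 10 so a perfect detector
scores 1. The symmetric horizontal anchoring keeps the area comparison
fair for detectors whose top ladder threshold already admits false
positives.

Size strata are half-open in diameter — [0, 6), [6, 10), [10, 20),
[20, 30), [30, ∞) mm — so a 10 mm nodule belongs to "10–20 mm". Table
percentages round half away from zero to one decimal, matching clinical
reporting.

## Temporal analysis

Time from detection to diagnosis is counted in whole days from the
earliest pre-diagnosis radiograph flagged by a source; a patient never
flagged contributes 0 ("not detected early"), which keeps all patients in
the cohort medians. AI-assisted reading is simulated as the per-record OR
of reader and AI flags, so the combined time is exactly the per-patient
maximum of the two — an identity asserted on every cohort, from which
median dominance of the combined reading follows. Overlap counts satisfy
their closure identities by construction.

The Wilcoxon signed-rank test drops zero differences (classical
convention, flagged in the result so a Pratt-style analysis can be run
instead), ranks absolute differences with midranks for ties, and uses
`W = min(W⁺, W⁻)`. With ≤ 15 informative pairs the two-sided p-value is
exact: full enumeration of the 2ⁿ equiprobable sign assignments, counting
both tails. Above that, a normal approximation with tie-corrected variance
and a 0.5 continuity correction is used; the suite checks the exact branch
against an independent enumeration oracle to 1e-12 and both branches
against scipy's implementation as an independent cross-check.

## Synthetic generators

**Phantoms** (default 512×512 at 0.35 mm/px, so the clinical strata map to
≈17–86 px): dark outside-air corners, a bright soft-tissue disc with a
brighter central mediastinal band, two dark elliptical lung fields with
optional sinusoidal rib texture and Gaussian pixel noise. Nodules are
isotropic Gaussian bumps whose *full width at half maximum* equals the
physical diameter, inserted only where the whole nodule fits inside a lung
field (resampled on failure, skipped after 200 attempts). A configurable
fraction of images is emitted polarity-inverted and brightness-jittered to
exercise normalization, and the generator returns its own labels so tests
can score the polarity corrector. What the phantoms deliberately lack:
overlapping bony anatomy, heart/diaphragm contours, scatter, pathology
other than nodules. Passing tests therefore demonstrate the *pipeline's
logic* — geometry bookkeeping, thresholds, set arithmetic, statistics —
not detector performance on real radiographs.

**Pseudo-detector outputs** bypass images entirely: each ground-truth
nodule is emitted as a hitting box with a per-stratum probability, scores
are drawn log-uniformly (hits 10⁻²…10⁰, false positives 10⁻⁴…10⁻¹ so the
threshold ladder sweeps an informative curve), and Poisson false boxes are
placed away from truth centers. The generator returns its miss mask, which
serves as the oracle for ensemble-dominance tests.

**Longitudinal cohorts** (default 383 patients, 5-year follow-up, visits
every 120 days): a nodule appears at a uniform random onset day, grows by
volume doubling — diameter `d(t) = d₀ · 2^(t/(3·DT))` with doubling time
DT drawn from 60–400 days — and is flagged independently per visit by each
source with per-stratum probabilities (reader 0.02→0.85, AI 0.05→0.90 from
the smallest to the largest stratum; both rise with size, the AI faster on
small nodules). Diagnosis falls 30 days after the first reader detection
or at the end of follow-up. The growth law and probabilities are generator
assumptions chosen to produce clinically plausible cohorts, not estimates
of any real reader or model.

Every generator is a pure function of its seed; identical configuration
gives bitwise-identical output.

## Problem sizes and numerical conventions

The test suite and the acceptance script run 100-phantom end-to-end
detection (three variants, ~1 minute), 500 random matcher instances
against brute force, 200 signed-rank instances against 2ⁿ enumeration, and
383-patient cohorts — sizes chosen to exercise every code path at high
statistical power while staying comfortable on a single CPU. Degenerate
inputs are defined, not rejected, wherever a convention exists (constant
images, empty detection sets, all-zero differences); genuinely undefined
quantities (sensitivity with no ground truth, ROI of an empty mask, median
of nothing) raise errors naming the offending input.

## Known limitations

* The fallback segmenter and toy detector are stand-ins with phantom-level
  fidelity; clinical use requires trained replacements behind the same
  contracts.
* The polarity rule can misfire on radiographs whose border is not air
  (heavily collimated or cropped films).
* FROC areas depend on the FP-axis range; [0, 10] is stated in every
  summary and should accompany any reported number.
* The exact Wilcoxon branch is O(2ⁿ) and capped at n = 15 by default;
  beyond that the tie-corrected normal approximation is used.
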