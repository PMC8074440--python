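# Methods

`cmrseg` implements a fully automatic analysis pipeline for short-axis
cardiovascular MR (CMR) studies spanning six sequence kinds — cine, late
gadolinium enhancement (LGE), native T1, post-contrast T1, native T2
maps, and aortic phase-contrast flow — together with a synthetic cardiac
phantom that supplies training data and analytically known ground truth.
This note records the model, its assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Pipeline

Each study is processed in five stages:

1. **Pre-processing.** Every 2D slice is resampled to a fixed network
   grid of 212 × 212 pixels at 1.37 mm × 1.37 mm, by bilinear
   interpolation to the target pixel size followed by a center
   crop/zero-pad, and intensity-normalized by a per-slice z-score
   (`(x − mean)/sd`, slices with sd < 1e−6 map to zeros). The z-score is
   computed on the resampled content region *before* padding so the
   padding never biases the statistics, and it makes the normalization
   exactly invariant to affine intensity rescaling. Whether
   normalization should be per-slice, per-stack or per-cohort was open;
   per-slice is the most robust to inter-scan intensity variation and is
   what is implemented. A `ResampleRecord` stores everything needed to
   map predictions back to the acquisition grid with nearest-neighbor
   interpolation.

2. **Segmentation.** One independent 2D U-Net per sequence kind
   (no weight sharing): a symmetric encoder–decoder with skip
   connections, `depth` resolution levels of `base · 2^i` channels,
   3 × 3 same-padded convolutions with batch normalization and ReLU,
   2 × 2 max-pooling, transposed-convolution upsampling, and a 1 × 1
   output convolution producing per-class softmax probabilities at input
   resolution. Defaults are depth 4 and base 16 (configurable up to the
   original 64-channel design). Inputs whose size is not a multiple of
   `2^(depth−1)` — including 212 — are zero-padded internally and the
   logits cropped back, so the output always matches the input grid.
   Training uses Adam (learning rate 0.01, β₁ = 0.9, β₂ = 0.999, batch
   size 5, no schedule). All models maximize the mean foreground soft
   Dice (ε = 1e−5 smoothing; an empty-foreground batch therefore yields
   zero loss rather than NaN), except the cine model, which minimizes a
   weighted cross-entropy with inverse-class-frequency weights
   renormalized to mean 1 — "weighted" is otherwise unspecified, and
   frequency balancing is the standard reading. The class count follows
   the sequence: cine 4 (background/LV cavity/LV myocardium/RV cavity),
   LGE 4 (scar instead of RV), maps 3, flow 2 (aorta).

   The network engine is a self-contained NumPy implementation
   (`cmrseg.nn`): channels-last activations, convolutions evaluated as
   shifted GEMMs so the arithmetic runs inside BLAS, hand-written
   backward passes, and an explicit `numpy.random.Generator` for
   bit-reproducible initialization and batching. Analytic gradients are
   verified against float64 central differences in the test suite.

3. **Post-processing**, in fixed order: per-pixel argmax (ties go to the
   lowest class index), inverse resampling and stacking to a 3D mask,
   largest-connected-component filtering per structure (26-connectivity
   in 3D, per frame for temporal stacks; the single-plane aorta uses
   8-connectivity in 2D; equal-size components are tie-broken by the
   lexicographically smallest voxel index for determinism), convex-hull
   regularization, and — for LGE and the three maps only — Random-Forest
   rejection of over-segmented slices. Each step is idempotent on its
   own output.

   *Convexity convention.* An annulus is not convex, so "convex
   myocardium" is realized on its two contours: the endocardial contour
   is the hull of the cavity, the epicardial contour is the hull of
   cavity ∪ myocardium (∪ scar), and the myocardium is the epicardial
   hull minus the cavity hull. Hulls are computed per 2D slice — a 3D
   hull would bridge base and apex — with pixel-center vertices
   (`offset_coordinates=False`), which makes hulling exactly idempotent
   on rasterized sets. Scar is exempt from both hulling and
   largest-component filtering (it is legitimately fragmented) but is
   clipped to the final myocardial shell.

   *Slice rejection.* Map and LGE models tend to segment an extra slice
   beyond the true basal/apical extent of the ventricle. A Random Forest
   of 6 trees with maximum depth 6 classifies each segmented slice as
   keep/discard from three features: the mean softmax of the predicted
   myocardium, its mean normalized intensity, and the normalized slice
   position `z/(n−1)` (slice 0 is most basal — the slice ordering
   convention is a repository choice; the feature only needs it fixed).
   Discarded slices are cleared to background. Slices with no predicted
   myocardium have undefined features and are cleared without consulting
   the forest. The decision threshold is the forest's majority vote.
   Whether the intensity feature is raw or normalized was open;
   normalized (post-preprocessing) is implemented, which keeps the
   feature comparable across scans. Training labels come from comparing
   a prediction with its reference: a slice segmented by the model but
   empty in the reference is a discard example.

4. **Parameter extraction.** Volumes are voxel summations
   (count × voxel volume; with per-slice masks this equals slice-wise
   Simpson summation). For cine, end-diastole is the frame of maximum
   LV-cavity volume and end-systole the minimum (ties → earliest frame);
   EF = 100·(EDV − ESV)/EDV, stroke volume = EDV − ESV, and LV mass =
   myocardial volume at ED × 1.05 g/mL (the conventional myocardial
   density). If segmentation error yields ESV > EDV, EF clamps to 0 and
   a warning is recorded. Scar percentage counts scar as diseased
   myocardium: 100 · scar/(myocardium + scar). Map means are arithmetic
   means of raw map values (ms) over myocardial voxels. Flow integrates
   through-plane velocity over the segmented aorta:
   Q_f = Σ_px v·a per frame, net flow = Σ_f Q_f·Δt, backward flow =
   |Σ_f min(Q_f, 0)·Δt|, with positive velocity defined as antegrade.
   An Otsu threshold on within-myocardium intensities provides
   semi-automatic scar extraction from LGE images (hyperenhancement is
   bright).

5. **Study reporting.** A batch runner processes a manifest, tabulates
   parameters, and flags any row with a value outside configurable
   physiological ranges; flag logic is exactly the range predicate.
   The shipped ranges (e.g. LVEF 20–80 %) are editable conventions, not
   clinical reference values. Per-subject failures are logged and
   skipped — one bad scan never aborts a batch. Once a corrected subset
   exists, per-parameter agreement statistics against the automatic
   results serve as a global confidence indicator.

## Evaluation metrics

Dice, Hausdorff distance (HD) and mean surface distance (MSD) are
computed in 3D. Surfaces are structure voxels with at least one
face-adjacent outside neighbor (array borders count as outside);
distances are between boundary voxel centers in physical millimeters
with anisotropic spacing. Conventions: both-empty Dice is 1, one-empty
Dice is 0; HD/MSD are reported missing (NaN) when either side lacks the
structure. For temporal stacks Dice pools all frames while HD takes the
per-frame maximum and MSD the per-frame mean. All three metrics are
cross-checked in the tests against brute-force oracles (set arithmetic
and all-pairs distance matrices) on randomized masks.

Parameter agreement reports Pearson's R (omitted when a vector has zero
variance), a mean error — absolute differences for percentage-based
parameters (EF, scar %), absolute relative differences in percent for
numerical ones — and Bland–Altman bias with ±1.96·sd limits of
agreement (sd with ddof = 1).

## The phantom

The phantom emulates the geometry the pipeline must segment, not MR
physics. Per slice, the LV cavity is a disk of per-slice/per-frame
radius, the myocardium an annulus of constant thickness around it, the
RV cavity a laterally offset disk minus the epicardial disk (a
crescent), scar a sector of the annulus with prescribed angular extent
and transmurality, and the aorta a disk carrying a parabolic in-plane
velocity profile modulated sinusoidally with a positive offset in time
(so a minority of frames are net-negative, emulating early-diastolic
backflow). Phase-contrast acquisitions are single-plane, so the flow
phantom has one slice. Cavity radii taper linearly toward the apex; the
cine radius schedule is piecewise linear in time with a unique maximum
(ED, frame 0) and unique minimum (ES), so ED/ES detection has an exact
answer. A voxel belongs to a structure iff its center lies inside the
analytic shape, which makes every ground-truth volume an exact voxel
count; EF, scar fraction and flow integrals stored in `PhantomTruth`
are recomputed from those counts (flow from the noiseless voxelized
velocity field), so parameter recovery from ground-truth masks is exact
by construction rather than approximate.

Default geometry (basal cavity radius 22 mm at ED, 14 mm at ES, 8 mm
wall, 6 slices of 10 mm, 35 % apical taper, 12 mm aorta, peak velocity
80 cm/s with +30 cm/s offset) gives an EDV of ~64 mL, EF ~60 %, scar
~14 % and net flow ~54 mL — a compact but physiologically plausible
heart that fits a 64 × 64 grid at 1.37 mm. Tissue means per kind
(e.g. myocardium 1000 ms / blood 1600 ms for native T1, bright scar on
LGE) are configuration constants, not claims about tissue; Gaussian
noise with per-kind defaults (chosen so structures are clearly but not
trivially separable, e.g. sd 20 against a 220-unit cine blood–myocardium
contrast) is added on top. Training corpora re-randomize cavity size
(±~15 %), wall thickness (±20 %), heart position, scar geometry and
aorta size per stack to emulate anatomical variability.

Deliberate over-segmentation fixtures append empty basal slices to the
stack and copy the first genuine heart slice's labels onto 1–2 of them,
painted over non-cardiac background tissue — the exact failure mode the
slice rejector addresses. The corresponding softmax maps are synthesized
from the corrupted masks with lower confidence on spurious slices
(0.55–0.80) than genuine ones (0.85–0.98), emulating a network that is
less certain off the heart.

What the phantom does *not* model: coil bias fields, k-space artifacts,
papillary muscles, trabeculation, partial-volume blur, through-plane
motion, or inter-observer contour ambiguity. Passing the phantom tests
therefore demonstrates that the pipeline machinery is correct —
geometry-faithful segmentation, exact bookkeeping from mask to clinical
parameter, a rejector that learns the intended discrimination — not that
the shipped defaults reach clinical-grade accuracy on patient data,
which requires training on real annotated studies.

## Problem sizes and numerical choices

The test suite and the acceptance script train at desk scale: 64 × 64
phantom grids, 200 training slices per sequence kind, 14 epochs, the
default depth-4/base-16 network — sizes chosen so a full verification
run completes in minutes on a single CPU core while still exercising
every pipeline stage end-to-end. At these sizes held-out phantom Dice
reaches ≈0.95–0.99 for LV/RV cavities and myocardium and ≈0.95 for the
aorta. The engine works in float32; soft-Dice smoothing ε = 1e−5;
BatchNorm ε = 1e−5 with 0.9 running-stat momentum; Adam ε = 1e−8.
All randomness (phantom sampling, initialization, batch shuffling,
forest seeds) flows through explicit seeds, and every CLI run writes a
JSON snapshot of its effective options.

## Known limitations

* The slice rejector is trained and evaluated on synthesized softmax
  confidence; with a real network the features come from its actual
  softmax, and the separation margin will differ.
* RV basal-slice ambiguity — the dominant real-world cine failure mode —
  has no counterpart in the phantom's clean crescent.
* Scar evaluation by overlap metrics is intrinsically unstable for
  fragmented regions; the scar *percentage* is the robust quantity.
* The phantom's flow plane has no magnitude image; near the temporal
  zero-crossings of the velocity profile the aorta is genuinely
  invisible to the segmenter, which bounds achievable aortic Dice
  slightly below 1.
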