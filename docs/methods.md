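# Methods

## The measurement

A differentiating myoblast culture is imaged in two channels: DAPI marks
all nuclei, MF20 (an antibody against sarcomeric myosin heavy chain)
marks cells committed to the muscle fate. With `N` the total nucleus
count in a field,

* `MDI = N_inside / N` — the fraction of nuclei lying in MF20⁺ cells —
  measures commitment to differentiation;
* `MFI = N_fused / N`, where `N_fused` counts nuclei in MF20⁺ objects
  holding at least `mfi_min_nuclei` (default 2) nuclei, measures fusion
  into syncytia. Mononucleated MF20⁺ cells appear as the reference bin of
  the per-object nucleus-count histogram (default bins 1, 2–4, ≥ 5).

Neither index has a single canonical denominator in the literature; both
the scalar indices and the per-object histogram are emitted so that
either convention (all nuclei, or MF20⁺ nuclei only) can be recomputed
from the tables.

## Segmentation pipelines

**Nuclei**: Gaussian blur (σ = `blur_sigma_px`, default 1 px) → Otsu
threshold → distance-transform watershed (seed separation
`nucleus_seed_separation_px`, default 6 px ≈ the expected nucleus radius)
→ size filter `[nucleus_min_area_px, nucleus_max_area_px]` (defaults
40–2000 px²). The watershed runs before the size filter so that split
fragments are size-checked individually.

**Myotubes**: Gaussian blur → Otsu threshold → despeckle (3×3 median) →
4× dilate → close → fill holes → 3× erode (3×3 square structuring
element throughout, one pass per iteration) → watershed (seed separation
`myotube_seed_separation_px`, default 15 px) → minimum-size filter
(`myotube_min_area_px`, default 500 px²). The 4-vs-3 dilate/erode
asymmetry is deliberate: each ROI retains a net one-iteration growth plus
the closing, so an ROI covers ≥ 99 % of its generating footprint on
noise-free scenes and nucleus assignment at ROI borders errs toward
inclusion. No boundary-restoring correction is applied.

Both channels are smoothed with the same σ. Otsu is used for both
channels — one mechanism, fewer knobs — with 256 histogram bins over the
observed range, ties broken toward the smallest maximizing cut, and
foreground defined as strictly above the threshold (the reported
threshold is the largest background-class value, making
`mask = image > threshold` exact).

### Blank-channel guard

Otsu always splits a histogram; on a channel containing only noise it
bisects the noise distribution and yields ~50 % spurious foreground. A
channel is therefore declared empty unless the threshold clears the image
median by at least 4 noise scales, where the noise scale is the standard
deviation of the sub-median pixels — a robust estimate unaffected by
foreground as long as foreground covers less than half the field. This
guard is intentionally internal (not a `PipelineParams` field): it
encodes "is there any signal at all", not a tunable analysis choice.
Fields whose foreground exceeds ~50 % coverage would need the guard
revisited; the cultures this pipeline targets are far below that.

### Watershed seeding

Splitting touching objects uses the watershed on the negated Euclidean
distance transform (EDT), flooding from seeds, with 1-px watershed lines
assigned to background so split objects are disconnected. Seed detection
is the delicate part: the EDT ridge of a discretized elongated object
(a myotube) carries staircase jitter of up to ~1 px, fragmenting into
many equal-height plateaus with shallow saddles, while the genuine neck
between two touching nuclei may be only 1–2 px below the adjacent peaks.
No absolute prominence threshold separates the two regimes — but a
*relative* one does: ridge jitter is a few percent of a ~15 px
half-width, whereas a splittable nucleus neck sits ≥ 8 % below a
5–6 px peak. A maximum of height `p` therefore keeps its own seed only
if its saddle toward higher ground lies below `0.92·p − 0.3` (computed
with one grayscale reconstruction); of any two surviving seeds closer
than `min_seed_separation`, only the one with the larger distance value
is kept, and a mask component whose every maximum was suppressed is
re-seeded at its distance argmax so no object is lost. This emulates the
classic ultimate-eroded-points binary watershed; it is an emulation, not
a bit-exact port.

## Counting and statistics

Each segmented nucleus is assigned to the myotube label under its rounded
centroid (0 = background). This counts every nucleus exactly once, making
`N_inside + N_outside = N` an exact integer identity that the test suite
asserts on every pipeline run. Group comparisons use the two-sided
unpaired Student *t* test with pooled variance (the historical default of
the graphing tools this workflow grew up with); zero pooled variance with
equal means returns t = 0, p = 1. The ΔΔCT utility implements
`fold = 2^−((Ct_t − Ct_ref)_treated − (Ct_t − Ct_ref)_control)` against a
housekeeping reference (18S rRNA in the assays this mirrors).

## The synthetic-data generator

`generate_image` renders a 16-bit two-channel scene with exact ground
truth. Defaults describe one 512×512 field of a well-differentiated
culture and were chosen once as realistic for 20× imaging at ~0.5 µm/px:

| parameter | default | rationale |
|---|---|---|
| nuclei | 150, radius 6 ± 0.8 px, eccentricity ≤ 0.6 | C2C12 nuclei (~10–15 µm) at this scale; keeps the 40 px² junk filter at ~35 % of the smallest expected nucleus area |
| touching pairs | 20 % of nuclei, co-oriented, boundary gap ≤ 1 px | exercises the watershed stage |
| myotubes | 6 capsules, 30 × 300 px | elongated syncytia without branching |
| target MDI | 0.5 | mid-differentiation field |
| PSF σ | 1 px | matches the analysis blur scale |
| background / noise | 100 / 25 (a.u.) | confocal-like SNR on a 16-bit scale |
| intensities | nuclei 2500, myotubes 1800 | bright immunofluorescence staining |

Placement is rejection sampling with 1000 retries per object and an
explicit `PlacementError` naming the violated constraint. Inside-nuclei
are allocated to myotubes by largest-remainder proportional to footprint
area (so no tube is overfilled), with in-tube spacing relaxed relative to
the sparse background population — nuclei do crowd inside syncytia.
Outside nuclei keep ≥ 4 px boundary clearance from any footprint so the
centroid rule stays unambiguous under the pipeline's net ROI growth.
Exactly `round(target_mdi · n_nuclei)` nuclei are placed inside when
feasible, so the ground-truth MDI equals the target exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: branching or crossing myotubes, sarcomeric
texture, intensity gradients and vignetting, out-of-focus light,
Poisson shot noise (the additive Gaussian SD covers the tested regime),
clumps of more than two touching nuclei, and edge-truncated objects.
Performance numbers on synthetic scenes are an upper bound on real-image
performance; the QC overlay exists precisely because real images need
eyeballing.

## Numerical choices and conventions

* 0-based row/column indexing; areas in px²; centroids are arithmetic
  means of pixel coordinates; all lengths in pixels (physical pixel size
  is carried as untrusted metadata only).
* Foreground connectivity 8, background connectivity 4 (in hole filling)
  — the standard complementary pair.
* Binary operators treat pixels outside the raster as background.
  Closing is the plain dilate-then-erode composition on the raster, which
  is idempotent; a 3×3 median (despeckle) is guaranteed stable only on
  its fixed points, as 2-D medians do not converge in one pass.
* Particle labels are re-indexed contiguously from 1 in raster-scan order
  of each component's first pixel; reruns are byte-identical.
* Edge-touching objects are not excluded (the centroid rule handles
  them); exclusion was considered and left out as it changes N without
  changing the indices' interpretation.

## Problem sizes in the validation

The test suite and `scripts/acceptance.py` validate at sizes chosen to
exercise every code path while keeping a full run in minutes: 50–100
random 32–64 px masks per primitive oracle, 50 single-pair scenes for
watershed resolution, 10 default 512×512 scenes for detection rates, 20
scenes spanning ground-truth MDI 0.1–0.9 for index recovery, and 5+5
scenes for the group comparison. Errors scale with boundary-to-area
ratios, so these sizes are representative of larger fields.
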