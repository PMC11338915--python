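# Methods

## Model and assumptions

`lungctr` measures the cardiothoracic ratio from lung-field masks alone.
The underlying anatomical assumption is that on a postero-anterior (P-A)
chest radiograph the cardiac silhouette indents the medial border of both
lungs, so the heart's lateral extent can be read off the lung contours:
the heart's patient-right border E1 is the most midline-distant point of
the right lung's medial edge within the cardiac segment, and likewise E2
on the left. The thoracic diameter needs no such subtlety — it is the
span between the outermost lung-boundary columns D2′ and D3′. Then

    Δx1 = |x(E1) − x(E2)|,   Δx2 = |x(D2′) − x(D3′)|,   CTR = Δx1/Δx2.

Assumptions this rests on: the mask is a frontal (P-A) projection with
patient-right on image-left; the two lungs are separate connected
components (fused masks are rejected, not split); the cardiac indentation
is present on both medial borders (severe rotation, dextrocardia or
massive effusion break the construction — no attempt is made to detect
these); and all geometry is integer-pixel, matching pixel-unit error
reporting downstream. No subpixel smoothing is applied anywhere.

### Coordinate and naming conventions

0-based integer coordinates, origin at the top-left pixel center, x along
columns (rightward), y along rows (downward). Every "right/left" in the
API is PATIENT-side; the P-A mapping (patient-right = image-left) is
asserted once in `mask_io` and used everywhere. CTR and all derived
ratios are reported rounded half-up to 4 decimals.

## Pipeline

1. **Binarize** (`mask_io.read_mask`): foreground iff 8-bit luma >
   threshold (default 127 — any mid threshold works for the {0, 255}
   masks upstream segmenters emit).
2. **Component cleanup** (`lungfields`): 8-connected labeling; keep the
   two largest components with area ≥ `min_area_frac` (default 0.005) of
   the image; fill interior holes (cavitary lesions would otherwise
   corrupt boundary tracing). Side assignment defaults to centroid-x
   (patient-right = smaller centroid x); the literal "largest component
   is the right lung" area heuristic is available as
   `area_paper_literal` for fidelity experiments, since real lung areas
   can invert it.
3. **Boundary tracing** (`contours`): a boundary pixel is foreground
   with a background 4-neighbor (the image border counts as background).
   Moore-neighborhood following, clockwise in image coordinates,
   canonical start at the topmost-then-leftmost boundary pixel. Tracing
   is a deterministic map on (pixel, backtrack) states; we iterate until
   a state repeats and keep exactly that cycle, which is robust even
   when the conventional stopping heuristic's synthetic initial state
   lies off the cycle (observed on noisy boundaries). An on-pixel
   contour (not an inter-pixel crack) keeps every landmark on an actual
   mask pixel.
4. **Landmarks** (`landmarks`): apices (min y, ties medial),
   costophrenic angles (max y within the lateral half of the lung's
   x-span, ties lateral — the lateral-half restriction stops a
   low-hanging cardiac silhouette from stealing the corner),
   cardiophrenic angles (chord-distance argmax over the *medial*
   apex→costophrenic arc, ties inferior; an unrestricted argmax can land
   on the lateral chest wall), right hemi-diaphragm top (min y on the
   inferior costophrenic→cardiophrenic arc, ties lateral), thoracic
   extremes (global min/max boundary column, ties superior).
5. **Cardiac margin** (`landmarks.termination_point`,
   `locate_heart_border`): the search for E runs along the per-row
   medial edge between the cardiophrenic angle and a superior
   termination point C′. The termination row sits at fraction f
   (default 0.5) of the apex-to-cardiophrenic height above the angle; an
   absolute-row mode exists. E is the candidate maximizing perpendicular
   distance to the vertical midline O–O′, ties inferior.
6. **CTR** (`ctr_core.compute_ctr`): absolute differences, so the result
   does not depend on which side is subtracted; `dx2 = 0` is rejected as
   a degenerate thorax.

### The termination point C′

A horizontal line through the cardiophrenic angle re-intersects the
*same* lung only on its lateral edge, which cannot bound a medial
cardiac-margin search; a literal horizontal-line construction is
therefore degenerate. The fraction rule used here (f = 0.5 of the
apex-to-angle height) brackets the cardiac silhouette on both sides
while excluding the aortic knob and hilum on typical anatomy. On the
phantom family, any f in [0.4, 0.6] leaves E1/E2 unchanged because the
bulge extremum always sits below the termination row (asserted by test).

### Midline invariance

The midline O–O′ (a₀x + c₀ = 0, placed at the thoracic center
(x(D2′)+x(D3′))/2) appears in the E-point definition but cannot affect
it: all candidates lie strictly on one side, so argmax |x − x₀| is
argmin/argmax of x regardless of x₀. Candidates straddling the midline
are rejected as an input error ("midline inside lung"). The test suite
asserts invariance by sweeping three midlines.

## Phantom generator

The phantom emulates what a lung-field segmenter emits: two lung-shaped
components (default 512×512, thoracic span 400 px, heart span 180 px,
one-third of the heart on the patient-right side, in line with textbook
anatomy). Each outline is a closed analytic curve: a lateral sine-eased
wall from apex to costophrenic corner, a sine-arched diaphragm (default
peak 40 px), a two-parabola cardiac bulge whose extremal column realizes
the specified heart border, and a near-vertical mediastinal segment. The
cardiophrenic corner is placed just lateral of the mediastinum — the
anatomically sensible position near the midline — which also keeps the
chord-distance definition of C pointing at the corner rather than at the
mediastinal recess. Curves are densely sampled and scanline-filled;
outline pixels are added explicitly because scanline fill can drop thin
wedge tips at the corners.

Optional realism knobs, all seeded and reproducible: low-frequency
boundary jitter (≤ 4 px, applied along outward normals before
rasterization), spurious blobs (< 100 px, kept clear of the lungs) and
interior holes (< 50 px, ≥ 2 px inside the boundary). The blob/hole caps
sit strictly below the component-area floor at default canvas size, so
perturbations can never change the retained pair — an invariant the
tests assert.

**Ground truth is scanned, not analytic.** Truth landmarks are
recomputed from the rasterized (clean, post-jitter) mask by brute-force
numpy row/column scans (`phantom.oracle_keypoints`) that share no code
path with the contour-tracing pipeline. This removes rasterization
rounding from every comparison: truth and detection live on the same
pixel grid, and the oracle doubles as the independent test oracle.

What the phantom does **not** emulate: real radiographic intensity,
pathology beyond boundary jitter, fused or missing lungs, rotation or
dextrocardia. Passing tests therefore demonstrate the geometric
algorithm's correctness on well-formed two-lung masks, not segmentation
robustness on clinical images.

## Evaluation arithmetic

Key-point errors are signed column differences (detected − truth,
pixels); CTR errors are signed ratio differences. Summary aggregation
averages the *absolute* per-case values by default (signed means are an
option, since published summary tables do not always state which they
print): per-model mean over the four key points → per-set mean over
models → grand mean over sets → deviation degree = grand mean / image
width × 100. Every aggregate is rounded half-up at 4 decimals (2 for
the percentage) before reporting, which reproduces the published
benchmark aggregates exactly from their leaf values
(`lungctr.reference_tables`).

Segmentation scores are pixelwise confusion-matrix ratios plus HD95: the
symmetric (max of the two directed) 95th-percentile Euclidean distance
between the two masks' boundary pixel sets, computed with a KD-tree and
verified against a quadratic-time pairwise-distance oracle. Ratios with
empty denominators are reported as undefined (`None`), never 0/0.

## Numerical choices and tie-breaks

- Rounding: decimal half-up (0.02075 → 0.0208), not banker's rounding.
- All landmark tie-breaks are fixed and documented in the operation
  docstrings (apex medial, costophrenic lateral, C and E inferior-most,
  D2′/D3′ superior-most, D1 lateral); they make every search
  deterministic and mirror-consistent.
- Rows where a lung is one pixel wide give x_medial = x_lateral; allowed.
- Degenerate inputs raise typed errors naming the failing stage
  (`PipelineError`), never return partial results.

## Problem sizes used in the checks

The oracle-equivalence suite runs 100 seeded phantoms with canvases
drawn from {192, 256, 384, 512} (weighted toward the smaller sizes);
parameter recovery uses a 5×5 heart-width × thorax-width grid at
512×512; robustness uses 20 phantoms at 256×256 with 3 spurious blobs
and 2 holes each. Landmark agreement with the scan oracles is exact
(100 %) at every size tested, and recovered CTR error on clean phantoms
is 0 px-equivalent across the grid.

## Known limitations

- Fused lungs (single-component masks) are rejected, not separated.
- The costophrenic lateral-half and cardiophrenic medial-arc
  restrictions assume roughly upright, non-rotated anatomy.
- The fraction-based termination rule is a design choice where the
  original construction is ambiguous; extreme aortic unfolding could
  require a smaller f (it is configurable per run).
- HD95 is defined per mask pair; median-over-cases reporting is an
  aggregation-level choice left to the caller.
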