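# Methods

This note documents the models and procedures implemented in
`nucleomech`, the parameter defaults and why they were chosen, what the
synthetic phantoms do and do not emulate, and the design decisions taken
where the original macro-based workflows leave the procedure
under-specified.

## Auto-thresholds

Both histogram thresholds operate on a 256-bin histogram stretched over
the image min–max.  This reproduces classic 8-bit threshold behavior on
data of any bit depth and makes both thresholds equivariant under
intensity translation and scaling.  Foreground is always *strictly
above* the returned threshold (dark-background polarity).

**Iso-data ("Default") threshold.**  The intermeans fixed point
t = (mean below t + mean above t)/2, found by the classic iterative scan
from the low end of the occupied range.  The historical variant also
zeroes the two extreme bins (a workaround for saturated or erased
pixels); that behavior is available via `clip_ends=True` but is off by
default because it destroys genuine two-level histograms — e.g. an image
of values {10, 200} correctly thresholds at 105, the midpoint of the two
class means.

**Moment-preserving (Tsai) threshold.**  The binarization preserving the
image's first three gray-level moments: the two-level system is solved
in closed form for the below-threshold mass p₀, and the threshold is the
upper edge of the first histogram bin whose cumulative mass reaches p₀.
The "first bin reaching p₀" convention keeps the below-threshold
fraction equal to p₀ even for exactly symmetric histograms (where the
strict-inequality variant degenerates).  One consequence, asserted in
the tests: under intensity inversion the extreme gray levels swap
partition sides exactly, but the level adjacent to the cut stays in the
below set on both sides.

Both implementations are validated against exhaustive brute-force
solutions of their defining criteria (independent code paths: direct
per-candidate means for iso-data; `np.roots` on the moment quadratic for
Tsai) on randomized bimodal histograms.

## Nucleus segmentation

Pipeline: Gaussian filter (σ = 2 px) → iso-data threshold → binary hole
filling → distance-transform watershed → area/border filtering.

- **Watershed seeding.**  Seeds are h-maxima of the Euclidean distance
  transform after light Gaussian smoothing (σ = 1 px) of the transform.
  The smoothing removes ridge wiggles caused by boundary pixelation that
  would otherwise seed spurious splits; h = 4 px suppresses shallow
  secondary maxima while still separating tangent nuclei, whose merged
  distance map has a deep saddle.  Both are config keys.
- **Filters.**  Objects below 10 µm² are discarded (debris at the
  0.2 µm/px calibration of the phantoms is far smaller than any nucleus)
  and border-touching objects are removed by default because their shape
  descriptors are undefined; a flag keeps them for intensity-only use.
- Zero detected nuclei is a valid (empty-mask) result, not an error.

## Lamina detection and assignment

The lamina mask is the intersection of the Moments threshold of the raw
lamin image and the Moments threshold of a filtered copy.  The
gray-morphology step of the filtered route is a **white top-hat with a
4 px circular structuring element**: the top-hat isolates structures
thinner than the element — precisely the thin bright rim — while the
subsequent Gaussian (σ = 1 px) suppresses pixel noise.  Opening and
erosion variants remain available (`morphology_op`), as the historical
recipe does not name the operation.

Lamina components are split by the same distance watershed and each
component is assigned to the nucleus with which it shares the most
pixels (≥ 1 px required; ties go to the lower nucleus label for
determinism).  Components overlapping no nucleus are reported
separately, never silently dropped.  Intensity means are computed per
nucleus region and per assigned lamina region; an empty region yields a
missing value, never zero.  Background subtraction is off by default
(whether the original measurements subtracted background is unknown; the
option exists).

## Nuclear morphometry

From the label mask, via image moments: fitted-ellipse major/minor axes,
roundness = 4·A/(π·major²), axial length ratio = minor/major,
width-to-length = short/long side of the axis-aligned bounding box, and
solidity = A / convex-hull area.  "Axial length ratio" and
"width-to-length ratio" are deliberately distinct (fitted-ellipse vs
bounding-box); both are emitted so users can match whichever convention
their upstream software used.  Masks under 9 px are measured but flagged
unreliable and excluded from condition summaries (with the exclusion
count reported).  A single-nucleus condition reports SD as missing, not
zero.

**Lamin fragmentation index.**  The historical score is proprietary and
undefined; the reconstruction here counts connected components of lamin
signal inside the nuclear interior, where the interior is the **convex
hull** of the nucleus eroded by a peripheral band equal to the lamina's
own median ring width (estimated from its distance transform) plus a
2 px discretization margin.  The convex hull matters: an envelope
invagination carries the lamina *with* it, so eroding the invaginated
mask itself would always exclude the rim and score zero everywhere.
Invaginations are by definition intrusions into the convex interior, so
a smooth peripheral ring scores 0 while each infolding contributes one
fragment — validated by monotonicity against the generator's invagination
count (the index equals the generated count on the standard phantom).
Fragments under 4 px are ignored.

**Deformed/normal rule.**  No published criterion exists; the default
rule is fragmentation index ≥ 1 OR roundness < 0.6 OR solidity < 0.92,
fully config-driven, and every report embeds the thresholds actually
used.  On synthetic cohorts mixing smooth and invaginated nuclei the
rule recovers the generating deformed fraction within binomial sampling
error.

## Focal adhesions and YAP-TAZ ratio

- **Best plane.**  Focus score = normalized variance (variance/mean²) per
  z-plane, robust to brightness differences between planes; ties go to
  the lowest index and the full score table is emitted.
- **Particles.**  Moments threshold → connected components → minimum
  particle size 25 px².  The historical "Moments (value 25)" setting is
  read as this particle-size cutoff — the common macro idiom — and is
  exposed as `min_area_px` so the alternative reading (threshold offset)
  is one config change.  Areas are emitted in px² and µm².
- **YAP-TAZ N/C ratio.**  The manual equal-area-ROI protocol is
  operationalized deterministically: the nuclear region keeps the A
  innermost nucleus pixels (ranked by distance to the nuclear boundary,
  flat-index tie-break), the cytoplasmic band keeps the A nearest pixels
  outside the nucleus, excluding other nuclei and the image border;
  A = 50% of the nucleus area by default.  If the band cannot reach A
  the error reports the achieved area.  User-supplied region masks are
  accepted for fidelity to manually drawn ROIs.  The ratio is invariant
  to intensity scaling but *not* to additive offsets (an offset pulls
  ratios toward 1 — asserted in the tests), so offsets must be removed
  upstream if present.

## AFM Hertz fitting

Model: F = (4/3)·E/(1−ν²)·√(R·δ³) for a rigid sphere on an elastic
half-space; ν = 0.5 (incompressible cell), R = 5 µm (10 µm bead),
cantilever k = 0.03 N/m for raw (z, deflection) input.  Only samples
with 0 < δ − δ₀ ≤ 0.5 µm and F − baseline ≤ 2 nN are fitted — the
shallow-indentation regime where the half-space approximation holds and
substrate contributions are small — and the fit asserts that no used
point violates either gate.

**Contact point.**  Not specified by vendor workflows in any standard
way; the procedure here is deterministic: baseline = median of the
leading 20% of samples, detection when the force exceeds baseline +
5 robust SDs (MAD-based; floored at 10⁻⁶ of the force span so noiseless
curves remain detectable), then linear back-extrapolation of the rising
flank to the baseline.  Because threshold crossing detects contact
*late* (the force must clear the noise floor first), δ₀ is subsequently
refined jointly with E by least squares, bounded to back up at most one
depth gate and advance at most 10 sample spacings; gating and fitting
iterate (≤ 5 times) until the gated sample set is stable.  Fixing δ₀ at
the detected crossing is available via `refine_contact=False`.

**Numerics.**  The closed-form regression of force on δ^{3/2} seeds E.
The least-squares problem is nondimensionalized (E in units of the seed,
δ₀ offset in sample spacings, residuals in units of the gated force
range): raw SI units put forces at ~10⁻⁹ N and make absolute optimizer
tolerances meaningless — the unscaled problem terminates at the start
point.  With scaling, noiseless round trips recover E to machine
precision and noisy recovery (2% of peak force) is unbiased to < 0.5%
across 0.5–5 kPa.  The fit is unweighted, matching the absence of any
stated noise model.  Condition summaries report n, median, quartiles and
mean ± SD of converged fits, counting exclusions.

## Synthetic phantoms

The generators emulate the *statistical structure the analysis assumes*,
with exact ground truth emitted before blur and noise:

- **Nuclei**: ellipses (semi-axes ~22–42 px at 0.2 µm/px, i.e. 9–17 µm
  diameters, typical of adherent human cell lines), lamina rim of 3 px
  traced by morphological erosion, interior/rim/background intensities
  1200/3000/100 a.u., Gaussian PSF σ = 1 px, additive Gaussian noise.
  Envelope invaginations are inward circular-segment bites at equally
  spaced jittered boundary angles with one depth knob (fraction of the
  minor semi-axis, ≤ 0.8 so the region stays simply connected).  The
  real morphology of nuclear invaginations is not published in any form
  usable here; the bite model is a stand-in whose virtue is exact,
  parameterized truth.
- **Adhesion fields**: disjoint bright ellipses (semi-axes 4–10 px)
  inside a cell footprint, rejection-sampled with a 3 px clearance;
  optional 3-plane stacks with defocused neighbours.
- **YAP cells**: nucleus-in-cell geometry with Normal(nuclear_mean, σ)
  and Normal(cytoplasm_mean, σ) compartments on zero background, with a
  clearance check guaranteeing the cytoplasmic band fits.
- **Force curves**: exact Hertz forward model (shared with the fitting
  module, so forward/inverse consistency is by construction) plus
  baseline offset, contact shift (0.2 µm), 0.5 µm of pre-contact travel,
  up to 1 µm of post-contact ramp sampled at 600 points, and — as on the
  instrument — truncation of the ramp at the 2 nN force threshold.

Not modeled: photon (Poisson) noise, 3-D PSFs, chromatic shifts, uneven
illumination, cell-to-cell intensity variation, cantilever drift or
viscoelastic response.  Passing the recovery tests therefore shows the
algorithms are correct and well-conditioned on data satisfying their
assumptions; it does not certify performance on real microscope or AFM
data, where those effects dominate failure modes.

## Study-scale validation

The acceptance computations use: 5 noiseless + 200 noisy force curves
across 0.5–10 kPa; 100 random bimodal histograms for the threshold
oracles; 20 scenes of 1–10 nuclei at up to 10%-of-range noise (512² px)
for segmentation; a 200-nucleus cohort at generating deformed fraction
0.5; one 50-particle adhesion field; four YAP ratios at 5% noise; and a
duplicate end-to-end pipeline run compared byte-for-byte.  These sizes
give binomial/bootstrap error bars comfortably inside the asserted
tolerances while keeping a full validation run in tens of seconds on one
CPU.

## Determinism

Every generator is a pure function of (spec, seed); all pipeline
randomness derives from one seeded generator; outputs carry no
timestamps; label masks, CSVs, JSON and TIFFs are byte-reproducible.
The run report records config, seeds and SHA-256 digests of every
output so reruns can be verified exactly.
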