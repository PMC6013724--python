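# Methods

This note documents the models, conventions and numerical choices behind
`mfc-sholl`, the defaults and why they were chosen, what the synthetic data
emulate (and what they do not), and the package's known limitations.

## Chamber model and coordinate conventions

The package models a compartmentalized microfluidic chamber as one
microgroove band of physical width `groove_length_um` (default 500 μm)
separating two axonal compartments; the columns bounding the band are the
*microgroove exits*. (In the physical tripartite device the somatic main
channel sits between two groove arrays; for the image analysis only the
exits and the flanking compartments matter, so the band is treated as one
block and somata are carried in a separate marker channel.)

Conventions, fixed once and used everywhere:

- pixel indices are 0-based; zone intervals are half-open `[x_start, x_end)`;
- a positive rotation angle means the chamber appears rotated
  counter-clockwise in the image; aligning rotates the content back;
- distance 0 is the microgroove exit on *both* sides — the left compartment's
  distance axis is mirrored so both compartments plot on one axis;
- foreground connectivity is 8-connectivity, everywhere;
- every μm→px conversion goes through `config.um_to_px`.

## Rotation estimation (Hough)

Edges are pixels whose Sobel gradient magnitude exceeds the 0.95 quantile
(`edge_quantile`). For each candidate angle a straight-line Hough transform
is evaluated at the two near-axis orientations the chamber generates
(vertical: exits and walls; horizontal: groove walls), and the score is the
mean of the strongest accumulator bins — votes concentrating onto few
straight lines. A coarse pass at 0.5° over ±`rotation_half_range_deg`
(default ±15°, an assumption: chambers are imaged near-axis) is refined at
`rotation_resolution_deg` (default 0.05°, well below the tolerance that
grid-line placement at 50 μm spacing demands). Ties break toward the
smallest |angle|. A constant image raises a degenerate-input error; if no
orientation scores at least 1.5× the median score (unstructured texture),
alignment fails with a diagnostic error.

Rotation of channels expands the canvas (the template stays centered),
bilinear for intensity channels and nearest-neighbor (binary-safe) for
masks; angle 0 is an exact identity.

## Zone location

On the aligned phase channel, the per-column sum of |horizontal Sobel|
measures vertical-edge strength. Candidate lines are its significant peaks
(prominence-filtered, and at least 1.3× the median column strength — random
texture never qualifies, which is what makes uniform noise fail cleanly).
The groove band is the pair of peaks whose separation best matches
`groove_length_um` within ±10% (`band_tolerance_frac`); each analysis zone
extends from its exit outward to the nearest strong vertical edge (the
compartment wall) or, if none is found, to the image border minus a 10 px
guard. Equivariance holds: shifting the image shifts all boundaries equally.

## Axon segmentation and skeletonization

The zone is first denoised with a small Gaussian (`seg_presmooth_um`,
default 1.0 μm) — this stabilizes the mask boundary so the skeleton does
not wobble across grid columns. A pixel is foreground iff its intensity
exceeds the local mean over an odd window (`seg_block_size_um`, default
51 μm) by `seg_offset_frac` (default 0.05) × the zone's 1st–99th percentile
range. Local-mean thresholding makes the mask invariant to constant offsets
and robust to illumination ramps; the percentile range makes the offset
scale with actual signal contrast. Components under `seg_min_area_um2`
(default 20 μm²) are removed — this kills noise speckle while keeping thin
axon fragments, and can be set to 0.

Masks are thinned with a topology-preserving skeletonization. The contract
is the output's properties, not the algorithm: the skeleton is a subset of
the mask, nowhere 3×3-solid (one pixel wide), and never has more
8-connected components than the mask. These are enforced by property tests
over hundreds of random masks.

## Linear Sholl readout

Grid lines sit at `first_line_um + k · grid_spacing_um` from the exit
(defaults 100 and 50 μm; the 50 μm line is omitted because axonal density
and post-axotomy debris at the exits corrupt it — set
`omit_debris_line: false` and `first_line_um: 50` to recover it). The pixel
column for distance *d* is the exit column ± `round_half_away_from_exit
(d / pixel_size)`; a grid line is exactly one pixel column (any thickness
would inflate pixel counts arbitrarily), and lines falling outside the zone
are dropped, not clamped.

Two counting modes exist because the readout can be defined either way:
`pixels` counts foreground skeleton pixels in the column; `runs` (default)
counts maximal vertically contiguous runs, so one transversal crossing is
one intersection regardless of slope. `pixels ≥ runs` always holds.

Normalization divides counts by the soma count. `normalized` is always the
correctly rounded quotient of the stored integers — rounding
`normalized × soma_count` recovers every count exactly. (Bit-exact float
equality of the product is unattainable for non-dyadic ratios: no double
`q` satisfies `q × 194 == 28`.)

## Soma counting

The counting procedure is deliberately simple and fully documented, with a
manual override as a first-class citizen (normalization correctness matters
more than detection elegance): Gaussian smoothing (5 μm) → Otsu threshold →
watershed split seeded at distance-transform maxima (minimum seed
separation = radius of the smallest acceptable soma) → area gate 80–800 μm²
(somata of ~10–30 μm diameter). Detection is invariant to constant
intensity offsets; a blank channel yields count 0 with a warning, never an
error. An optional nuclei channel can gate detections (off by default).

## Statistics

Treatments are compared with a two-way mixed (split-plot) repeated-measures
ANOVA: treatment between subjects, grid-line distance within subjects. The
*subject* is design-driven: a chamber when both compartments share one
treatment, a compartment side when the two compartments of one chamber
receive different treatments — encoded in the design mapping, never guessed
at runtime. Distance bins of one profile are strongly autocorrelated, so
sphericity cannot be assumed: the within-subject tests are reported both
raw and Greenhouse–Geisser-corrected, with ε computed from the pooled
within-group covariance (clamped to [1/(d−1), 1]). The implementation is a
direct sums-of-squares decomposition; tests verify it against an
independent brute-force decomposition (1e-9 relative) and against
`pingouin.mixed_anova` (SS, F and uncorrected p to 1e-9; pingouin pools the
covariance across groups differently, so ε is checked against its own
eigenvalue formula instead). Monte-Carlo calibration over 1000 null
experiments shows the nominal α = 0.05 is honest (empirical rate ≈ 0.045).

Aggregation reports mean ± SEM (sample SD/√n) per treatment and distance;
with a single subject the SEM is reported as 0 with an explicit warning
rather than NaN. The per-treatment median of the outermost grid line with
intersections uses the lower of the two central values for even counts —
grid distances are discrete, so interpolated medians would be fictitious.

## Synthetic chambers and ground truth

The generator renders, at 1.3 μm/px (a typical 10× wide-field sampling):

- a phase channel with chamber walls, the groove band (horizontal groove
  walls every 50 μm) and strong vertical exit lines;
- an axon channel with ~30 axons per side, drawn as persistent random walks
  starting at groove exits: heading steps are Gaussian (σ = 18°) and
  clamped strictly inside ±78° of the outward axis, so every step advances
  outward and *no segment can parallel a grid line* — all crossings are
  transversal, and the exact per-line crossing count is the number of sign
  changes of `x − d` along each polyline (endpoint-on-line excluded, a
  vertex-on-line crossing counted iff the polyline continues to the other
  side). Axons are drawn at 1.5 px FWHM so skeletonization recovers the
  centerline faithfully;
- a soma channel with (default) 120 non-overlapping disks of 6–11 μm radius
  in a central main-channel strip, optionally with a fraction placed as
  near-touching pairs to exercise blob splitting;
- rotation by the true angle, then Gaussian read noise (σ = 25 on an axon
  amplitude of 600) and optional shot noise and background ramp.

All randomness flows from one seed through separate sub-streams for axons,
somata and noise, so toggling the noise does not change the geometry; a
fixed seed is bit-reproducible.

What the synthetic data do *not* emulate: optics (PSF, depth blur),
stitching seams and vignetting, axon fasciculation and branching,
debris, and treatment-dependent growth kinetics. Passing recovery tests
therefore demonstrates the correctness of the measurement chain on
known geometry — not segmentation performance on real, messier
fluorescence data, where the exposed thresholding parameters will need
adjustment.

## Problem sizes and measured behavior

The validation batches use 50 chambers for rotation/zone recovery, 100
polyline sets for the counting oracle, 20 full pipeline runs for
end-to-end recovery and 1000 simulated experiments for ANOVA calibration —
sizes at which the measured rates are stable across seeds. Typical results
(see `scripts/acceptance.py`): rotation recovered to ≤0.2° in 100% of
chambers (MAE ≈ 0.01°), exits localized to ≤ ~2 px, end-to-end per-line
crossing recovery with ~13% mean absolute relative error over lines with
≥5 true crossings, soma counts within 5% on ≥95% of chambers.

Two discretization effects bound what per-line agreement can mean:

- a pixel column represents the physical distance `col × pixel_size`, not
  the nominal grid distance, and a polyline *ending* within half a pixel of
  a column is inherently ambiguous — the counting oracle is therefore
  evaluated at the column's physical distance, with one count of slack per
  ambiguous endpoint;
- on the *combined* skeleton of many axons, two crossings passing a column
  within a pixel of each other merge into one run. This is a property of
  the scene (it would happen to any skeleton-based counter), grows with
  axon density, and is the main contributor to the ~13% end-to-end error at
  the dense inner grid lines.

## Known limitations

- Perspective/affine distortion, flat-field correction and stitching are
  out of scope; inputs are assumed pre-stitched single-plane TIFFs.
- No gap closing across broken axon segments and no per-axon tracing; an
  axon fragmented by weak staining counts once per fragment crossing.
- The adaptive-threshold defaults were calibrated on the synthetic
  fixtures; real data will need per-dataset tuning of `seg_offset_frac`
  and `seg_block_size_um`.
- Whether the original readout counted raw pixels or contiguous runs is
  ambiguous; both are implemented (`intersection_mode`), with `runs` as the
  default since "intersections" is the quantity named throughout.
- Normalization uses one soma count per chamber for both compartments.
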