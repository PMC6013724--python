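# mfc-sholl

Linear Sholl analysis of axonal outgrowth in compartmentalized microfluidic
chambers (MFCs).

## The problem

In a tripartite MFC, neuronal somata sit in a central main channel and extend
axons through 500 μm microgrooves into two fluidically isolated axonal
compartments. Quantifying axonal outgrowth there needs a *linear* analogue of
the classical concentric-circle Sholl analysis: vertical grid lines are drawn
at fixed 50 μm increments from the microgroove exits, the number of axonal
intersections with each line is counted, and counts are normalized by the
number of neurons in the main channel. The resulting profile

*I(d) = (axonal intersections at distance d from the exits) / (NeuN⁺ neurons)*

is the per-neuron outgrowth readout; its decay with *d* and the outermost
grid line still harboring intersections summarize total outgrowth and
pioneering-axon elongation. `mfc-sholl` implements the whole image-analysis
chain for stitched wide-field images of a chamber plus the statistics used to
compare treatment groups:

1. **Alignment** — a straight-line Hough transform of the phase-contrast
   channel estimates the chamber's in-plane rotation (the chamber walls and
   the parallel microgroove array dominate the edge map); all channels are
   rotated to axis alignment and the two analysis zones flanking the groove
   band are located from the dominant vertical edges.
2. **Segmentation** — fluorescent axons are binarized with an adaptive (local
   mean) threshold, robust to uneven illumination, and small debris is
   removed.
3. **Skeletonization** — masks are thinned to one-pixel-wide centerlines.
4. **Linear Sholl readout** — intersections are counted per grid line (as
   contiguous runs, or raw pixels) with distance 0 at the microgroove exit on
   both sides; the 50 μm line is skipped by default because axotomy debris
   accumulates at the exits. Counts are normalized by an automatic (or
   manual) soma count.
5. **Statistics** — profiles from replicate chambers are aggregated as
   mean ± SEM and compared with a two-way mixed repeated-measures ANOVA
   (treatment × distance, Greenhouse–Geisser-corrected within-subject
   tests), plus the per-treatment median of the outermost grid line.

Because no public chamber images exist, the package ships a first-class
synthetic-chamber generator (`mfcsholl.synthetic`) that renders the rotated
chamber template, curvilinear axons with analytically known grid-line
crossings, and somata with a known count — ground truth for every stage.

## Worked example

Simulate one chamber rotated by −3.5° and analyze it:

```
$ mfc-sholl simulate --out-prefix demo --seed 42 --rotation-deg -3.5
wrote demo.tif (planes ['phase', 'axon_fluor', 'soma_marker']) and demo_truth.json

$ mfc-sholl sholl demo.tif --soma-plane 2 --out demo_profiles.csv
demo left: [21, 21, 18, 18, 12, 11, 12, 12, 8, 9, 8, 9, 5, 5, 5, 5, 0, 4] (soma_count=120, outermost=950.0)
demo right: [24, 21, 21, 18, 19, 15, 14, 13, 9, 9, 7, 6, 7, 4, 4, 2, 3, 3] (soma_count=120, outermost=950.0)
```

Each list is the intersection count per grid line at 100, 150, …, 950 μm
from the microgroove exit for one compartment; 120 somata were detected in
the main channel (the generator planted 120), and the outermost line with
intersections lies at 950 μm. The CSV holds one row per grid line:

```
chamber_id,side,distance_um,intersections,normalized,soma_count,intersection_mode
demo,left,100.0,21,0.175,120,runs
demo,left,150.0,21,0.175,120,runs
```

`normalized` is intersections per neuron. With profiles from several
chambers and a design file mapping chambers (or compartment sides) to
treatments, `mfc-sholl compare profiles.csv --design design.yaml` runs the
mixed ANOVA and reports per-effect F, degrees of freedom and raw +
Greenhouse–Geisser p-values; `mfc-sholl run-all` chains everything over a
batch of images and writes a reproducible run manifest.

The same operations are available as a library:

```python
from mfcsholl import PipelineConfig, SyntheticSpec, analyze_chamber, generate_chamber

image, truth = generate_chamber(SyntheticSpec(seed=42, rotation_deg=-3.5))
analysis = analyze_chamber(image, PipelineConfig(), chamber_id="demo")
left, right = analysis.profiles
```

## Layout

```
src/mfcsholl/
  config.py        pipeline parameters; the single μm→px conversion utility
  image_io.py      TIFF reading, profile CSV writing/reading
  alignment.py     Hough rotation estimate, channel rotation, zone location
  segmentation.py  adaptive thresholding, skeletonization
  sholl.py         grid lines, intersection counting, normalization
  soma.py          soma counting (auto + manual override)
  stats.py         aggregation, mixed RM-ANOVA, median outermost line
  synthetic.py     synthetic chamber generator + exact crossing oracle
  pipeline.py      one-call chamber analysis
  cli.py           `mfc-sholl` command-line interface
```

See `docs/methods.md` for the method description, parameter defaults and
known limitations.
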