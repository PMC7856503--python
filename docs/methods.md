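# Methods

## The measurement model

A portal image is treated as a calibrated 2-D signal grid proportional to
delivered dose (vendor calibration — dark/flood field, gain, bad-pixel
correction — is assumed already applied by the acquisition software). All
geometry is expressed at the isocenter plane: a detector pixel of spacing
`p` at source-to-detector distance SDD maps to `p · SAD/SDD` mm at
isocenter (0.4 mm at SDD 1600 mm → 0.25 mm; 0.39 mm at SDD = SAD 1000 mm
→ 0.39 mm). Because export pipelines may apply an arbitrary constant
scaling, every dosimetric quantity is used only as a ratio to a baseline
acquired with the same pipeline; a constant factor cancels exactly (this
is also why a deliberate global gain drift moves *only* the output
deviation, a property the test suite asserts).

Coordinate convention (fixed once, used everywhere): 0-based pixel
indices, a pixel's position is its center, origin at the geometric center
of the grid, X = crossline (columns, +x right), Y = inline (rows, +y
toward the gantry). iViewGT-style raw TIFFs may encode dose inversely;
polarity is detected by comparing a central 40 × 40 px mean against a
10 px border frame and inverted (`max − value`) when the border is
brighter, with the action logged. TIFFs carry no geometry tags, so
missing machine-profile geometry is a hard error rather than a silent
default.

## Edge detection

For a smooth penumbra, "first derivative extremal and second derivative
zero" is the analytic definition of the profile's inflection point, the
standard radiological field edge. On sampled data:

1. average 10 adjacent rows (columns) through the field center — 2.5 mm
   at the default raster — to suppress pixel noise;
2. smooth with a Gaussian of σ = 2 samples and take central differences
   (`numpy.gradient`);
3. the rising edge is the derivative maximum, the falling edge the
   minimum; each is refined by a three-point parabola through the
   derivative at the extremal sample and its neighbours.

The smoothing width is a bias/variance trade-off measured on synthetic
fields: the kernel is symmetric, so it does not displace the symmetric
penumbra inflection (noiseless recovery bias stays ≈ 0.015 mm, far below
half a pixel), while at σ = 1 sample the sub-pixel refinement is
noticeably noise-sensitive (at 0.5 % signal-proportional noise, ~8 % of
replicates moved the size estimate by more than one pixel; at σ = 2
samples none of 200 did, 95th percentile 0.08 mm). Tied derivative
extrema (degenerate, essentially noiseless plateaus) resolve to the
candidate nearest the provisional center and are logged.

Field geometry is a two-pass procedure: pass 1 extracts profiles through
the grid center and yields a provisional center; pass 2 re-extracts the
profile bands through that center and re-detects. A center moving more
than 2 px between passes produces a warning (the pass-2 result is still
returned). The field center is the midpoint of opposing edges per axis —
for a rectangular field exactly the intersection of the diagonals.

`Dcenter` in the flatness/symmetry denominators is the profile value
linearly interpolated at the detected field center, not the profile
maximum; this is the standard reading and remains well-defined for
centrally peaked FFF beams. Flatness is not reported for FFF beams.
Symmetry pairs every in-region sample with the linearly interpolated
value at its mirror position about the center and takes the maximum
imbalance.

## Baseline comparison

Output and beam quality compare as ratios expressed as percent-from-100
(`daily/baseline × 100 − 100`); W ratio rather than difference was chosen
because W is itself a ratio and a gain drift must cancel in it. F and S
compare as absolute percentage-point differences, size and center as mm
differences. Default tolerances: output ±2.5 % (deliberately tighter than
the generic 3 % daily bound — a flat-panel ROI mean fluctuates slightly
more shot-to-shot than an ion chamber, so headroom is given back to the
clinic), BQ 2 %, F/S 2 points, size 2 mm, center 2 mm; all overridable in
the config. Baselines are one human-diffable JSON document per
machine + beam, valid 365 days; an expired baseline flags the report
`stale_baseline` but comparisons are still computed, since the flag, not
a refusal, is the auditable signal.

## Synthetic beams

The generator emulates the daily acquisition geometry (default: 640 × 640
detector pixels of 0.4 mm at SDD 1600 / SAD 1000, i.e. 0.25 mm isocenter
pixels over a 160 mm span; 10 cm × 10 cm field; 100 MU):

    signal(x, y) = offset + MU · gain · Px(x) · Py(y) · M(x, y) · T(x) + ε

- `Px`, `Py`: top-hats with logistic edges of scale σ (default 1.5 mm) at
  ±field/2 + shift. The logistic was chosen over an error function for
  analytic simplicity; its inflection is exactly the nominal edge, which
  makes half-pixel recovery bounds meaningful.
- FF modulation: separable quadratic horns `(1 + a·(2x/field)²)`,
  default a = 0.02 — ≈ 1.15 % flatness, a plausible flattened 6 MV value.
- FFF modulation: cone `max(0, 1 − 0.004/mm · r)`, giving the
  characteristic centrally peaked profile; the default falloff makes a
  15 mm ROI displacement clearly distinguishable from ≤ 10 mm ones.
- Wedge: `T(x) = 0.55 · exp(−0.012/mm · x)`; the central transmission
  0.55 puts W near a typical 60° wedge factor, the gradient gives a
  visible transverse tilt. Both are model knobs, not claims about a real
  wedge.
- Noise: i.i.d. Gaussian with SD = `noise_frac` × local deterministic
  signal, seeded through `numpy.random.default_rng`; images are
  bit-reproducible per seed, series derive per-image child seeds from a
  `SeedSequence`.

Each image carries a ground-truth record: true edges, center, size, the
expected central-ROI mean (the analytic model averaged on a fine sub-grid
independent of the pixel raster) and the true wedge factor (ratio of
analytic ROI means with and without the wedge — the same definition the
analyzer measures).

What the generator does *not* model: scatter, off-axis energy response,
detector glare/ghosting, saturation, beam spectrum, pixel defects.
Passing tests therefore demonstrate the correctness and numerical
stability of the *analysis* under the stated beam shapes and noise, not
clinical accuracy on any particular EPID; on real panels the absolute F/S
values in particular depend on the detector's off-axis response and are
meaningful as trends only.

### Property domains (documented grids)

- Closure (size/center within half a pixel, noiseless): field sizes
  {40, 100, 200} mm × penumbra σ {1, 2, 4} mm × shifts up to (−10, +5)
  mm, hornless. Horns are excluded because a horn modulation `H`
  displaces the physical inflection by ≈ 4σ²·H′/H (up to +0.2 mm at a
  40 mm field with σ = 4 mm): the detector reads the delivered profile
  correctly; the profile itself moves.
- Flatness floor ≤ 0.1 % (hornless FF): sizes ≥ 80 mm with σ = 1 mm. A
  logistic edge leaks ≈ `expit(−0.1·size/σ)` into the 80 % region
  boundary, so sharper penumbrae or larger fields are required for a
  sub-0.1 % floor; at the defaults (σ = 1.5 mm, 100 mm) the floor is
  ≈ 0.13 %, which is why the grid pins σ = 1 mm.
- Noise robustness: 200 seeded replicates at 0.5 % noise; the size
  estimate moves < 1 pixel from its noiseless value in ≥ 95 % (measured:
  all) of them.

## Validation experiment sizes

The validation experiments run at the sizes a desk reproduction supports
and the suite re-runs in seconds: the adjacent-field-size series uses the
seven square fields 94–106 mm (six 2.00 mm steps per axis, noiseless);
linearity uses the 27-beam MU ladder (1–300 MU) with four 1 %-noise
replicates and the 8-beam 10–600 MU ladder noiseless; shift sensitivity
scans the 13-offset ladder (1–10, 15, 20, 30 mm) in four cardinal
directions. Long-series stability (multi-month drift, collimator-pair
tracking over weeks) reduces here to the mean/SD summary operating on
whatever series the user collects.

## Numerical details and degenerate inputs

- Parabolic refinement clips its sub-pixel shift to ±1 sample; a
  vanishing curvature denominator falls back to the grid extremum.
- Profiles require ≥ 16 samples, uniform spacing (1 nm tolerance),
  finite non-negative values.
- ROI membership is strict (`|x − c| < side/2`), so a 10 mm ROI centered
  between pixels of a 0.25 mm grid selects exactly 40 × 40 pixels; an
  ROI extending past the detector is a geometry error (flagged, not
  fatal, inside the sensitivity scan).
- A monotone profile (no plateau), derivative extrema in the wrong order
  or at the profile boundary raise a detection error naming the side.
- `Dcenter ≤ 0`, non-positive μ or doses raise numeric errors rather
  than returning infinities.
- Wedge/open consistency: a wedge field size differing from the open
  field by > 5 mm aborts the acquisition analysis. The wedge ROI is read
  at the open image's detected center: the wedge gradient biases the
  derivative-based center of the wedge image by ≈ 4·gradient·σ²
  (≈ 0.1 mm at the defaults), and reading both ROIs at one well-defined
  center keeps W free of that bias — consistent with how setup-error
  sensitivity displaces both ROIs identically.

## Known limitations

- The depth-dose beam-quality ratio D20/D10 is a bookkeeping utility for
  cross-validation against water-tank measurements; no depth-dose
  modelling is attempted.
- Electron beams, ghosting/saturation corrections, trending dashboards
  and multi-user record systems are out of scope.
- The 16-bit TIFF fixture writer quantizes to integers; round-trip
  equality holds at the written (rounded) values.
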