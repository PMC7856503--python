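# epidqa

Daily quality assurance of a medical linear accelerator (LINAC) from two
portal images.

Morning QA on a busy LINAC must fit a minutes-long window. Instead of
setting up a dedicated QA phantom, `epidqa` reads the machine's own
electronic portal imaging device (EPID): one 10 cm × 10 cm open field and
the same field through a 60° wedge, each delivered with 100 MU, are enough
to monitor every TG-142 daily photon parameter — output constancy, beam
quality, flatness, symmetry, field size and field center — as day-to-day
*trends* against a benchmark acquired with the machine in its best state.
It works for flattened (FF) and flattening-filter-free (FFF) beams and is
vendor-independent: it reads iViewGT-style 16-bit TIFF exports (geometry
supplied by a machine profile) and TrueBeam-style DICOM RT Image exports
(geometry read from the file).

## Metrics

All positions are mm at the isocenter plane (detector spacing × SAD/SDD).
With μ the mean signal of the central 10 mm × 10 mm region of interest
(40 × 40 pixels at 0.25 mm spacing) and D(·) a beam profile averaged over
10 rows/columns through the field center:

- **Output**: μ of the open image, as a ratio to baseline.
- **Beam quality**: wedge factor W = μ_wedge / μ_open. An energy drift
  changes the wedge transmission, so W tracks beam quality while a pure
  output drift cancels in the ratio.
- **Flatness** F = (Dmax − Dmin)/Dcenter × 100 % and **symmetry**
  S = max |D(c+d) − D(c−d)|/Dcenter × 100 %, both over the central 80 % of
  the field (F is not reported for FFF beams).
- **Field edges** at the extremum of the profile's first derivative (the
  penumbra inflection), refined to sub-pixel precision by a three-point
  parabola on the derivative; sizes are edge-to-edge distances, the center
  is the midpoint of opposing edges.

A daily run compares each metric to the stored baseline (output and W as
percent-from-100 ratios, F/S as absolute percentage-point differences,
size/center in mm) under configurable tolerances, ±2.5 % for output by
default.

A synthetic portal-image generator (logistic-penumbra top-hat beams with
FF horns, FFF cone falloff, exponential wedge transmission and
signal-proportional noise) provides exact ground truth for every analysis
step, so the whole chain is testable without hardware.

## Worked example

```sh
# write a noiseless synthetic open + wedge pair as TIFF, with ground truth
epidqa simulate --out-dir fixtures --format tiff

# freeze the benchmark
epidqa baseline fixtures/open.tif --wedge fixtures/wedge.tif \
    --machine synergy1 --config config.yaml --out baseline.json --date 2026-01-05
```

with `config.yaml` declaring the detector geometry for the TIFF dialect:

```yaml
machines:
  synergy1: {pixel_spacing_detector: 0.4, sdd: 1600, sad: 1000}
```

prints the frozen metric set:

```
baseline written to baseline.json (valid until 2027-01-05)
         mu_open: 10051.3200
      symmetry_x: 0.0000
      symmetry_y: 0.0000
          size_x: 100.0147
          size_y: 100.0147
        center_x: 0.0000
        center_y: 0.0000
      flatness_x: 1.1542
      flatness_y: 1.1542
        mu_wedge: 5554.0238
    wedge_factor: 0.5526
```

i.e. a 100 mm field recovered to 0.015 mm, a 1.15 % flat-beam flatness
from the 2 % horns, and a wedge factor of 0.55 (the generator's central
wedge transmission). The daily check against that baseline

```sh
epidqa daily fixtures/open.tif --wedge fixtures/wedge.tif \
    --machine synergy1 --config config.yaml --baseline baseline.json
```

prints one deviation per parameter and `QA PASS`, exiting 0 (1 = out of
tolerance, 2 = error), so it can gate the morning treatment start from a
shell script. `epidqa experiment {linearity,sensitivity,size-series,
collimator-center}` runs the validation experiments on synthetic series
and writes CSV.

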