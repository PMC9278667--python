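# atcmlab

Phantom-based evaluation of CT **automatic tube current modulation**
(ATCM). Modern CT scanners continuously adapt the tube current (mA) — and
hence the per-rotation dose, CTDI<sub>vol</sub> — to the attenuation of the
object being scanned. How a given scanner does this is proprietary, but it
can be probed with QC phantoms: scan a phantom of known geometry in both
directions, extract the per-slice CTDI<sub>vol</sub> from the DICOM
headers, compute the water-equivalent diameter (WED) of every slice, and
model the dose response. `atcmlab` implements that entire workflow for
medical physicists, together with a synthetic scanner so every stage is
testable without scanner data.

## The model

For a slice at table position *z*, the dose is modelled as responding to
the attenuation *ahead* of the table in the scanning direction:

```
CTDIvol(z) = a · exp(b · f(WED; z, d)) + c
f(WED; z, d) = w1·max + w2·Q3 + w3·median + w4·min      (over the d slices ahead)
w1 + w2 + w3 + w4 = 1,  wi ≥ 0
```

The lookahead depth `d` (an integer number of reconstruction slices) is
found by grid search; for each candidate `d` the continuous parameters
`(a, b, c, w)` are fitted by constrained nonlinear least squares (softmax
parameterization keeps the weights on the probability simplex). Because the
window looks *ahead*, head-to-feet (HF) and feet-to-head (FH) scans of the
same phantom give different modulation curves — mirror images on a
symmetric phantom — even though their total dose (DLP) is essentially
identical. The fitted `d` grows with helical pitch, reflecting the larger
effective beam width.

## What is in the box

| module        | role                                                                  |
|---------------|-----------------------------------------------------------------------|
| `phantoms`    | geometry of the four QC phantoms (multi-diameter polyethylene phantom; three PMMA dosimetry-phantom configurations), HU rasterization, closed-form WED profiles |
| `wed`         | water-equivalent diameter from HU images, per-series WED profiles     |
| `atcm_sim`    | forward ATCM simulator: WED profile + protocol → mA/CTDI<sub>vol</sub> series and noisy slice images |
| `curves_io`   | DICOM series read/write (table position, mA, exposure time, CTDI<sub>vol</sub>), CSV export |
| `noise`       | band-ROI noise (SD) per slice with the HU validity rule               |
| `fitting`     | grid-search fit of the lookahead model, axial step detection, CTDI-vs-WED scatter |
| `pipeline`/`cli` | end-to-end orchestration from a YAML config; `atcmlab` console command |

## Worked example

Simulate both scanning directions over the multi-diameter phantom with the
chest protocol (pitch 0.8, 2 mm slices, 40 mm generator lookahead) and fit
a single parameter set to both curves:

```python
from atcmlab import (THORAX_PLAIN, analytic_wed_profile, build_phantom,
                     dlp, fit_model, simulate_modulation)

phantom = build_phantom("mercury4")
profile = analytic_wed_profile(phantom, dz=2.0, margin=60.0)
hf = simulate_modulation(profile, THORAX_PLAIN, "HF", lookahead_mm=40.0, seed=1)
fh = simulate_modulation(profile, THORAX_PLAIN, "FH", lookahead_mm=40.0, seed=1)
fit = fit_model([(hf, profile), (fh, profile)], d_candidates=range(1, 41))
```

which prints (via the snippet in `docs/methods.md`):

```
slices per scan:  296
mean CTDIvol HF:  3.22 mGy   DLP: 190.7 mGy cm
mean CTDIvol FH:  3.22 mGy   DLP: 190.7 mGy cm
best lookahead depth d = 20 slices (40 mm)
a = 0.374 mGy, b = 0.00856 /mm, c = 0.068 mGy
weights (max, Q3, median, min) = (0.395, 0.255, 0.2, 0.15)
pooled RMSE = 0.011 mGy, r^2 = 1.0000
```

The two directions deposit the same total dose (DLP 190.7 mGy·cm) while
their curves differ pointwise; the grid search identifies the generator's
40 mm window as d = 20 slices of 2 mm; and the recovered weights are all
non-zero — the modulation is driven by more than just the extreme WED
values in the window. The small departures of `(a, b, c, w)` from the
generator's exact values come from the slices where the tube-current floor
clips the exponential response (air gaps).

The same analysis from the shell:

```sh
atcmlab simulate --phantom mercury4 --protocol thorax --direction HF \
    --seed 1 --render --out run_hf
atcmlab extract-curve run_hf/dicom --out run_hf/curve.csv
atcmlab fit-curve --curve run_hf/curve.csv --wed run_hf/wed.csv
```

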