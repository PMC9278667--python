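# Methods

## Problem and scope

Automatic tube current modulation (ATCM) adapts the CT tube current along
the patient axis to the local attenuation, mapped beforehand from scout
projections. `atcmlab` provides the analysis chain used to characterize an
ATCM system with QC phantoms — geometry → water-equivalent diameter (WED)
profiles → dose-modulation curves → noise QC → model fitting — plus a
forward simulator that stands in for the scanner. The simulator is not a
physical dose model (no Monte Carlo, bowtie filtration or beam hardening)
and makes no claim to reproduce any vendor's proprietary algorithm; it
realises one well-defined response class so that the estimation machinery
can be validated by exact parameter recovery and so that the qualitative
behaviours seen on hardware (direction asymmetry, pitch dependence,
under-compensated noise) have a controlled synthetic counterpart.

## Phantom geometry

Four phantoms are modelled piecewise along the axis z (mm, 0 at the
Head-facing end):

* **mercury4** — polyethylene bulk (−90 HU), five cylinders of 16, 21, 26,
  31, 36 cm diameter (lengths 7, 9, 6, 6, 7 cm) joined by four 4 cm cone
  rings, 51 cm overall. Each cylinder carries five rods (2.5 cm diameter,
  3 cm long, centres 4.5 cm off axis): solid water 0 HU, bone 910 HU,
  polystyrene −40 HU, iodine 245 HU, air −985 HU. The rods' axial placement
  within a cylinder is not published; they are centred in each cylinder's
  extent (configurable). The carrying handle is available as an optional
  nominal cylinder (WED cap 255 mm) and is off by default; the solid-water
  resolution ramp is not modelled.
* **ctdi_p1 / ctdi_p2** — the 32 cm × 15 cm PMMA body dosimetry phantom
  lying with its cylinder axis perpendicular to z. Axial cross-sections are
  chord × 15 cm rectangles; P1 varies the chord along x, P2 along y. Their
  cross-section areas are equal at every z, so their WED profiles are
  identical by construction.
* **ctdi_t** — head insert offset halfway out of the nested body ring:
  16 cm cylinder ("head"), 32 cm cylinder ("abdomen"), 32/16 cm annulus
  ("lung"), 7.5 cm each.

PMMA's CT number is not published for the scanner studied; it defaults to
+120 HU (typical at 120 kVp) and is configurable. Nominal WED figures
quoted for the multi-diameter phantom by its analysis software exceed the
values implied by −90 HU bulk plus the rods (its segmentation and the
handle/ramp contributions are unknown); the package derives WED from the
geometry and does not force agreement with those nominal figures.

Scanner-frame table positions run opposite to the phantom axis with the
Head end positive (t = L/2 − z), so an HF (head-to-feet) scan has
decreasing table position.

## Water-equivalent diameter

For an HU image, `A_w = Σ max(0, 1 + HU/1000)·pixel_area` over the object
mask and `WED = 2·√(A_w/π)`. The mask is pixels above −800 HU, reduced to
the largest connected component and hole-filled, so internal air cavities
(the lung-section hole, the air rod) stay inside the object and contribute
their floored-at-zero water-equivalent area; the −800 HU threshold and the
per-pixel floor are the package's choices where the reference software's
segmentation is undocumented. The analytic profile evaluates the same
formula on exact section areas; rasterized and analytic WED agree within
one pixel away from section boundaries, and the image-based estimate
converges to the closed form at first order in pixel size.

## ATCM simulator

At each slice position the simulator summarizes the WED profile over the
lookahead window — the `d = round(lookahead_mm / slice_thickness)` samples
starting at the current slice and extending towards the scanning
direction — with `f = w1·max + w2·Q3 + w3·median + w4·min` and sets

```
eff_mAs = reference_mas · exp(s · β · (f − WED_ref)),   CTDIvol = k_dose · eff_mAs,
```

clamped to the tube-current limits `[min_ma, max_ma] · rotation_time /
pitch`. The window reads the true profile beyond the end of the planned
scan; only positions beyond the profile itself count as air (WED 0). The
window includes the current slice so that depth d = 1 degenerates to the
instantaneous response `a·exp(b·WED(z)) + c`; lookahead causality —
positions already scanned never influence the current slice — holds
exactly either way.

Defaults (all configurable on `Protocol`): slice thickness 2 mm,
collimation 64 × 0.6 mm (38.4 mm beam width), rotation 0.5 s, 120 kVp,
reference mAs 66 (chest) / 210 (abdomen helical and sequential), pitch
0.8, current limits 10–650 mA, `WED_ref` = 300 mm, `β` = 0.012 /mm (about
a factor 2 in dose per +60 mm of water-equivalent size), modulation
strength `s` = 0.7 (clinical systems deliberately under-compensate),
`k_dose` = 0.075 mGy per effective mAs, chosen so the chest protocol on the
multi-diameter phantom averages ≈ 3 mGy; default weights (0.40, 0.25,
0.20, 0.15) — non-degenerate, as fits to scanner data require. The
effective lookahead window grows with pitch (32/40/50/52 mm at pitch
0.6/0.8/1.0/1.2, interpolated between); scans extend 40 mm beyond the
phantom into air. These values define the synthetic study conditions; none
of them is a claim about any particular scanner.

Sequential (axial) mode holds the current constant within each table step
(default step: beam width × pitch), producing piecewise-constant curves
whose edges precede the WED ramps in the scanning direction.

**Noise rendering.** Slice images are the rasterized cross-section plus
i.i.d. Gaussian noise with `σ(z) = σ_ref · √(D_full(z) / CTDIvol(z))`,
where `D_full` is the per-slice dose that would hold noise constant for
the same window statistic (the `s = 1` response, unclamped). Equivalently
`σ(z) = σ_ref · exp((1−s)·β·(f − WED_ref)/2)`: constant noise under full
compensation, noise rising with WED when `s < 1`, and `σ ∝ 1/√CTDIvol` at
fixed structure. `σ_ref` defaults to 12 HU, capped at 100 HU for
zero-dose slices. This emulates only the dose–noise scaling; real
reconstructions have textured, spatially correlated noise, streaks and
beam-hardening, so passing noise tests here validates the measurement
chain, not any image-quality claim about real data.

## Noise measurement

Per-slice noise is the SD over an annular band centred on the phantom
axis; a sample is valid only when the band mean lies in the range expected
for the bulk material (−110..−70 HU for polyethylene, +90..+150 HU for
PMMA). Validity is a pure function of the band mean and the interval.
Band radii default to 20–30 mm: the band must stay inside the smallest
(16 cm) section yet clear of the rods, which reach down to radius
45 − 12.5 = 32.5 mm — this is why the outer radius sits below 32.5 mm.
For the three-section phantom two ROIs are provided (head: r ≤ 40 mm;
body ring: 100–140 mm) whose validity patterns cover complementary
sections, since each lies in air somewhere along the phantom.

## Fitting

For each candidate integer depth d the model `a·exp(b·f) + c` is fitted by
`scipy.optimize.least_squares` over `(u1, u2, u3, log a, b, c)`, with the
weights the softmax of `(u1, u2, u3, 0)` — non-negative and summing to 1
by construction (signed weights are deliberately not offered: f stays a
convex combination of order statistics and the model interpretable).
Initialisation uses uniform weights with a log-linear regression for
`(a, b)`, plus a warm start from the previous depth in the grid; the
reported d minimizes pooled RMSE, ties (within 1e−9 relative) broken
towards smaller d. Quartiles use linear interpolation between order
statistics (the common type-7 rule); WED is in mm throughout (b rescales
accordingly if cm are preferred). The exponent `b·f` is capped at ±50. A
constant curve is returned flagged `degenerate` with b pinned to 0.
Multiple curves (e.g. HF + FH) can share one parameter set by pooling
residuals.

On noise-free simulator output the fit recovers the generator exactly
(machine precision) when the current limits are open; with the default
10 mA floor the air-gap slices clip the exponential and the continuous
parameters shift by a few percent while the recovered depth is unaffected.
With 5% multiplicative dose noise the depth stays within ±1 slice of the
truth in ≥ 90% of seeded replicates.

## Problem sizes and determinism

The standard synthetic acquisition is the full multi-diameter phantom at
2 mm slices with 40 mm air margins — 296 slices — and the grid search
spans d = 1..40; one full fit takes well under a second, so the test
suite and the reproduction script run in minutes on a single CPU. All
randomness (noise rendering, replicate perturbations) flows through
explicit integer seeds; simulation itself is deterministic unless the
optional angular-modulation jitter is enabled.

## Known limitations

* The simulator's response class is an assumption; a scanner whose ATCM
  uses thresholds, presets or scout-domain processing will not be captured
  beyond what the fitted model class can express.
* No detectability index, TTF or NPS: these require task-based image
  quality machinery outside this package's scope.
* WED is circular-equivalent only (no AP/LAT effective-diameter variants,
  no truncation compensation); the patient table is not modelled.
* DICOM support covers single-series directories of CT image slices, not
  dose structured reports or multi-series studies.
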