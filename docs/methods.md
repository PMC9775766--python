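# Methods

## Signal statistic

The pipeline quantifies a paper-disc colorimetric assay from RGB images.
The measured quantity per disc is the vector of arithmetic mean pixel
intensities of the red, green and blue channels over a circular region
of interest (ROI), on the raw 8-bit sRGB scale with no gamma
linearisation — smartphone colorimetry conventionally averages camera
values as-is, and the calibration absorbs the (monotone) nonlinearity.
The analytical statistic is the blank-referenced log-ratio

    effective I_c = log10( I_c(blank) / I_c(sample) ),   c in {R, G, B},

analogous to absorbance: zero when the sample equals the blank,
increasing as the chromophore absorbs more of channel c's light, and
additive across serial attenuations. One blank disc per batch supplies
the reference. Sample means of zero (saturated-dark artifacts) are
clipped to 0.5, half an 8-bit step, with a warning; a non-positive blank
mean is an error because the blank defines the scale.

## ROI handling

The disc is located automatically: the background level is estimated per
channel from the image border (median), pixels deviating by more than 8
intensity units (max over channels) are foreground, and the largest
connected component gives the disc's centroid and area-equivalent
radius. A pixel belongs to a circular ROI when its center lies strictly
inside the radius — an unambiguous, exactly testable rule, matched by
the renderer so noise-free round trips are exact. The working radius is
shrunk by `shrink_fraction` (default 0.8) to stay inside the uniformly
coloured center and away from rim artifacts; the assay literature
selects "the uniform area" without defining it, so the fraction is an
explicit parameter here. Saturated pixels are kept in the mean but
reported through `saturation_fraction`, warning above 1%; excluding them
would bias blank measurements, which legitimately sit near the top of
the scale.

## Channel selection

Colour development is assumed linear in time through the origin (no
colour at t = 0), so per-channel development rates are fitted by
through-origin least squares of effective intensity against time
(a free-intercept mode is available; whether published rates were fitted
through the origin is generally not stated). The analytical channel is
the one with the largest fitted rate; ties break blue > green > red,
matching the expectation for a reddish-orange product. The default rates
(0.0248, 0.0619, 0.1138 a.u./min for R, G, B over a 1–7 min reaction)
make blue the analytical channel.

## Calibration, LOD, LOQ

Concentration response is linear over two disjoint dynamic ranges
(defaults 5–20 µM and 35–400 µM, boundaries inclusive), each fitted by
unweighted OLS (the assay's published diagnostics are plain regression
coefficients with adjusted R², not variance-weighted fits). Reported per
range: slope, intercept, their standard errors, adjusted R², residual
SD. Detection limits use the blank-replicate convention

    LOD = k_LOD · σ_blank / b_low,  k_LOD = 3 (default)
    LOQ = k_LOQ · σ_blank / b_low,  k_LOQ = 10 (default)

with σ_blank the n−1 sample SD of repeated blank effective intensities
and b_low the lower-range slope — the lower curve governs both limits.
The multipliers are exposed rather than hard-coded because the "95%
confidence" language often attached to LODs is not operational; the
3σ/10σ convention is consistent with a published LOQ/LOD ratio of ≈3.3.

Inverse prediction routes low-range-first: invert the low line, and only
if the implied concentration exceeds the low range's upper bound invert
the high line. A high-range inverse landing between the ranges is
flagged `in-gap` and reported through the gap-interpolated inverse;
below-LOD and above-range signals are flagged but still carry values.
Boundary concentrations are protected against last-digit rounding by a
1e-9-relative tolerance. No inverse-prediction confidence intervals are
computed beyond the residual SD; nonlinear (4PL) calibration is out of
scope.

## Synthetic data generator

The generator emulates the forward structure the analysis assumes, so
every stage is testable against ground truth:

1. concentration → blue effective intensity at the full reaction time
   via the piecewise two-range linear model; between the ranges
   (20–35 µM) it interpolates linearly between the boundary values
   (continuity; behaviour there is otherwise unspecified), and below the
   low range it ramps linearly from (0, 0) since a blank develops no
   signal;
2. times before `reaction_time` (default 7.0 min) scale the signal by
   t/reaction_time; red and green scale from blue by their rate ratios —
   linear kinetics are the simplest model consistent with single
   per-minute rate values;
3. effective intensities map to channel means by mean = blank·10^(−eff),
   clipped to [0, 255];
4. discs render as centered filled circles (default 120 px diameter,
   representing a 5.0 mm reaction zone) on a uniform background
   (default 245) with independent Gaussian pixel noise (default SD 2,
   clipped and rounded to 8 bits). Blank channel means default to
   (200, 190, 200) — a white paper disc under enclosure illumination;
   these are free parameters, not measured constants;
5. replicate scatter is Gaussian noise on the blue effective intensity
   (default SD 4.611e-5 a.u. = slope × LOD / 3, the level at which
   3σ/slope reproduces a 15.37 nM detection limit); red/green follow the
   noisy blue via the rate ratios, preserving per-replicate channel
   ordering.

All randomness flows from a single root seed through stable per-image
offsets; identical configurations produce bit-identical images and
tables. The generator does **not** simulate illumination gradients, lens
vignetting, JPEG compression, white-balance drift, chemical kinetics
beyond linear time scaling, or serum-matrix effects — passing tests
demonstrate the correctness of the quantification arithmetic on data
satisfying the model's assumptions, not robustness of disc photography
in the field.

A separate kinetic time-course generator produces effective intensities
rate·t per channel, emulating the channel-selection experiment at its
fixed assay concentration (the piecewise calibration model and the
absolute kinetic rates describe different experimental conditions and
are deliberately not coupled).

## Validation statistics

* selectivity coefficient k_sel = interferent signal / creatinine
  signal (≪ 1 for a specific sensor); the screened interferent panel is
  glucose, BSA, uric acid, citric acid, vitamin C, Na⁺, K⁺, Cl⁻;
* mixed-sample sensitivity = 100 · mixed signal / pure signal, the
  percentage of signal retained with co-present interferents (this
  ratio reading is one of two plausible definitions of a published
  "sensitivity" percentage; the ratio is implemented);
* percent recovery %R = 100·(spiked − blank)/added, with blank
  correction performed in concentration units: the blank's signal is
  converted through the same calibration before subtraction;
* RSD = 100 · sample SD / mean, always with the n−1 SD (replicate
  counts of 3 make the population SD misleading); zero mean raises
  rather than returning NaN;
* shelf-life series report percent-of-initial signal without enforcing
  monotone decay.

Recovery studies convert each replicate signal to concentration, flag
and exclude levels with above-range replicates, and emit records in the
conventional spiked / recovered / recovery% / RSD% layout. Reference
recovery-table comparisons tolerate 0.1 percentage points, the rounding
granularity of recovered means printed to two decimals.

## Numerical and testing choices

Problem sizes are chosen for exactness and speed: noise-free standards
at 5, 7.5, 10, 15, 20 µM (low) and 35–400 µM (high) make OLS recovery
of the generating coefficients exact to machine precision; detection-
limit simulations use 200 replicate draws of 10 blanks; image tests use
60–120 px discs (≥ 2,800 ROI pixels), where the standard error of a
noisy ROI mean is below 0.1 intensity units. With all noise off, the
only error source is 8-bit pixel quantization, bounding the effective-
intensity error below 0.005 a.u. for blank means ≥ 150 — equivalent to
±0.5 µM in the low range and ±15 µM in the high range (slope 0.001),
the tolerances used by the end-to-end round-trip tests. The mean of the
3·(sample SD)/slope LOD estimator over n = 10 blanks is biased low by
the Gaussian c4(10) ≈ 0.973 factor; the plain sample-SD estimator is the
field convention and is left uncorrected.

## Known limitations

Single-disc images only (no multi-disc layouts); no colour-space
conversion (HSV/Lab) or white-balance correction; selectivity and
recovery treat signals as given and do not model cross-reactivity
mechanisms; the inter-range gap inverse is an interpolation convention,
not chemistry.
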