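# Methods

`renalpet` is a synthetic-data replica of a feasibility analysis of
dose-reduced [<sup>18</sup>F]PSMA-1007 PET for functional imaging of the
renal cortex.  The clinical raw images behind that analysis are not
public, so the package pairs the deterministic parts of the analysis
(the pediatric dose chain, the printed per-patient summary table) with a
digital-phantom simulation engineered to have the statistical structure
the analysis assumes: renal tracer kinetics with fluorine-18 decay,
Poisson counting noise proportional to activity × acquisition duration,
retrospective list-mode-style rebinning, and segmentation variability.

## The phantom

A 288 × 288 × 192 mm abdominal scene, rasterized at an isotropic voxel
size (default 4 mm; the mm geometry is fixed, so VOI totals are nearly
voxel-size independent).  It contains:

- two mirrored ellipsoidal kidneys (semi-axes 22 × 26 × 48 mm, ≈ 113 mL);
- a renal-pelvis region carved from each kidney holding excreted
  activity (3× parenchymal uptake), excluded from the cortical VOI the
  way a reader excludes pelvic activity;
- an aortic blood pool, liver and spleen (0.7 / 0.5 relative uptake,
  placed ≥ 14 mm from the kidneys so resolution blur cannot couple them
  to the renal VOIs), and low-uptake background (0.02);
- optional spherical cold defects (uptake multiplier in [0, 1]).

Each kidney voxel is a 25% blood / 75% tissue mixture.  The total
parenchymal (tissue) activity divides between the kidneys by the left
split fraction *f*; the intrarenal blood signal is split by volume.  A
consequence worth knowing: for *f* ≠ 0.5 the blood compartment pulls the
measured left renal uptake percentage (LRU%) toward 50 by an amount that
follows the blood curve, strongly so for extreme splits at early time
points when blood activity still dominates parenchymal uptake.  At the
reference protocol (1 h p.i.) the pull is ≈ +0.1 pp at *f* = 0.483.

## Kinetics

Tissue: b(t) = A·(1 − e<sup>−k_u·t</sup>)·e<sup>−k_w·t</sup>, with
defaults A = 22 kBq/mL per MBq/kg injected, k_u = 0.03 /min,
k_w = 5·10⁻⁴ /min.  Blood: biexponential clearance, 16 kBq/mL per MBq/kg,
75% clearing at 0.15 /min and 25% at 0.004 /min.  Measured concentrations
are the biological curves × e<sup>−λt</sup> with λ = ln 2 / 109.77 min
(fluorine-18).  The clinical study does not report absolute renal uptake;
these amplitudes are declared assumptions chosen to give a kidney
concentration ≈ 50 kBq/mL and renal uptake ≈ 5% of injected activity at
4 MBq/kg, plausible for this tracer.  The rates place the maximum of the
*decayed* tissue curve at the 1 h sample of the standard schedule, and
with the default between-patient uptake-rate jitter (lognormal, σ = 0.4)
a minority of patients peak at the 0.5 h sample instead — mirroring the
clinically observed peak-time distribution.

## Acquisition model

Expected counts per voxel: concentration × voxel volume × sensitivity ×
duration × g(d), with g(d) = (1 − e^(−λd))/(λd) the exact decay-averaging
factor relative to frame-start activity (≤ 0.5% below 1 for d ≤ 180 s,
4.6% for 15 min).  Counts are Poisson; the concentration estimate is
counts / (sensitivity × volume × duration × g), blurred with an isotropic
Gaussian (FWHM 5 mm) standing in for regularized iterative
reconstruction — the analysis depends only on VOI sums and noise, not on
reconstruction fidelity.  Default sensitivity is 5 counts/(kBq·s), a
single-bed effective value.

Rebinning thins the parent's pre-blur counts binomially with the
decay-exact prefix probability (1 − e^(−λd))/(1 − e^(−λD)), which reduces
to d/D without decay.  Thinned frames are prefixes of one event stream:
durations within an acquisition are correlated exactly as in
retrospectively rebinned list-mode data, sub-bins of a partition sum to
the parent exactly, and the marginal of a sub-bin equals a direct
simulation at the shorter duration (Poisson thinning theorem).

## Segmentation variability

At realistic count levels, counting noise alone gives a per-acquisition
LRU% SD of ~0.03 pp — far below the clinically observed 0.5–2.2 pp.  The
dominant real-world sources (boundary placement, respiration) are
modeled by warping each kidney mask with a smooth random displacement
field (correlation length 16 mm, per-component RMS = the boundary-noise
parameter) and re-thresholding the interpolated indicator.  The default
1.25 mm was calibrated once against the published per-patient SD band
(pilot: 0.5 mm → 0.05 pp, 1.0 → 0.50, 1.5 → 0.98, 2.0 → 1.45 pp), then
frozen.  Masks are drawn per acquisition and shared by all rebinned
durations of that acquisition; scans earlier than 0.5 h reuse the 0.5 h
mask, as in the clinical protocol.

## Study design defaults

12 patients; scans at {5, 12, 20, 30, 60, 120, 210, 330} min p.i. (the
four early minutes are config, not protocol facts); native durations
30/30/30/30/120/120/120/180 s; rebins (10, 20) s at 0.5 h,
(10…90) s at 1–3.5 h, plus 120 s at 5.5 h; first three scans not
rebinned.  Injected activity 4.0 ± 0.4 MBq/kg.  Left split fractions
drawn from a truncated Normal(0.483, 0.03) with one extreme-split
patient fixed at 0.058 (the published cohort median and extreme).  Two
patients lose their 2 h list-mode rebins (native kept), giving 362
series.  One study-level master seed; every patient/frame/mask stream is
a `numpy` `SeedSequence` keyed by (patient, time index, duration,
stream tag), so outputs are bit-identical across reruns.

## Statistics

LRU% is normalized by each patient's median (ratio form; a subtraction
variant exists behind a flag), gated through Shapiro–Wilk, then tested
with Kruskal–Wallis by duration and by time point on normalized and raw
values, with Dunn's tie-corrected z tests and Bonferroni adjustment
(m = k(k−1)/2, adjusted p capped at 1) for both factors.  Kruskal–Wallis
and Shapiro–Wilk delegate to `scipy.stats`; Dunn's test is implemented
here.  All-identical input is reported as (H, p) = (0, 1) by convention.

Type-I calibration uses a balanced homogeneous VOI-count-level cohort
simulator (equal expected counts in every cell) because the
Kruskal–Wallis null is *identical* distributions: on the real study grid
the count level varies across time points, so even with no injected
effect the group variances differ and the test's level is not exactly α.
On the homogeneous design, normalized p-values are uniform, while
non-normalized p-values are strongly conservative (between-patient split
differences dominate the ranks) — the same normalized-vs-raw discrepancy
the clinical analysis reported.

## Dosimetry

Pediatric chain: conversion factor = mean of six published
adult-to-one-year-old effective-dose ratios {5.0, 4.0, 5.0, 4.5, 5.9,
5.1} → 4.9; × 0.022 mSv/MBq adult coefficient → 0.11 mSv/MBq; 60 s → 15
min at constant activity × time → 15-fold activity reduction,
4.0 → 0.27 MBq/kg; for a 10 kg one-year-old: 2.7 MBq, 0.3 mSv PET,
0.4 mSv with a 0.1 mSv CT.  Intermediates are carried at full precision
and rounded only at report time; a rounded-intermediate evaluation is
also provided and agrees at printed precision (asserted by a test, not
assumed).  Multi-bed budgets divide the per-bed duration, not the
activity.  The constant activity × time premise is exact only without
decay: over a 15 min frame, within-frame decay removes ≈ 4.3% of counts
(g(900 s) = 0.954 vs g(60 s) = 0.997), so VOI noise at (a/15, 15d) is
≈ 2% above (a, d); tests allow 5% for this physical effect plus
Monte-Carlo error.

## Numerical and design choices

- Negative blood-corrected tissue concentrations are returned with a
  warning, never clipped (clipping would bias peak-time selection).
- Peak-time ties break toward the earlier time point.
- Per-patient SD is the sample SD (n − 1).
- Left/right are defined in phantom label coordinates, not radiological
  display convention.
- The packaged per-patient summary table stores the printed values
  verbatim; its printed delta max was computed from unrounded data and
  may differ from range max − min by 0.1, so the loader checks
  consistency to ±0.15 plus a SHA-256 checksum.
- Default problem sizes: Monte-Carlo checks run the voxel pipeline at
  6 mm voxels (identical mm geometry and count levels; VOI totals are
  voxel-size independent), the full-grid default study at 4 mm runs once
  and takes ~15 s; these sizes are the package's chosen desk scale.

## What the synthetic data does and does not show

The generator reproduces: Poisson count scaling with activity ×
duration and its 1/√duration noise law; correlated rebinned durations;
decay-correct frame averaging; segmentation-driven LRU% variability of
clinically observed magnitude; a heavy-tailed normalized LRU%
distribution (the extreme-split patient) that fails normality, as the
clinical data did.  It does not model attenuation, scatter, randoms,
reconstruction artifacts, respiratory motion as such (only its
boundary-error footprint), CT, or whole-body biodistribution; the
extreme-split patient's early-time LRU% excursions are larger than the
clinical counterpart's because the single-compartment uptake curve
leaves early frames blood-dominated.  Passing tests therefore validate
the analysis machinery and its statistical calibration — not the
biological fidelity of any individual simulated patient.
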