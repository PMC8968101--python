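# Methods

This note documents the models behind `myoecv`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions a maintainer would want to know.

## Contrast kinetics

Blood enhancement after a gadolinium bolus is modeled as a bi-exponential,

    dR1_b(t) = D · [ f·e^(−k_f·t) + (1−f)·e^(−k_s·t) ],

with peak enhancement `D = 12 s⁻¹`, fast fraction `f = 0.6`, and clearance
rates `k_f = 0.8 /min`, `k_s = 0.02 /min` — a fast redistribution phase on
top of slow renal clearance, enough structure to reproduce proportional
blood/tissue recovery over 5–60 min. Myocardial enhancement relaxes
first-order toward `λ·dR1_b(t)` with exchange time constant `τ = 1.5 min`;
both courses have closed forms (the tissue response to `e^(−k t)` is
`(e^(−k t) − e^(−t/τ))/(1 − kτ)`).

A property of this model worth stating explicitly: while blood decays as
`e^(−k_s t)`, the quasi-steady tissue/blood enhancement ratio is
`λ/(1 − k_s·τ)`, about 3% above λ for the defaults (≈5% at 8 min, relaxing
toward 3%). Tissue concentration lags a falling input, so any finite-τ course
overestimates λ slightly; the instantaneous-equilibrium limit `τ → 0` makes
the ratio exactly λ. Consequences:

- noiseless λ/ECV recovery is exact (relative error < 1e-4, in practice
  ~1e-16) on τ→0 courses, which is the regime in which a single λ is
  strictly defined;
- at the default τ = 1.5 min the end-to-end ECV estimate carries a ~3–5%
  multiplicative bias (absolute error up to ≈0.02). This bias is common-mode
  across animals and therefore barely touches the cross-animal ECV–CmyB
  correlation, which is the study's endpoint.

The acquisition schedule is pre-contrast plus 1–60 min with gaps growing from
0.5 to 5 min (0, 1, 1.5, 2, 2.5, 3, 4, 5, 7, 10, 13, 17, 21, then every
5 min to 60). The exact times are a reconstruction — only the gap-growth rule
and the 1–60 min span are fixed by the protocol being emulated — and the
tail uses uniform 5-min gaps so that gaps are non-decreasing throughout.

## Equilibrium detection

The per-time enhancement ratio
`(R1_myo − R1_myo,pre)/(R1_blood − R1_blood,pre)` is smoothed with a 3-point
running median and fitted (weighted by blood enhancement, since the ratio's
noise scales inversely with its denominator) to a convergence model

    ratio(t) = c + d·e^(−t/τ_r),    t ≥ 5 min.

Equilibrium starts at the earliest sample where the modeled transient
`|d|·e^(−t/τ_r)` falls below `rel_tol·|c|` (default `rel_tol = 0.05`), with
at least 3 later samples confirming; τ_r is bounded by the observation span
so the amplitude stays identifiable on near-flat noisy courses. A course
whose transient never falls below tolerance early enough to be confirmed
raises a no-equilibrium error. Points before 5 min are never eligible: the
uptake phase is categorically pre-equilibrium.

Fitting the transient, rather than thresholding raw point-to-point spread,
is what makes the detector usable at realistic noise: late post-contrast
points have small blood enhancement and correspondingly large ratio noise
(comparable to the 5% tolerance itself), and a raw-spread rule rejects
>15% of perfectly well-behaved courses. With the fitted rule the spurious
failure rate is below ~2% across the cohort λ range, while monotonically
drifting courses (e.g. a 20% ratio drift, or τ comparable to the whole
observation window) are still refused. The tolerance and the confirmation
count are exposed as configuration.

## λ regression and ECV

Ordinary least squares of myocardial R1 on blood R1 over the pre-contrast
point plus all points inside the equilibrium window. The pre-contrast point
is included deliberately: it anchors the intercept and is part of the
proportional-recovery picture. `ECV = λ·(1 − hematocrit)` exactly; ECV is
reported to 3 decimals in tables, full float internally.

## MOLLI simulation and fitting

Inversion times follow the two-block schemes 4(7)3 (pre-contrast) and 4(3)3
(post-contrast): images every two heartbeats after each inversion, with the
block pause separating them in scanner time. RR = 60000/heart-rate ms; heart
rate defaults to the 55–70 bpm trigger window. Signals follow
`|A − B·e^(−TI/T1*)|` with `T1* = T1/(B/A − 1)`; the generator's default
apparent-saturation ratio is B/A = 1.9. Noise is Gaussian on the signed
signal before the magnitude (the high-SNR Rician approximation).

Fitting: polarity restoration scores candidate flip positions within two
samples of the magnitude minimum by the residual of the three-parameter fit;
the fit itself is Levenberg–Marquardt with analytic Jacobian, initialized at
`A₀ = max signal`, `B₀ = 2A₀`, `T1*₀ = TI at minimum magnitude`, tolerances
1e-10 on parameters. Non-convergent or unphysical fits (`B ≤ A`) return a
flagged result with a non-positive T1 sentinel rather than raising;
downstream ROI means exclude flagged pixels. No B1/inversion-efficiency or
motion correction is attempted.

ROI extraction erodes the region mask by one pixel (border-zone avoidance)
and requires ≥10 valid pixels. The free wall is refused outright — the
phantom can place a multiplicative artifact band there, mirroring why the
analysis is restricted to the interventricular septum.

## Histology generator and morphometry

Fields are 356 × 266 µm, rendered at 0.25 µm/px by default (1424 × 1064 px;
a 400× sampling scale), with 100–200 cells on a jittered hexagonal lattice.
Per-cell breadth is truncated-normal (floor 3 µm) with per-animal SD
defaulting to 1.5 µm, in-plane aspect ratio uniform in [1.3, 1.8], and
out-of-plane tilt |N(0, 15°)| (capped at 65°) stretching the rendered long
diameter by 1/cos(tilt) while leaving the breadth untouched — the geometric
fact that motivates measuring the shorter diameter. 80% of cells get a
centered hematoxylin nucleus (minor axis ≈ 0.3 × breadth), 12% an off-center
one (displaced 55% of the equivalent radius), 8% none. Images are composed
in optical-density stain space and converted with the standard H&E stain
matrix, so color deconvolution on the rendered image recovers the channels
cleanly. Every rendered cell appears in the truth table.

Measurement: eosin-channel Otsu foreground (nucleus holes filled), debris
below 20 µm² dropped, distance-transform watershed with seeds at least 7 µm
apart (the distance map is Gaussian-smoothed so an elongated cell yields a
single seed), second-moment equivalent ellipse per region. Inclusion requires
a nucleus blob ≥ 2 µm² whose centroid lies within 25% of the cell's
equivalent radius, no border contact, and eccentricity ≤ 0.95
("approximately oval"). Both thresholds are configuration knobs, since the
manual protocol they operationalize was qualitative. The per-animal SD pools
cells across fields (not a mean of per-field SDs), matching the per-animal
mean ± SD presentation.

What the generator does *not* emulate: stain variability between slides,
fibrosis/collagen, cardiac motion, Rician-exact noise, vendor T1-map
processing, or the behavior of human readers clicking in measurement
software. Passing recovery tests therefore demonstrates that the automated
chain is unbiased against its own ground truth across the cohort's breadth
range (8.6–11.5 µm, recovered within 2%), not that it replicates manual
readings on real slides.

## Synthetic cohort

Per-animal true (ECV, CmyB) pairs come from a bivariate normal with the
cohort means/SDs (0.253/0.043 and 10.02/0.84 µm) and an adjustable
correlation (−0.73 by default); hematocrit is uniform on the observed
0.21–0.37 range; λ is back-solved as ECV/(1 − Hct) so the defining identity
is bit-exact per animal. Everything is a pure function of (parameters, seed).

## Reader agreement

κ is the standard unweighted Cohen statistic; when both raters are constant
and identical it is defined as 1. Continuous breadth readings are made
categorical by tertile binning (configurable edges) before κ, since κ needs
categories. The published inter-/intra-observer κ values cannot be recomputed
here — the per-reader measurements behind them were never published — so the
tests assert only the statistic's own properties (identity, chance level,
agreement with an independent reference implementation, analytic κ of a
known confusion structure).

## Problem sizes and determinism

The default test and acceptance runs use reduced problem sizes chosen to keep
recovery statistically meaningful: per-pixel map fitting on small phantoms,
morphometry at full 0.25 µm/px resolution on a few fields per condition, and
the 100-seed correlation-coverage study at 1.0 µm/px with 2 fields per animal
and an idealized T1 readout (Gaussian R1 noise in place of per-signal MOLLI
refits). The coverage of the Fisher-z interval is dominated by n = 14
cross-animal sampling, not by measurement noise, so the reduced setting
measures the same thing. Every stochastic component is seeded; identical
configurations reproduce byte-identical outputs.

## Known limitations

- The equilibrium criterion is a principled reconstruction, not a published
  algorithm; its tolerance is a knob.
- λ estimated from finite-τ courses carries the lag bias described above.
- The automated morphometry is a surrogate for a manual protocol and is
  validated only against synthetic truth.
- No DICOM/vendor-format ingestion; inputs are the package's own TIFF/PNG/CSV
  conventions.
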