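# Methods

## Calibration model

All calibrations are single-response (PLS1) NIPALS decompositions on
mean-centered data. For one response the NIPALS weight step is
closed-form (w ∝ Xᵀy), so each component is a single deflation: t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, X ← X − tpᵀ, y ← y − qt. The compact
regression vector is b = W(PᵀW)⁻¹q and new-sample scores are
t = (x − x̄)W(PᵀW)⁻¹, equivalent to walking the deflation path. Invariants
asserted in the test suite: WᵀW = I, TᵀT diagonal, and equality of the
deflation-path and compact-vector predictions. Rank exhaustion (the
covariance Xᵀy or a score collapsing to numerical zero) raises rather
than silently returning garbage components.

Cross-validation is segmented leave-one-out: one segment per
replicate-averaged sample. Each fold refits the *entire* pretreatment
chain — including OSC when enabled — on the training portion and pushes
the held-out spectrum through the fold's fitted record, so no held-out
information reaches the transformation. A fast mode reusing the
full-data pretreatment exists (`refit_pretreatment=False`) but is off by
default; whether published workflows refit OSC per segment is rarely
stated, and the conservative choice is the defensible default. The
number of latent variables is the smallest A whose RMSECV is within a
factor (1 + τ) of the minimum, τ = 0.02 by default — a reproducible
reading of "minimize RMSECV while avoiding overfitting". R²CV and R²TSV
are computed against the variance of the evaluated subset's own y, the
convention of common chemometrics software; the denominator convention
is not universal, so it is stated here explicitly.

## Pretreatment chain

Fixed order: Savitzky–Golay second derivative (order 2, window 9;
interior channels by the centered filter, each 4-channel edge evaluated
from the polynomial fitted to the nearest full window, so the channel
grid is preserved) → SNV (row centering and scaling by the sample n−1
standard deviation; MSC against the calibration column-mean spectrum is
the alternative and gives closely similar results on scatter of the
gain/offset form) → optional single-component OSC → mean-centering
inside the regression. A row counts as degenerate (constant) when its
standard deviation is below 1e−12 of its largest magnitude.

OSC is Wold-style NIPALS: starting from the dominant PC score of the
centered matrix, iterate score-orthogonalization against y with a
least-squares weight update until stable, then deflate X ← X − tpᵀ.
After convergence the weight is re-solved so that Xw equals the
orthogonalized score *exactly*; with that refinement the out-of-sample
correction X − (Xw/wᵀw)pᵀ reproduces the calibration deflation, is
exactly idempotent, and the removed score has exactly zero correlation
with y. Convergence tolerance 1e−10, cap 500 iterations.

## Detection-limit frameworks

*Variance-leverage mLOD* uses: σx² = channel-wise variance of the
pretreated calibration matrix averaged over channels (default; a
replicate mode using the mean per-channel variance among replicate scans
before averaging is selectable and is closer to purely instrumental
noise); σy² = sample (n−1) variance of the calibration concentrations;
h₀ = leverage of the lowest-concentration sample (the blank surrogate —
conservative, since a true blank does not exist for plant material);
h₀ᵐᵃˣ = largest calibration leverage. Leverage is the pure score-space
quadratic form t₀ᵀ(TᵀT)⁻¹t₀; the affine 1/n centering term is available
as an option but excluded by default. The *avg* variant is the midpoint
of min and max. mLOQ is exactly (10/3.3)·mLOD.

*NAS-LOD* fixes the analyte LV to LV1 (standardized, conservative when
analyte variance leaks into later LVs; configurable for sensitivity
studies). The NAS vector is w₁ minus its least-squares projection onto
the remaining X-loadings, which guarantees orthogonality to their span
even for non-orthonormal loadings. For genuine NIPALS PLS1 models the
one-step textbook form w − P(Pᵀw) turns out to be *already* orthogonal
to P_rest — the two modes coincide to machine precision (a consequence
of the NIPALS wᵢᵀpⱼ cross-product structure) — so the `literal` switch
only matters when loadings come from outside a NIPALS fit. s_a is the
standard deviation (n−1) of the cross-validation residuals at the
model's size; RMSECV is reported alongside (they differ only through the
residual mean). A vanishing NAS norm (below 1e−12 of ‖w₁‖) yields +∞
LOD as a reportable diagnostic, not an exception.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not radiative transfer. Spectra are Beer-like mixtures of broad Gaussian
bands: two analyte band sets (slightly shifted, heavily overlapping, a
few 1e−3 AU per mg/g — so a 10 mg/g load contributes ~1–3% of the ~1 AU
matrix background) and three matrix components (cellulose-, protein- and
water-like) with log-normal abundances. The protein-like component's
abundance is correlated (ρ = 0.6) with the total analyte load, giving
OSC genuinely separable y-correlated and y-orthogonal matrix variance —
without a confounder OSC has nothing interesting to remove. Reference
concentrations are uniform on 0.3–10 mg/g per analyte; 50 samples and
triplicate scans are the default campaign.

Scatter is multiplicative gain ~ N(1, 0.05) truncated positive plus an
additive offset (sd 0.02 AU) and linear baseline slope (sd 0.02 AU over
the scaled wavenumber axis), redrawn per replicate scan — exactly the
structure SNV/MSC remove. Intact (unmilled) presentation multiplies the
scatter sds by 2.5 and the channel noise by 2, encoding the higher
heterogeneity of whole material. Instrument degradation is Gaussian
line-shape convolution at the profile's resolution FWHM, truncation to
the device window, linear resampling to the device channel count, and
additive channel noise. Four built-in profiles mirror the public
specifications of a benchtop FT-NIR (10000–4000 cm⁻¹, 8 cm⁻¹, 751
channels) and three handhelds (8000–4651 cm⁻¹/128 px; 10526–6060
cm⁻¹/125 px; 6250–4170 cm⁻¹/131 channels at ~16 cm⁻¹). Channel counts
not published (the MEMS handheld) were fixed once from the nominal
resolution. Noise levels (3e−4 AU benchtop to ~1e−3 AU handheld) are
not published for any device; they were chosen once so that the default
milled benchtop campaign lands at RMSECV a few tenths of a mg/g
(R²CV ≈ 0.94) and handheld/intact campaigns degrade qualitatively, and
are not tuned thereafter. All randomness flows from one
`numpy.random.Generator` seeded at the top level; equal seeds give
bit-identical datasets. The generator also returns the noiseless pure
analyte spectra on the instrument grid, the "pure standard" used by the
projection diagnostic (pretreated through the calibration-fitted chain —
OSC applied, never refitted — mirroring how a physical standard would be
measured and processed).

What the generator does *not* emulate: Kubelka–Munk/radiative-transfer
nonlinearity, moisture and temperature drift, wavelength-axis
miscalibration, detector nonlinearity, and real band shapes
(Gaussian, not Voigt, since the broad NIR overtone/combination bands
make the distinction immaterial at these resolutions). Passing tests
therefore demonstrate correctness of the *algorithms* and
reproduction of the *structural* phenomena (OSC concentrating analyte
variance in LV1, the opposite LV-dependence of the two LOD frameworks),
not quantitative agreement with any physical instrument.

## Problem sizes and numerical choices

Default study conditions: 50 calibration samples (+10 external test in
the pipeline), triplicate replicates, A up to 8–10; multi-seed
structural checks use 20 seeds with a one-sided sign test. The matched
model size for OSC-contrast comparisons is F = 3: the contrast is a
compact-model phenomenon — near the CV optimum the unconstrained model
has learned the confounder itself and the two variants converge.
LV-truncation summaries across seeds use medians, which are stable
against the occasional seed whose CV curve is flat.

Tie-breaks and degeneracies: LV selection prefers the smallest A on
ties; the blank-surrogate leverage is clipped to h₀ᵐᵃˣ (the lowest-
concentration sample need not be the most extreme point of the score
cloud); zero-variance spectra raise a named degenerate-spectrum error;
MSC with a constant reference and OSC with constant y are rejected.
Wavenumber axes are stored high→low (FT-NIR convention) but readers
accept either order.

## Known limitations

Leverage-based mLOD inherits the instability of (TᵀT)⁻¹ when late
scores are numerically small. s_a is taken at the model's own A from a
single CV pass at the largest A of interest; per-A refitting of the
pretreatment inside that pass makes the truncation study O(n·A_max)
model fits, which is cheap at these sizes but would need the fast mode
for very large campaigns. The JCAMP-DX reader covers plain AFFN tables
only (no ASDF/DIF compression).
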