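# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are validated against, the numerical choices, and the limits of
what the tests demonstrate.

## Laurdan GP

GP is computed from two band intensities, GP = (I440 − I490)/(I440 + I490).
Band extraction defaults to point interpolation at exactly 440 and 490 nm
(`band_window_nm = 0`); a positive half-width instead averages the
piecewise-linear spectrum over [center − w, center + w].  Point
interpolation is the default because the measurement convention is a fixed
pair of emission wavelengths; windowed averaging is provided for noisy
spectra.

Replicates are aggregated **at the GP level**, not the spectrum level:
spectra whose temperatures agree within 0.01 °C are treated as replicates,
each is reduced to its own GP, and the mean and sample SD (ddof = 1) are
recorded per temperature.  Reported uncertainties in this kind of
experiment are GP-level SDs over repeated measurements, and GP's
scale-invariance makes spectrum-level averaging equivalent only when
replicate intensities share a common scale — which instrument drift breaks.
Single-replicate temperatures carry SD = NaN, and the sigmoid fit falls
back to unweighted least squares unless every point has a finite positive
SD.

The dose-response statistic is ΔGP/GP = 100·(GP_dose − GP_0)/|GP_0| %.
The absolute value in the denominator is deliberate: fluid-phase controls
have negative GP, and without it a dose that *orders* such a membrane would
produce a negative percentage.  With |GP_0|, positive always means ordering
and negative always means fluidization.  The crossover dose (where an
additive switches from fluidizing to ordering) is the first zero of the
piecewise-linear interpolant of ΔGP/GP versus dose; with fewer than two
doses or unsorted doses the operation refuses, and a response with no sign
change returns an explicit "no crossover" result rather than extrapolating.

## Transition extraction (Tm pipeline)

The thermal curve is fitted with a four-parameter Boltzmann sigmoid

    GP(T) = A2 + (A1 − A2) / (1 + exp((T − Tm)/dT)),

the standard form for two-state thermotropic data; Tm is the inflection
point and dT the steepness.  Initialization is deterministic (no random
restarts): plateaus from the endpoint GPs, Tm from the steepest
finite-difference midpoint, dT = 3 °C; tolerances 1e-10, at most 10000
function evaluations, and dT bounded positive.  Series whose GP range is
below 0.02 are rejected as transition-free rather than fitted.

The "first derivative" stage differentiates the **fitted** curve
analytically and samples it on a 0.1 °C grid over the data range — not
finite differences on the coarse 5 °C measurement grid, which would be both
biased and noisy.  The derivative, −(A1 − A2)/(4dT)·sech²((T − Tm)/2dT),
peaks exactly at Tm, so the subsequent Lorentzian fit

    L(T) = offset + (2A/π) · w / (4(T − c)² + w²)

(FWHM parameterization, baseline offset included) is a redundancy check on
Tm plus a width estimate.  A Lorentzian is not a sech² — the fit is a
convention, and the recovered FWHM depends mildly on the fitted temperature
range.  A pre-build pilot over dT = 1–8 °C on the 27–57 °C range
established the mapping (e.g. dT = 3.0 °C → FWHM 11.40 °C) and that the
fitted center tracks Tm to better than 0.01 °C; the width is strictly
increasing in dT throughout.  Width is reported as FWHM; a Lorentzian
scale-parameter convention would differ by a factor of 2, which matters
when comparing absolute widths across studies.

## TEMPO-DPH quenching ruler

DPH partitions evenly between L_o and L_d phases while TEMPO quenches
essentially only L_d-resident DPH, so the residual fraction Q = F/F_o rises
with L_o domain size.  The ruler

    R = Ro · (Q − Q_PC) / (Q_SM/Chol − Q_PC)

is affine in Q between the L_d baseline (pure PC) and the L_o ceiling
(SM/Chol 50/50).  Defaults: Q_PC = 0.60 for POPC matrices, 0.58 for PDPC
matrices, Q_SM/Chol = 0.93 for both, Ro = 47.5 Å.  Ro is not an independent
physical constant here: the four control radii of the reference data set
back-compute to 47.4–47.5 Å (each pair inverts to within 0.1 Å of the
common least-squares value), and the nitroxide sensing-range bound
(Rc = 6–12 Å, Ro ≈ 4Rc, hence at most ~48 Å) brackets it.  `calibrate_ro`
re-estimates Ro from any set of (Q, known radius) controls by closed-form
least squares.

Noisy replicate Qs can fall outside [Q_PC, Q_SM/Chol]; the resulting radii
are clamped into [0, Ro] and flagged rather than rejected, because a
replicate 1% above the ceiling is information, not an error.  Uncertainty
is propagated to first order, sd_R = Ro·sd_Q/(Q_SM/Chol − Q_PC), which
Monte-Carlo replication shows agrees with empirical replicate scatter
within a factor of 2 at 1% multiplicative noise.

Dose-bearing samples are converted with the *control* baselines: whether
the pure-PC baseline itself shifts under the additive is unknowable from
the ratio alone, so dosed radii are interpreted as directions and relative
changes (ΔR/R), not absolute sizes.

## DLS cumulant sizing

The correlogram model is the second-order cumulant expansion in the
g2 domain,

    g2(τ) − 1 = β · exp(−2Γτ) · (1 + (μ2/2)τ²)²,

with PDI = μ2/Γ² and D_h from Stokes–Einstein at the instrument defaults
(633 nm, 173° backscatter, n = 1.330, 37 °C, η = 0.6913 mPa·s — water;
the ≤2% buffer-salt viscosity correction is ignored).  The fit is nonlinear
least squares of this expression directly (the appropriate estimator under
additive correlogram noise), seeded by a weighted linear fit of ln g1 on
the early decay (g1 ≥ 0.2·g1(0), weights g1²).  A purely linearized
log-cumulant fit was rejected: ln(1 + μ2τ²/2) ≠ μ2τ²/2 in the tail, which
biases Γ and μ2 at PDI ≳ 0.2 and breaks sub-0.1% size round-trips.  The
tail is truncated at the first nonpositive g2 − 1 point; at least 5 usable
points are required, and a correlogram that does not decay by at least a
factor of 2 over the lag range is rejected.  Tiny negative fitted μ2
(noise around a monodisperse sample) is clamped to zero in the reported
PDI.  "PDI within 10%" recovery claims are relative for nonzero PDI and
absolute (< 0.02) for PDI = 0, where a relative criterion is meaningless.

Vendor instruments report Z-average sizes from proprietary cumulant
variants; this implementation makes no claim of matching a specific
instrument's numbers, only of recovering its own generator's ground truth
and the published magnitudes (~170–200 nm LUVs, PDI 0.1–0.35).

## Synthetic data and presets

The generator produces raw data with the statistical structure the
analysis assumes:

* **Spectra** — two Gaussian bands (centers 440/490 nm, common σ = 18 nm)
  whose amplitudes solve a 2×2 linear system including cross-band overlap,
  so the 440/490 nm point intensities hit the target GP exactly.  Real
  Laurdan bands are skewed; since GP uses only two point intensities, band
  shape does not affect correctness, only realism of the full spectrum.
  GP-level Gaussian noise (default sd 0.005 per replicate) emulates
  replicate scatter; this noise level reproduces the ±0.3–0.5 °C Tm
  uncertainty scale of replicate fluorimetry.
* **Quenching pairs** — ruler inversion at a known radius, 1% default
  multiplicative noise on F.
* **Correlograms** — the cumulant expression above on an 80-point
  geometric lag grid (0.5 µs – 5 ms), intercept β = 0.9, additive noise
  1e-3.

Seventy presets (14 composition families × 5 doses: 0, 50, 100, 200,
500 µM) encode the study conditions: the SM family carries the Tm ladder
38.5 → 37.4 °C with slopes 3.00 → 4.25 °C chosen so fitted Lorentzian
widths land on the published 11.4 → 17.4 °C scale and increase strictly
with dose (the published width sequence has a single non-monotone pair at
50/100 µM; the presets use the sorted sequence, preserving the set and the
stated broadening trend).  Ternary presets carry the published domain
radii, vesicle sizes and PDIs.  Dose-response tables encode the qualitative
structure reported for GP at 37 °C: monotone ordering for POPC-containing
families, monotone mild fluidization for SM/Chol, and a bimodal
fluidize-then-order response for every PDPC-containing family with a single
sign change at the stated crossover (350 µM for pure PDPC and PDPC/Chol,
150 µM for ternary PDPC mixtures).  The percentages themselves are design
choices (the source reports bar plots, not tables), set so that
sign-determining doses sit ≥ 4σ from zero at the default noise with
3 replicates.  Base GP(37 °C) levels are likewise chosen to reproduce the
reported ordering ranks (pure PDPC below pure POPC; ternary PDPC above
ternary POPC; GP rising with cholesterol).

What passing tests therefore show: the analysis recovers known parameters
from data with the assumed structure at realistic noise.  What they do not
show: robustness to spectral baselines, scattering backgrounds, multimodal
size distributions, baseline shifts of the quenching calibration under
dosing, or any feature of real instruments absent from the generator.

## Problem sizes

Tests and the acceptance script run at desk scale: 7-point thermal scans
(27–57 °C, 5 °C steps, up to 3 replicates), 200-seed Tm scatter estimates,
80-point correlograms, and the full 70-preset identifiability sweep with
3 noisy replicates each; the whole suite completes in a few seconds.
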