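"""Phase-transition extraction from thermal GP series.

The melting of a saturated-lipid bilayer (gel -> liquid-disordered) shows up
as a sigmoidal drop of GP with temperature.  The pipeline mirrors common
fluorimetry practice:

1. fit a four-parameter Boltzmann sigmoid
       GP(T) = A2 + (A1 - A2) / (1 + exp((T - Tm)/dT)),
   whose inflection point Tm is the transition midpoint;
2. take the *analytic* first derivative of the fitted curve on a dense grid;
3. fit that derivative with a Lorentzian, whose center is a second Tm
   estimate and whose FWHM quantifies transition width (cooperativity).

Both Tm estimates coincide for noiseless data (the logistic derivative is
symmetric about Tm); reporting both follows the convention of thermotropic
GP studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError, UsageError, ValidationError
from .laurdan_gp import ThermalGPSeries
from .spectra_io import LipidComposition

#: minimum GP span below which a series carries no transition signal
MIN_GP_RANGE = 0.02

#: fit controls (relative tolerance and evaluation budget for curve_fit)
FIT_XTOL = 1e-10
FIT_MAX_EVALS = 10000

#: default resolution (°C) of the derivative grid
DERIVATIVE_GRID_STEP_C = 0.1


def boltzmann_gp(t, gp_low_T, gp_high_T, tm_C, slope_C):
    """Boltzmann sigmoid: plateau ``gp_low_T`` below Tm, ``gp_high_T`` above."""
    return gp_high_T + (gp_low_T - gp_high_T) / (1.0 + np.exp((t - tm_C) / slope_C))


def lorentzian(t, center_C, width_C, amplitude, offset):
    """Lorentzian in FWHM form: offset + (2A/pi) * w / (4(t-c)^2 + w^2)."""
    return offset + (2.0 * amplitude / np.pi) * width_C / (
        4.0 * (t - center_C) ** 2 + width_C**2)


@dataclass(frozen=True, eq=False)
class SigmoidFit:
    """Fitted Boltzmann parameters of one thermal GP curve."""

    gp_low_T: float
    gp_high_T: float
    tm_C: float
    slope_C: float
    r_squared: float
    covariance: np.ndarray
    t_min_C: float
    t_max_C: float

    def __post_init__(self) -> None:
        if self.slope_C <= 0:
            raise FitError(f"slope_C must be > 0, got {self.slope_C:g}")
        if not (self.t_min_C - 10 <= self.tm_C <= self.t_max_C + 10):
            raise FitError(
                f"fitted Tm {self.tm_C:g} C far outside the data range "
                f"[{self.t_min_C:g}, {self.t_max_C:g}] C")
        if self.r_squared > 1 + 1e-12:
            raise ValidationError("r_squared cannot exceed 1")

    def __call__(self, t):
        return boltzmann_gp(t, self.gp_low_T, self.gp_high_T, self.tm_C,
                            self.slope_C)


@dataclass(frozen=True)
class LorentzianFit:
    """Lorentzian fitted to the sigmoid's first derivative.

    ``width_C`` is the full width at half maximum; ``amplitude`` is the area
    parameter of the FWHM form (negative when GP falls with temperature, so
    its sign matches the derivative's).
    """

    center_C: float
    width_C: float
    amplitude: float
    offset: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.width_C <= 0:
            raise FitError(f"width_C must be > 0, got {self.width_C:g}")

    @property
    def peak_height(self) -> float:
        """Signed derivative extremum, 2A/(pi*w), in GP/°C."""
        return 2.0 * self.amplitude / (np.pi * self.width_C)

    def __call__(self, t):
        return lorentzian(t, self.center_C, self.width_C, self.amplitude,
                          self.offset)


@dataclass(frozen=True)
class TransitionResult:
    """Both Tm estimates (sigmoid inflection and Lorentzian center)."""

    sigmoid: SigmoidFit
    lorentzian: LorentzianFit
    composition: LipidComposition | None = None


def fit_boltzmann_sigmoid(series: ThermalGPSeries) -> SigmoidFit:
    """Least-squares Boltzmann fit of GP(T).

    Points are weighted by 1/SD^2 when every temperature carries a finite,
    positive replicate SD; otherwise the fit is unweighted.  Initialization
    is deterministic: plateaus from the endpoint GPs, Tm from the steepest
    finite-difference midpoint, dT = 3 °C.
    """
    order = np.argsort(series.temperature_C)
    t = series.temperature_C[order]
    gp = series.gp[order]
    if t.size < 5:
        raise UsageError(f"need >= 5 temperature points, got {t.size}")
    if np.ptp(gp) < MIN_GP_RANGE:
        raise DegenerateDataError(
            f"GP range {np.ptp(gp):.3g} < {MIN_GP_RANGE}; no transition signal")
    slopes = np.diff(gp) / np.diff(t)
    k = int(np.argmax(np.abs(slopes)))
    p0 = (gp[0], gp[-1], 0.5 * (t[k] + t[k + 1]), 3.0)
    sigma = None
    if series.gp_sd is not None:
        sd = np.asarray(series.gp_sd, dtype=float)[order]
        if np.all(np.isfinite(sd)) and np.all(sd > 0):
            sigma = sd
    bounds = ([-2.0, -2.0, t[0] - 20.0, 1e-3], [2.0, 2.0, t[-1] + 20.0, 100.0])
    try:
        popt, pcov = curve_fit(
            boltzmann_gp, t, gp, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=bounds, xtol=FIT_XTOL, ftol=FIT_XTOL, gtol=FIT_XTOL,
            max_nfev=FIT_MAX_EVALS)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    resid = gp - boltzmann_gp(t, *popt)
    ss_tot = float(np.sum((gp - gp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return SigmoidFit(gp_low_T=float(popt[0]), gp_high_T=float(popt[1]),
                      tm_C=float(popt[2]), slope_C=float(popt[3]),
                      r_squared=r2, covariance=pcov,
                      t_min_C=float(t[0]), t_max_C=float(t[-1]))


def first_derivative_curve(fit: SigmoidFit,
                           grid_step_C: float = DERIVATIVE_GRID_STEP_C
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic dGP/dT of the fitted sigmoid on a dense grid.

    dGP/dT = -(A1 - A2)/(4 dT) * sech^2((T - Tm)/(2 dT)); its extremum sits
    exactly at Tm with magnitude |A1 - A2| / (4 dT).
    """
    if grid_step_C <= 0:
        raise UsageError("grid_step_C must be > 0")
    t = np.arange(fit.t_min_C, fit.t_max_C + 0.5 * grid_step_C, grid_step_C)
    x = (t - fit.tm_C) / (2.0 * fit.slope_C)
    dgp = -(fit.gp_low_T - fit.gp_high_T) / (4.0 * fit.slope_C) / np.cosh(x) ** 2
    return t, dgp


def fit_lorentzian(curve: tuple[np.ndarray, np.ndarray]) -> LorentzianFit:
    """Least-squares Lorentzian (FWHM form, with baseline offset)."""
    t, y = (np.asarray(a, dtype=float) for a in curve)
    if t.size < 5 or t.shape != y.shape:
        raise UsageError("derivative curve must hold >= 5 (T, dGP/dT) samples")
    offset0 = 0.5 * (y[0] + y[-1])
    k = int(np.argmax(np.abs(y - offset0)))
    peak = y[k] - offset0
    if peak == 0:
        raise DegenerateDataError("derivative curve has no extremum")
    half = np.abs(y - offset0) >= 0.5 * abs(peak)
    width0 = max(float(t[half][-1] - t[half][0]), float(t[1] - t[0]))
    p0 = (t[k], width0, peak * np.pi * width0 / 2.0, offset0)
    try:
        popt, _ = curve_fit(lorentzian, t, y, p0=p0, xtol=FIT_XTOL,
                            ftol=FIT_XTOL, gtol=FIT_XTOL, maxfev=FIT_MAX_EVALS)
    except RuntimeError as exc:
        raise FitError(f"Lorentzian fit did not converge: {exc}") from exc
    if popt[1] < 0:  # width/amplitude sign ambiguity: fold onto width > 0
        popt[1] = -popt[1]
        popt[2] = -popt[2]
    resid = y - lorentzian(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return LorentzianFit(center_C=float(popt[0]), width_C=float(popt[1]),
                         amplitude=float(popt[2]), offset=float(popt[3]),
                         r_squared=r2)


def transition_summary(series: ThermalGPSeries,
                       grid_step_C: float = DERIVATIVE_GRID_STEP_C
                       ) -> TransitionResult:
    """Full Tm pipeline: sigmoid fit -> analytic derivative -> Lorentzian."""
    sig = fit_boltzmann_sigmoid(series)
    lor = fit_lorentzian(first_derivative_curve(sig, grid_step_C))
    return TransitionResult(sigmoid=sig, lorentzian=lor,
                            composition=series.composition)
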