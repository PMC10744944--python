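"""Vesicle sizing from DLS intensity autocorrelation by the method of cumulants.

The normalized intensity autocorrelation of a dilute vesicle suspension,
g2(tau) - 1, decays with the translational diffusion of the scatterers.
Within the cumulant expansion truncated at second order,

    g2(tau) - 1 = beta * exp(-2 Gamma tau) * (1 + (mu2/2) tau^2)^2,

where Gamma = D q^2 is the mean decay rate, mu2 the variance of the decay
rate distribution, and beta the coherence intercept.  The polydispersity
index is PDI = mu2 / Gamma^2, and the hydrodynamic diameter follows from
Stokes-Einstein:  D_h = k_B T / (3 pi eta D).

``cumulant_fit`` seeds a nonlinear least-squares fit of the expression above
(the standard g2-domain cumulant fit) with a linearized log-g1 fit, which
keeps the estimate exact for noiseless data at any admissible mu2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.optimize import curve_fit

from .errors import FitError, UsageError, ValidationError


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and sample constants of the light-scattering setup.

    Defaults describe a 633 nm backscatter (173°) instrument with an
    aqueous buffer at 37 °C (viscosity of water, 0.6913 mPa·s; the <=2%
    salt correction is ignored).
    """

    wavelength_nm: float = 633.0
    angle_deg: float = 173.0
    refractive_index: float = 1.330
    temperature_K: float = 310.15
    viscosity_mPa_s: float = 0.6913

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "refractive_index", "temperature_K",
                     "viscosity_mPa_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0.0 < self.angle_deg < 180.0):
            raise ValidationError("angle_deg must lie in (0, 180)")


@dataclass(frozen=True, eq=False)
class Correlogram:
    """Baseline-subtracted intensity autocorrelation g2(tau) - 1."""

    lag_s: np.ndarray
    g2_minus_1: np.ndarray
    config: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_s, dtype=float)
        g2 = np.asarray(self.g2_minus_1, dtype=float)
        object.__setattr__(self, "lag_s", lag)
        object.__setattr__(self, "g2_minus_1", g2)
        if lag.ndim != 1 or lag.shape != g2.shape:
            raise ValidationError("lag and g2-1 arrays must match in length")
        if lag[0] <= 0 or not np.all(np.diff(lag) > 0):
            raise ValidationError("lag times must be positive and strictly increasing")
        if not np.all(np.isfinite(g2)):
            raise ValidationError("g2-1 values must be finite")
        if not (0.0 < g2[0] <= 1.2):
            raise ValidationError(
                f"first g2-1 value {g2[0]:g} outside (0, 1.2]; check baseline")

    def __len__(self) -> int:
        return self.lag_s.size


@dataclass(frozen=True)
class SizeResult:
    """Hydrodynamic diameter and polydispersity of one correlogram."""

    dh_nm: float
    pdi: float
    gamma_s: float
    mu2: float
    beta: float

    def __post_init__(self) -> None:
        if self.dh_nm <= 0:
            raise ValidationError("dh_nm must be > 0")
        if self.pdi < 0:
            raise ValidationError("pdi must be >= 0")
        if abs(self.pdi - self.mu2 / self.gamma_s**2) > 1e-9:
            raise ValidationError("pdi inconsistent with mu2 / gamma^2")


def scattering_vector(config: InstrumentConfig) -> float:
    """Magnitude of the scattering vector, q = (4 pi n / lambda) sin(theta/2), 1/m."""
    lam_m = config.wavelength_nm * 1e-9
    theta = np.deg2rad(config.angle_deg)
    return float(4.0 * np.pi * config.refractive_index / lam_m * np.sin(theta / 2.0))


def _cumulant_g2(tau, beta, gamma, mu2):
    return beta * np.exp(-2.0 * gamma * tau) * (1.0 + 0.5 * mu2 * tau**2) ** 2


def cumulant_fit(correlogram: Correlogram, order: int = 2
                 ) -> tuple[float, float, float]:
    """Fit (beta, Gamma, mu2) to a correlogram by the method of cumulants.

    The tail is truncated at the first nonpositive g2-1 point (noise takes
    over there); at least 5 usable points must remain.  ``order=1`` forces
    mu2 = 0 (single-exponential); ``order=2`` returns the second cumulant.
    """
    if order not in (1, 2):
        raise UsageError("order must be 1 or 2")
    lag, g2 = correlogram.lag_s, correlogram.g2_minus_1
    if lag.size < 10:
        raise UsageError("need >= 10 lag points")
    nonpos = np.nonzero(g2 <= 0)[0]
    if nonpos.size:
        lag, g2 = lag[: nonpos[0]], g2[: nonpos[0]]
    if lag.size < 5:
        raise FitError(f"only {lag.size} usable points after truncation")
    if np.min(g2) > 0.5 * g2[0]:
        raise FitError("correlogram does not decay over the lag range")
    # linearized log-g1 fit on the early decay for initialization
    g1 = np.sqrt(g2)
    early = g1 >= 0.2 * g1[0]
    te, ye, we = lag[early], np.log(g1[early]), g1[early] ** 2
    design = np.stack([np.ones_like(te), -te], axis=1)
    sw = np.sqrt(we)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], ye * sw, rcond=None)
    beta0 = float(np.exp(2.0 * coef[0]))
    gamma0 = float(coef[1])
    if not np.isfinite(gamma0) or gamma0 <= 0:
        raise FitError("no measurable decay in correlogram")
    try:
        if order == 1:
            popt, _ = curve_fit(lambda t, b, g: _cumulant_g2(t, b, g, 0.0),
                                lag, g2, p0=(beta0, gamma0), maxfev=10000)
            beta, gamma, mu2 = float(popt[0]), float(popt[1]), 0.0
        else:
            popt, _ = curve_fit(_cumulant_g2, lag, g2,
                                p0=(beta0, gamma0, 0.05 * gamma0**2),
                                maxfev=10000)
            beta, gamma, mu2 = (float(v) for v in popt)
    except RuntimeError as exc:
        raise FitError(f"cumulant fit did not converge: {exc}") from exc
    if gamma <= 0 or beta <= 0:
        raise FitError(
            f"unphysical cumulant parameters (beta={beta:g}, gamma={gamma:g})")
    return beta, gamma, mu2


def size_from_gamma(gamma_s: float, config: InstrumentConfig) -> float:
    """Stokes-Einstein inversion: Gamma -> D = Gamma/q^2 -> D_h (nm)."""
    if gamma_s <= 0:
        raise UsageError("gamma_s must be > 0")
    q = scattering_vector(config)
    diffusion = gamma_s / q**2  # m^2/s
    eta = config.viscosity_mPa_s * 1e-3  # Pa s
    dh_m = K_B * config.temperature_K / (3.0 * np.pi * eta * diffusion)
    return float(dh_m * 1e9)


def analyze_correlogram(correlogram: Correlogram, order: int = 2) -> SizeResult:
    """Full sizing chain: cumulant fit plus Stokes-Einstein inversion."""
    beta, gamma, mu2 = cumulant_fit(correlogram, order=order)
    mu2 = max(mu2, 0.0)  # tiny negative second cumulants are noise
    return SizeResult(dh_nm=size_from_gamma(gamma, correlogram.config),
                      pdi=mu2 / gamma**2, gamma_s=gamma, mu2=mu2, beta=beta)


def relative_dh_change(dh_resv_nm: float, dh_0_nm: float) -> float:
    """dD_h/D_h in percent against the dose-free control."""
    if dh_0_nm <= 0:
        raise UsageError("control diameter must be > 0")
    return 100.0 * (dh_resv_nm - dh_0_nm) / dh_0_nm
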