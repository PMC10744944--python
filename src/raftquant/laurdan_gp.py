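"""Generalized polarization (GP) of Laurdan emission and derived statistics.

GP is the normalized two-band ratio

    GP = (I440 - I490) / (I440 + I490)

where I440 and I490 are the emission intensities at the characteristic
wavelengths of the ordered (440 nm) and disordered (490 nm) lipid phases
under 355 nm excitation.  GP lies in [-1, 1]; positive values indicate
tightly packed (gel or liquid-ordered) bilayers, negative values a
liquid-disordered state.

This module turns spectra into GP values, builds GP-versus-temperature
series with replicate statistics, and computes the dose-response statistic
dGP/GP (in %) together with its zero-crossing dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, RangeError, UsageError, ValidationError
from .spectra_io import (
    BAND_FLUID_NM,
    BAND_ORDERED_NM,
    TEMPERATURE_MATCH_TOL_C,
    EmissionSpectrum,
    LipidComposition,
    SpectralSeries,
)

#: |GP_0| below which the relative change dGP/|GP_0| is undefined
BASELINE_EPSILON = 1e-6


@dataclass(frozen=True)
class GPValue:
    """GP of one spectrum, with the band intensities that produced it."""

    gp: float
    i440_au: float
    i490_au: float
    temperature_C: float
    composition: LipidComposition | None = None

    def __post_init__(self) -> None:
        if self.i440_au + self.i490_au <= 0:
            raise DegenerateDataError("band intensities sum to zero")
        expected = (self.i440_au - self.i490_au) / (self.i440_au + self.i490_au)
        if abs(self.gp - expected) > 1e-12:
            raise ValidationError("gp inconsistent with band intensities")


@dataclass(frozen=True, eq=False)
class ThermalGPSeries:
    """GP versus temperature for one composition/dose.

    ``gp_sd`` holds the replicate sample SD per temperature (NaN where only
    a single replicate was measured) and may be None when unavailable.
    """

    temperature_C: np.ndarray
    gp: np.ndarray
    gp_sd: np.ndarray | None = None
    composition: LipidComposition | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        gp = np.asarray(self.gp, dtype=float)
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "gp", gp)
        if t.shape != gp.shape or t.ndim != 1:
            raise ValidationError("temperature and gp arrays must match in length")
        if np.any(np.abs(gp) > 1 + 1e-12):
            raise ValidationError("GP values must lie in [-1, 1]")
        if self.gp_sd is not None:
            sd = np.asarray(self.gp_sd, dtype=float)
            object.__setattr__(self, "gp_sd", sd)
            if sd.shape != t.shape:
                raise ValidationError("gp_sd length must match temperature grid")
            if np.any(sd[np.isfinite(sd)] < 0):
                raise ValidationError("gp_sd must be >= 0")

    def __len__(self) -> int:
        return self.temperature_C.size


@dataclass(frozen=True)
class GPChange:
    """Relative GP change of a dosed sample against its control.

    ``relative_pct = 100 * (gp_resv - gp_0) / |gp_0|``; positive values mean
    ordering (rigidification), negative fluidization, regardless of the sign
    of the control GP.
    """

    gp_resv: float
    gp_0: float
    delta_gp: float
    relative_pct: float

    def __post_init__(self) -> None:
        if abs(self.delta_gp - (self.gp_resv - self.gp_0)) > 1e-12:
            raise ValidationError("delta_gp inconsistent with gp_resv - gp_0")
        if self.delta_gp * self.relative_pct < 0:
            raise ValidationError("relative_pct sign must match delta_gp sign")


@dataclass(frozen=True)
class CrossoverResult:
    """Zero-crossing dose of a dGP/GP dose-response curve (µM), if any."""

    dose_uM: float | None
    reason: str | None = None


def band_intensity(spectrum: EmissionSpectrum, center_nm: float,
                   window_nm: float = 0.0) -> float:
    """Band intensity at ``center_nm``.

    With ``window_nm == 0`` the spectrum is linearly interpolated at the
    center; with a positive half-width the mean intensity over
    ``[center - w, center + w]`` is returned (trapezoidal average of the
    piecewise-linear spectrum).
    """
    wl, inten = spectrum.wavelength_nm, spectrum.intensity_au
    if window_nm < 0:
        raise UsageError("window_nm must be >= 0")
    if center_nm - window_nm < wl[0] or center_nm + window_nm > wl[-1]:
        raise RangeError(
            f"band [{center_nm - window_nm:g}, {center_nm + window_nm:g}] nm "
            f"outside the spectral grid [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    if window_nm == 0:
        return float(np.interp(center_nm, wl, inten))
    dense = np.linspace(center_nm - window_nm, center_nm + window_nm, 201)
    return float(np.trapezoid(np.interp(dense, wl, inten), dense) / (2 * window_nm))


def generalized_polarization(i440: float, i490: float) -> float:
    """GP = (I440 - I490) / (I440 + I490), in [-1, 1]."""
    if i440 < 0 or i490 < 0:
        raise ValidationError("band intensities must be >= 0")
    total = i440 + i490
    if total <= 0:
        raise DegenerateDataError("both bands are zero; GP undefined")
    return (i440 - i490) / total


def gp_from_spectrum(spectrum: EmissionSpectrum,
                     band_window_nm: float = 0.0) -> GPValue:
    """Extract both band intensities from one spectrum and form its GP."""
    i440 = band_intensity(spectrum, BAND_ORDERED_NM, band_window_nm)
    i490 = band_intensity(spectrum, BAND_FLUID_NM, band_window_nm)
    return GPValue(
        gp=generalized_polarization(i440, i490),
        i440_au=i440,
        i490_au=i490,
        temperature_C=spectrum.temperature_C,
        composition=spectrum.composition,
    )


def gp_thermal_series(series: SpectralSeries,
                      band_window_nm: float = 0.0) -> ThermalGPSeries:
    """One GP per scan temperature, replicates averaged at the GP level.

    Spectra whose temperatures agree within 0.01 °C are treated as
    replicates; their GPs are averaged and the sample SD (ddof=1) recorded.
    Temperatures with a single replicate get SD = NaN.
    """
    groups: list[tuple[float, list[float]]] = []
    for spec in series.spectra:  # already temperature-sorted
        gp = gp_from_spectrum(spec, band_window_nm).gp
        if groups and spec.temperature_C - groups[-1][0] <= TEMPERATURE_MATCH_TOL_C:
            groups[-1][1].append(gp)
        else:
            groups.append((spec.temperature_C, [gp]))
    temps = np.array([t for t, _ in groups])
    means = np.array([float(np.mean(g)) for _, g in groups])
    sds = np.array([float(np.std(g, ddof=1)) if len(g) > 1 else np.nan
                    for _, g in groups])
    return ThermalGPSeries(temperature_C=temps, gp=means, gp_sd=sds,
                           composition=series.composition)


def relative_gp_change(gp_resv: float, gp_0: float) -> GPChange:
    """dGP/GP in percent, with |GP_0| in the denominator.

    Using the absolute control GP keeps the sign convention physical:
    positive always means ordering, even for fluid membranes whose control
    GP is negative.
    """
    if abs(gp_0) <= BASELINE_EPSILON:
        raise DegenerateDataError(
            f"|GP_0| <= {BASELINE_EPSILON:g}; relative change undefined")
    delta = gp_resv - gp_0
    return GPChange(gp_resv=gp_resv, gp_0=gp_0, delta_gp=delta,
                    relative_pct=100.0 * delta / abs(gp_0))


def crossover_concentration(doses_uM, relative_pct) -> CrossoverResult:
    """Piecewise-linear zero crossing of dGP/GP versus dose.

    Returns the first dose at which the interpolated dose-response changes
    sign; a response that never changes sign yields ``dose_uM=None`` with a
    reason.
    """
    doses = np.asarray(doses_uM, dtype=float)
    pct = np.asarray(relative_pct, dtype=float)
    if doses.size < 2 or doses.shape != pct.shape:
        raise UsageError("need >= 2 (dose, pct) pairs of equal length")
    if not np.all(np.diff(doses) > 0):
        raise UsageError("doses must be strictly increasing")
    for i in range(doses.size):
        if pct[i] == 0.0:
            return CrossoverResult(dose_uM=float(doses[i]))
        if i + 1 < doses.size and pct[i] * pct[i + 1] < 0:
            frac = pct[i] / (pct[i] - pct[i + 1])
            return CrossoverResult(
                dose_uM=float(doses[i] + frac * (doses[i + 1] - doses[i])))
    return CrossoverResult(dose_uM=None, reason="no sign change in dose response")
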