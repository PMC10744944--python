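"""Synthetic raw-data generators emulating the study's instrument outputs.

Three generators produce the raw inputs of the three analysis chains:

* ``synth_laurdan_spectrum`` — a two-Gaussian Laurdan emission spectrum
  (ordered band at 440 nm, disordered band at 490 nm) whose amplitudes are
  solved from a 2x2 linear system so the point intensities at exactly
  440/490 nm reproduce a target GP *including* cross-band overlap.  Real
  Laurdan bands are log-normal-skewed, but GP depends only on the two point
  intensities, so the Gaussian shape is sufficient and exact.
* ``synth_quenching_pair`` — an (F, F_o) DPH fluorescence pair obtained by
  inverting the linear quenching ruler at a known true domain radius.
* ``synth_dls_correlogram`` — a second-order-cumulant correlogram for a
  known hydrodynamic diameter and PDI with additive Gaussian noise.

``preset_registry`` enumerates every composition/dose condition of the
study (pure PCs, PC/Chol binaries, SM, SM/Chol, PC/SM/Chol ternaries at
five resveratrol doses) with encoded ground truth: thermal Boltzmann
parameters (the SM family carries the published Tm ladder 38.5 -> 37.4 °C),
dose-response tables for dGP/GP at 37 °C, the published control and dosed
domain radii, and the published vesicle sizes and PDIs.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dls_sizing import Correlogram, InstrumentConfig, scattering_vector
from .errors import RangeError, UsageError, ValidationError
from .spectra_io import (
    BAND_FLUID_NM,
    BAND_ORDERED_NM,
    EmissionSpectrum,
    LipidComposition,
    SpectralSeries,
)
from .tempo_quenching import QuenchingCalibration
from .thermotropy import boltzmann_gp

K_B = 1.380649e-23  # J/K

#: default temperature scan: 27-57 °C in 5 °C steps
DEFAULT_SCAN_GRID_C = np.arange(27.0, 58.0, 5.0)

#: default noise levels (GP sd per replicate; fractional quenching noise;
#: additive correlogram noise) matching the scatter of the emulated data
DEFAULT_GP_NOISE_SD = 0.005
DEFAULT_QUENCH_NOISE_FRACTION = 0.01
DEFAULT_DLS_NOISE_SD = 1e-3


def _rng(seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SpectralShapeParams:
    """Band-shape parameters of the two-Gaussian Laurdan emission model."""

    center_ordered_nm: float = BAND_ORDERED_NM
    center_fluid_nm: float = BAND_FLUID_NM
    sigma_nm: float = 18.0
    total_intensity_au: float = 1000.0
    noise_sd_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for c in (self.center_ordered_nm, self.center_fluid_nm):
            if not (390.0 <= c <= 600.0):
                raise ValidationError("band centers must lie in 390-600 nm")
        if self.sigma_nm <= 0:
            raise ValidationError("sigma_nm must be > 0")
        if self.total_intensity_au <= 0:
            raise ValidationError("total_intensity_au must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValidationError("noise_sd_fraction must be >= 0")


@dataclass(frozen=True)
class ThermalModelParams:
    """Boltzmann GP(T) model with per-dose modifiers.

    ``delta_tm_by_dose`` / ``delta_slope_by_dose`` shift the transition
    midpoint and steepness at each resveratrol dose (µM);
    ``gp_offset_by_dose`` shifts the whole curve, encoding the dGP/GP
    dose response at 37 °C.
    """

    gp_ordered: float
    gp_fluid: float
    tm_C: float
    slope_C: float
    delta_tm_by_dose: dict[float, float] = field(default_factory=dict)
    delta_slope_by_dose: dict[float, float] = field(default_factory=dict)
    gp_offset_by_dose: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gp_ordered <= self.gp_fluid:
            raise ValidationError("gp_ordered must exceed gp_fluid")
        if self.slope_C <= 0:
            raise ValidationError("slope_C must be > 0")

    def gp_at(self, temperature_C, dose_uM: float = 0.0):
        """Model GP at one or more temperatures for the given dose."""
        tm = self.tm_C + self.delta_tm_by_dose.get(dose_uM, 0.0)
        dt = self.slope_C + self.delta_slope_by_dose.get(dose_uM, 0.0)
        off = self.gp_offset_by_dose.get(dose_uM, 0.0)
        return off + boltzmann_gp(np.asarray(temperature_C, dtype=float),
                                  self.gp_ordered, self.gp_fluid, tm, dt)


@dataclass(frozen=True)
class GeneratorPreset:
    """Ground-truth parameters of one composition/dose condition."""

    name: str
    composition: LipidComposition
    thermal: ThermalModelParams
    true_radius_A: float | None = None
    true_dh_nm: float | None = None
    true_pdi: float | None = None
    bimodal: bool = False
    crossover_uM: float | None = None

    @property
    def dose_uM(self) -> float:
        return self.composition.resv_uM

    @property
    def true_tm_C(self) -> float:
        return self.thermal.tm_C + self.thermal.delta_tm_by_dose.get(
            self.dose_uM, 0.0)

    @property
    def true_slope_C(self) -> float:
        return self.thermal.slope_C + self.thermal.delta_slope_by_dose.get(
            self.dose_uM, 0.0)

    def true_gp_at(self, temperature_C):
        return self.thermal.gp_at(temperature_C, self.dose_uM)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def synth_laurdan_spectrum(gp_target: float,
                           shape: SpectralShapeParams | None = None,
                           temperature_C: float = 37.0,
                           composition: LipidComposition | None = None,
                           replicate_id: str = "r1",
                           rng: np.random.Generator | None = None
                           ) -> EmissionSpectrum:
    """Two-band spectrum on a 1 nm grid hitting ``gp_target`` exactly.

    The band amplitudes (Ao, Af) solve

        [[1, c], [c, 1]] @ [Ao, Af] = [I440, I490],

    with c the cross-band Gaussian overlap and the point intensities chosen
    as I440 = (1+gp)/2 * S, I490 = (1-gp)/2 * S, so the analyzed GP equals
    the target to machine precision before noise.  Multiplicative Gaussian
    noise is applied last.
    """
    shape = shape or SpectralShapeParams()
    if not (-1.0 < gp_target < 1.0):
        raise RangeError(f"gp_target must lie in (-1, 1), got {gp_target:g}")
    sep = shape.center_fluid_nm - shape.center_ordered_nm
    c = math.exp(-(sep**2) / (2.0 * shape.sigma_nm**2))
    i440 = 0.5 * (1.0 + gp_target) * shape.total_intensity_au
    i490 = 0.5 * (1.0 - gp_target) * shape.total_intensity_au
    det = 1.0 - c * c
    a_o = (i440 - c * i490) / det
    a_f = (i490 - c * i440) / det
    if a_o < 0 or a_f < 0:
        raise RangeError(
            f"gp_target {gp_target:g} unreachable with band overlap c={c:.3g}")
    wl = np.arange(390.0, 601.0, 1.0)
    inten = (a_o * np.exp(-((wl - shape.center_ordered_nm) ** 2)
                          / (2.0 * shape.sigma_nm**2))
             + a_f * np.exp(-((wl - shape.center_fluid_nm) ** 2)
                            / (2.0 * shape.sigma_nm**2)))
    if shape.noise_sd_fraction > 0:
        gen = _rng(shape.seed, rng)
        inten = inten * (1.0 + gen.normal(0.0, shape.noise_sd_fraction, wl.size))
        inten = np.clip(inten, 0.0, None)
    return EmissionSpectrum(wavelength_nm=wl, intensity_au=inten,
                            temperature_C=temperature_C,
                            composition=composition, replicate_id=replicate_id)


def synth_thermal_scan(preset: GeneratorPreset,
                       grid_C: np.ndarray | None = None,
                       noise_sd_gp: float = DEFAULT_GP_NOISE_SD,
                       seed: int | None = None,
                       n_replicates: int = 1,
                       shape: SpectralShapeParams | None = None
                       ) -> SpectralSeries:
    """Temperature scan of the preset: one spectrum per grid point/replicate.

    GP-level Gaussian noise (sd ``noise_sd_gp``) jitters each replicate's
    target GP before the exact spectrum is built, matching how replicate
    scatter appears on GP in the emulated experiment.
    """
    grid = DEFAULT_SCAN_GRID_C if grid_C is None else np.asarray(grid_C, float)
    if n_replicates < 1:
        raise UsageError("n_replicates must be >= 1")
    gen = _rng(seed)
    spectra = []
    for t in grid:
        gp_true = float(preset.true_gp_at(t))
        for rep in range(n_replicates):
            gp = gp_true
            if noise_sd_gp > 0:
                gp = float(np.clip(gp + gen.normal(0.0, noise_sd_gp),
                                   -0.99, 0.99))
            spectra.append(synth_laurdan_spectrum(
                gp, shape=shape, temperature_C=float(t),
                composition=preset.composition,
                replicate_id=f"r{rep + 1}", rng=gen))
    return SpectralSeries(spectra=tuple(spectra))


# ---------------------------------------------------------------------------
# quenching
# ---------------------------------------------------------------------------


def synth_quenching_pair(true_radius_A: float,
                         cal: QuenchingCalibration,
                         f0_au: float = 1000.0,
                         noise_sd_fraction: float = 0.0,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> tuple[float, float]:
    """(F, F_o) pair whose ratio encodes ``true_radius_A`` via the ruler.

    Inverts R = Ro (Q - Q_ld)/(Q_lo - Q_ld) and applies multiplicative
    Gaussian noise to F only (F_o is the common reference).
    """
    if not (0.0 <= true_radius_A <= cal.ro_A):
        raise RangeError(
            f"true_radius_A must lie in [0, {cal.ro_A:g}] Å, got {true_radius_A:g}")
    q_true = cal.q_ld + (true_radius_A / cal.ro_A) * (cal.q_lo - cal.q_ld)
    f = q_true * f0_au
    if noise_sd_fraction > 0:
        f *= 1.0 + float(_rng(seed, rng).normal(0.0, noise_sd_fraction))
    return float(f), float(f0_au)


# ---------------------------------------------------------------------------
# DLS
# ---------------------------------------------------------------------------


def gamma_from_dh(dh_nm: float, config: InstrumentConfig) -> float:
    """Forward Stokes-Einstein chain: D_h -> D -> Gamma = D q^2 (1/s)."""
    eta = config.viscosity_mPa_s * 1e-3
    diffusion = K_B * config.temperature_K / (3.0 * np.pi * eta * dh_nm * 1e-9)
    return float(diffusion * scattering_vector(config) ** 2)


def synth_dls_correlogram(true_dh_nm: float,
                          true_pdi: float,
                          config: InstrumentConfig | None = None,
                          lag_grid_s: np.ndarray | None = None,
                          noise_sd: float = DEFAULT_DLS_NOISE_SD,
                          seed: int | None = None,
                          beta: float = 0.9,
                          rng: np.random.Generator | None = None
                          ) -> Correlogram:
    """Second-order-cumulant correlogram for a known (D_h, PDI)."""
    if true_dh_nm <= 0:
        raise RangeError("true_dh_nm must be > 0")
    if true_pdi < 0:
        raise RangeError("true_pdi must be >= 0")
    config = config or InstrumentConfig()
    lag = (np.geomspace(5e-7, 5e-3, 80) if lag_grid_s is None
           else np.asarray(lag_grid_s, dtype=float))
    gamma = gamma_from_dh(true_dh_nm, config)
    mu2 = true_pdi * gamma**2
    g2 = beta * np.exp(-2.0 * gamma * lag) * (1.0 + 0.5 * mu2 * lag**2) ** 2
    if noise_sd > 0:
        g2 = g2 + _rng(seed, rng).normal(0.0, noise_sd, lag.size)
        g2[0] = max(g2[0], 1e-6)  # keep the intercept usable
    return Correlogram(lag_s=lag, g2_minus_1=g2, config=config)


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

_DOSES_UM = (0.0, 50.0, 100.0, 200.0, 500.0)

#: SM thermal ladder: published sigmoid midpoints per dose, and frozen
#: slopes whose fitted Lorentzian FWHMs land on the published width scale
#: (11.4 -> 17.4 °C, strictly increasing with dose)
_SM_TM_BY_DOSE = {0.0: 38.5, 50.0: 37.9, 100.0: 37.7, 200.0: 37.6, 500.0: 37.4}
_SM_SLOPE_BY_DOSE = {0.0: 3.00, 50.0: 3.36, 100.0: 3.51, 200.0: 3.64,
                     500.0: 4.25}

#: dGP/GP (%) dose-response tables at 37 °C.  Directions follow the study
#: (ordering monotone for every POPC-containing family; bimodal for every
#: PDPC-containing family with sign change at the stated crossover dose:
#: 350 µM for pure PDPC and PDPC/Chol, 150 µM for ternary PDPC; SM/Chol is
#: monotone fluidizing).  Magnitudes are representative of the bar plots.
_PCT_TABLES: dict[str, dict[float, float]] = {
    "POPC": {50.0: -1.0, 100.0: 1.0, 200.0: 3.0, 500.0: 10.0},
    "PDPC": {50.0: -10.0, 100.0: -9.0, 200.0: -8.0, 500.0: 8.0},
    "POPC-Chol_75-25": {50.0: 2.0, 100.0: 4.0, 200.0: 8.0, 500.0: 15.0},
    "POPC-Chol_50-50": {50.0: 1.0, 100.0: 2.0, 200.0: 3.0, 500.0: 5.0},
    "PDPC-Chol_75-25": {50.0: -12.0, 100.0: -10.0, 200.0: -8.0, 500.0: 8.0},
    "PDPC-Chol_50-50": {50.0: -10.0, 100.0: -9.0, 200.0: -8.0, 500.0: 8.0},
    "SM": {50.0: 2.0, 100.0: 3.0, 200.0: 4.0, 500.0: 5.0},
    "SM-Chol_50-50": {50.0: -2.0, 100.0: -3.0, 200.0: -4.0, 500.0: -6.0},
    "POPC-SM-Chol_45-45-10": {50.0: 6.0, 100.0: 12.0, 200.0: 25.0, 500.0: 45.0},
    "POPC-SM-Chol_40-40-20": {50.0: 5.0, 100.0: 10.0, 200.0: 20.0, 500.0: 40.0},
    "POPC-SM-Chol_33-33-34": {50.0: 4.0, 100.0: 8.0, 200.0: 15.0, 500.0: 30.0},
    "PDPC-SM-Chol_45-45-10": {50.0: -9.0, 100.0: -8.0, 200.0: 8.0, 500.0: 12.0},
    "PDPC-SM-Chol_40-40-20": {50.0: -9.0, 100.0: -8.0, 200.0: 8.0, 500.0: 10.0},
    "PDPC-SM-Chol_33-33-34": {50.0: -9.0, 100.0: -8.0, 200.0: 8.0, 500.0: 9.0},
}

#: published domain radii (Å) per ternary mixture and dose
_RADIUS_TABLES: dict[str, dict[float, float]] = {
    "POPC-SM-Chol_40-40-20": {0.0: 24.3, 50.0: 25.2, 100.0: 26.7,
                              200.0: 30.2, 500.0: 34.4},
    "PDPC-SM-Chol_40-40-20": {0.0: 42.9, 50.0: 43.2, 100.0: 43.3,
                              200.0: 42.5, 500.0: 40.7},
    "POPC-SM-Chol_33-33-34": {0.0: 30.9, 50.0: 32.6, 100.0: 33.9,
                              200.0: 35.7, 500.0: 36.1},
    "PDPC-SM-Chol_33-33-34": {0.0: 43.1, 50.0: 45.2, 100.0: 45.7,
                              200.0: 45.0, 500.0: 44.4},
}

#: published vesicle sizes (nm) and PDIs per ternary mixture, doses 0/100/500
_DH_TABLES: dict[str, dict[float, float]] = {
    "POPC-SM-Chol_40-40-20": {0.0: 173.0, 100.0: 167.0, 500.0: 165.0},
    "PDPC-SM-Chol_40-40-20": {0.0: 177.0, 100.0: 180.0, 500.0: 176.0},
    "POPC-SM-Chol_33-33-34": {0.0: 188.0, 100.0: 169.0, 500.0: 177.0},
    "PDPC-SM-Chol_33-33-34": {0.0: 169.0, 100.0: 176.0, 500.0: 199.0},
}
_PDI_TABLES: dict[str, dict[float, float]] = {
    "POPC-SM-Chol_40-40-20": {0.0: 0.11, 100.0: 0.16, 500.0: 0.20},
    "PDPC-SM-Chol_40-40-20": {0.0: 0.19, 100.0: 0.22, 500.0: 0.26},
    "POPC-SM-Chol_33-33-34": {0.0: 0.19, 100.0: 0.20, 500.0: 0.25},
    "PDPC-SM-Chol_33-33-34": {0.0: 0.20, 100.0: 0.18, 500.0: 0.34},
}

#: base Boltzmann parameters per composition family (gp_ordered, gp_fluid,
#: tm_C, slope_C).  Families without a transition inside 27-57 °C place Tm
#: below the scan so GP declines gently; GP(37 °C) levels reproduce the
#: ordering ranks of the study (PDPC < POPC when pure; PDPC > POPC in
#: ternaries; all pure-PC GPs negative over the scan).
_THERMAL_BASE: dict[str, tuple[float, float, float, float]] = {
    "POPC": (-0.06, -0.30, 25.0, 10.0),
    "PDPC": (-0.12, -0.38, 20.0, 10.0),
    "POPC-Chol_75-25": (0.42, 0.18, 20.0, 14.0),
    "POPC-Chol_50-50": (0.55, 0.30, 15.0, 16.0),
    "PDPC-Chol_75-25": (0.42, 0.16, 20.0, 14.0),
    "PDPC-Chol_50-50": (0.50, 0.25, 15.0, 16.0),
    "SM": (0.55, -0.08, 38.5, 3.00),
    "SM-Chol_50-50": (0.62, 0.35, 12.0, 16.0),
    "POPC-SM-Chol_45-45-10": (0.30, 0.02, 22.0, 12.0),
    "POPC-SM-Chol_40-40-20": (0.38, 0.08, 22.0, 12.0),
    "POPC-SM-Chol_33-33-34": (0.48, 0.18, 20.0, 13.0),
    "PDPC-SM-Chol_45-45-10": (0.40, 0.16, 22.0, 12.0),
    "PDPC-SM-Chol_40-40-20": (0.44, 0.14, 22.0, 12.0),
    "PDPC-SM-Chol_33-33-34": (0.52, 0.22, 20.0, 13.0),
}

_COMPOSITIONS: dict[str, tuple[str, float, float, float]] = {
    "POPC": ("POPC", 1.0, 0.0, 0.0),
    "PDPC": ("PDPC", 1.0, 0.0, 0.0),
    "POPC-Chol_75-25": ("POPC", 0.75, 0.0, 0.25),
    "POPC-Chol_50-50": ("POPC", 0.50, 0.0, 0.50),
    "PDPC-Chol_75-25": ("PDPC", 0.75, 0.0, 0.25),
    "PDPC-Chol_50-50": ("PDPC", 0.50, 0.0, 0.50),
    "SM": ("none", 0.0, 1.0, 0.0),
    "SM-Chol_50-50": ("none", 0.0, 0.5, 0.5),
    "POPC-SM-Chol_45-45-10": ("POPC", 0.45, 0.45, 0.10),
    "POPC-SM-Chol_40-40-20": ("POPC", 0.40, 0.40, 0.20),
    "POPC-SM-Chol_33-33-34": ("POPC", 0.33, 0.33, 0.34),
    "PDPC-SM-Chol_45-45-10": ("PDPC", 0.45, 0.45, 0.10),
    "PDPC-SM-Chol_40-40-20": ("PDPC", 0.40, 0.40, 0.20),
    "PDPC-SM-Chol_33-33-34": ("PDPC", 0.33, 0.33, 0.34),
}

#: stated crossover doses (µM) of the bimodal (PDPC) families
_CROSSOVERS_UM: dict[str, float] = {
    "PDPC": 350.0,
    "PDPC-Chol_75-25": 350.0,
    "PDPC-Chol_50-50": 350.0,
    "PDPC-SM-Chol_45-45-10": 150.0,
    "PDPC-SM-Chol_40-40-20": 150.0,
    "PDPC-SM-Chol_33-33-34": 150.0,
}

_registry_cache: dict[str, GeneratorPreset] | None = None


def _build_registry() -> dict[str, GeneratorPreset]:
    registry: dict[str, GeneratorPreset] = {}
    for family, (species, pc, sm, chol) in _COMPOSITIONS.items():
        gp_o, gp_f, tm, dt = _THERMAL_BASE[family]
        base = ThermalModelParams(gp_ordered=gp_o, gp_fluid=gp_f,
                                  tm_C=tm, slope_C=dt)
        gp0_37 = float(base.gp_at(37.0, 0.0))
        pct = _PCT_TABLES[family]
        gp_offsets = {d: pct.get(d, 0.0) / 100.0 * abs(gp0_37)
                      for d in _DOSES_UM}
        if family == "SM":
            delta_tm = {d: _SM_TM_BY_DOSE[d] - _SM_TM_BY_DOSE[0.0]
                        for d in _DOSES_UM}
            delta_dt = {d: _SM_SLOPE_BY_DOSE[d] - _SM_SLOPE_BY_DOSE[0.0]
                        for d in _DOSES_UM}
        else:
            delta_tm, delta_dt = {}, {}
        thermal = ThermalModelParams(
            gp_ordered=gp_o, gp_fluid=gp_f, tm_C=tm, slope_C=dt,
            delta_tm_by_dose=delta_tm, delta_slope_by_dose=delta_dt,
            gp_offset_by_dose=gp_offsets)
        for dose in _DOSES_UM:
            name = (f"{family}_control" if dose == 0
                    else f"{family}_resv{dose:g}")
            comp = LipidComposition(pc_species=species, pc_frac=pc,
                                    sm_frac=sm, chol_frac=chol, resv_uM=dose)
            registry[name] = GeneratorPreset(
                name=name, composition=comp, thermal=thermal,
                true_radius_A=_RADIUS_TABLES.get(family, {}).get(dose),
                true_dh_nm=_DH_TABLES.get(family, {}).get(dose),
                true_pdi=_PDI_TABLES.get(family, {}).get(dose),
                bimodal=family in _CROSSOVERS_UM,
                crossover_uM=_CROSSOVERS_UM.get(family))
    return registry


def preset_registry() -> list[GeneratorPreset]:
    """All registered composition/dose presets (70 in total)."""
    global _registry_cache
    if _registry_cache is None:
        _registry_cache = _build_registry()
    return list(_registry_cache.values())


def get_preset(name: str) -> GeneratorPreset:
    """Look one preset up by name (e.g. ``"SM_control"``)."""
    preset_registry()
    assert _registry_cache is not None
    try:
        return _registry_cache[name]
    except KeyError:
        raise UsageError(f"unknown preset {name!r}") from None


def preset_families() -> dict[str, list[GeneratorPreset]]:
    """Presets grouped by composition family, doses ascending."""
    families: dict[str, list[GeneratorPreset]] = {}
    for preset in preset_registry():
        family = preset.name.rsplit("_", 1)[0]
        families.setdefault(family, []).append(preset)
    for members in families.values():
        members.sort(key=lambda p: p.dose_uM)
    return families
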