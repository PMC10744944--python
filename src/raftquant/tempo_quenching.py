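"""Liquid-ordered domain sizing from TEMPO quenching of DPH fluorescence.

DPH partitions evenly between liquid-ordered (L_o) and liquid-disordered
(L_d) phases, while the nitroxide quencher TEMPO accesses mainly the L_d
phase.  The residual fluorescence ratio Q = F/F_o (F with TEMPO, F_o
without) therefore grows with the fraction of DPH shielded inside L_o
domains.  Between the all-L_d baseline (pure PC, Q_PC) and the all-L_o
ceiling (SM/Chol 50/50, Q_SM/Chol), Q maps linearly onto a mean domain
radius:

    R = Ro * (Q - Q_PC) / (Q_SM/Chol - Q_PC)

with Ro the quenching sensing range (~4 Rc, Rc ≈ 6-12 Å, so Ro tops out
near 48 Å).  The default calibration uses Q_PC = 0.60 (POPC matrix) or
0.58 (PDPC matrix), Q_SM/Chol = 0.93, Ro = 47.5 Å — the value the four
control radii of the reference data set back-compute to within 0.1 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DegenerateDataError, UsageError, ValidationError
from .spectra_io import LipidComposition

#: default quenching sensing range (Å); see calibrate_ro
DEFAULT_RO_A = 47.5


@dataclass(frozen=True)
class QuenchingMeasurement:
    """One F/F_o pair measured at 37 °C."""

    f_au: float
    f0_au: float
    q: float
    composition: LipidComposition | None = None
    temperature_C: float = 37.0

    def __post_init__(self) -> None:
        if self.f0_au <= 0:
            raise DegenerateDataError("reference fluorescence F_o must be > 0")
        if abs(self.q - self.f_au / self.f0_au) > 1e-12:
            raise ValidationError("q inconsistent with f_au / f0_au")
        if not (0.0 <= self.q <= 1.05):
            raise ValidationError(
                f"Q = {self.q:g} outside [0, 1.05]; check the F/F_o pairing")


@dataclass(frozen=True)
class QuenchingCalibration:
    """L_d baseline, L_o ceiling and sensing range of the quenching ruler."""

    q_ld: float
    q_lo: float
    ro_A: float = DEFAULT_RO_A
    rc_A: float | None = None

    def __post_init__(self) -> None:
        if self.q_lo <= self.q_ld:
            raise CalibrationError(
                f"q_lo ({self.q_lo:g}) must exceed q_ld ({self.q_ld:g})")
        if self.ro_A <= 0:
            raise CalibrationError("ro_A must be > 0")
        if self.rc_A is not None:
            if not (6.0 <= self.rc_A <= 12.0):
                raise CalibrationError("rc_A must lie in [6, 12] Å")
            if abs(self.ro_A - 4.0 * self.rc_A) > 1e-9:
                raise CalibrationError("ro_A must equal 4 * rc_A")


#: calibrations for the two PC matrices (POPC vs PDPC L_d baselines)
POPC_CALIBRATION = QuenchingCalibration(q_ld=0.60, q_lo=0.93)
PDPC_CALIBRATION = QuenchingCalibration(q_ld=0.58, q_lo=0.93)


@dataclass(frozen=True)
class DomainRadiusResult:
    """Mean L_o domain radius (Å) with uncertainty and clamping flag."""

    radius_A: float
    sd_A: float = 0.0
    clamped: bool = False
    composition: LipidComposition | None = None

    def __post_init__(self) -> None:
        if self.sd_A < 0:
            raise ValidationError("sd_A must be >= 0")


@dataclass(frozen=True)
class RoCalibration:
    """Least-squares sensing range with per-control residuals (Å)."""

    ro_A: float
    max_residual_A: float
    residuals_A: tuple[float, ...]


def quenching_ratio(f: float, f0: float,
                    composition: LipidComposition | None = None,
                    temperature_C: float = 37.0) -> QuenchingMeasurement:
    """Form Q = F/F_o from one fluorescence pair."""
    if f0 <= 0:
        raise DegenerateDataError("reference fluorescence F_o must be > 0")
    if f < 0:
        raise ValidationError("fluorescence F must be >= 0")
    return QuenchingMeasurement(f_au=float(f), f0_au=float(f0),
                                q=float(f) / float(f0),
                                composition=composition,
                                temperature_C=temperature_C)


def domain_radius(q: float | QuenchingMeasurement,
                  cal: QuenchingCalibration,
                  q_sd: float = 0.0,
                  composition: LipidComposition | None = None
                  ) -> DomainRadiusResult:
    """Linear quenching ruler: R = Ro (Q - Q_ld)/(Q_lo - Q_ld).

    Raw values outside [0, Ro] — possible for noisy Q beyond the calibration
    baselines — are clamped into range with ``clamped=True``.
    """
    if isinstance(q, QuenchingMeasurement):
        composition = composition or q.composition
        q = q.q
    span = cal.q_lo - cal.q_ld
    raw = cal.ro_A * (q - cal.q_ld) / span
    clamped = not (0.0 <= raw <= cal.ro_A)
    radius = float(min(max(raw, 0.0), cal.ro_A))
    return DomainRadiusResult(radius_A=radius,
                              sd_A=radius_uncertainty(q_sd, cal),
                              clamped=clamped, composition=composition)


def radius_uncertainty(q_sd: float, cal: QuenchingCalibration) -> float:
    """First-order propagation of replicate Q scatter: Ro * sd(Q) / span."""
    if q_sd < 0:
        raise ValidationError("q_sd must be >= 0")
    return cal.ro_A * q_sd / (cal.q_lo - cal.q_ld)


def relative_radius_change(r_resv_A: float, r_0_A: float) -> float:
    """dR/R in percent against the dose-free control radius."""
    if r_0_A <= 0:
        raise DegenerateDataError("control radius must be > 0")
    return 100.0 * (r_resv_A - r_0_A) / r_0_A


def calibrate_ro(controls, cal_baselines) -> RoCalibration:
    """Least-squares sensing range Ro from (Q, known radius) control pairs.

    ``controls`` is a sequence of ``(q, known_radius_A)``; ``cal_baselines``
    is either one ``(q_ld, q_lo)`` pair applied to every control or a
    sequence of per-control pairs (needed when controls span both PC
    matrices).  Minimizes sum((Ro * x_i - r_i)^2) with
    x_i = (q_i - q_ld_i)/(q_lo_i - q_ld_i), which has the closed form
    Ro = sum(x r) / sum(x^2).
    """
    controls = list(controls)
    if not controls:
        raise UsageError("need at least one (q, radius) control pair")
    baselines = list(cal_baselines)
    if len(baselines) == 2 and np.isscalar(baselines[0]):
        baselines = [tuple(baselines)] * len(controls)
    if len(baselines) != len(controls):
        raise UsageError("one baseline pair, or one per control, required")
    x = np.empty(len(controls))
    r = np.empty(len(controls))
    for i, ((q, radius), (q_ld, q_lo)) in enumerate(zip(controls, baselines)):
        if q_lo <= q_ld:
            raise CalibrationError("q_lo must exceed q_ld")
        if not (q_ld < q < q_lo):
            raise UsageError(
                f"control Q = {q:g} not strictly between baselines "
                f"({q_ld:g}, {q_lo:g})")
        x[i] = (q - q_ld) / (q_lo - q_ld)
        r[i] = radius
    ro = float(np.sum(x * r) / np.sum(x * x))
    residuals = tuple(float(v) for v in (ro * x - r))
    return RoCalibration(ro_A=ro,
                         max_residual_A=float(np.max(np.abs(residuals))),
                         residuals_A=residuals)
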