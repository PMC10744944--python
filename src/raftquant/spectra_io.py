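"""Validated containers and plain-text I/O for fluorimeter-style tables.

Spectral files are plain CSV (comma separator, dot decimal) in one of two
dialects:

``long``
    columns ``sample, temperature_C, wavelength_nm, intensity`` — one row
    per (replicate, temperature, wavelength).
``wide``
    one ``wavelength_nm`` column plus one intensity column per temperature,
    the column header holding the temperature in °C (e.g. ``27.0``).

Sample metadata (lipid composition, resveratrol dose, excitation wavelength)
travels in a YAML sidecar named ``<file>.meta.yaml``, because a bare
intensity table has nowhere to put it.  Result tables are written as UTF-8
CSV with a fixed column order and 6-significant-digit floats.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CoverageError, UsageError, ValidationError

#: wavelengths (nm) every usable Laurdan spectrum must cover
BAND_ORDERED_NM = 440.0
BAND_FLUID_NM = 490.0

#: tolerance (°C) when grouping replicate spectra by temperature
TEMPERATURE_MATCH_TOL_C = 0.01

_PC_SPECIES = ("POPC", "PDPC", "none")


@dataclass(frozen=True)
class LipidComposition:
    """Mole-fraction composition of one vesicle preparation plus doses.

    ``pc_frac + sm_frac + chol_frac`` must sum to 1; ``resv_uM`` is the
    resveratrol dose (µM) and ``lipid_uM`` the total lipid concentration.
    """

    pc_species: str = "none"
    pc_frac: float = 0.0
    sm_frac: float = 0.0
    chol_frac: float = 0.0
    resv_uM: float = 0.0
    lipid_uM: float = 1000.0

    def __post_init__(self) -> None:
        if self.pc_species not in _PC_SPECIES:
            raise ValidationError(
                f"pc_species must be one of {_PC_SPECIES}, got {self.pc_species!r}"
            )
        fracs = (self.pc_frac, self.sm_frac, self.chol_frac)
        if any(f < 0 for f in fracs):
            raise ValidationError(f"mole fractions must be >= 0, got {fracs}")
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValidationError(f"mole fractions must sum to 1, got {sum(fracs)!r}")
        if self.resv_uM < 0:
            raise ValidationError("resv_uM must be >= 0")
        if self.lipid_uM <= 0:
            raise ValidationError("lipid_uM must be > 0")

    @property
    def label(self) -> str:
        """Compact composition label, e.g. ``POPC-SM-Chol_40-40-20``."""
        parts, fracs = [], []
        if self.pc_frac > 0:
            parts.append(self.pc_species)
            fracs.append(self.pc_frac)
        if self.sm_frac > 0:
            parts.append("SM")
            fracs.append(self.sm_frac)
        if self.chol_frac > 0:
            parts.append("Chol")
            fracs.append(self.chol_frac)
        pct = "-".join(f"{round(100 * f):g}" for f in fracs)
        return "-".join(parts) + (f"_{pct}" if len(parts) > 1 else "")


@dataclass(frozen=True, eq=False)
class EmissionSpectrum:
    """One Laurdan emission scan at one temperature for one replicate."""

    wavelength_nm: np.ndarray
    intensity_au: np.ndarray
    temperature_C: float
    excitation_nm: float = 355.0
    composition: LipidComposition | None = None
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        inten = np.asarray(self.intensity_au, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity_au", inten)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("wavelength grid must be 1-D with >= 2 points")
        if inten.shape != wl.shape:
            raise ValidationError("wavelength and intensity arrays differ in length")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if wl[0] > BAND_ORDERED_NM or wl[-1] < BAND_FLUID_NM:
            raise CoverageError(
                f"spectrum [{wl[0]:g}, {wl[-1]:g}] nm does not cover the "
                f"{BAND_ORDERED_NM:g}/{BAND_FLUID_NM:g} nm bands"
            )
        if not np.all(np.isfinite(inten)):
            raise ValidationError("intensities must be finite")
        if np.any(inten < 0):
            raise ValidationError("intensities must be >= 0")
        if not np.any(inten > 0):
            raise ValidationError("spectrum carries no signal (all intensities 0)")


@dataclass(frozen=True, eq=False)
class SpectralSeries:
    """Emission spectra of one sample over a temperature scan.

    Spectra are stored sorted by temperature (replicates at the same
    temperature are adjacent) and must all share one composition.
    """

    spectra: tuple[EmissionSpectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(
            sorted(self.spectra, key=lambda s: (s.temperature_C, s.replicate_id))
        )
        object.__setattr__(self, "spectra", spectra)
        if not spectra:
            raise ValidationError("series must contain at least one spectrum")
        comps = {s.composition for s in spectra}
        if len(comps) > 1:
            raise ValidationError("all spectra in a series must share one composition")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def composition(self) -> LipidComposition | None:
        return self.spectra[0].composition

    @property
    def temperatures(self) -> np.ndarray:
        """Unique scan temperatures (°C), ascending, grouped to 0.01 °C."""
        out: list[float] = []
        for s in self.spectra:
            if not out or s.temperature_C - out[-1] > TEMPERATURE_MATCH_TOL_C:
                out.append(s.temperature_C)
        return np.array(out)


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_metadata(path: str | Path, composition: LipidComposition,
                   excitation_nm: float = 355.0) -> None:
    """Write the YAML sidecar describing the sample in ``path``."""
    payload = {
        "composition": dataclasses.asdict(composition),
        "excitation_nm": float(excitation_nm),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(payload), encoding="utf-8")


def read_metadata(path: str | Path) -> tuple[LipidComposition | None, float]:
    """Read the sidecar for ``path`` if present; returns (composition, excitation)."""
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return None, 355.0
    payload = yaml.safe_load(sidecar.read_text(encoding="utf-8")) or {}
    comp = payload.get("composition")
    composition = LipidComposition(**comp) if comp else None
    return composition, float(payload.get("excitation_nm", 355.0))


# ---------------------------------------------------------------------------
# spectral readers / writers
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["sample", "temperature_C", "wavelength_nm", "intensity"]


def read_spectra(path: str | Path, dialect: str = "long") -> SpectralSeries:
    """Read a spectral CSV in the ``long`` or ``wide`` dialect.

    Temperatures are returned sorted ascending regardless of file order.
    Composition metadata is taken from the ``<path>.meta.yaml`` sidecar when
    present.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    composition, excitation = read_metadata(path)
    frame = pd.read_csv(path)
    spectra: list[EmissionSpectrum] = []
    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"long dialect requires columns {missing}")
        for (sample, temp), grp in frame.groupby(["sample", "temperature_C"],
                                                 sort=True):
            grp = grp.sort_values("wavelength_nm")
            spectra.append(EmissionSpectrum(
                wavelength_nm=grp["wavelength_nm"].to_numpy(float),
                intensity_au=grp["intensity"].to_numpy(float),
                temperature_C=float(temp),
                excitation_nm=excitation,
                composition=composition,
                replicate_id=str(sample),
            ))
    elif dialect == "wide":
        if "wavelength_nm" not in frame.columns:
            raise ValidationError("wide dialect requires a wavelength_nm column")
        frame = frame.sort_values("wavelength_nm")
        wl = frame["wavelength_nm"].to_numpy(float)
        for col in frame.columns:
            if col == "wavelength_nm":
                continue
            try:
                temp = float(col)
            except ValueError as exc:
                raise ValidationError(
                    f"wide-dialect column {col!r} is not a temperature"
                ) from exc
            spectra.append(EmissionSpectrum(
                wavelength_nm=wl,
                intensity_au=frame[col].to_numpy(float),
                temperature_C=temp,
                excitation_nm=excitation,
                composition=composition,
            ))
    else:
        raise UsageError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    return SpectralSeries(spectra=tuple(spectra))


def write_spectra(series: SpectralSeries, path: str | Path,
                  dialect: str = "long") -> None:
    """Write a series back to CSV in either dialect (plus metadata sidecar).

    The wide dialect admits only one replicate per temperature.
    """
    path = Path(path)
    if dialect == "long":
        rows = [
            {"sample": s.replicate_id, "temperature_C": s.temperature_C,
             "wavelength_nm": w, "intensity": i}
            for s in series.spectra
            for w, i in zip(s.wavelength_nm, s.intensity_au)
        ]
        pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)
    elif dialect == "wide":
        temps = [s.temperature_C for s in series.spectra]
        if len(set(temps)) != len(temps):
            raise UsageError("wide dialect cannot hold replicate spectra")
        wl = series.spectra[0].wavelength_nm
        data = {"wavelength_nm": wl}
        for s in series.spectra:
            if not np.array_equal(s.wavelength_nm, wl):
                raise UsageError("wide dialect requires a shared wavelength grid")
            data[f"{s.temperature_C:g}"] = s.intensity_au
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise UsageError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    if series.composition is not None:
        write_metadata(path, series.composition,
                       series.spectra[0].excitation_nm)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_results_table(rows: Sequence, path: str | Path,
                        columns: Sequence[str] | None = None) -> None:
    """Write homogeneous result records as CSV (fixed column order, %.6g).

    ``rows`` may be dataclass instances or mappings.  An empty ``rows`` with
    explicit ``columns`` produces a header-only file.
    """
    records: list[dict] = []
    for row in rows:
        if dataclasses.is_dataclass(row) and not isinstance(row, type):
            records.append(dataclasses.asdict(row))
        elif isinstance(row, Mapping):
            records.append(dict(row))
        else:
            raise UsageError(f"unsupported record type {type(row).__name__}")
    if records:
        cols = columns or list(records[0].keys())
        for rec in records:
            if list(rec.keys()) != list(records[0].keys()):
                raise UsageError("records are not homogeneous")
        frame = pd.DataFrame(records, columns=cols)
    else:
        frame = pd.DataFrame(columns=list(columns or []))
    # flatten nested dataclass fields (e.g. composition) into their label
    for col in frame.columns:
        if frame[col].map(lambda v: isinstance(v, dict)).any():
            frame[col] = frame[col].map(
                lambda v: v.get("label", str(v)) if isinstance(v, dict) else v)
    frame.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
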