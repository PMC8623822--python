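"""Fluorescence probes of bilayer order and dipole potential.

Three ratiometric read-outs, each a small closed-form statistic on raw
spectrofluorimeter records:

* **Laurdan generalized polarization** — the probe's emission blue-shifts
  in ordered, dehydrated lipid surroundings (peak near 440 nm) and
  red-shifts in disordered ones (490 nm):
  GP = (I440 − I490)/(I440 + I490) ∈ [−1, 1].
* **DPH steady-state anisotropy** — rotational freedom in the bilayer
  core, from the four polarized intensity components with the
  spectrometer's grating factor G = I_HV/I_HH:
  r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH).
* **di-8-ANEPPS dipole potential** — dual-excitation ratio
  R_ex = I670(exc 420)/I670(exc 520) mapped to millivolts via the
  published calibration Ψ_d = (R_ex + 0.3)/0.0043.

Summary Δ statistics compare conditions: temperature deltas
(value at 60 °C minus 20 °C per condition), sugar-versus-control deltas
at 20 °C, and the ratio ΔGP/Δr_DPH locating where in the bilayer a solute
acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "PolarizedIntensities",
    "AneppsReading",
    "generalized_polarization",
    "gp_from_spectrum",
    "grating_factor",
    "dph_anisotropy",
    "anisotropy_from_record",
    "dipole_potential",
    "excitation_ratio_from_potential",
    "temperature_deltas",
    "condition_deltas",
    "delta_ratio",
]

#: Eq.-of-calibration constants for the di-8-ANEPPS dipole-potential map,
#: Ψ_d = (R_ex + B)/A mV.  Published calibration; overridable per call.
ANEPPS_OFFSET = 0.3
ANEPPS_SLOPE_PER_MV = 0.0043

#: Laurdan evaluation band centres, nm.
GP_BLUE_NM = 440.0
GP_RED_NM = 490.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan on an ascending wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    temperature_c: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise ValueError("wavelength and intensity must be 1-D, equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")

    def subtract_background(self, blank: "EmissionSpectrum") -> "EmissionSpectrum":
        """Paired-blank background subtraction, clipped at zero."""
        if not np.array_equal(blank.wavelength_nm, self.wavelength_nm):
            raise ValueError("blank must share the wavelength grid")
        return EmissionSpectrum(
            self.wavelength_nm,
            np.clip(self.intensity - blank.intensity, 0.0, None),
            self.temperature_c,
            self.label,
        )


@dataclass(frozen=True)
class PolarizedIntensities:
    """The four polarized components I_VV, I_VH, I_HV, I_HH of one reading."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float
    temperature_c: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("i_vv", "i_vh", "i_hv", "i_hh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AneppsReading:
    """Dual-excitation di-8-ANEPPS intensities detected at 670 nm."""

    i670_exc420: float
    i670_exc520: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.i670_exc420 > 0 and self.i670_exc520 > 0):
            raise ValueError("both intensities must be positive")

    @property
    def excitation_ratio(self) -> float:
        return self.i670_exc420 / self.i670_exc520


# ---------------------------------------------------------------------------
# Laurdan GP
# ---------------------------------------------------------------------------

def generalized_polarization(i440: float, i490: float) -> float:
    """GP = (I440 − I490)/(I440 + I490)."""
    if i440 < 0 or i490 < 0:
        raise ValueError("band intensities must be non-negative")
    total = i440 + i490
    if total == 0:
        raise ZeroDivisionError("GP undefined: both band intensities are zero")
    return (i440 - i490) / total


def _band_intensity(spec: EmissionSpectrum, center_nm: float,
                    half_width_nm: float) -> float:
    wl, it = spec.wavelength_nm, spec.intensity
    if half_width_nm == 0:
        if not (wl[0] <= center_nm <= wl[-1]):
            raise ValueError(f"{center_nm} nm outside spectrum grid")
        return float(it[np.argmin(np.abs(wl - center_nm))])
    lo, hi = center_nm - half_width_nm, center_nm + half_width_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"band [{lo}, {hi}] nm outside spectrum grid")
    mask = (wl >= lo) & (wl <= hi)
    return float(it[mask].mean())


def gp_from_spectrum(spec: EmissionSpectrum,
                     band_half_width_nm: float = 0.0) -> float:
    """GP from a full emission scan.

    Band intensities are read at the grid point nearest 440/490 nm, or
    boxcar-averaged over ±``band_half_width_nm`` when nonzero.
    """
    i440 = _band_intensity(spec, GP_BLUE_NM, band_half_width_nm)
    i490 = _band_intensity(spec, GP_RED_NM, band_half_width_nm)
    return generalized_polarization(i440, i490)


# ---------------------------------------------------------------------------
# DPH anisotropy
# ---------------------------------------------------------------------------

def grating_factor(i_hv: float, i_hh: float) -> float:
    """Spectrometer polarization-sensitivity correction G = I_HV/I_HH."""
    if i_hv < 0:
        raise ValueError("I_HV must be non-negative")
    if not i_hh > 0:
        raise ZeroDivisionError("I_HH must be positive to form G")
    return i_hv / i_hh


def dph_anisotropy(i_vv: float, i_vh: float, g: float) -> float:
    """Steady-state anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)."""
    if g < 0:
        raise ValueError("grating factor must be non-negative")
    denom = i_vv + 2.0 * g * i_vh
    if denom <= 0:
        raise ZeroDivisionError("anisotropy undefined: I_VV + 2G I_VH <= 0")
    return (i_vv - g * i_vh) / denom


def anisotropy_from_record(rec: PolarizedIntensities) -> float:
    """Anisotropy of one four-component reading, G taken from its own
    horizontal-excitation pair."""
    return dph_anisotropy(rec.i_vv, rec.i_vh,
                          grating_factor(rec.i_hv, rec.i_hh))


# ---------------------------------------------------------------------------
# di-8-ANEPPS dipole potential
# ---------------------------------------------------------------------------

def dipole_potential(
    rex: float,
    offset: float = ANEPPS_OFFSET,
    slope_per_mv: float = ANEPPS_SLOPE_PER_MV,
) -> float:
    """Dipole potential Ψ_d = (R_ex + offset)/slope, in mV (full precision;
    round for table presentation)."""
    if not math.isfinite(rex):
        raise ValueError("excitation ratio must be finite")
    return (rex + offset) / slope_per_mv


def excitation_ratio_from_potential(
    psi_mv: float,
    offset: float = ANEPPS_OFFSET,
    slope_per_mv: float = ANEPPS_SLOPE_PER_MV,
) -> float:
    """Inverse calibration: R_ex = slope·Ψ_d − offset."""
    return slope_per_mv * psi_mv - offset


# ---------------------------------------------------------------------------
# Δ summary statistics
# ---------------------------------------------------------------------------

def _require(mapping: Mapping, keys: Sequence, what: str) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise KeyError(f"missing {what}: {missing}")


def temperature_deltas(
    series: Mapping[str, Mapping[float, float]],
    t_high_c: float = 60.0,
    t_low_c: float = 20.0,
) -> dict[str, float]:
    """Per-condition value(60 °C) − value(20 °C).

    ``series`` maps condition label → {temperature °C → metric value}.
    """
    out = {}
    for cond, by_t in series.items():
        _require(by_t, [t_high_c, t_low_c], f"temperatures for {cond!r}")
        out[cond] = by_t[t_high_c] - by_t[t_low_c]
    return out


def condition_deltas(
    values: Mapping[str, float],
    control_key: str = "control",
) -> dict[str, float]:
    """Sugar-versus-control differences at a fixed temperature."""
    _require(values, [control_key], "control condition")
    ref = values[control_key]
    return {k: v - ref for k, v in values.items() if k != control_key}


def delta_ratio(delta_gp: float, delta_r: float) -> float:
    """ΔGP/Δr_DPH, sign preserved — >1 means the solute reorders the
    glycerol level more than the hydrophobic core."""
    if delta_r == 0:
        raise ZeroDivisionError("Δr_DPH is zero; ratio undefined")
    return delta_gp / delta_r
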