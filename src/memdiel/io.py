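"""Schema-validated CSV readers/writers and run provenance.

All tables are plain comma-separated UTF-8 with ``.`` decimals and
full-precision floats; readers validate headers and cell types and name
the offending row/column on failure.  Every pipeline output can embed a
:class:`RunManifest` so reruns are reproducible and attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .electrodeformation import (
    ElectrodefExperiment,
    ElectrolyteCondition,
    VesicleRecord,
)
from .eis import ImpedanceSpectrum
from .fluorescence import AneppsReading, EmissionSpectrum, PolarizedIntensities
from .units import uS_per_cm_to_S_per_m

__all__ = [
    "SchemaError",
    "RunManifest",
    "read_vesicle_table",
    "write_vesicle_table",
    "read_batch_config",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_emission_csv",
    "write_emission_csv",
    "read_polarized_csv",
    "read_anepps_csv",
    "file_digest",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{required}, found {list(df.columns)}"
        )


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row(s) {list(bad[:5])}"
            )
        if df[col].isna().any():
            raise SchemaError(f"{path}: empty cell in column {col!r}")
        df[col] = coerced


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Provenance record embedded in every pipeline output."""

    command: str
    config: dict
    input_digests: dict[str, str]
    seed: int | None
    package_version: str
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, config: dict, inputs: dict[str, str],
               seed: int | None = None) -> "RunManifest":
        from . import __version__
        return cls(
            command=command,
            config=config,
            input_digests={k: file_digest(v) for k, v in inputs.items()},
            seed=seed,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# vesicle tables + batch config
# ---------------------------------------------------------------------------

VESICLE_COLUMNS = ["vesicle_id", "radius_um", "fcr_hz"]


def read_vesicle_table(path) -> tuple[VesicleRecord, ...]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, VESICLE_COLUMNS, path)
    _check_numeric(df, ["radius_um", "fcr_hz"], path)
    try:
        return tuple(
            VesicleRecord(str(row.vesicle_id), float(row.radius_um),
                          float(row.fcr_hz))
            for row in df.itertuples()
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_vesicle_table(records, path) -> None:
    df = pd.DataFrame(
        {
            "vesicle_id": [r.vesicle_id for r in records],
            "radius_um": [repr(r.radius_um) for r in records],
            "fcr_hz": [repr(r.fcr_hz) for r in records],
        }
    )
    df.to_csv(path, index=False)


BATCH_CONFIG_KEYS = ["lambda_in_uS_cm", "conductivity_ratio", "nacl_inner_mM",
                     "nacl_outer_mM", "sugar", "sugar_mM"]


def read_batch_config(path) -> dict:
    """Key = value batch metadata (structured text, one pair per line)."""
    text = Path(path).read_text()
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = value
    missing = [k for k in BATCH_CONFIG_KEYS if k not in out]
    if missing:
        raise SchemaError(f"{path}: missing config key(s) {missing}")
    for key in ("lambda_in_uS_cm", "conductivity_ratio", "nacl_inner_mM",
                "nacl_outer_mM", "sugar_mM"):
        try:
            out[key] = float(out[key])
        except ValueError as exc:
            raise SchemaError(f"{path}: non-numeric value for {key!r}") from exc
    return out


def experiment_from_files(vesicle_path, config_path) -> ElectrodefExperiment:
    records = read_vesicle_table(vesicle_path)
    cfg = read_batch_config(config_path)
    condition = ElectrolyteCondition(
        nacl_inner_mol_l=cfg["nacl_inner_mM"] * 1e-3,
        nacl_outer_mol_l=cfg["nacl_outer_mM"] * 1e-3,
        sugar_name=cfg["sugar"],
        sugar_mmol_l=cfg["sugar_mM"],
    )
    return ElectrodefExperiment(
        records=records,
        lambda_in_s_m=uS_per_cm_to_S_per_m(cfg["lambda_in_uS_cm"]),
        conductivity_ratio=cfg["conductivity_ratio"],
        condition=condition,
    )


# ---------------------------------------------------------------------------
# impedance spectra
# ---------------------------------------------------------------------------

SPECTRUM_COLUMNS = ["freq_hz", "z_re_ohm", "z_im_ohm"]


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SPECTRUM_COLUMNS, path)
    numeric = SPECTRUM_COLUMNS + (["sigma_ohm"] if "sigma_ohm" in df else [])
    _check_numeric(df, numeric, path)
    freq = df["freq_hz"].to_numpy()
    if np.any(np.diff(freq) <= 0):
        raise SchemaError(
            f"{path}: frequencies must be strictly increasing "
            "(sort the table by freq_hz)"
        )
    return ImpedanceSpectrum(
        freq_hz=freq,
        z_ohm=df["z_re_ohm"].to_numpy() + 1j * df["z_im_ohm"].to_numpy(),
        sigma_ohm=df["sigma_ohm"].to_numpy() if "sigma_ohm" in df else None,
    )


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path) -> None:
    data = {
        "freq_hz": [repr(float(f)) for f in spectrum.freq_hz],
        "z_re_ohm": [repr(float(z.real)) for z in spectrum.z_ohm],
        "z_im_ohm": [repr(float(z.imag)) for z in spectrum.z_ohm],
    }
    if spectrum.sigma_ohm is not None:
        data["sigma_ohm"] = [repr(float(s)) for s in spectrum.sigma_ohm]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fluorescence records
# ---------------------------------------------------------------------------

def read_emission_csv(path) -> list[EmissionSpectrum]:
    """Single- or multi-spectrum emission file.

    Required columns ``wavelength_nm,intensity``; optional ``label`` and
    ``temperature_c`` columns split the file into one spectrum per
    (label, temperature) group.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["wavelength_nm", "intensity"], path)
    _check_numeric(df, ["wavelength_nm", "intensity"], path)
    group_cols = [c for c in ("label", "temperature_c") if c in df.columns]
    if not group_cols:
        return [EmissionSpectrum(df["wavelength_nm"].to_numpy(),
                                 df["intensity"].to_numpy())]
    out = []
    for key, sub in df.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_cols, key))
        out.append(
            EmissionSpectrum(
                sub["wavelength_nm"].to_numpy(),
                sub["intensity"].to_numpy(),
                temperature_c=float(info["temperature_c"])
                if "temperature_c" in info else None,
                label=str(info.get("label", "")),
            )
        )
    return out


def write_emission_csv(spectra, path) -> None:
    frames = []
    for spec in spectra:
        frame = pd.DataFrame({
            "label": spec.label,
            "temperature_c": spec.temperature_c,
            "wavelength_nm": spec.wavelength_nm,
            "intensity": spec.intensity,
        })
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


POLARIZED_COLUMNS = ["label", "temperature_c", "i_vv", "i_vh", "i_hv", "i_hh"]


def read_polarized_csv(path) -> list[PolarizedIntensities]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, POLARIZED_COLUMNS, path)
    _check_numeric(df, POLARIZED_COLUMNS[1:], path)
    return [
        PolarizedIntensities(
            i_vv=float(r.i_vv), i_vh=float(r.i_vh),
            i_hv=float(r.i_hv), i_hh=float(r.i_hh),
            temperature_c=float(r.temperature_c), label=str(r.label),
        )
        for r in df.itertuples()
    ]


ANEPPS_COLUMNS = ["label", "i670_exc420", "i670_exc520"]


def read_anepps_csv(path) -> list[AneppsReading]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ANEPPS_COLUMNS, path)
    _check_numeric(df, ANEPPS_COLUMNS[1:], path)
    return [
        AneppsReading(i670_exc420=float(r.i670_exc420),
                      i670_exc520=float(r.i670_exc520), label=str(r.label))
        for r in df.itertuples()
    ]


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
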