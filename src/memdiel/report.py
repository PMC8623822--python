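"""Summary tables and plots over a directory of stage outputs.

``run_report`` collects the JSON records emitted by the fitting and
fluorescence subcommands and lays them out as the three standard result
tables of a capacitance/fluorescence campaign — per-condition GUV
capacitances (C̄_m, C_m, GF, n), planar-bilayer circuit fits (R_m, C_m,
GF), and dipole potentials (R_ex, Ψ_d) — plus optional Nyquist and
GP-versus-temperature figures.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .eis import ImpedanceSpectrum

__all__ = ["run_report", "percent_change", "nyquist_plot", "gp_temperature_plot"]


def percent_change(reference: float, value: float) -> float:
    """Signed relative change in percent, (value − reference)/reference·100."""
    if reference == 0:
        raise ZeroDivisionError("reference value is zero")
    return (value - reference) / reference * 100.0


def _load_stage_records(results_dir: Path, stage: str) -> list[dict]:
    out = []
    for path in sorted(results_dir.glob(f"{stage}*.json")):
        payload = json.loads(path.read_text())
        payload.setdefault("source_file", path.name)
        out.append(payload)
    return out


def run_report(results_dir, out_path=None) -> dict[str, pd.DataFrame]:
    """Aggregate stage outputs into table-shaped summaries.

    Scans ``results_dir`` for ``guv-*.json``, ``eis-*.json`` and
    ``dipole-*.json`` records and builds one DataFrame per family.
    Raises if the directory holds nothing reportable; inconsistent
    condition labels across stages produce a warning column, not a
    failure.
    """
    results_dir = Path(results_dir)
    tables: dict[str, pd.DataFrame] = {}

    guv = _load_stage_records(results_dir, "guv")
    if guv:
        tables["guv_capacitance"] = pd.DataFrame(
            [
                {
                    "condition": rec.get("condition", "?"),
                    "cm_eff_uF_cm2": rec["cm_eff_uF_cm2"],
                    "cm_eff_sd_uF_cm2": rec.get("cm_eff_sd_uF_cm2"),
                    "cm_bare_uF_cm2": rec["cm_bare_uF_cm2"],
                    "cm_bare_sd_uF_cm2": rec.get("cm_bare_sd_uF_cm2"),
                    "gf": rec.get("gf"),
                    "n_vesicles": rec.get("n_vesicles"),
                }
                for rec in guv
            ]
        )

    eis = _load_stage_records(results_dir, "eis")
    if eis:
        tables["eis_circuit"] = pd.DataFrame(
            [
                {
                    "condition": rec.get("condition", "?"),
                    "rm_specific_Mohm_cm2": rec["rm_specific_ohm_cm2"] / 1e6,
                    "cm_specific_uF_cm2": rec["cm_specific_uF_cm2"],
                    "gf": rec.get("gf"),
                }
                for rec in eis
            ]
        )

    dipole = _load_stage_records(results_dir, "dipole")
    if dipole:
        tables["dipole_potential"] = pd.DataFrame(
            [
                {
                    "condition": rec.get("condition", rec.get("label", "?")),
                    "rex": rec["rex"],
                    "psi_mv": round(rec["psi_mv"]),
                }
                for rec in dipole
            ]
        )

    if not tables:
        raise FileNotFoundError(
            f"nothing to report: no guv-/eis-/dipole- JSON records in "
            f"{results_dir}"
        )

    if out_path is not None:
        with open(out_path, "w") as fh:
            for name, df in tables.items():
                fh.write(f"# {name}\n")
                df.to_csv(fh, index=False)
                fh.write("\n")
    return tables


def nyquist_plot(spectrum: ImpedanceSpectrum, out_path, fit=None) -> None:
    """Complex-plane impedance plot (−Im Z vs Re Z), optionally overlaying
    a fitted circuit curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(spectrum.z_ohm.real, -spectrum.z_ohm.imag, "o", ms=4,
            label="spectrum")
    if fit is not None:
        from .eis import circuit_impedance
        z_fit = circuit_impedance(fit, spectrum.freq_hz)
        ax.plot(z_fit.real, -z_fit.imag, "-", label="circuit fit")
    ax.set_xlabel("Re Z (Ω)")
    ax.set_ylabel("−Im Z (Ω)")
    ax.set_aspect("equal", adjustable="datalim")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def gp_temperature_plot(series: dict[str, dict[float, float]], out_path) -> None:
    """Laurdan GP versus temperature, one curve per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, by_t in series.items():
        temps = sorted(by_t)
        ax.plot(temps, [by_t[t] for t in temps], "o-", label=label)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("Laurdan GP")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
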