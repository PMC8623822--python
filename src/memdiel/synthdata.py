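"""Synthetic measurement generators for every pipeline stage.

Each generator is the forward model of one analysis operation plus a
documented noise process, so analysis code can be exercised closed-loop:
at zero noise the paired analysis recovers the generating truth exactly,
and at realistic noise levels parameter-recovery statistics can be
computed over seeds.  All generators are deterministic functions of
(parameters, seed).

Noise conventions: strictly positive observables (transition frequencies,
fluorescence intensities) get multiplicative lognormal noise with unit
mean and a configured coefficient of variation; complex impedance gets
proportional complex Gaussian noise (see :func:`memdiel.eis.simulate_fft_eis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .electrodeformation import (
    ElectrodefExperiment,
    ElectrolyteCondition,
    VesicleRecord,
    critical_frequency,
)
from .eis import (
    CircuitParams,
    ImpedanceSpectrum,
    MultisineSpec,
    circuit_impedance,
    coherent_log_grid,
    simulate_fft_eis,
)
from .fluorescence import (
    AneppsReading,
    EmissionSpectrum,
    PolarizedIntensities,
    excitation_ratio_from_potential,
    GP_RED_NM,
)

__all__ = [
    "GeneratorConfig",
    "gen_vesicle_batch",
    "gen_impedance_spectrum",
    "laurdan_weight_for_gp",
    "gen_laurdan_spectrum",
    "gen_dph_quadruple",
    "gen_anepps_pair",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of
    variation ``cv`` (degenerate at 1 for cv = 0)."""
    if cv < 0:
        raise ValueError("noise cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions shared by the generators.

    Defaults mirror a typical electrodeformation/fluorescence campaign:
    seven vesicles per batch, 3% multiplicative scatter on transition
    frequencies, 1% proportional impedance noise, emission spectra on a
    1-nm grid over 390–600 nm, and a control-POPC Laurdan calibration
    running from GP = 0.05 at 20 °C to −0.35 at 60 °C.
    """

    seed: int = 0
    n_vesicles: int = 7
    radius_law: str = "lognormal"  # or "uniform"
    radius_range_um: tuple[float, float] = (5.0, 25.0)
    radius_log_median_um: float = 12.0
    radius_log_sigma: float = 0.35
    fcr_noise_cv: float = 0.03
    eis_noise_frac: float = 0.01
    wavelength_min_nm: float = 390.0
    wavelength_max_nm: float = 600.0
    wavelength_step_nm: float = 1.0
    gp_calibration: tuple[float, float] = (0.05, -0.35)  # (GP@20°C, GP@60°C)
    laurdan_ordered_peak_nm: float = 440.0
    laurdan_sigma_ord_nm: float = 30.0
    laurdan_sigma_dis_nm: float = 30.0

    def __post_init__(self) -> None:
        if self.fcr_noise_cv < 0 or self.eis_noise_frac < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.radius_law not in ("lognormal", "uniform"):
            raise ValueError(f"unknown radius law {self.radius_law!r}")
        lo, hi = self.radius_range_um
        if not 0 < lo < hi:
            raise ValueError("invalid radius range")

    @property
    def wavelength_grid_nm(self) -> np.ndarray:
        return np.arange(self.wavelength_min_nm,
                         self.wavelength_max_nm + 0.5 * self.wavelength_step_nm,
                         self.wavelength_step_nm)


# ---------------------------------------------------------------------------
# GUV electrodeformation batches
# ---------------------------------------------------------------------------

def _draw_radii(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.radius_range_um
    if config.radius_law == "uniform":
        return rng.uniform(lo, hi, config.n_vesicles)
    # truncated lognormal: rejection-sample within the stated range
    out = np.empty(config.n_vesicles)
    filled = 0
    mu = math.log(config.radius_log_median_um)
    while filled < config.n_vesicles:
        draw = rng.lognormal(mu, config.radius_log_sigma,
                             2 * (config.n_vesicles - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, config.n_vesicles - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def gen_vesicle_batch(
    truth_cm_eff_uF_cm2: float,
    lambda_in_s_m: float,
    ratio: float,
    config: GeneratorConfig,
    condition: ElectrolyteCondition | None = None,
) -> ElectrodefExperiment:
    """One synthetic GUV batch obeying the transition-frequency model.

    Radii are drawn from the configured law, each exact transition
    frequency is computed from the generating effective capacitance, and
    multiplicative lognormal noise with CV ``fcr_noise_cv`` is applied.
    """
    if not 0 < ratio < 1:
        raise ValueError("conductivity ratio must lie in (0, 1)")
    rng = np.random.default_rng(config.seed)
    radii = _draw_radii(rng, config)
    noise = _lognormal_factors(rng, config.fcr_noise_cv, radii.size)
    records = tuple(
        VesicleRecord(
            vesicle_id=f"v{i:03d}",
            radius_um=float(r),
            fcr_hz=critical_frequency(float(r), truth_cm_eff_uF_cm2,
                                      lambda_in_s_m, ratio) * float(eta),
        )
        for i, (r, eta) in enumerate(zip(radii, noise))
    )
    return ElectrodefExperiment(
        records=records,
        lambda_in_s_m=lambda_in_s_m,
        conductivity_ratio=ratio,
        condition=condition or ElectrolyteCondition(),
    )


# ---------------------------------------------------------------------------
# impedance spectra
# ---------------------------------------------------------------------------

def gen_impedance_spectrum(
    params: CircuitParams,
    config: GeneratorConfig,
    spec: MultisineSpec | None = None,
    path: str = "fast",
) -> tuple[ImpedanceSpectrum, str]:
    """Synthetic impedance spectrum of the equivalent circuit.

    ``path="full"`` runs the complete multisine → FFT acquisition chain;
    ``path="fast"`` evaluates the circuit analytically on the same
    frequency grid and adds the identical proportional complex noise
    model.  Returns the spectrum and the path flag actually used.
    """
    if path not in ("fast", "full"):
        raise ValueError(f"unknown synthesis path {path!r}")
    spec = spec or coherent_log_grid()
    if path == "full":
        return (
            simulate_fft_eis(params, spec, noise_frac=config.eis_noise_frac,
                             seed=config.seed),
            "full",
        )
    freqs = np.asarray(spec.excited_freqs_hz, dtype=float)
    freqs = np.sort(freqs)
    z = circuit_impedance(params, freqs)
    sigma = None
    if config.eis_noise_frac > 0:
        rng = np.random.default_rng(config.seed)
        scale = config.eis_noise_frac * np.abs(z)
        z = z + scale * (rng.standard_normal(z.size)
                         + 1j * rng.standard_normal(z.size))
        sigma = scale
    return ImpedanceSpectrum(freq_hz=freqs, z_ohm=z, sigma_ohm=sigma), "fast"


# ---------------------------------------------------------------------------
# Laurdan emission spectra
# ---------------------------------------------------------------------------

def _peak_cross_terms(config: GeneratorConfig) -> tuple[float, float]:
    """(a, b): disordered-peak weight at 440 nm and ordered-peak weight at
    490 nm, for unit-height Gaussian peaks."""
    lam_ord = config.laurdan_ordered_peak_nm
    a = math.exp(-((440.0 - GP_RED_NM) ** 2)
                 / (2.0 * config.laurdan_sigma_dis_nm ** 2))
    b = math.exp(-((GP_RED_NM - lam_ord) ** 2)
                 / (2.0 * config.laurdan_sigma_ord_nm ** 2))
    return a, b


def laurdan_weight_for_gp(gp: float, config: GeneratorConfig) -> float:
    """Ordered-peak mixing weight w producing a target GP at the band
    centres; the GP ↔ w map is a Möbius function, linear in w once
    cleared, so the inverse is closed-form."""
    a, b = _peak_cross_terms(config)
    denom = (2.0 - a - b) - gp * (b - a)
    if denom <= 0:
        raise ValueError(f"GP = {gp} unreachable for the configured peaks")
    w = ((1.0 - a) + gp * (1.0 + a)) / denom
    if not 0.0 <= w <= 1.0:
        raise ValueError(
            f"GP = {gp} outside the achievable range for the configured "
            f"peak shapes (implied weight {w:.3f})"
        )
    return w


def _weight_profile(temperature_c: float, config: GeneratorConfig,
                    t_mid_c: float = 40.0, tau_c: float = 10.0) -> float:
    """Affine-logistic interpolation of the mixing weight between the
    calibrated 20 °C and 60 °C endpoints."""
    gp20, gp60 = config.gp_calibration
    w20 = laurdan_weight_for_gp(gp20, config)
    w60 = laurdan_weight_for_gp(gp60, config)

    def logistic(t: float) -> float:
        return 1.0 / (1.0 + math.exp((t - t_mid_c) / tau_c))

    l20, l60, lt = logistic(20.0), logistic(60.0), logistic(temperature_c)
    return w60 + (w20 - w60) * (lt - l60) / (l20 - l60)


def gen_laurdan_spectrum(
    temperature_c: float,
    config: GeneratorConfig,
    intensity_scale: float = 1000.0,
    noise_sd: float = 0.0,
) -> EmissionSpectrum:
    """Two-peak Laurdan emission spectrum at one temperature.

    I(λ) = A·[w(T)·g(λ; λ_ord, σ_ord) + (1 − w(T))·g(λ; 490, σ_dis)]
    with unit-height Gaussian peaks; w(T) interpolates affine-logistically
    between mixing weights calibrated so the band-centre GP reproduces the
    configured 20 °C and 60 °C endpoints.  Optional additive Gaussian
    noise (clipped at zero) models detector scatter.
    """
    if not 20.0 <= temperature_c <= 60.0:
        raise ValueError("temperature must lie within the calibrated 20-60 °C")
    w = _weight_profile(temperature_c, config)
    wl = config.wavelength_grid_nm
    g_ord = np.exp(-((wl - config.laurdan_ordered_peak_nm) ** 2)
                   / (2.0 * config.laurdan_sigma_ord_nm ** 2))
    g_dis = np.exp(-((wl - GP_RED_NM) ** 2)
                   / (2.0 * config.laurdan_sigma_dis_nm ** 2))
    intensity = intensity_scale * (w * g_ord + (1.0 - w) * g_dis)
    if noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        intensity = np.clip(intensity + rng.normal(0, noise_sd, wl.size),
                            0.0, None)
    return EmissionSpectrum(
        wavelength_nm=wl,
        intensity=intensity,
        temperature_c=temperature_c,
        label="synthetic-laurdan",
    )


# ---------------------------------------------------------------------------
# polarized-intensity quadruples and dual-excitation pairs
# ---------------------------------------------------------------------------

def gen_dph_quadruple(
    true_r: float,
    g_true: float = 1.0,
    total_intensity: float = 3.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> PolarizedIntensities:
    """Polarized intensities consistent with a true anisotropy.

    Inverts the anisotropy relation: with S the total intensity,
    I_VV = S(1+2r)/3 and I_VH = S(1−r)/(3G); the horizontal-excitation
    pair carries the grating factor, I_HV = G·I_HH.  At zero noise the
    analysis chain (grating factor, then anisotropy) returns ``true_r``
    exactly.
    """
    if not -0.5 < true_r <= 1.0:
        raise ValueError("anisotropy must lie in (-0.5, 1]")
    if not g_true > 0:
        raise ValueError("grating factor must be positive")
    if not total_intensity > 0:
        raise ValueError("total intensity must be positive")
    s = total_intensity
    i_vv = s * (1.0 + 2.0 * true_r) / 3.0
    i_vh = s * (1.0 - true_r) / (3.0 * g_true)
    i_hh = s / 3.0
    i_hv = g_true * i_hh
    vals = np.array([i_vv, i_vh, i_hv, i_hh])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        vals = vals * _lognormal_factors(rng, noise_cv, 4)
    return PolarizedIntensities(*map(float, vals), label="synthetic-dph")


def gen_anepps_pair(
    true_psi_mv: float,
    intensity_scale: float = 1000.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> AneppsReading:
    """Dual-excitation intensity pair consistent with a true dipole
    potential, via the inverse calibration R_ex = 0.0043·Ψ_d − 0.3."""
    rex = excitation_ratio_from_potential(true_psi_mv)
    if rex <= 0:
        raise ValueError(
            f"dipole potential {true_psi_mv} mV implies non-positive "
            f"excitation ratio {rex:.4f}; no physical intensity pair exists"
        )
    if not intensity_scale > 0:
        raise ValueError("intensity scale must be positive")
    i520 = intensity_scale
    i420 = rex * i520
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        f420, f520 = _lognormal_factors(rng, noise_cv, 2)
        i420, i520 = i420 * f420, i520 * f520
    return AneppsReading(i670_exc420=float(i420), i670_exc520=float(i520),
                         label="synthetic-anepps")
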