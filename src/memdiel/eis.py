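"""FFT electrochemical impedance spectroscopy of planar lipid bilayers.

A Montal–Mueller bilayer lipid membrane (BLM) suspended across an aperture
in a Teflon film is electrically a parallel R_BLM‖C_BLM element, shunted
by the Teflon-film capacitance C_TM and fed through the series solution
resistance R_s:

    Z(ω) = R_s + [ jω(C_BLM + C_TM) + 1/R_BLM ]^(−1)

The spectrum is acquired in one shot: a small multisine voltage
(~10 mV peak-to-peak, 1.5 Hz–50 kHz) is applied, voltage and current are
recorded in the time domain, and Z is formed bin-wise as V(ω)/I(ω) after
an FFT.  Coherent sampling (every excited frequency an exact integer
multiple of the bin width) keeps the excited bins leakage-free.

Circuit parameters are recovered by complex nonlinear least squares with
modulus weighting, C_TM held fixed at its independently measured value.
Specific quantities follow from the aperture area S_m:
C_m = C_BLM/S_m and R_m = R_BLM·S_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_AREA_CM2",
    "DEFAULT_CTM_F",
    "CircuitParams",
    "ImpedanceSpectrum",
    "MultisineSpec",
    "CircuitFitResult",
    "circuit_impedance",
    "nyquist_geometry",
    "make_multisine",
    "coherent_log_grid",
    "simulate_fft_eis",
    "fit_circuit",
    "weighted_average",
]

#: Aperture area of the Montal–Mueller cell (100 µm hole), cm².
DEFAULT_AREA_CM2 = 8e-5
#: Independently measured Teflon-film capacitance, F.
DEFAULT_CTM_F = 56.33e-12
#: Measurement window, Hz.
DEFAULT_FMIN_HZ = 1.5
DEFAULT_FMAX_HZ = 50e3


class FitConvergenceError(RuntimeError):
    """Equivalent-circuit fit failed to converge to a physical optimum."""


@dataclass(frozen=True)
class CircuitParams:
    """Equivalent-circuit elements of the Montal–Mueller cell."""

    c_blm_f: float
    r_blm_ohm: float
    c_tm_f: float = DEFAULT_CTM_F
    r_s_ohm: float = 1e5
    area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        for name in ("c_blm_f", "r_blm_ohm", "c_tm_f", "r_s_ohm", "area_cm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_specific(
        cls,
        cm_uF_cm2: float,
        rm_ohm_cm2: float,
        *,
        c_tm_f: float = DEFAULT_CTM_F,
        r_s_ohm: float = 1e5,
        area_cm2: float = DEFAULT_AREA_CM2,
    ) -> "CircuitParams":
        """Build circuit elements from area-normalised membrane values."""
        return cls(
            c_blm_f=cm_uF_cm2 * 1e-6 * area_cm2,
            r_blm_ohm=rm_ohm_cm2 / area_cm2,
            c_tm_f=c_tm_f,
            r_s_ohm=r_s_ohm,
            area_cm2=area_cm2,
        )

    @property
    def cm_specific_uF_cm2(self) -> float:
        return self.c_blm_f / self.area_cm2 * 1e6

    @property
    def rm_specific_ohm_cm2(self) -> float:
        return self.r_blm_ohm * self.area_cm2


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a strictly increasing frequency grid."""

    freq_hz: np.ndarray
    z_ohm: np.ndarray
    sigma_ohm: np.ndarray | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq_hz, dtype=float)
        z = np.asarray(self.z_ohm, dtype=complex)
        object.__setattr__(self, "freq_hz", freq)
        object.__setattr__(self, "z_ohm", z)
        if freq.ndim != 1 or z.shape != freq.shape:
            raise ValueError("freq_hz and z_ohm must be 1-D of equal length")
        if freq.size and (np.any(freq <= 0) or np.any(np.diff(freq) <= 0)):
            raise ValueError("frequencies must be positive, strictly increasing")
        if self.sigma_ohm is not None:
            sig = np.asarray(self.sigma_ohm, dtype=float)
            object.__setattr__(self, "sigma_ohm", sig)
            if sig.shape != freq.shape:
                raise ValueError("sigma_ohm length mismatch")


@dataclass(frozen=True)
class MultisineSpec:
    """Coherent multisine excitation: which FFT bins carry energy.

    Every excited frequency must be an exact integer multiple of the bin
    width ``sample_rate_hz / n_samples`` so the discrete spectrum is
    leakage-free.  Phases default to the Schroeder schedule, which keeps
    the crest factor low; random phases may be supplied with a recorded
    seed.
    """

    excited_freqs_hz: tuple[float, ...]
    sample_rate_hz: float
    n_samples: int
    amplitude_v_pp: float = 0.010
    phases_rad: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.excited_freqs_hz)
        object.__setattr__(self, "excited_freqs_hz", freqs)
        if not freqs:
            raise ValueError("at least one excited frequency required")
        if not self.amplitude_v_pp > 0:
            raise ValueError("amplitude must be positive")
        df = self.sample_rate_hz / self.n_samples
        for f in freqs:
            k = f / df
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise ValueError(
                    f"excited frequency {f} Hz is not an integer multiple of "
                    f"the bin width {df} Hz (non-coherent sampling would leak)"
                )
            if f >= self.sample_rate_hz / 2:
                raise ValueError(f"{f} Hz violates Nyquist for fs={self.sample_rate_hz}")
        if self.phases_rad is not None and len(self.phases_rad) != len(freqs):
            raise ValueError("one phase per excited frequency required")

    @property
    def bins(self) -> np.ndarray:
        df = self.sample_rate_hz / self.n_samples
        return np.rint(np.asarray(self.excited_freqs_hz) / df).astype(int)


@dataclass(frozen=True)
class CircuitFitResult:
    """Fitted circuit with per-parameter standard errors.

    ``gf`` is 1 − (weighted residual sum)/(weighted total sum) of the
    complex fit; ``cm_specific``/``rm_specific`` are the aperture-scaled
    membrane quantities.
    """

    params: CircuitParams
    c_blm_sd_f: float
    r_blm_sd_ohm: float
    r_s_sd_ohm: float
    gf: float

    @property
    def cm_specific_uF_cm2(self) -> float:
        return self.params.cm_specific_uF_cm2

    @property
    def rm_specific_ohm_cm2(self) -> float:
        return self.params.rm_specific_ohm_cm2

    @property
    def cm_specific_sd_uF_cm2(self) -> float:
        return self.c_blm_sd_f / self.params.area_cm2 * 1e6

    @property
    def rm_specific_sd_ohm_cm2(self) -> float:
        return self.r_blm_sd_ohm * self.params.area_cm2


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def circuit_impedance(params: CircuitParams, freq_hz) -> np.ndarray | complex:
    """Complex impedance of the cell at one or many frequencies (Ω)."""
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * math.pi * f
    y_parallel = 1j * omega * (params.c_blm_f + params.c_tm_f) + 1.0 / params.r_blm_ohm
    z = params.r_s_ohm + 1.0 / y_parallel
    return complex(z) if np.isscalar(freq_hz) else z


def nyquist_geometry(params: CircuitParams) -> tuple[float, float]:
    """Apex frequency (Hz) and semicircle diameter (Ω) of the Nyquist arc.

    For R_s + R‖C the locus of Z − R_s is a semicircle of diameter R_BLM;
    −Im Z peaks at ω* = 1/(R_BLM (C_BLM + C_TM)) where −Im Z = R_BLM/2.
    """
    omega_star = 1.0 / (params.r_blm_ohm * (params.c_blm_f + params.c_tm_f))
    return omega_star / (2.0 * math.pi), params.r_blm_ohm


# ---------------------------------------------------------------------------
# multisine synthesis and FFT measurement
# ---------------------------------------------------------------------------

def schroeder_phases(n_tones: int) -> np.ndarray:
    """Schroeder phase schedule φ_k = −π k(k−1)/K for low crest factor."""
    k = np.arange(1, n_tones + 1)
    return -math.pi * k * (k - 1) / n_tones


def coherent_log_grid(
    fmin_hz: float = DEFAULT_FMIN_HZ,
    fmax_hz: float = DEFAULT_FMAX_HZ,
    n_freqs: int = 30,
    sample_rate_hz: float = 131072.0,
    n_samples: int = 262144,
) -> MultisineSpec:
    """Quasi-logarithmic coherent frequency grid covering the window.

    Log-spaced target frequencies are snapped to the nearest FFT bin and
    de-duplicated; the end points land exactly on ``fmin`` and ``fmax``
    when those are themselves coherent (they are, for the defaults:
    bin width 0.5 Hz).
    """
    df = sample_rate_hz / n_samples
    targets = np.geomspace(fmin_hz, fmax_hz, n_freqs)
    bins = np.unique(np.clip(np.rint(targets / df), 1, None).astype(int))
    freqs = tuple(bins * df)
    return MultisineSpec(
        excited_freqs_hz=freqs,
        sample_rate_hz=sample_rate_hz,
        n_samples=n_samples,
    )


def make_multisine(spec: MultisineSpec) -> np.ndarray:
    """Synthesize the excitation voltage time series (V).

    Sum of unit sinusoids at the excited bins with the spec's phases,
    rescaled so the realised peak-to-peak span equals ``amplitude_v_pp``.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate_hz
    if spec.phases_rad is not None:
        phases = np.asarray(spec.phases_rad, dtype=float)
    elif spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        phases = rng.uniform(0.0, 2.0 * math.pi, len(spec.excited_freqs_hz))
    else:
        phases = schroeder_phases(len(spec.excited_freqs_hz))
    v = np.zeros(n)
    for f, ph in zip(spec.excited_freqs_hz, phases):
        v += np.cos(2.0 * math.pi * f * t + ph)
    span = v.max() - v.min()
    return v * (spec.amplitude_v_pp / span)


def simulate_fft_eis(
    params: CircuitParams,
    spec: MultisineSpec,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> ImpedanceSpectrum:
    """One synthetic FFT-EIS acquisition of the cell.

    The multisine voltage is synthesized, the current response is formed
    in the frequency domain (I(ω) = V(ω)/Z(ω) at the excited bins — exact
    for a linear circuit under coherent sampling), transformed back to a
    time series, and both records are re-FFT'd to produce Z = V(ω)/I(ω)
    bin-wise.  Proportional complex Gaussian noise (σ = noise_frac·|Z| on
    the real and imaginary parts independently) then models instrument
    scatter on the measured impedance.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    v = make_multisine(spec)
    n = spec.n_samples
    bins = spec.bins
    v_spec = np.fft.rfft(v)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate_hz)
    z_model = circuit_impedance(params, freqs[bins])
    i_spec = np.zeros_like(v_spec)
    i_spec[bins] = v_spec[bins] / z_model
    # round-trip through the time domain, as the instrument does
    i_t = np.fft.irfft(i_spec, n=n)
    i_meas = np.fft.rfft(i_t)[bins]
    if np.any(i_meas == 0):
        raise FloatingPointError("zero current at an excited bin")
    z = v_spec[bins] / i_meas
    order = np.argsort(freqs[bins])
    z = z[order]
    f_out = freqs[bins][order]
    sigma = None
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        scale = noise_frac * np.abs(z)
        z = z + scale * (rng.standard_normal(z.size)
                         + 1j * rng.standard_normal(z.size))
        sigma = scale
    return ImpedanceSpectrum(freq_hz=f_out, z_ohm=z, sigma_ohm=sigma)


# ---------------------------------------------------------------------------
# equivalent-circuit fitting
# ---------------------------------------------------------------------------

def _initial_guess(spectrum: ImpedanceSpectrum, c_tm_f: float) -> np.ndarray:
    """Heuristic start: R_s from the high-frequency Re Z plateau, R_BLM
    from low-frequency extrapolation (or 10× the largest |Z| when the arc
    is truncated), total capacitance from the highest-frequency −Im Z."""
    f = spectrum.freq_hz
    z = spectrum.z_ohm
    r_s = max(float(z[-1].real), 1e-3)
    r_low = float(z[0].real - r_s)
    zmax = float(np.abs(z).max())
    # low-frequency arc closure visible only if Re Z has levelled off
    r_blm = r_low if r_low > 5 * zmax * 0.1 else 10.0 * zmax
    r_blm = max(r_blm, 1e-3)
    c_tot = 1.0 / (2.0 * math.pi * f[-1] * max(-float(z[-1].imag), 1e-12))
    c_blm = max(c_tot - c_tm_f, 0.1 * c_tm_f)
    return np.log(np.array([c_blm, r_blm, r_s]))


def fit_circuit(
    spectrum: ImpedanceSpectrum,
    c_tm_f: float = DEFAULT_CTM_F,
    area_cm2: float = DEFAULT_AREA_CM2,
    init: CircuitParams | None = None,
    weighting: str = "modulus",
) -> CircuitFitResult:
    """Complex nonlinear least-squares fit of (C_BLM, R_BLM, R_s).

    Minimises Σ_k w_k |Z_k − Z_model(f_k)|² with modulus weighting
    w_k = 1/|Z_k|² (|Z| spans decades in these spectra; an ``"none"``
    option disables weighting).  C_TM is held fixed.  Parameters are
    log-transformed internally, which enforces positivity; on failure the
    optimiser restarts from three perturbed initial points.  Standard
    errors come from the Jacobian at the optimum.
    """
    if spectrum.freq_hz.size < 4:
        raise ValueError("need at least 4 frequency points")
    if not c_tm_f > 0:
        raise ValueError("c_tm_f must be positive")
    if weighting == "modulus":
        w = 1.0 / np.abs(spectrum.z_ohm)
    elif weighting == "none":
        w = np.ones(spectrum.freq_hz.size)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    f = spectrum.freq_hz
    z_obs = spectrum.z_ohm

    def residuals(logp: np.ndarray) -> np.ndarray:
        c_blm, r_blm, r_s = np.exp(logp)
        p = CircuitParams(c_blm_f=c_blm, r_blm_ohm=r_blm, c_tm_f=c_tm_f,
                          r_s_ohm=r_s, area_cm2=area_cm2)
        dz = (circuit_impedance(p, f) - z_obs) * w
        return np.concatenate([dz.real, dz.imag])

    if init is not None:
        x0 = np.log(np.array([init.c_blm_f, init.r_blm_ohm, init.r_s_ohm]))
    else:
        x0 = _initial_guess(spectrum, c_tm_f)

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(4):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, 3)
        sol = least_squares(residuals, start, method="lm", xtol=1e-14,
                            ftol=1e-14, max_nfev=2000)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
            if sol.cost < 1e-20:
                break
    if best is None:
        raise FitConvergenceError(
            "equivalent-circuit fit did not converge from any start point"
        )
    sol = best
    c_blm, r_blm, r_s = np.exp(sol.x)

    # covariance in log space -> SDs of the physical parameters
    m, p_free = sol.fun.size, 3
    dof = max(m - p_free, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = np.linalg.inv(jtj) * s2
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:
        sd_log = np.full(3, np.nan)
    sds = np.exp(sol.x) * sd_log  # |d exp(x)/dx| = exp(x)

    wz = z_obs * w
    ss_tot = float(np.sum(np.abs(wz - wz.mean()) ** 2))
    gf = 1.0 - 2.0 * sol.cost / ss_tot if ss_tot > 0 else 1.0

    params = CircuitParams(c_blm_f=c_blm, r_blm_ohm=r_blm, c_tm_f=c_tm_f,
                           r_s_ohm=r_s, area_cm2=area_cm2)
    return CircuitFitResult(
        params=params,
        c_blm_sd_f=float(sds[0]),
        r_blm_sd_ohm=float(sds[1]),
        r_s_sd_ohm=float(sds[2]),
        gf=gf,
    )


def weighted_average(
    values: Sequence[float], sds: Sequence[float]
) -> tuple[float, float]:
    """Inverse-variance weighted mean and its standard error.

    mean = Σ(v_i/σ_i²)/Σ(1/σ_i²),  se = (Σ 1/σ_i²)^(−1/2).
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sds, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != s.shape:
        raise ValueError("values and sds must have equal length")
    if np.any(s <= 0):
        raise ValueError("all sds must be positive")
    w = 1.0 / s**2
    return float(np.sum(w * v) / np.sum(w)), float(1.0 / math.sqrt(np.sum(w)))
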