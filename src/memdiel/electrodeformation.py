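"""Membrane capacitance from GUV electrodeformation.

A giant unilamellar vesicle (GUV) suspended in a medium more conductive
than its interior (conductivity ratio Λ = λ_in/λ_out < 1) deforms from a
prolate to an oblate ellipsoid as the frequency of an applied AC field is
raised.  At the transition the vesicle passes through a quasispherical
shape at the critical frequency

    f_cr = λ_in / (2π r C̄_m) · [(1 − Λ)(Λ + 3)]^(−1/2)

where r is the vesicle radius and C̄_m the *effective* specific membrane
capacitance.  Fitting f_cr against 1/r across a batch of vesicles with a
single free parameter yields C̄_m.

C̄_m is the series combination of the bare bilayer capacitance C_m with
the diffuse-double-layer capacitances C_D on either side of the membrane:

    C̄_m = (1/C_m + 1/C_D,in + 1/C_D,ex)^(−1)

Each double layer is modelled as a planar capacitor of thickness equal to
the Debye length λ_D = 0.303/√c nm (1:1 electrolyte, molarity c) filled
with solvent of relative permittivity ε_r ≈ 80.  Inverting the series
relation converts the fitted C̄_m to the bare C_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import (
    EPS0_F_PER_M,
    F_PER_M2_TO_UF_PER_CM2,
    NM_TO_M,
    UF_PER_CM2_TO_F_PER_M2,
    UM_TO_M,
)

__all__ = [
    "ElectrolyteCondition",
    "VesicleRecord",
    "ElectrodefExperiment",
    "CapacitanceFitResult",
    "debye_length",
    "double_layer_capacitance",
    "critical_frequency",
    "fit_effective_capacitance",
    "bare_capacitance",
    "effective_capacitance",
    "propagate_bare_sd",
    "analyze_experiment",
]

#: Debye length prefactor for a 1:1 electrolyte at room temperature,
#: nm·(mol/L)^(1/2):  λ_D = 0.303/√c.
DEBYE_PREFACTOR_NM = 0.303


class InsufficientDataError(ValueError):
    """Raised when a batch has too few vesicles to support a fit."""


class SeriesCapacitanceError(ValueError):
    """Raised when an effective capacitance is inconsistent with the
    stated double-layer capacitances (series inversion would give a
    non-positive bare capacitance)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrolyteCondition:
    """Ionic and sugar composition of the aqueous phases.

    The exterior NaCl concentration is conventionally the interior one
    plus 0.1 mmol/L, added to make the suspending medium more conductive
    so the prolate→oblate transition exists.
    """

    nacl_inner_mol_l: float = 1.0e-3
    nacl_outer_mol_l: float = 1.1e-3
    sugar_name: str = "none"
    sugar_mmol_l: float = 0.0
    solvent_rel_permittivity: float = 80.0
    temperature_c: float = 23.0  # metadata only

    def __post_init__(self) -> None:
        if self.nacl_inner_mol_l < 0 or self.nacl_outer_mol_l < 0:
            raise ValueError("NaCl concentrations must be >= 0")
        if self.sugar_mmol_l < 0:
            raise ValueError("sugar concentration must be >= 0")
        if not self.solvent_rel_permittivity > 1:
            raise ValueError("solvent relative permittivity must exceed 1")
        if self.sugar_name not in ("none", "glucose", "fructose", "sucrose"):
            raise ValueError(f"unknown sugar: {self.sugar_name!r}")


@dataclass(frozen=True)
class VesicleRecord:
    """One vesicle: radius and measured prolate→oblate transition frequency."""

    vesicle_id: str
    radius_um: float
    fcr_hz: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError(f"radius must be positive, got {self.radius_um}")
        if not self.fcr_hz > 0:
            raise ValueError(f"f_cr must be positive, got {self.fcr_hz}")


@dataclass(frozen=True)
class ElectrodefExperiment:
    """A GUV batch measured at fixed bath composition.

    ``lambda_in_s_m`` is the interior conductivity in S/m and
    ``conductivity_ratio`` the interior/exterior ratio Λ, shared by all
    vesicles in the batch.
    """

    records: tuple[VesicleRecord, ...]
    lambda_in_s_m: float
    conductivity_ratio: float
    condition: ElectrolyteCondition = field(default_factory=ElectrolyteCondition)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) < 1:
            raise InsufficientDataError("a batch needs at least one vesicle")
        if not self.lambda_in_s_m > 0:
            raise ValueError("lambda_in must be positive")
        if not 0 < self.conductivity_ratio < 1:
            raise ValueError(
                "conductivity ratio must lie in (0, 1) for a prolate->oblate "
                f"transition; got {self.conductivity_ratio}"
            )


@dataclass(frozen=True)
class CapacitanceFitResult:
    """Fitted effective and bare specific capacitance with uncertainties.

    ``gf`` is the coefficient of determination R² of the f_cr-vs-1/r fit
    (centred total sum of squares); the convention is recorded in
    ``gf_definition``.  ``cm_eff_sd`` is NaN for degenerate batches where
    no residual degree of freedom exists.
    """

    cm_eff_uF_cm2: float
    cm_eff_sd_uF_cm2: float
    cm_bare_uF_cm2: float
    cm_bare_sd_uF_cm2: float
    gf: float
    n_vesicles: int
    cd_in_uF_cm2: float
    cd_ex_uF_cm2: float
    gf_definition: str = "R2_centered"


# ---------------------------------------------------------------------------
# double-layer electrostatics
# ---------------------------------------------------------------------------

def debye_length(c_mol_l: float) -> float:
    """Debye screening length of a 1:1 electrolyte, in nm.

    λ_D = 0.303/√c with c the molar salt concentration (mol/L).
    """
    if not c_mol_l > 0:
        raise ValueError(f"molar concentration must be positive, got {c_mol_l}")
    return DEBYE_PREFACTOR_NM / math.sqrt(c_mol_l)


def double_layer_capacitance(
    c_mol_l: float,
    eps_r: float = 80.0,
    eps0: float = EPS0_F_PER_M,
) -> float:
    """Specific capacitance of one diffuse double layer, in µF/cm².

    Planar-capacitor model: C_D = ε_r ε_0 / λ_D(c).
    """
    if not eps_r > 1:
        raise ValueError(f"eps_r must exceed 1, got {eps_r}")
    lam_m = debye_length(c_mol_l) * NM_TO_M
    return eps_r * eps0 / lam_m * F_PER_M2_TO_UF_PER_CM2


# ---------------------------------------------------------------------------
# transition-frequency model
# ---------------------------------------------------------------------------

def _shape_factor(ratio: float) -> float:
    """[(1 − Λ)(Λ + 3)]^(−1/2), defined for 0 < Λ < 1."""
    if not 0 < ratio < 1:
        raise ValueError(
            f"conductivity ratio must lie in (0, 1), got {ratio}"
        )
    return ((1.0 - ratio) * (ratio + 3.0)) ** -0.5


def critical_frequency(
    radius_um: float,
    cm_eff_uF_cm2: float,
    lambda_in_s_m: float,
    ratio: float,
) -> float:
    """Prolate→oblate transition frequency f_cr in Hz.

    f_cr = λ_in/(2π r C̄_m) · [(1 − Λ)(Λ + 3)]^(−1/2).
    """
    if not radius_um > 0:
        raise ValueError("radius must be positive")
    if not cm_eff_uF_cm2 > 0:
        raise ValueError("capacitance must be positive")
    if not lambda_in_s_m > 0:
        raise ValueError("conductivity must be positive")
    r_m = radius_um * UM_TO_M
    c_si = cm_eff_uF_cm2 * UF_PER_CM2_TO_F_PER_M2
    return lambda_in_s_m / (2.0 * math.pi * r_m * c_si) * _shape_factor(ratio)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Through-origin OLS slope Σxy/Σx² and its standard error.

    The standard error uses the n−1 residual degrees of freedom of the
    one-parameter model; NaN when n == 1.
    """
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ZeroDivisionError("all abscissae are zero")
    k = float(np.dot(x, y)) / sxx
    n = x.size
    if n < 2:
        return k, float("nan")
    resid = y - k * x
    se = math.sqrt(float(np.dot(resid, resid)) / (n - 1) / sxx)
    return k, se


def fit_effective_capacitance(
    exp: ElectrodefExperiment, *, allow_degenerate: bool = False
) -> CapacitanceFitResult:
    """Estimate the effective specific capacitance C̄_m from one batch.

    The transition-frequency model is linear in x = 1/r:
    f_cr = k·x with k = λ_in/(2π C̄_m)·[(1−Λ)(Λ+3)]^(−1/2), so the single
    fitting parameter is the through-origin least-squares slope.  The
    slope's standard error propagates to C̄_m via the exact Jacobian of
    C̄_m ∝ 1/k.  Goodness of fit is R² with centred total sum of squares.

    Batches with a single vesicle are rejected unless ``allow_degenerate``
    is set, in which case the point estimate is returned with NaN
    uncertainties and NaN goodness of fit — flagged, never silent.

    Double-layer fields of the result are filled from the experiment's
    electrolyte condition; the bare capacitance is obtained by inverting
    the three-capacitor series relation.
    """
    radii = np.array([rec.radius_um for rec in exp.records], dtype=float)
    fcr = np.array([rec.fcr_hz for rec in exp.records], dtype=float)
    if radii.size < 2 and not allow_degenerate:
        raise InsufficientDataError(
            f"need >= 2 vesicles to fit, got {radii.size} "
            "(pass allow_degenerate=True for a flagged point estimate)"
        )
    if radii.size >= 2 and np.unique(radii).size < 2:
        raise np.linalg.LinAlgError(
            "all vesicle radii identical: slope of f_cr vs 1/r is not "
            "identifiable"
        )
    x = 1.0 / (radii * UM_TO_M)
    k, k_se = _origin_slope(x, fcr)
    if not k > 0:
        raise ValueError("non-positive fitted slope: data violate the model")

    shape = _shape_factor(exp.conductivity_ratio)
    cm_eff_si = exp.lambda_in_s_m / (2.0 * math.pi * k) * shape
    cm_eff = cm_eff_si * F_PER_M2_TO_UF_PER_CM2
    # C̄_m ∝ 1/k  =>  sd(C̄_m) = C̄_m · se(k)/k
    cm_eff_sd = cm_eff * k_se / k if math.isfinite(k_se) else float("nan")

    if radii.size < 2:
        gf = float("nan")
    else:
        resid = fcr - k * x
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.sum((fcr - fcr.mean()) ** 2))
        # noiseless data can make both sums vanish to rounding; R2 := 1 then
        gf = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    cond = exp.condition
    cd_in = double_layer_capacitance(cond.nacl_inner_mol_l,
                                     cond.solvent_rel_permittivity)
    cd_ex = double_layer_capacitance(cond.nacl_outer_mol_l,
                                     cond.solvent_rel_permittivity)
    cm_bare = bare_capacitance(cm_eff, cd_in, cd_ex)
    cm_bare_sd = (propagate_bare_sd(cm_eff, cm_eff_sd, cm_bare)
                  if math.isfinite(cm_eff_sd) else float("nan"))

    return CapacitanceFitResult(
        cm_eff_uF_cm2=cm_eff,
        cm_eff_sd_uF_cm2=cm_eff_sd,
        cm_bare_uF_cm2=cm_bare,
        cm_bare_sd_uF_cm2=cm_bare_sd,
        gf=gf,
        n_vesicles=len(exp.records),
        cd_in_uF_cm2=cd_in,
        cd_ex_uF_cm2=cd_ex,
    )


# ---------------------------------------------------------------------------
# series-capacitor algebra
# ---------------------------------------------------------------------------

def bare_capacitance(cm_eff: float, cd_in: float, cd_ex: float) -> float:
    """Invert the three-capacitor series relation to the bare bilayer value.

    C_m = (1/C̄_m − 1/C_D,in − 1/C_D,ex)^(−1); any consistent unit works
    as long as all three arguments share it.
    """
    if not (cm_eff > 0 and cd_in > 0 and cd_ex > 0):
        raise ValueError("capacitances must be positive")
    inv = 1.0 / cm_eff - 1.0 / cd_in - 1.0 / cd_ex
    if inv <= 0:
        raise SeriesCapacitanceError(
            f"effective capacitance {cm_eff} too large for double layers "
            f"({cd_in}, {cd_ex}): series inversion gives a non-positive "
            "bare capacitance"
        )
    return 1.0 / inv


def effective_capacitance(cm_bare: float, cd_in: float, cd_ex: float) -> float:
    """Series combination C̄_m = (1/C_m + 1/C_D,in + 1/C_D,ex)^(−1)."""
    if not (cm_bare > 0 and cd_in > 0 and cd_ex > 0):
        raise ValueError("capacitances must be positive")
    return 1.0 / (1.0 / cm_bare + 1.0 / cd_in + 1.0 / cd_ex)


def propagate_bare_sd(cm_eff: float, cm_eff_sd: float, cm_bare: float) -> float:
    """Delta-method SD of the bare capacitance with fixed double layers.

    dC_m/dC̄_m = (C_m/C̄_m)², hence sd(C_m) = sd(C̄_m)·(C_m/C̄_m)².
    """
    if not (cm_eff > 0 and cm_bare > 0) or cm_eff_sd < 0:
        raise ValueError("invalid inputs to uncertainty propagation")
    return cm_eff_sd * (cm_bare / cm_eff) ** 2


def analyze_experiment(exp: ElectrodefExperiment) -> CapacitanceFitResult:
    """Full per-batch analysis: fit C̄_m, correct for double layers."""
    return fit_effective_capacitance(exp)
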