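"""Relative dielectric permittivity of the bilayer from its capacitance.

Treating the membrane as a thin planar dielectric sheet of thickness d,
the specific capacitance is C_m = ε_rm·ε_0/d, so

    ε_rm = C_m · d / ε_0.

A finer picture splits the bilayer into three series layers — two polar
headgroup slabs (thickness ~9 Å per leaflet, capacitance ~15 µF/cm²,
relative permittivity ~30) flanking the hydrocarbon core (~27.1 Å for
POPC).  Removing the headgroup contributions in series,

    1/C_core = 1/C_m − 2/C_head,      ε_core = C_core·d_core/ε_0,

isolates the permittivity of the acyl-chain region, the layer most
sensitive to solute-induced structural change.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import EPS0_F_PER_M, NM_TO_M, UF_PER_CM2_TO_F_PER_M2

__all__ = [
    "LayerModel",
    "relative_permittivity",
    "capacitance_from_permittivity",
    "core_capacitance",
    "core_permittivity",
    "permittivity_change",
]


class LayerInconsistencyError(ValueError):
    """Series decomposition impossible for the stated capacitances."""


@dataclass(frozen=True)
class LayerModel:
    """Headgroup/core geometry and dielectric parameters.

    Defaults are literature values for phosphatidylcholine bilayers:
    per-leaflet headgroup thickness 0.9 nm and capacitance 15 µF/cm²
    (headgroup ε_r ≈ 30), hydrophobic thickness 2.71 nm.  All fields are
    overridable per condition — e.g. sugar-thinned cores.
    """

    d_head_nm: float = 0.9
    d_core_nm: float = 2.71
    c_head_uF_cm2: float = 15.0
    eps_head: float = 30.0
    d_total_nm: float | None = None

    def __post_init__(self) -> None:
        for name in ("d_head_nm", "d_core_nm", "c_head_uF_cm2", "eps_head"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.d_total_nm is not None:
            expected = 2.0 * self.d_head_nm + self.d_core_nm
            if abs(self.d_total_nm - expected) > 0.1 * expected:
                raise ValueError(
                    f"d_total_nm={self.d_total_nm} inconsistent with "
                    f"2*d_head + d_core = {expected:.3f} nm (>10% off)"
                )

    @property
    def total_thickness_nm(self) -> float:
        if self.d_total_nm is not None:
            return self.d_total_nm
        return 2.0 * self.d_head_nm + self.d_core_nm


def relative_permittivity(cm_uF_cm2: float, d_nm: float,
                          eps0: float = EPS0_F_PER_M) -> float:
    """ε_rm = C_m·d/ε_0 for a uniform dielectric slab."""
    if not (cm_uF_cm2 > 0 and d_nm > 0):
        raise ValueError("capacitance and thickness must be positive")
    return cm_uF_cm2 * UF_PER_CM2_TO_F_PER_M2 * d_nm * NM_TO_M / eps0


def capacitance_from_permittivity(eps_rm: float, d_nm: float,
                                  eps0: float = EPS0_F_PER_M) -> float:
    """Inverse slab relation: C_m = ε_rm·ε_0/d, in µF/cm²."""
    if not (eps_rm > 0 and d_nm > 0):
        raise ValueError("permittivity and thickness must be positive")
    return eps_rm * eps0 / (d_nm * NM_TO_M) / UF_PER_CM2_TO_F_PER_M2


def core_capacitance(cm_uF_cm2: float, layers: LayerModel) -> float:
    """Hydrocarbon-core capacitance after stripping two headgroup layers
    in series: 1/C_core = 1/C_m − 2/C_head (µF/cm²)."""
    if not cm_uF_cm2 > 0:
        raise ValueError("capacitance must be positive")
    inv = 1.0 / cm_uF_cm2 - 2.0 / layers.c_head_uF_cm2
    if inv <= 0:
        raise LayerInconsistencyError(
            f"C_m = {cm_uF_cm2} µF/cm² with C_head = "
            f"{layers.c_head_uF_cm2} µF/cm² per leaflet leaves no positive "
            "core capacitance"
        )
    return 1.0 / inv


def core_permittivity(cm_uF_cm2: float, layers: LayerModel | None = None,
                      eps0: float = EPS0_F_PER_M) -> float:
    """Relative permittivity of the hydrocarbon core under the three-layer
    series decomposition."""
    layers = layers or LayerModel()
    c_core = core_capacitance(cm_uF_cm2, layers)
    return relative_permittivity(c_core, layers.d_core_nm, eps0)


def permittivity_change(
    cm_control_uF_cm2: float,
    cm_treated_uF_cm2: float,
    layers_control: LayerModel | None = None,
    layers_treated: LayerModel | None = None,
) -> float:
    """Fractional change of the core permittivity between two conditions.

    (ε_core,treated − ε_core,control)/ε_core,control; a per-condition
    ``layers_treated`` lets a thinned core enter the treated branch.
    """
    layers_control = layers_control or LayerModel()
    layers_treated = layers_treated or layers_control
    e0 = core_permittivity(cm_control_uF_cm2, layers_control)
    e1 = core_permittivity(cm_treated_uF_cm2, layers_treated)
    return (e1 - e0) / e0
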