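"""Physical constants and unit conversions used across the package.

All internal computation is in SI; presentation-layer quantities use the
units conventional in membrane electrochemistry (µF/cm² for specific
capacitance, µS/cm for conductivity, µm for vesicle radii, nm/Å for
molecular lengths).  Every conversion constant lives here so round-trip
consistency can be asserted in one place.
"""

from __future__ import annotations

#: CODATA vacuum permittivity, F/m.
EPS0_F_PER_M: float = 8.854187e-12

#: Rounded vacuum permittivity (two significant decimals), F/m.  Some
#: published capacitance work quotes ε0 ≈ 8.85e-12; passing this value
#: through the ``eps0`` arguments reproduces numbers computed that way.
EPS0_ROUNDED_F_PER_M: float = 8.85e-12

# --- specific capacitance ---------------------------------------------------
# 1 µF/cm² = 1e-6 F / 1e-4 m² = 1e-2 F/m²
UF_PER_CM2_TO_F_PER_M2: float = 1e-2
F_PER_M2_TO_UF_PER_CM2: float = 1e2

# --- conductivity -----------------------------------------------------------
# 1 µS/cm = 1e-6 S / 1e-2 m = 1e-4 S/m
US_PER_CM_TO_S_PER_M: float = 1e-4
S_PER_M_TO_US_PER_CM: float = 1e4

# --- lengths ----------------------------------------------------------------
UM_TO_M: float = 1e-6
M_TO_UM: float = 1e6
NM_TO_M: float = 1e-9
M_TO_NM: float = 1e9
ANGSTROM_TO_NM: float = 0.1
NM_TO_ANGSTROM: float = 10.0

# --- areas / resistances for planar-bilayer scaling -------------------------
CM2_TO_M2: float = 1e-4
OHM_CM2_TO_OHM_M2: float = 1e-4


def uF_per_cm2_to_F_per_m2(c: float) -> float:
    return c * UF_PER_CM2_TO_F_PER_M2


def F_per_m2_to_uF_per_cm2(c: float) -> float:
    return c * F_PER_M2_TO_UF_PER_CM2


def uS_per_cm_to_S_per_m(lam: float) -> float:
    return lam * US_PER_CM_TO_S_PER_M


def S_per_m_to_uS_per_cm(lam: float) -> float:
    return lam * S_PER_M_TO_US_PER_CM
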