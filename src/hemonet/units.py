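"""Unit conventions and conversions.

The package works in a coherent "model" unit system chosen so that numbers
for capillary-scale flow are O(1):

==========  ==========  =====================================
quantity    model unit  SI equivalent
==========  ==========  =====================================
length      um          1e-6 m
time        ms          1e-3 s
velocity    um/ms       1e-3 m/s (= mm/s)
pressure    Pa          Pa
viscosity   Pa*ms       1e-3 Pa*s
2D tension  Pa*um       1e-6 N/m
3D force    Pa*um^2     1e-12 N (pN)
3D energy   Pa*um^3     1e-18 J
==========  ==========  =====================================

Material parameters are *stored* in the SI units the literature quotes
(membrane shear modulus in N/m, bending modulus in J, viscosity in Pa*s)
and converted once at the point of use via the helpers below.
"""

from __future__ import annotations

MMHG_TO_PA = 133.322387415
PA_TO_DYN_CM2 = 10.0  # 1 Pa = 10 dyn/cm^2, exact

# conversion factors from the quoted SI unit into model units
SHEAR_MODULUS_N_PER_M_TO_MODEL = 1.0e6     # N/m -> Pa*um
BENDING_MODULUS_J_TO_MODEL = 1.0e18        # J -> Pa*um^3
VISCOSITY_PA_S_TO_MODEL = 1.0e3            # Pa*s -> Pa*ms


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    """Convert pressure from Pa to mmHg."""
    return p_pa / MMHG_TO_PA


def pa_to_dyn_cm2(tau_pa: float) -> float:
    """Convert a stress from Pa to dyn/cm^2 (exact factor of 10)."""
    return tau_pa * PA_TO_DYN_CM2


def dyn_cm2_to_pa(tau_dyn: float) -> float:
    """Convert a stress from dyn/cm^2 to Pa (exact factor of 10)."""
    return tau_dyn / PA_TO_DYN_CM2
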