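"""Unit conversions used at the package boundary.

Everything internal is SI (m, s, Pa, Pa.s).  The lab-facing units are
mL/min for flow rate, mm/µm for lengths and dyn/cm² for wall shear
stress (1 dyn/cm² = 0.1 Pa).
"""

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0
M3_PER_S_TO_ML_PER_MIN = 1.0 / ML_PER_MIN_TO_M3_PER_S

DYN_PER_CM2_TO_PA = 0.1
PA_TO_DYN_PER_CM2 = 10.0

MM_TO_M = 1e-3
UM_TO_M = 1e-6
MPAS_TO_PAS = 1e-3


def ml_per_min(q_si: float) -> float:
    """Express a volumetric flow rate given in m³/s in mL/min."""
    return q_si * M3_PER_S_TO_ML_PER_MIN


def m3_per_s(q_ml_min: float) -> float:
    """Express a volumetric flow rate given in mL/min in m³/s."""
    return q_ml_min * ML_PER_MIN_TO_M3_PER_S


def dyn_per_cm2(tau_pa: float) -> float:
    """Express a shear stress given in Pa in dyn/cm²."""
    return tau_pa * PA_TO_DYN_PER_CM2


def pa(tau_dyn_cm2: float) -> float:
    """Express a shear stress given in dyn/cm² in Pa."""
    return tau_dyn_cm2 * DYN_PER_CM2_TO_PA
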