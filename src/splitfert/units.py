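"""Unit conversions between field and column scales.

Areal nitrogen densities are reported in kg N ha^-1; the soil column works
in mg N cm^-2 (per unit surface area).  1 kg ha^-1 = 1e6 mg / 1e8 cm^2
= 1e-2 mg cm^-2.  Water fluxes arrive as mm day^-1 and the column uses
cm day^-1.
"""

KG_HA_TO_MG_CM2 = 1e-2
MG_CM2_TO_KG_HA = 1e2
MM_TO_CM = 0.1
CM_TO_MM = 10.0


def kg_ha_to_mg_cm2(x: float) -> float:
    """Convert an areal N density from kg ha^-1 to mg cm^-2."""
    return x * KG_HA_TO_MG_CM2


def mg_cm2_to_kg_ha(x: float) -> float:
    """Convert an areal N density from mg cm^-2 to kg ha^-1."""
    return x * MG_CM2_TO_KG_HA


def mm_to_cm(x: float) -> float:
    return x * MM_TO_CM


def cm_to_mm(x: float) -> float:
    return x * CM_TO_MM
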