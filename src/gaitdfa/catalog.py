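"""The fixed catalog of the 30 waveform variables describing one gait cycle.

Twenty-seven joint variables — {hip, knee, ankle} x {angle, moment, power} x
{sagittal, coronal, transverse} — plus the three ground-reaction-force (GRF)
components. The catalog order is total and stable: it defines the column order
of trial files and the variable-major block order of the flattened feature
matrix, so changing it silently changes every downstream artefact. Angles are
in degrees, moments in N.m/kg, powers in W/kg and GRFs in multiples of body
weight (BW).
"""

from __future__ import annotations

JOINTS = ("hip", "knee", "ankle")
QUANTITIES = ("angle", "moment", "power")
PLANES = ("sagittal", "coronal", "transverse")

GRF_VARIABLES = ("grf_anterior_posterior", "grf_medial_lateral", "grf_vertical")

VARIABLE_NAMES: tuple[str, ...] = tuple(
    f"{joint}_{quantity}_{plane}"
    for joint in JOINTS
    for quantity in QUANTITIES
    for plane in PLANES
) + GRF_VARIABLES

N_VARIABLES = len(VARIABLE_NAMES)
assert N_VARIABLES == 30

UNITS: dict[str, str] = {
    name: (
        "deg" if "_angle_" in name
        else "N.m/kg" if "_moment_" in name
        else "W/kg" if "_power_" in name
        else "BW"
    )
    for name in VARIABLE_NAMES
}

#: Index of the vertical GRF column, used for gait-event detection.
VERTICAL_GRF = "grf_vertical"
VERTICAL_GRF_INDEX = VARIABLE_NAMES.index(VERTICAL_GRF)

CONDITIONS = ("shod", "barefoot")
#: The class treated as "positive" in sensitivity/specificity.
POSITIVE_CONDITION = "shod"
NEGATIVE_CONDITION = "barefoot"


def is_grf(name: str) -> bool:
    """True for the three ground-reaction-force channels (filtered at the GRF cutoff)."""
    return name in GRF_VARIABLES


def variable_index(name: str) -> int:
    """Catalog position of ``name``; raises ``KeyError`` for unknown variables."""
    try:
        return VARIABLE_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown variable {name!r}; catalog has {N_VARIABLES} fixed names") from None
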