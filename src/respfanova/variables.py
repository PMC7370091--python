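"""Registry of cardioventilatory variables and their analysis metadata.

Each variable measured during a constant-load walking test is classified
*a priori* by the direction in which the nasal-restriction (FB) condition is
hypothesized to differ from free oronasal breathing (ONB): variables expected
to be *higher* under FB (slower, deeper breathing: longer inspiratory and
expiratory times, larger tidal volumes, higher end-tidal and expired CO2,
oxygen uptake, heart rate) versus variables expected to be *higher* under ONB
(faster shallow breathing: breathing frequency, minute ventilation,
ventilatory equivalents, expired/end-tidal O2, dead-space fraction, RER).

The hypothesized direction drives the one-sided responder classification;
the log-transform flag marks variables analysed on the natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Direction(str, Enum):
    """Hypothesized direction of the condition effect."""

    FB_GT_ONB = "FB_gt_ONB"
    ONB_GT_FB = "ONB_gt_FB"


@dataclass(frozen=True)
class VariableSpec:
    """Per-variable analysis metadata.

    Parameters
    ----------
    name : str
        Short variable identifier (e.g. ``"Tin"``, ``"VE"``).
    units : str
        Measurement units as reported by the metabolic cart.
    direction : Direction
        Hypothesized direction of the FB-vs-ONB effect.
    log_transform : bool
        Whether the variable is analysed on the natural-log scale.
    """

    name: str
    units: str
    direction: Direction
    log_transform: bool = False


_FB_GT_ONB = Direction.FB_GT_ONB
_ONB_GT_FB = Direction.ONB_GT_FB

#: Canonical registry: 19 cardioventilatory variables with their a-priori
#: direction groups and log-scale flags.
VARIABLES: dict[str, VariableSpec] = {
    spec.name: spec
    for spec in [
        VariableSpec("Tin", "s", _FB_GT_ONB),
        VariableSpec("Tin/Tot", "%", _FB_GT_ONB),
        VariableSpec("Tex", "s", _FB_GT_ONB),
        VariableSpec("VTex", "L", _FB_GT_ONB),
        VariableSpec("VTin", "L", _FB_GT_ONB),
        VariableSpec("FECO2", "%", _FB_GT_ONB),
        VariableSpec("PETCO2", "mmHg", _FB_GT_ONB),
        VariableSpec("VO2", "mL/min", _FB_GT_ONB, log_transform=True),
        VariableSpec("HR", "beats/min", _FB_GT_ONB),
        VariableSpec("VCO2", "mL/min", _FB_GT_ONB, log_transform=True),
        VariableSpec("RER", "", _ONB_GT_FB),
        VariableSpec("BF", "breaths/min", _ONB_GT_FB),
        VariableSpec("EqO2", "L/min", _ONB_GT_FB),
        VariableSpec("FEO2", "%", _ONB_GT_FB),
        VariableSpec("Tex/Tot", "%", _ONB_GT_FB),
        VariableSpec("PETO2", "mmHg", _ONB_GT_FB),
        VariableSpec("VE", "L/min", _ONB_GT_FB),
        VariableSpec("EqCO2", "L/min", _ONB_GT_FB),
        VariableSpec("VD/VT", "L/min", _ONB_GT_FB),
    ]
}


def get_spec(name: str) -> VariableSpec:
    """Look up a variable spec by name, raising ``KeyError`` if unknown."""
    return VARIABLES[name]
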