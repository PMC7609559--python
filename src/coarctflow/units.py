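"""Unit conventions.

Clinical quantities cross the API boundary in the units cardiologists use
(mmHg, ml/s, bpm, ml); everything inside the solver and mesh is SI.
"""

from __future__ import annotations

#: Pa per mmHg (conventional mercury-column definition).
MMHG_TO_PA: float = 133.322

#: m^3/s per ml/s.
MLPS_TO_M3PS: float = 1e-6

_PRESSURE_UNITS = {"mmHg", "Pa"}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg and Pa.

    Exact linear conversion by 133.322 Pa/mmHg; round-trips are identity to
    machine precision.
    """
    for u in (from_unit, to_unit):
        if u not in _PRESSURE_UNITS:
            raise ValueError(f"unknown pressure unit {u!r}; expected one of {sorted(_PRESSURE_UNITS)}")
    if from_unit == to_unit:
        return value
    if from_unit == "mmHg":
        return value * MMHG_TO_PA
    return value / MMHG_TO_PA


def mlps_to_m3ps(q_mlps: float) -> float:
    """Volume flow rate ml/s -> m^3/s."""
    return q_mlps * MLPS_TO_M3PS


def m3ps_to_mlps(q_m3ps: float) -> float:
    """Volume flow rate m^3/s -> ml/s."""
    return q_m3ps / MLPS_TO_M3PS
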