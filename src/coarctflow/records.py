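"""Cohort record types.

A :class:`PatientRecord` holds one participant's clinical measurements at
rest and during exercise (cuff pressures, heart rate, stroke volume and the
peak-systolic volume flow rates measured on velocity-encoded MRI planes in
the ascending and descending aorta). A :class:`HemoMetricsRecord` holds the
hemodynamic descriptors computed for the same participant (transstenotic
pressure gradient, surface-averaged wall shear stress, secondary flow degree
and normalized flow displacement at the ascending/descending stations).
All fields are in clinical units: mmHg, bpm, ml, ml/s, Pa, m².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Optional


class CohortWarning(UserWarning):
    """Non-fatal data oddity (e.g. apparent collateral flow)."""


@dataclass
class PatientRecord:
    id: str
    bsa: float                 # body surface area, m^2
    sex: str                   # "M" / "F"
    age: float                 # years
    sbp_rest: Optional[float] = None   # systolic cuff pressure, mmHg
    sbp_ex: Optional[float] = None
    dbp_rest: Optional[float] = None   # diastolic cuff pressure, mmHg
    dbp_ex: Optional[float] = None
    hr_rest: float = math.nan  # heart rate, bpm
    hr_ex: float = math.nan
    sv_rest: float = math.nan  # stroke volume, ml
    sv_ex: float = math.nan
    q_asc_rest: float = math.nan  # peak-systolic ascending flow, ml/s
    q_asc_ex: float = math.nan
    q_desc_rest: float = math.nan  # peak-systolic descending flow, ml/s
    q_desc_ex: float = math.nan

    def __post_init__(self) -> None:
        if not self.bsa > 0:
            raise ValueError(f"patient {self.id}: bsa must be > 0, got {self.bsa}")
        for name in ("hr_rest", "hr_ex", "sv_rest", "sv_ex"):
            v = getattr(self, name)
            if not math.isnan(v) and not v > 0:
                raise ValueError(f"patient {self.id}: {name} must be > 0, got {v}")
        # descending flow exceeding ascending flow hints at collateral
        # circulation; flagged, not rejected
        for cond in ("rest", "ex"):
            qa = getattr(self, f"q_asc_{cond}")
            qd = getattr(self, f"q_desc_{cond}")
            if not (math.isnan(qa) or math.isnan(qd)) and qd > qa:
                warnings.warn(
                    f"patient {self.id}: descending flow {qd} ml/s exceeds "
                    f"ascending flow {qa} ml/s at {cond} (collateral flow?)",
                    CohortWarning,
                    stacklevel=2,
                )


@dataclass
class HemoMetricsRecord:
    id: str
    pg_rest: float = math.nan   # transstenotic pressure gradient, mmHg
    pg_ex: float = math.nan
    wss_rest: float = math.nan  # surface-averaged WSS, ascending aorta, Pa
    wss_ex: float = math.nan
    sfd_asc_rest: float = math.nan   # secondary flow degree, dimensionless
    sfd_asc_ex: float = math.nan
    sfd_desc_rest: float = math.nan
    sfd_desc_ex: float = math.nan
    nfd_asc_rest: float = math.nan   # normalized flow displacement
    nfd_asc_ex: float = math.nan
    nfd_desc_rest: float = math.nan
    nfd_desc_ex: float = math.nan

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "id":
                continue
            v = getattr(self, f.name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"patient {self.id}: {f.name} must be >= 0, got {v}")


@dataclass
class CohortTable:
    """A cohort: patient records plus (optionally partial) metric records."""

    patients: list[PatientRecord] = field(default_factory=list)
    metrics: dict[str, HemoMetricsRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dup}")
        extra = set(self.metrics) - set(ids)
        if extra:
            raise ValueError(f"metric records without patients: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, pid: str) -> PatientRecord:
        for p in self.patients:
            if p.id == pid:
                return p
        raise KeyError(pid)
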