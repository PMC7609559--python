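"""Cohort CSV I/O, the packaged reference cohort, and VTK field output.

CSV dialect: comma-separated, dot decimal, UTF-8, one header row whose
column names are the snake_case record field names. Missing values are
empty cells (never zero). Clinical units throughout.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

from .records import CohortTable, HemoMetricsRecord, PatientRecord

PATIENT_FIELDS = [
    "id", "bsa", "sex", "age",
    "sbp_rest", "sbp_ex", "dbp_rest", "dbp_ex",
    "hr_rest", "hr_ex", "sv_rest", "sv_ex",
    "q_asc_rest", "q_asc_ex", "q_desc_rest", "q_desc_ex",
]
METRIC_FIELDS = [
    "pg_rest", "pg_ex", "wss_rest", "wss_ex",
    "sfd_asc_rest", "sfd_asc_ex", "sfd_desc_rest", "sfd_desc_ex",
    "nfd_asc_rest", "nfd_asc_ex", "nfd_desc_rest", "nfd_desc_ex",
]

_REQUIRED = {"id", "bsa", "sex", "age"}


class CohortParseError(ValueError):
    """Malformed cohort CSV; message names the row and column."""


def _parse_float(raw: str, row: int, col: str) -> float:
    raw = raw.strip()
    if raw == "":
        return math.nan
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortParseError(f"row {row}, column {col!r}: cannot parse {raw!r}") from exc


def load_cohort_table(path: Union[str, Path, IO[str]]) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    One :class:`PatientRecord` per row; rows whose metric cells are all
    empty contribute no :class:`HemoMetricsRecord`. Raises
    :class:`CohortParseError` naming row and column on malformed input.
    """
    if hasattr(path, "read"):
        return _load(path)  # type: ignore[arg-type]
    with open(path, newline="", encoding="utf-8") as fh:
        return _load(fh)


def _load(fh: IO[str]) -> CohortTable:
    reader = csv.DictReader(fh)
    header = set(reader.fieldnames or [])
    missing = _REQUIRED - header
    if missing:
        raise CohortParseError(f"missing required columns: {sorted(missing)}")
    patients: list[PatientRecord] = []
    metrics: dict[str, HemoMetricsRecord] = {}
    for rownum, row in enumerate(reader, start=2):
        pid = (row.get("id") or "").strip()
        if not pid:
            raise CohortParseError(f"row {rownum}, column 'id': empty patient id")
        kwargs = {}
        for name in PATIENT_FIELDS:
            if name in ("id", "sex"):
                continue
            if name in row and row[name] is not None:
                kwargs[name] = _parse_float(row[name], rownum, name)
        try:
            rec = PatientRecord(id=pid, sex=(row.get("sex") or "").strip(), **kwargs)
        except ValueError as exc:
            raise CohortParseError(f"row {rownum}: {exc}") from exc
        patients.append(rec)
        mvals = {
            name: _parse_float(row[name], rownum, name)
            for name in METRIC_FIELDS
            if name in row and row[name] is not None
        }
        if mvals and not all(math.isnan(v) for v in mvals.values()):
            try:
                metrics[pid] = HemoMetricsRecord(id=pid, **mvals)
            except ValueError as exc:
                raise CohortParseError(f"row {rownum}: {exc}") from exc
    return CohortTable(patients=patients, metrics=metrics)


def save_cohort_table(table: CohortTable, path: Union[str, Path]) -> None:
    """Write a cohort CSV; lossless round-trip with :func:`load_cohort_table`."""
    def fmt(v: float) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return repr(float(v))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_FIELDS + METRIC_FIELDS)
        for p in table.patients:
            m = table.metrics.get(p.id)
            row = [p.id, fmt(p.bsa), p.sex, fmt(p.age)]
            row += [fmt(getattr(p, n)) for n in PATIENT_FIELDS[4:]]
            row += [fmt(getattr(m, n)) if m is not None else "" for n in METRIC_FIELDS]
            writer.writerow(row)


def load_reference_cohort() -> CohortTable:
    """The packaged reference cohort: 20 patients with aortic coarctation.

    Per-patient clinical measurements (cuff pressures, heart rate, stroke
    volume, peak-systolic ascending/descending flow at rest and during
    MRI-ergometry exercise) together with the CFD-derived hemodynamic
    descriptors (transstenotic pressure gradient, surface-averaged WSS,
    SFD and NFD), transcribed from a published MRI-ergometry/CFD study of
    aortic coarctation. Pressure gradients are integer-rounded and WSS is
    rounded to 0.1 Pa in the source table; cohort summaries therefore
    reproduce the published means within that rounding.
    """
    ref = importlib.resources.files("coarctflow.data").joinpath("coarctation_cohort.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_cohort_table(fh)


# ---------------------------------------------------------------------------
# Legacy ASCII VTK structured-grid output
# ---------------------------------------------------------------------------

def write_vtk_structured_grid(
    path: Union[str, Path],
    z: np.ndarray,
    r: np.ndarray,
    point_data: dict[str, np.ndarray],
    title: str = "coarctflow field",
) -> None:
    """Write a 2-D (axisymmetric z-r) structured grid as legacy ASCII VTK.

    ``z`` and ``r`` are node coordinate arrays of shape (nz, nr); each entry
    of ``point_data`` is either a scalar array (nz, nr) or a vector array
    (nz, nr, 3).
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.shape != r.shape or z.ndim != 2:
        raise ValueError("z and r must be 2-D arrays of identical shape")
    nz, nr = z.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nr} {nz} 1",
        f"POINTS {nz * nr} double",
    ]
    pts = np.column_stack([z.ravel(), r.ravel(), np.zeros(z.size)])
    lines += [" ".join(f"{c:.9g}" for c in p) for p in pts]
    lines.append(f"POINT_DATA {nz * nr}")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape == (nz, nr):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in arr.ravel()]
        elif arr.shape == (nz, nr, 3):
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{c:.9g}" for c in v) for v in arr.reshape(-1, 3)]
        else:
            raise ValueError(f"field {name!r}: shape {arr.shape} incompatible with grid {(nz, nr)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
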