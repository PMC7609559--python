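"""Hemodynamic descriptors.

Field-based metrics (transstenotic pressure gradient, surface-averaged wall
shear stress) operate on a solved :class:`~coarctflow.solver.FlowField`;
plane-based metrics (secondary flow degree, normalized flow displacement)
operate on velocity-encoded measurement planes; the clinical indices
(cardiac index, stroke-volume index) are simple per-patient arithmetic.
"""

from __future__ import annotations

import numpy as np

from .geometry import VesselGeometry
from .planes import PlaneVelocityField
from .solver import FlowField, wall_shear
from .units import MMHG_TO_PA


# ---------------------------------------------------------------------------
# field-based metrics
# ---------------------------------------------------------------------------

def _plane_avg_pressure(field: FlowField) -> np.ndarray:
    """Area-averaged pressure per axial cell column, Pa."""
    R = field.mesh.r_nodes
    rmid = 0.5 * (R[:-1, :] + R[1:, :])          # per-cell radial extents
    areas = np.pi * (rmid[:, 1:] ** 2 - rmid[:, :-1] ** 2)
    return (field.p * areas).sum(axis=1) / areas.sum(axis=1)


def pressure_gradient(field: FlowField, geometry: VesselGeometry) -> float:
    """Transstenotic pressure gradient, mmHg.

    P1 is the area-averaged pressure at the inlet-side plane (sinotubular
    junction); P2 is the pressure at the downstream plane of maximal
    pressure recovery, i.e. the maximum area-averaged pressure over stations
    beyond the throat. The gradient (P1 - P2) is floored at zero.
    """
    if not field.converged:
        raise ValueError("pressure gradient requires a converged field")
    pbar = _plane_avg_pressure(field)
    zc = 0.5 * (field.mesh.z[:-1] + field.mesh.z[1:])
    p1 = pbar[0]
    downstream = zc > geometry.stenosis_center
    if not downstream.any():
        raise ValueError("no stations downstream of the throat")
    p2 = pbar[downstream].max()
    return max(0.0, (p1 - p2) / MMHG_TO_PA)


def surface_averaged_wss(field: FlowField, segment: tuple[float, float] | None = None
                         ) -> float:
    """Area-weighted mean wall shear stress over a wall segment, Pa.

    ``segment`` is an axial interval [z0, z1]; the default is the ascending
    aorta, i.e. from the inlet to the start of the branch band. Weights are
    the revolved wall-face areas (2 pi r x arc length).
    """
    geom = field.mesh.geometry
    if segment is None:
        segment = (0.0, geom.branch_band[0])
    z0, z1 = segment
    tau = wall_shear(field)
    z = field.mesh.z
    wz = 0.5 * (z[:-1] + z[1:])
    R = field.mesh.r_nodes[:, -1]
    arc = np.sqrt(np.diff(z) ** 2 + np.diff(R) ** 2)
    areas = 2.0 * np.pi * 0.5 * (R[:-1] + R[1:]) * arc
    sel = (wz >= z0) & (wz <= z1)
    if not sel.any():
        raise ValueError(f"empty wall segment [{z0}, {z1}]")
    return float((tau[sel] * areas[sel]).sum() / areas[sel].sum())


# ---------------------------------------------------------------------------
# plane-based metrics
# ---------------------------------------------------------------------------

def secondary_flow_degree(plane: PlaneVelocityField, eps: float = 1e-9) -> float:
    """SFD: mean in-plane speed / mean through-plane velocity over the lumen."""
    m = plane.mask
    through = float(plane.vz[m].mean())
    if through <= eps:
        raise ValueError(
            f"mean through-plane velocity {through:.3e} m/s too small; SFD undefined")
    inplane = float(np.sqrt(plane.vx[m] ** 2 + plane.vy[m] ** 2).mean())
    return inplane / through


def normalized_flow_displacement(plane: PlaneVelocityField,
                                 variant: str = "velocity_max") -> float:
    """NFD: off-center position of the through-plane flow, in lumen radii.

    ``velocity_max``: distance from the lumen center to the grid location of
    the maximum through-plane velocity (ties broken toward the center).
    ``flow_centroid``: distance to the through-plane-velocity-weighted
    centroid. Both clipped to [0, 1].
    """
    m = plane.mask
    vz = plane.vz[m]
    if np.all(vz == 0.0):
        raise ValueError("through-plane field is identically zero; NFD undefined")
    cx, cy = plane.center
    x, y = plane.x[m], plane.y[m]
    if variant == "velocity_max":
        vmax = vz.max()
        cand = vz == vmax
        d2 = (x[cand] - cx) ** 2 + (y[cand] - cy) ** 2
        dist = np.sqrt(d2.min())
    elif variant == "flow_centroid":
        w = vz.sum()
        if w == 0:
            raise ValueError("zero net through-plane flow; centroid undefined")
        dist = float(np.hypot((x * vz).sum() / w - cx, (y * vz).sum() / w - cy))
    else:
        raise ValueError(f"unknown NFD variant {variant!r}")
    return float(np.clip(dist / plane.radius, 0.0, 1.0))


# ---------------------------------------------------------------------------
# clinical indices
# ---------------------------------------------------------------------------

def cardiac_index(hr: float, sv: float, bsa: float) -> float:
    """Cardiac index, l/min/m^2: heart rate (bpm) x stroke volume (ml) / BSA."""
    if hr <= 0 or sv <= 0 or bsa <= 0:
        raise ValueError("hr, sv and bsa must be positive")
    return hr * sv / (1000.0 * bsa)


def stroke_volume_index(sv: float, bsa: float) -> float:
    """Stroke-volume index, ml/m^2."""
    if sv <= 0 or bsa <= 0:
        raise ValueError("sv and bsa must be positive")
    return sv / bsa
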