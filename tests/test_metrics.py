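"""Hemodynamic descriptors: pressure gradient, WSS averaging, SFD/NFD, indices."""

import numpy as np
import pytest

import coarctflow as cf
from coarctflow.metrics import (
    cardiac_index,
    normalized_flow_displacement,
    pressure_gradient,
    secondary_flow_degree,
    stroke_volume_index,
    surface_averaged_wss,
)
from coarctflow.planes import PlaneVelocityField
from coarctflow.synthetic import swirl_amplitude_for_sfd, synthesize_plane
from coarctflow.units import MMHG_TO_PA

MU = 0.0035
R = 0.010
Q = 100.0


# ---------------------------------------------------------------------------
# field-based
# ---------------------------------------------------------------------------

def test_gradient_invariant_to_pressure_offset(poiseuille_field, straight_tube):
    pg = pressure_gradient(poiseuille_field, straight_tube)
    poiseuille_field.p += 123.4
    try:
        assert pressure_gradient(poiseuille_field, straight_tube) == pytest.approx(pg, abs=1e-12)
    finally:
        poiseuille_field.p -= 123.4


def test_straight_tube_gradient_bounded_by_viscous_drop(poiseuille_field, straight_tube):
    pg = pressure_gradient(poiseuille_field, straight_tube)
    full_drop = 8 * MU * Q * 1e-6 * straight_tube.length / (np.pi * R ** 4) / MMHG_TO_PA
    assert 0.0 <= pg <= full_drop


def test_wss_segment_additivity(poiseuille_field):
    # split exactly between two cell centers so the sub-segments are disjoint
    # and cover the full segment
    mesh = poiseuille_field.mesh
    wz = 0.5 * (mesh.z[:-1] + mesh.z[1:])
    im = mesh.nz // 2
    z0, z1 = 0.005, 0.045
    zm = 0.5 * (wz[im] + wz[im + 1])
    w_full = surface_averaged_wss(poiseuille_field, (z0, z1))
    w_a = surface_averaged_wss(poiseuille_field, (z0, zm))
    w_b = surface_averaged_wss(poiseuille_field, (zm, z1))
    Rw = mesh.r_nodes[:, -1]
    arc = np.sqrt(np.diff(mesh.z) ** 2 + np.diff(Rw) ** 2)
    areas = 2 * np.pi * 0.5 * (Rw[:-1] + Rw[1:]) * arc
    a_a = areas[(wz >= z0) & (wz <= zm)].sum()
    a_b = areas[(wz > zm) & (wz <= z1)].sum()
    combined = (w_a * a_a + w_b * a_b) / (a_a + a_b)
    assert combined == pytest.approx(w_full, rel=1e-9)


def test_wss_empty_segment_rejected(poiseuille_field):
    with pytest.raises(ValueError, match="empty wall segment"):
        surface_averaged_wss(poiseuille_field, (0.048, 0.0481))


# ---------------------------------------------------------------------------
# plane-based
# ---------------------------------------------------------------------------

def test_centered_symmetric_plane_has_zero_sfd_nfd():
    plane = synthesize_plane(R, 300.0, blunt_exponent=2.0)
    assert secondary_flow_degree(plane) == 0.0
    assert normalized_flow_displacement(plane, "velocity_max") <= plane.grid_spacing / R
    assert normalized_flow_displacement(plane, "flow_centroid") < 1e-12


def test_constructed_sfd_is_exact():
    s = swirl_amplitude_for_sfd(R, 400.0, 0.2)
    plane = synthesize_plane(R, 400.0, swirl_amplitude=s)
    assert secondary_flow_degree(plane) == pytest.approx(0.2, rel=1e-12)


def test_sfd_linear_in_swirl():
    s = swirl_amplitude_for_sfd(R, 400.0, 0.2)
    p1 = synthesize_plane(R, 400.0, swirl_amplitude=s)
    p2 = synthesize_plane(R, 400.0, swirl_amplitude=2 * s)
    assert secondary_flow_degree(p2) == pytest.approx(2 * secondary_flow_degree(p1), rel=1e-12)


def test_displaced_jet_nfd():
    plane = synthesize_plane(R, 400.0, displacement=0.3)
    nfd = normalized_flow_displacement(plane, "velocity_max")
    assert nfd == pytest.approx(0.3, abs=plane.grid_spacing / R)


def test_plug_flow_tie_break_returns_center():
    plane = synthesize_plane(R, 400.0)
    plane.vz[plane.mask] = 1.0
    assert normalized_flow_displacement(plane, "velocity_max") <= plane.grid_spacing / R
    assert normalized_flow_displacement(plane, "flow_centroid") < 1e-12


def test_metrics_invariant_under_quarter_rotation():
    s = swirl_amplitude_for_sfd(R, 400.0, 0.35, displacement=0.25)
    plane = synthesize_plane(R, 400.0, displacement=0.25, swirl_amplitude=s)
    # rotate the sampled field by 90 degrees about the lumen center
    rot = PlaneVelocityField(
        x=plane.x, y=plane.y,
        vx=-np.rot90(plane.vy), vy=np.rot90(plane.vx), vz=np.rot90(plane.vz),
        mask=np.rot90(plane.mask), center=plane.center, radius=plane.radius,
    )
    assert secondary_flow_degree(rot) == pytest.approx(secondary_flow_degree(plane), rel=0.02)
    for variant in ("velocity_max", "flow_centroid"):
        assert normalized_flow_displacement(rot, variant) == pytest.approx(
            normalized_flow_displacement(plane, variant), abs=0.02)


def test_nfd_centroid_bounded_by_one():
    plane = synthesize_plane(R, 400.0, displacement=0.9, blunt_exponent=12.0)
    assert 0.0 <= normalized_flow_displacement(plane, "flow_centroid") <= 1.0


def test_undefined_metrics_raise():
    plane = synthesize_plane(R, 400.0)
    plane.vz[:] = 0.0
    with pytest.raises(ValueError, match="SFD undefined"):
        secondary_flow_degree(plane)
    with pytest.raises(ValueError, match="NFD undefined"):
        normalized_flow_displacement(plane)
    with pytest.raises(ValueError, match="unknown NFD variant"):
        normalized_flow_displacement(synthesize_plane(R, 400.0), "median")


# ---------------------------------------------------------------------------
# clinical indices
# ---------------------------------------------------------------------------

def test_cardiac_index_arithmetic():
    assert cardiac_index(60.0, 80.0, 1.6) == pytest.approx(3.0)
    assert stroke_volume_index(80.0, 1.6) == pytest.approx(50.0)


def test_indices_reject_nonpositive_inputs():
    with pytest.raises(ValueError):
        cardiac_index(0.0, 80.0, 1.6)
    with pytest.raises(ValueError):
        stroke_volume_index(80.0, -1.0)
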