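"""Boundary-condition construction: inlet mapping, Murray splits, sink band."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coarctflow as cf
from coarctflow.boundary import (
    BoundaryConditionWarning,
    BranchNode,
    BranchTree,
    build_boundary_conditions,
    build_sink_band,
    default_arch_tree,
    map_inlet_profile,
    murray_split,
)
from coarctflow.synthetic import synthesize_plane


# ---------------------------------------------------------------------------
# inlet mapping
# ---------------------------------------------------------------------------

def test_matching_plane_needs_no_renormalization(straight_mesh):
    plane = synthesize_plane(0.01, 300.0, blunt_exponent=2.0)
    prof = map_inlet_profile(plane, straight_mesh, 300.0)
    assert prof.renormalization == pytest.approx(1.0, abs=5e-3)
    assert prof.flux() == pytest.approx(300e-6, rel=1e-12)


def test_doubled_plane_gives_half_factor(straight_mesh):
    plane = synthesize_plane(0.01, 300.0, blunt_exponent=2.0)
    plane.vz *= 2.0
    with pytest.warns(BoundaryConditionWarning, match="25%"):
        prof = map_inlet_profile(plane, straight_mesh, 300.0)
    assert prof.renormalization == pytest.approx(0.5, abs=5e-3)


def test_noisy_plane_flux_exact_after_scaling(straight_mesh):
    plane = synthesize_plane(0.01, 300.0, noise_sd=0.05, seed=11)
    prof = map_inlet_profile(plane, straight_mesh, 300.0)
    assert prof.flux() == pytest.approx(300e-6, rel=1e-12)


def test_zero_flow_plane_rejected(straight_mesh):
    plane = synthesize_plane(0.01, 300.0)
    plane.vz[:] = 0.0
    with pytest.raises(ValueError, match="no net through-plane flow"):
        map_inlet_profile(plane, straight_mesh, 300.0)


# ---------------------------------------------------------------------------
# Murray splitting
# ---------------------------------------------------------------------------

def _two_child_tree(r1, r2):
    bct = BranchNode("bct", 6e-3, children=[BranchNode("c1", r1), BranchNode("c2", r2)])
    return BranchTree(brachiocephalic=bct,
                      left_common_carotid=BranchNode("lcc", 3.5e-3),
                      left_subclavian=BranchNode("lsa", 4.2e-3))


def test_equal_radii_split_evenly():
    flows = murray_split(_two_child_tree(2e-3, 2e-3), 100.0)
    assert flows["c1"] == pytest.approx(flows["c2"])
    assert flows["c1"] == pytest.approx(100.0 * 0.5 * 0.5)


def test_radius_cubed_rule():
    """Children with radii 2:1 split the parent flow 8:1."""
    flows = murray_split(_two_child_tree(2e-3, 1e-3), 90.0)
    parent = 90.0 * 0.5
    assert flows["c1"] == pytest.approx(parent * 8 / 9)
    assert flows["c2"] == pytest.approx(parent * 1 / 9)


def test_zero_total_flow():
    flows = murray_split(default_arch_tree(), 0.0)
    assert all(v == 0.0 for v in flows.values())


def test_arch_rules():
    tree_w = default_arch_tree("weighted")
    tree_t = default_arch_tree("thirds")
    fw = murray_split(tree_w, 120.0)
    ft = murray_split(tree_t, 120.0)
    assert fw["right_subclavian"] + fw["right_common_carotid"] == pytest.approx(60.0)
    assert fw["left_common_carotid"] == pytest.approx(30.0)
    assert ft["left_common_carotid"] == pytest.approx(40.0)


@given(scale=st.floats(1e-3, 1e3), q=st.floats(0.0, 1e3),
       r1=st.floats(0.5e-3, 8e-3), r2=st.floats(0.5e-3, 8e-3))
@settings(max_examples=60, deadline=None)
def test_split_sums_exactly_and_scale_invariant(scale, q, r1, r2):
    t1 = _two_child_tree(r1, r2)
    t2 = _two_child_tree(r1 * scale, r2 * scale)
    f1 = murray_split(t1, q)
    f2 = murray_split(t2, q)
    assert sum(f1.values()) == pytest.approx(q, rel=1e-12, abs=1e-12)
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# sink band and global budget
# ---------------------------------------------------------------------------

def test_equal_flows_give_zero_sink():
    g = cf.build_vessel()
    band = build_sink_band(g, 300.0, 300.0)
    assert band.normal_velocity == 0.0 and band.flux == 0.0


def test_sink_flux_is_flow_difference():
    """Cohort rest means: 407 ml/s ascending, 225.5 ml/s descending."""
    g = cf.build_vessel()
    band = build_sink_band(g, 407.0, 225.5)
    assert band.flux == pytest.approx(181.5e-6, rel=1e-12)
    assert band.normal_velocity == pytest.approx(band.flux / band.lateral_area)


def test_doubled_band_area_halves_velocity():
    g1 = cf.build_vessel(branch_band=(0.06, 0.09))
    g2 = cf.build_vessel(branch_band=(0.03, 0.09))
    b1 = build_sink_band(g1, 400.0, 200.0)
    b2 = build_sink_band(g2, 400.0, 200.0)
    assert b2.lateral_area == pytest.approx(2.0 * b1.lateral_area, rel=1e-6)
    assert b2.normal_velocity == pytest.approx(0.5 * b1.normal_velocity, rel=1e-6)
    assert b2.flux == pytest.approx(b1.flux)


def test_collateral_flow_rejected():
    with pytest.raises(ValueError, match="collateral"):
        build_sink_band(cf.build_vessel(), 200.0, 300.0)


def test_global_mass_budget_closes(straight_mesh):
    bcs = build_boundary_conditions(straight_mesh, None, 407.0, 225.5)
    assert bcs.mass_budget_error() < 1e-3
    plane = synthesize_plane(0.01, 407.0, displacement=0.2, noise_sd=0.03, seed=3)
    bcs2 = build_boundary_conditions(straight_mesh, plane, 407.0, 225.5)
    assert bcs2.mass_budget_error() < 1e-3
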