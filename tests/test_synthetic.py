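"""Synthetic cohort generation: determinism, moments, plane construction."""

import numpy as np
import pytest

import coarctflow as cf
from coarctflow.metrics import normalized_flow_displacement, secondary_flow_degree
from coarctflow.synthetic import (
    CohortDistributionSpec,
    sample_cohort,
    sample_patient,
    swirl_amplitude_for_sfd,
    synthesize_plane,
)


def test_same_seed_same_patient():
    spec = CohortDistributionSpec()
    a = sample_patient(spec, 42)
    b = sample_patient(spec, 42)
    assert a.record == b.record
    for key in a.planes:
        assert np.array_equal(a.planes[key].vz, b.planes[key].vz)
    c = sample_patient(spec, 43)
    assert c.record != a.record


def test_degenerate_spec_yields_exact_means(zero_sd_spec):
    p = sample_patient(zero_sd_spec, 7)
    assert p.record.hr_rest == pytest.approx(72.9)
    assert p.geometry.stenosis_degree == pytest.approx(0.351)
    assert p.record.q_asc_rest == pytest.approx(407.0)
    assert p.record.hr_ex == pytest.approx(72.9 + 50 * 0.8579)
    assert p.record.sv_rest == pytest.approx(50.6 * 1.6)
    assert p.record.q_desc_rest == pytest.approx(407.0 * 225.5 / 407.0)


def test_cohort_moments_match_population(rng):
    """Sample means land within 3 standard errors of the population values."""
    spec = CohortDistributionSpec()
    cohort = sample_cohort(spec, 500, 10_000)
    D = np.array([p.geometry.stenosis_degree for p in cohort])
    q = np.array([p.record.q_asc_rest for p in cohort])
    hr = np.array([p.record.hr_rest for p in cohort])
    # truncation shifts the mean slightly; compare against the truncated law
    mc = np.random.default_rng(99).normal(0.351, 0.181, 400_000)
    mc = mc[(mc >= spec.stenosis_bounds[0]) & (mc <= spec.stenosis_bounds[1])]
    assert abs(D.mean() - mc.mean()) < 3 * D.std(ddof=1) / np.sqrt(D.size)
    assert abs(q.mean() - 407.0) < 3 * q.std(ddof=1) / np.sqrt(q.size)
    assert abs(hr.mean() - 72.9) < 3 * hr.std(ddof=1) / np.sqrt(hr.size)
    assert np.all([p.record.q_asc_ex > 0 for p in cohort])


def test_invalid_spec_rejected():
    import dataclasses
    spec = CohortDistributionSpec()
    with pytest.raises(ValueError, match="noise"):
        sample_patient(dataclasses.replace(spec, noise_sd_ex=0.01), 1)
    with pytest.raises(ValueError, match="standard deviations"):
        sample_patient(dataclasses.replace(spec, bsa_sd=-0.1), 1)


def test_plane_flow_matches_target_noise_free():
    for d, k in [(0.0, 2.0), (0.4, 4.0), (0.7, 8.0)]:
        plane = synthesize_plane(0.01, 350.0, blunt_exponent=k, displacement=d)
        assert plane.integrated_flow() == pytest.approx(350.0, rel=5e-3)


def test_plane_rejects_bad_arguments():
    with pytest.raises(ValueError, match="q_target"):
        synthesize_plane(0.01, 0.0)
    with pytest.raises(ValueError, match="displacement"):
        synthesize_plane(0.01, 100.0, displacement=1.0)
    with pytest.raises(ValueError, match="blunt"):
        synthesize_plane(0.01, 100.0, blunt_exponent=1.0)


def test_noise_determinism_and_magnitude():
    a = synthesize_plane(0.01, 400.0, noise_sd=0.05, seed=5)
    b = synthesize_plane(0.01, 400.0, noise_sd=0.05, seed=5)
    clean = synthesize_plane(0.01, 400.0)
    assert np.array_equal(a.vz, b.vz)
    resid = (a.vz - clean.vz)[a.mask]
    assert resid.std() == pytest.approx(0.05, rel=0.1)
    assert np.all((a.vx == 0.0) | a.mask)


def test_aliasing_wraps_into_venc_interval():
    fast = synthesize_plane(0.01, 2000.0)           # peak ~ 9.5 m/s
    assert fast.vz.max() > 3.0                      # unbounded without venc
    wrapped = synthesize_plane(0.01, 2000.0, venc=3.0)
    assert np.all(wrapped.vz > -3.0) and np.all(wrapped.vz <= 3.0)
    # wrapping is the identity where |v| < venc
    slow = synthesize_plane(0.01, 300.0, venc=3.0)
    ref = synthesize_plane(0.01, 300.0)
    assert np.allclose(slow.vz, ref.vz)


def test_planes_recover_ground_truth(zero_sd_spec):
    """Noise-free synthetic patients: plane metrics reproduce the stored
    ground truth (displacement within one grid spacing, SFD exactly)."""
    import dataclasses
    spec = dataclasses.replace(zero_sd_spec, nfd_asc_mean=0.25, sfd_asc_mean=0.4)
    patient = sample_patient(spec, 3)
    for (station, cond), plane in patient.planes.items():
        truth = patient.ground_truth[(station, cond)]
        nfd = normalized_flow_displacement(plane, "velocity_max")
        assert nfd == pytest.approx(truth.displacement, abs=plane.grid_spacing / plane.radius)
        assert secondary_flow_degree(plane) == pytest.approx(truth.sfd, rel=1e-9)
        assert plane.integrated_flow() == pytest.approx(truth.q_target, rel=5e-3)


def test_plane_csv_round_trip(tmp_path):
    plane = synthesize_plane(0.01, 400.0, displacement=0.2, swirl_amplitude=0.1,
                             noise_sd=0.02, seed=9)
    plane.to_csv(tmp_path / "plane.csv")
    back = cf.PlaneVelocityField.from_csv(tmp_path / "plane.csv")
    for f in ("x", "y", "vx", "vy", "vz"):
        assert np.allclose(getattr(back, f), getattr(plane, f), atol=0, rtol=0)
    assert np.array_equal(back.mask, plane.mask)
    assert back.radius == plane.radius
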