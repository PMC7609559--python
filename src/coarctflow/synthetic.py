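"""Synthetic cohort generation.

Generates patients whose statistics emulate the study population this
package models: adolescents and young adults with aortic coarctation
(stenosis degree 35.1 +/- 18.1 %), measured at rest and during moderate
MRI-ergometry exercise targeting a heart-rate increase of 50 bpm (of which
85.79 +/- 10.28 % is achieved on average). Each patient carries a
parametric vessel geometry and velocity-encoded measurement planes at the
sinotubular junction, mid-ascending and descending stations, for rest and
exercise, built from known ground-truth profile parameters (jet
displacement, swirl amplitude, bluntness) so that the plane metrics can be
validated against the truth. Exercise planes reuse the rest profile shape
with rescaled velocities and larger noise, reflecting the noisier exercise
acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import VesselGeometry, build_vessel
from .planes import PlaneVelocityField, make_circular_grid
from .records import PatientRecord

STATIONS = ("sinotubular", "mid_ascending", "descending")
CONDITIONS = ("rest", "ex")


@dataclass(frozen=True)
class CohortDistributionSpec:
    """Population moments (clinical units; fractions as fractions)."""

    stenosis_mean: float = 0.351
    stenosis_sd: float = 0.181
    stenosis_bounds: tuple[float, float] = (0.02, 0.95)
    bsa_mean: float = 1.6          # m^2
    bsa_sd: float = 0.4
    bsa_bounds: tuple[float, float] = (0.6, 2.6)
    age_mean: float = 21.5         # years
    age_sd: float = 13.7
    age_bounds: tuple[float, float] = (5.0, 70.0)
    male_fraction: float = 0.65
    hr_rest_mean: float = 72.9     # bpm
    hr_rest_sd: float = 14.2
    hr_rest_bounds: tuple[float, float] = (40.0, 120.0)
    hr_increase_target: float = 50.0   # bpm
    hr_achieved_mean: float = 0.8579   # fraction of the target increase
    hr_achieved_sd: float = 0.1028
    hr_achieved_bounds: tuple[float, float] = (0.1, 1.4)
    svi_mean: float = 50.6         # ml/m^2
    svi_sd: float = 6.0
    svi_bounds: tuple[float, float] = (25.0, 80.0)
    svi_ex_scale_mean: float = 1.032   # 52.2 / 50.6
    svi_ex_scale_sd: float = 0.08
    svi_ex_scale_bounds: tuple[float, float] = (0.6, 1.6)
    q_asc_rest_mean: float = 407.0     # ml/s
    q_asc_rest_sd: float = 87.3
    q_asc_rest_bounds: tuple[float, float] = (100.0, 900.0)
    #: exercise/rest ascending-flow ratio: lognormal about the cohort ratio
    flow_scale_log_mean: float = float(np.log(494.4 / 407.0))
    flow_scale_log_sd: float = 0.15
    desc_fraction_mean: float = 225.5 / 407.0   # descending/ascending flow
    desc_fraction_sd: float = 0.12
    desc_fraction_bounds: tuple[float, float] = (0.15, 0.95)
    sbp_rest_mean: float = 128.45  # mmHg
    sbp_rest_sd: float = 21.45
    sbp_delta_mean: float = 30.2
    sbp_delta_sd: float = 25.0
    dbp_rest_mean: float = 64.8
    dbp_rest_sd: float = 9.1
    dbp_delta_mean: float = 14.0
    dbp_delta_sd: float = 15.0
    # plane ground-truth profile parameters per station family
    nfd_asc_mean: float = 0.08
    nfd_asc_sd: float = 0.06
    nfd_desc_mean: float = 0.11
    nfd_desc_sd: float = 0.06
    nfd_bounds: tuple[float, float] = (0.0, 0.8)
    sfd_asc_mean: float = 0.46
    sfd_asc_sd: float = 0.39
    sfd_desc_mean: float = 0.50
    sfd_desc_sd: float = 0.45
    sfd_bounds: tuple[float, float] = (0.0, 2.0)
    blunt_exponent: float = 4.0    # through-plane profile (1 - rho^k)
    noise_sd_rest: float = 0.05    # m/s
    noise_sd_ex: float = 0.10      # m/s (exercise images are noisier)
    venc_low: float = 3.0          # m/s, mild stenosis
    venc_high: float = 4.0         # m/s, severe stenosis
    venc_switch_degree: float = 0.4
    plane_grid_n: int = 64
    vessel_r_ref: float = 0.010    # m

    def validate(self) -> None:
        sds = [self.stenosis_sd, self.bsa_sd, self.age_sd, self.hr_rest_sd,
               self.hr_achieved_sd, self.svi_sd, self.q_asc_rest_sd,
               self.flow_scale_log_sd, self.desc_fraction_sd,
               self.nfd_asc_sd, self.nfd_desc_sd, self.sfd_asc_sd,
               self.sfd_desc_sd, self.noise_sd_rest, self.noise_sd_ex]
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")
        lo, hi = self.stenosis_bounds
        if not (0.0 <= lo < hi <= 0.95):
            raise ValueError("stenosis truncation must lie within (0, 0.95)")
        if self.noise_sd_ex < self.noise_sd_rest:
            raise ValueError("exercise noise must be >= rest noise")
        if not 2 <= self.blunt_exponent or not 0 < self.venc_low <= self.venc_high:
            raise ValueError("invalid profile or velocity-encoding parameters")

    def venc(self, stenosis_degree: float) -> float:
        """Velocity-encoding limit adapted to the stenosis severity."""
        return self.venc_high if stenosis_degree >= self.venc_switch_degree else self.venc_low


@dataclass
class PlaneGroundTruth:
    displacement: float     # jet displacement, fraction of lumen radius
    swirl_amplitude: float  # in-plane solid-body speed at the lumen edge, m/s
    sfd: float              # secondary flow degree of the noise-free plane
    blunt_exponent: float
    q_target: float         # ml/s


@dataclass
class SyntheticPatient:
    record: PatientRecord
    geometry: VesselGeometry
    planes: dict = field(default_factory=dict)        # (station, condition) -> plane
    ground_truth: dict = field(default_factory=dict)  # (station, condition) -> truth


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               bounds: tuple[float, float], max_tries: int = 10_000) -> float:
    """Truncated-normal draw by rejection (degenerate sd = 0 allowed)."""
    lo, hi = bounds
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError(f"degenerate draw {mean} outside bounds {bounds}")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError(f"rejection sampling failed for N({mean}, {sd}) in {bounds}")


def synthesize_plane(radius: float, q_target: float, *, blunt_exponent: float = 4.0,
                     displacement: float = 0.0, swirl_amplitude: float = 0.0,
                     noise_sd: float = 0.0, venc: Optional[float] = None,
                     seed: Optional[int] = None, n: int = 64) -> PlaneVelocityField:
    """Build one velocity-encoded measurement plane.

    Through-plane component: u(rho') = U (1 - (rho'/R)^k), clipped at zero,
    centred at ``displacement * R`` along +x and scaled so the noise-free
    lumen integral equals ``q_target`` (ml/s). In-plane component: solid-body
    swirl about the lumen center with edge speed ``swirl_amplitude`` (m/s).
    Independent Gaussian noise of ``noise_sd`` is added per component inside
    the mask; if ``venc`` is given, every component is wrapped into
    (-venc, venc] as velocity-encoding aliasing would.
    """
    if q_target <= 0:
        raise ValueError(f"q_target must be positive, got {q_target}")
    if not 0.0 <= displacement < 1.0:
        raise ValueError("displacement must be in [0, 1)")
    if blunt_exponent < 2:
        raise ValueError("blunt exponent must be >= 2")
    plane = make_circular_grid(radius, n=n)
    cx, cy = plane.center
    jet_x = cx + displacement * radius
    rho = np.hypot(plane.x - jet_x, plane.y - cy)
    u_unit = np.clip(1.0 - (rho / radius) ** blunt_exponent, 0.0, None)
    u_unit[~plane.mask] = 0.0
    integral = u_unit[plane.mask].sum() * plane.pixel_area  # m^2 x (unit speed)
    if integral <= 0:
        raise ValueError("degenerate through-plane profile")
    U = (q_target * 1e-6) / integral
    plane.vz = U * u_unit
    # solid-body swirl about the lumen center
    plane.vx = -swirl_amplitude * (plane.y - cy) / radius
    plane.vy = swirl_amplitude * (plane.x - cx) / radius
    plane.vx[~plane.mask] = 0.0
    plane.vy[~plane.mask] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for comp in (plane.vx, plane.vy, plane.vz):
            comp[plane.mask] += rng.normal(0.0, noise_sd, int(plane.mask.sum()))
    if venc is not None:
        for name in ("vx", "vy", "vz"):
            w = getattr(plane, name)
            wrapped = np.mod(w + venc, 2.0 * venc) - venc
            wrapped[wrapped == -venc] = venc
            setattr(plane, name, wrapped)
    return plane


def swirl_amplitude_for_sfd(radius: float, q_target: float, sfd_target: float, *,
                            blunt_exponent: float = 4.0, displacement: float = 0.0,
                            n: int = 64) -> float:
    """Edge swirl speed making the noise-free discrete SFD exactly sfd_target."""
    ref = synthesize_plane(radius, q_target, blunt_exponent=blunt_exponent,
                           displacement=displacement, n=n)
    m = ref.mask
    mean_through = float(ref.vz[m].mean())
    cx, cy = ref.center
    mean_unit_inplane = float((np.hypot(ref.x - cx, ref.y - cy)[m] / radius).mean())
    return sfd_target * mean_through / mean_unit_inplane


def sample_patient(spec: CohortDistributionSpec, seed: int,
                   patient_id: str = "S01") -> SyntheticPatient:
    """Draw one synthetic patient; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    D = _truncnorm(rng, spec.stenosis_mean, spec.stenosis_sd, spec.stenosis_bounds)
    bsa = _truncnorm(rng, spec.bsa_mean, spec.bsa_sd, spec.bsa_bounds)
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, spec.age_bounds)
    sex = "M" if (spec.male_fraction == 1.0 or rng.random() < spec.male_fraction) else "F"
    hr_rest = _truncnorm(rng, spec.hr_rest_mean, spec.hr_rest_sd, spec.hr_rest_bounds)
    achieved = _truncnorm(rng, spec.hr_achieved_mean, spec.hr_achieved_sd,
                          spec.hr_achieved_bounds)
    hr_ex = hr_rest + spec.hr_increase_target * achieved
    svi = _truncnorm(rng, spec.svi_mean, spec.svi_sd, spec.svi_bounds)
    svi_scale = _truncnorm(rng, spec.svi_ex_scale_mean, spec.svi_ex_scale_sd,
                           spec.svi_ex_scale_bounds)
    q_asc_rest = _truncnorm(rng, spec.q_asc_rest_mean, spec.q_asc_rest_sd,
                            spec.q_asc_rest_bounds)
    flow_scale = float(np.exp(spec.flow_scale_log_mean
                              + spec.flow_scale_log_sd * rng.standard_normal())) \
        if spec.flow_scale_log_sd > 0 else float(np.exp(spec.flow_scale_log_mean))
    desc_frac = _truncnorm(rng, spec.desc_fraction_mean, spec.desc_fraction_sd,
                           spec.desc_fraction_bounds)
    sbp_rest = _truncnorm(rng, spec.sbp_rest_mean, spec.sbp_rest_sd, (60, 260))
    sbp_ex = sbp_rest + _truncnorm(rng, spec.sbp_delta_mean, spec.sbp_delta_sd, (-20, 140))
    dbp_rest = _truncnorm(rng, spec.dbp_rest_mean, spec.dbp_rest_sd, (30, 130))
    dbp_ex = dbp_rest + _truncnorm(rng, spec.dbp_delta_mean, spec.dbp_delta_sd, (-20, 90))

    record = PatientRecord(
        id=patient_id, bsa=bsa, sex=sex, age=age,
        sbp_rest=sbp_rest, sbp_ex=sbp_ex, dbp_rest=dbp_rest, dbp_ex=dbp_ex,
        hr_rest=hr_rest, hr_ex=hr_ex,
        sv_rest=svi * bsa, sv_ex=svi * svi_scale * bsa,
        q_asc_rest=q_asc_rest, q_asc_ex=q_asc_rest * flow_scale,
        q_desc_rest=q_asc_rest * desc_frac, q_desc_ex=q_asc_rest * flow_scale * desc_frac,
    )
    # lengthen the bump for severe narrowings so the wall slope stays within
    # the solver's robust range (peak slope = pi * D * R / l_s)
    l_s = max(0.04, float(np.pi) * D * spec.vessel_r_ref / 0.45)
    geometry = build_vessel(r_ref=spec.vessel_r_ref, degree=D, stenosis_length=l_s)
    venc = spec.venc(D)

    patient = SyntheticPatient(record=record, geometry=geometry)
    for station in STATIONS:
        if station == "descending":
            d_mean, d_sd = spec.nfd_desc_mean, spec.nfd_desc_sd
            s_mean, s_sd = spec.sfd_desc_mean, spec.sfd_desc_sd
            q_rest, q_ex = record.q_desc_rest, record.q_desc_ex
        else:
            d_mean, d_sd = spec.nfd_asc_mean, spec.nfd_asc_sd
            s_mean, s_sd = spec.sfd_asc_mean, spec.sfd_asc_sd
            q_rest, q_ex = record.q_asc_rest, record.q_asc_ex
        radius = float(geometry.radius(geometry.stations[station]))
        d = _truncnorm(rng, d_mean, d_sd, spec.nfd_bounds)
        sfd = _truncnorm(rng, s_mean, s_sd, spec.sfd_bounds)
        for cond, q, noise in (("rest", q_rest, spec.noise_sd_rest),
                               ("ex", q_ex, spec.noise_sd_ex)):
            s_amp = swirl_amplitude_for_sfd(
                radius, q, sfd, blunt_exponent=spec.blunt_exponent,
                displacement=d, n=spec.plane_grid_n)
            plane = synthesize_plane(
                radius, q, blunt_exponent=spec.blunt_exponent, displacement=d,
                swirl_amplitude=s_amp, noise_sd=noise, venc=venc,
                seed=int(rng.integers(2 ** 31)), n=spec.plane_grid_n)
            patient.planes[(station, cond)] = plane
            patient.ground_truth[(station, cond)] = PlaneGroundTruth(
                displacement=d, swirl_amplitude=s_amp, sfd=sfd,
                blunt_exponent=spec.blunt_exponent, q_target=q)
    return patient


def sample_cohort(spec: CohortDistributionSpec, n: int, seed: int
                  ) -> list[SyntheticPatient]:
    """n synthetic patients; patient i uses the per-id seed ``seed + i``."""
    return [sample_patient(spec, seed + i, patient_id=f"S{i + 1:02d}")
            for i in range(n)]
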