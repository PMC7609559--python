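"""Steady laminar incompressible axisymmetric finite-volume Navier-Stokes.

Desk-scale replacement for a commercial 3-D solver: cell-centred finite
volumes on the body-fitted structured grid of :class:`~coarctflow.geometry.AxiMesh`,
SIMPLE pressure-velocity coupling with Rhie-Chow face interpolation,
first-order upwind convection, over-relaxed orthogonal/deferred-correction
diffusion, and a generalized-Newtonian (Carreau-Yasuda) effective viscosity
evaluated from the axisymmetric rate-of-deformation tensor (including the
hoop term v/r). Boundary conditions: prescribed inlet velocity profile,
no-slip rigid wall with an optional suction band extracting the arch-branch
flow, symmetry at the axis (automatic: revolved face areas vanish at r = 0),
and a fixed-pressure outlet so the reported pressure field is gauge,
outlet-referenced.

The flow is solved at peak systole only and the model is laminar; at
exercise flow rates the Reynolds number leaves the comfortably laminar
range, so every run reports its Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boundary import BoundaryConditions
from .geometry import AxiMesh
from .rheology import CarreauYasudaParams, NewtonianParams

Rheology = Union[CarreauYasudaParams, NewtonianParams]


class SolverDivergence(RuntimeError):
    """Raised when residuals grow; carries the residual history."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class SolverParams:
    density: float = 1050.0        # blood density, kg/m^3
    relax_u: float = 0.7           # velocity under-relaxation
    relax_p: float = 0.3           # pressure under-relaxation
    relax_mu: float = 0.5          # viscosity under-relaxation
    tolerance: float = 1e-6        # normalized-residual convergence target
    max_iterations: int = 20000
    divergence_factor: float = 1e6  # residual growth treated as divergence
    #: include the explicit transpose (full-stress) viscous terms
    full_stress: bool = True
    #: include the explicit non-orthogonal diffusion corrections
    nonorth_correction: bool = True
    #: under-relaxation of the explicit deferred corrections
    relax_deferred: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.tolerance <= 0:
            raise ValueError("density and tolerance must be positive")
        for r in (self.relax_u, self.relax_p, self.relax_mu):
            if not 0 < r <= 1:
                raise ValueError("relaxation factors must be in (0, 1]")


@dataclass
class FlowField:
    """Converged (or reported non-converged) steady axisymmetric flow."""

    mesh: AxiMesh
    u: np.ndarray            # axial velocity at cell centers, m/s, (nz, nr)
    v: np.ndarray            # radial velocity, m/s
    p: np.ndarray            # gauge pressure (outlet-referenced), Pa
    mu_eff: np.ndarray       # effective viscosity, Pa s
    face_flux_z: np.ndarray  # volume flux through axial faces, m^3/s, (nz+1, nr)
    converged: bool = True
    residual_history: list[dict] = field(default_factory=list)
    reynolds: float = 0.0    # inlet Reynolds number (diameter-based)

    def plane_flux(self, z: float) -> float:
        """Discrete volume flux (m^3/s) through the transverse plane nearest z."""
        i = int(np.argmin(np.abs(self.mesh.z - z)))
        return float(self.face_flux_z[i].sum())

    def wall_tau(self) -> np.ndarray:
        return wall_shear(self)


# ---------------------------------------------------------------------------
# mesh-derived operators
# ---------------------------------------------------------------------------

class _Grid:
    """Precomputed face geometry for an AxiMesh (see solver docstring)."""

    def __init__(self, mesh: AxiMesh):
        self.mesh = mesh
        z, R = mesh.z, mesh.r_nodes
        self.nz, self.nr = mesh.nz, mesh.nr
        # axial (station) faces: annulus areas, (nz+1, nr)
        self.Az = np.pi * (R[:, 1:] ** 2 - R[:, :-1] ** 2)
        # radial surfaces j=0..nr: outward (+r) area vectors, (nz, nr+1)
        dz = np.diff(z)[:, None]
        dr = R[1:, :] - R[:-1, :]
        rbar = 0.5 * (R[1:, :] + R[:-1, :])
        self.Sn_z = -2.0 * np.pi * rbar * dr
        self.Sn_r = 2.0 * np.pi * rbar * dz
        self.Sn_mag = np.sqrt(self.Sn_z ** 2 + self.Sn_r ** 2)
        self.V = mesh.cell_volumes()
        self.zc, self.rc = mesh.cell_centers()
        # east-face center-to-center vectors (internal stations 1..nz-1)
        self.de_z = self.zc[1:, :] - self.zc[:-1, :]
        self.de_r = self.rc[1:, :] - self.rc[:-1, :]
        Ai = self.Az[1:-1, :]
        self.gdiff_e = Ai ** 2 / (Ai * self.de_z + 1e-300)   # |S|^2/(S.d)
        # north-face vectors (internal surfaces 1..nr-1)
        self.dn_z = self.zc[:, 1:] - self.zc[:, :-1]
        self.dn_r = self.rc[:, 1:] - self.rc[:, :-1]
        Snz, Snr = self.Sn_z[:, 1:-1], self.Sn_r[:, 1:-1]
        sd = Snz * self.dn_z + Snr * self.dn_r
        self.gdiff_n = (Snz ** 2 + Snr ** 2) / (sd + 1e-300)
        # boundary distances
        self.d_in = self.zc[0, :] - z[0]                  # inlet face -> first centers
        self.d_out = z[-1] - self.zc[-1, :]               # last centers -> outlet face
        # --- planar (z, r) geometry for Green-Gauss gradients ---
        # axial faces are vertical: planar outward vector (+z side) = (dR, 0)
        self.Pz_ax = R[:, 1:] - R[:, :-1]                 # (nz+1, nr)
        # radial surfaces: planar outward (+r side) vector = (-dr, dz)
        self.Pn_z = -dr                                    # (nz, nr+1)
        self.Pn_r = dz * np.ones_like(dr)
        # planar quadrilateral cell areas (trapezoid in z)
        self.A_cell = 0.5 * ((R[:-1, 1:] - R[:-1, :-1]) + (R[1:, 1:] - R[1:, :-1])) * dz
        # wall faces: midpoints, outward unit normals, distance center->wall
        wz = 0.5 * (z[:-1] + z[1:])
        wr = 0.5 * (R[:-1, -1] + R[1:, -1])
        self.wall_mid = np.column_stack([wz, wr])
        nzv = self.Sn_z[:, -1] / (self.Sn_mag[:, -1] + 1e-300)
        nrv = self.Sn_r[:, -1] / (self.Sn_mag[:, -1] + 1e-300)
        self.wall_nz, self.wall_nr = nzv, nrv
        dwz = wz - self.zc[:, -1]
        dwr = wr - self.rc[:, -1]
        self.dwz, self.dwr = dwz, dwr                     # center -> wall-face vector
        self.d_wall = dwz * nzv + dwr * nrv               # normal distance
        Sm = self.Sn_mag[:, -1]
        self.gdiff_wall = Sm ** 2 / (Sm * self.d_wall + 1e-300)
        self.gdiff_out = self.Az[-1, :] / (self.d_out + 1e-300)
        self.gdiff_in = self.Az[0, :] / (self.d_in + 1e-300)

    def _boundary_value(self, phi: np.ndarray, which: str, given) -> np.ndarray:
        """Face value on a boundary: Dirichlet array, mirrored interior value
        ("mirror", i.e. zero normal gradient) or linear extrapolation from the
        two nearest cell centers ("extrapolate")."""
        if isinstance(given, np.ndarray):
            return given
        if which == "inlet":
            p0, p1 = phi[0, :], phi[1, :]
            t = self.d_in / (self.zc[1, :] - self.zc[0, :])
        elif which == "outlet":
            p0, p1 = phi[-1, :], phi[-2, :]
            t = self.d_out / (self.zc[-1, :] - self.zc[-2, :])
        elif which == "wall":
            p0, p1 = phi[:, -1], phi[:, -2]
            t = self.d_wall / np.maximum(
                (self.rc[:, -1] - self.rc[:, -2]) * self.wall_nr
                + (self.zc[:, -1] - self.zc[:, -2]) * self.wall_nz, 1e-300)
        elif which == "axis":
            p0, p1 = phi[:, 0], phi[:, 1]
            t = self.rc[:, 0] / np.maximum(self.rc[:, 1] - self.rc[:, 0], 1e-300)
        else:  # pragma: no cover
            raise ValueError(which)
        if given == "mirror":
            return p0
        if given == "extrapolate":
            return p0 + (p0 - p1) * t
        raise ValueError(f"unknown boundary treatment {given!r}")

    # Green-Gauss cell gradient (planar z-r geometry; exact for linear fields)
    def gradient(self, phi: np.ndarray, phi_in="mirror", phi_wall="mirror",
                 phi_out="mirror", phi_axis="mirror") -> tuple[np.ndarray, np.ndarray]:
        nz, nr = self.nz, self.nr
        gz = np.zeros((nz, nr))
        gr = np.zeros((nz, nr))
        # internal axial faces (vertical): planar vector (dR, 0)
        f = 0.5 * (phi[1:, :] + phi[:-1, :])
        Ain = self.Pz_ax[1:-1, :]
        gz[:-1, :] += f * Ain
        gz[1:, :] -= f * Ain
        gz[0, :] -= self._boundary_value(phi, "inlet", phi_in) * self.Pz_ax[0, :]
        gz[-1, :] += self._boundary_value(phi, "outlet", phi_out) * self.Pz_ax[-1, :]
        # internal radial surfaces: planar vector (-dr, dz)
        f = 0.5 * (phi[:, 1:] + phi[:, :-1])
        gz[:, :-1] += f * self.Pn_z[:, 1:-1]
        gr[:, :-1] += f * self.Pn_r[:, 1:-1]
        gz[:, 1:] -= f * self.Pn_z[:, 1:-1]
        gr[:, 1:] -= f * self.Pn_r[:, 1:-1]
        fb = self._boundary_value(phi, "wall", phi_wall)
        gz[:, -1] += fb * self.Pn_z[:, -1]
        gr[:, -1] += fb * self.Pn_r[:, -1]
        fb = self._boundary_value(phi, "axis", phi_axis)
        gz[:, 0] -= fb * self.Pn_z[:, 0]
        gr[:, 0] -= fb * self.Pn_r[:, 0]
        return gz / self.A_cell, gr / self.A_cell


def _spsolve_structured(aP, aE, aW, aN, aS, b):
    """Solve the 5-point-stencil system (arrays shaped (nz, nr))."""
    nz, nr = aP.shape
    n = nz * nr
    main = aP.ravel()
    east = aE.ravel()[:-nr]
    west = aW.ravel()[nr:]
    north = aN.ravel()[:-1]
    south = aS.ravel()[1:]
    A = sp.diags([main, east, west, north, south], [0, nr, -nr, 1, -1], format="csc")
    return spla.spsolve(A, b.ravel()).reshape(nz, nr)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

def solve_steady_flow(mesh: AxiMesh, bcs: BoundaryConditions,
                      rheology: Rheology = CarreauYasudaParams(),
                      params: SolverParams = SolverParams(),
                      raise_on_nonconvergence: bool = False) -> FlowField:
    """SIMPLE iteration to a steady solution.

    Deterministic given inputs. Returns a :class:`FlowField`; if the
    residual targets are not met within ``max_iterations`` the field is
    returned with ``converged=False`` (or raises if requested). Residual
    growth beyond ``divergence_factor`` raises :class:`SolverDivergence`.
    """
    g = _Grid(mesh)
    nz, nr = g.nz, g.nr
    rho = params.density
    q_in = bcs.q_in

    r_in = float(mesh.r_nodes[0, -1])
    u_mean = q_in / (np.pi * r_in ** 2) if q_in > 0 else 0.0
    mu_ref = rheology.viscosity(np.array([max(u_mean / r_in, 1.0)]))
    reynolds = float(rho * u_mean * 2 * r_in / mu_ref[0]) if q_in > 0 else 0.0

    # trivial rest state
    if q_in == 0.0 and bcs.sink.flux == 0.0:
        zero = np.zeros((nz, nr))
        mu0 = np.full((nz, nr), float(rheology.viscosity(np.zeros(1))[0]))
        return FlowField(mesh=mesh, u=zero, v=zero.copy(), p=zero.copy(),
                         mu_eff=mu0, face_flux_z=np.zeros((nz + 1, nr)),
                         converged=True, reynolds=0.0)

    # boundary data
    u_in = bcs.inlet.u                       # (nr,)
    F_in = rho * u_in * g.Az[0, :]           # fixed inlet mass fluxes (+z)
    band = (g.wall_mid[:, 0] >= bcs.sink.z0) & (g.wall_mid[:, 0] <= bcs.sink.z1)
    v_sink = bcs.sink.normal_velocity
    F_wall = np.where(band, rho * v_sink * g.Sn_mag[:, -1], 0.0)  # outward
    # rescale so the discrete sink matches the continuous band flux exactly
    if F_wall.sum() > 0:
        F_wall *= (rho * bcs.sink.flux) / F_wall.sum()
    # wall velocity (suction band moves fluid outward at v_sink)
    uw_z = np.where(band, v_sink * g.wall_nz, 0.0)
    uw_r = np.where(band, v_sink * g.wall_nr, 0.0)

    # state
    u = np.full((nz, nr), 0.0)
    u += np.interp(g.rc[0, :], bcs.inlet.face_radii, u_in)[None, :]
    v = np.zeros((nz, nr))
    p = np.zeros((nz, nr))
    mu = np.full((nz, nr), float(rheology.viscosity(np.zeros(1))[0]))
    # face fluxes: mass (kg/s)
    Fz = np.zeros((nz + 1, nr))
    Fz[:] = F_in[None, :]
    Fr = np.zeros((nz, nr + 1))

    scale_mom = max(rho * q_in * max(u_mean, 1e-12), 1e-30)
    scale_mass = max(rho * q_in, 1e-30)

    history: list[dict] = []
    converged = False

    for it in range(params.max_iterations):
        # -- effective viscosity from the rate-of-deformation tensor
        duz, dur = g.gradient(u, phi_in=u_in, phi_wall=uw_z)
        dvz, dvr = g.gradient(v, phi_in=np.zeros(nr), phi_wall=uw_r,
                              phi_axis=np.zeros(nz))
        hoop = np.where(g.rc > 0, v / np.maximum(g.rc, 1e-300), 0.0)
        gdot = np.sqrt(2.0 * (duz ** 2 + dvr ** 2 + hoop ** 2) + (dur + dvz) ** 2)
        mu_new = rheology.viscosity(gdot)
        mu = mu + params.relax_mu * (mu_new - mu)

        # face viscosities (arithmetic)
        mu_e = 0.5 * (mu[1:, :] + mu[:-1, :])
        mu_n = 0.5 * (mu[:, 1:] + mu[:, :-1])
        mu_wall = mu[:, -1]

        # -- assemble shared convection/diffusion coefficients
        De = mu_e * g.gdiff_e                   # (nz-1, nr)
        Dn = mu_n * g.gdiff_n                   # (nz, nr-1)
        Fe = Fz[1:-1, :]                        # internal axial faces
        Fn = Fr[:, 1:-1]                        # internal radial surfaces

        aE = np.zeros((nz, nr)); aW = np.zeros((nz, nr))
        aN = np.zeros((nz, nr)); aS = np.zeros((nz, nr))
        aP = np.zeros((nz, nr))
        aE[:-1, :] = -(De + np.maximum(-Fe, 0.0))
        aW[1:, :] = -(De + np.maximum(Fe, 0.0))
        aP[:-1, :] += De + np.maximum(Fe, 0.0)
        aP[1:, :] += De + np.maximum(-Fe, 0.0)
        aN[:, :-1] = -(Dn + np.maximum(-Fn, 0.0))
        aS[:, 1:] = -(Dn + np.maximum(Fn, 0.0))
        aP[:, :-1] += Dn + np.maximum(Fn, 0.0)
        aP[:, 1:] += Dn + np.maximum(-Fn, 0.0)
        # inlet
        D_in = mu[0, :] * g.gdiff_in
        aP[0, :] += D_in                        # conv inflow handled via b
        # outlet: upwind outflow + no diffusion (zero gradient)
        aP[-1, :] += np.maximum(Fz[-1, :], 0.0)
        # wall
        D_wall = mu_wall * g.gdiff_wall
        aP[:, -1] += D_wall + np.maximum(F_wall, 0.0)

        # -- deferred corrections (non-orthogonal diffusion + transpose stress)
        w_no = params.relax_deferred if params.nonorth_correction else 0.0
        w_fs = params.relax_deferred if params.full_stress else 0.0

        def deferred(phi, gpz, gpr, other_gz, other_gr, comp):
            b = np.zeros((nz, nr))
            # internal axial faces: S=(A,0); d=(de_z, de_r)
            gzf = 0.5 * (gpz[1:, :] + gpz[:-1, :])
            grf = 0.5 * (gpr[1:, :] + gpr[:-1, :])
            Ai = g.Az[1:-1, :]
            cross = mu_e * (gzf * (Ai - g.gdiff_e * g.de_z) + grf * (-g.gdiff_e * g.de_r))
            # transpose term: mu * (d(comp-dir of other grads)) . S
            if comp == "u":
                tz = 0.5 * (duz[1:, :] + duz[:-1, :])
                tr = 0.5 * (dvz[1:, :] + dvz[:-1, :])
            else:
                tz = 0.5 * (dur[1:, :] + dur[:-1, :])
                tr = 0.5 * (dvr[1:, :] + dvr[:-1, :])
            trans = mu_e * (tz * Ai)  # radial component of S is zero
            flux = w_no * cross + w_fs * trans
            b[:-1, :] += flux
            b[1:, :] -= flux
            # internal radial surfaces
            gzf = 0.5 * (gpz[:, 1:] + gpz[:, :-1])
            grf = 0.5 * (gpr[:, 1:] + gpr[:, :-1])
            Snz, Snr = g.Sn_z[:, 1:-1], g.Sn_r[:, 1:-1]
            cross = mu_n * (gzf * (Snz - g.gdiff_n * g.dn_z) + grf * (Snr - g.gdiff_n * g.dn_r))
            if comp == "u":
                tz = 0.5 * (duz[:, 1:] + duz[:, :-1])
                tr = 0.5 * (dvz[:, 1:] + dvz[:, :-1])
            else:
                tz = 0.5 * (dur[:, 1:] + dur[:, :-1])
                tr = 0.5 * (dvr[:, 1:] + dvr[:, :-1])
            trans = mu_n * (tz * Snz + tr * Snr)
            flux = w_no * cross + w_fs * trans
            b[:, :-1] += flux
            b[:, 1:] -= flux
            # boundary faces carry the transpose stress too (one-sided
            # gradients); omitting them leaves spurious sources in the
            # boundary rows. Inlet/outlet faces are vertical: S = (A, 0).
            if comp == "u":
                tin, tout = duz[0, :], duz[-1, :]
                twz, twr = duz[:, -1], dvz[:, -1]
            else:
                tin, tout = dur[0, :], dur[-1, :]
                twz, twr = dur[:, -1], dvr[:, -1]
            gwz, gwr = gpz[:, -1], gpr[:, -1]  # component's own gradient
            b[0, :] -= w_fs * mu[0, :] * tin * g.Az[0, :]
            b[-1, :] += w_fs * mu[-1, :] * tout * g.Az[-1, :]
            # wall face: transpose + non-orthogonal correction
            Swz, Swr = g.Sn_z[:, -1], g.Sn_r[:, -1]
            trans_w = mu[:, -1] * (twz * Swz + twr * Swr)
            cross_w = mu[:, -1] * (gwz * (Swz - g.gdiff_wall * g.dwz)
                                   + gwr * (Swr - g.gdiff_wall * g.dwr))
            b[:, -1] += w_fs * trans_w + w_no * cross_w
            return b

        # pressure gradients (Green-Gauss, outlet gauge p_b = 0)
        gpz, gpr = g.gradient(p, phi_in="extrapolate", phi_wall="extrapolate",
                              phi_out=np.zeros(nr))

        # ---- u momentum
        b_u = -gpz * g.V
        b_u[0, :] += F_in * u_in + D_in * u_in          # inlet conv + diff
        b_u[:, -1] += D_wall * uw_z                      # wall (band suction)
        b_u += deferred(u, duz, dur, dvz, dvr, "u")
        aPu = aP.copy()
        # ---- v momentum (extra hoop sink, implicit)
        b_v = -gpr * g.V
        b_v[:, -1] += D_wall * uw_r
        b_v += deferred(v, dvz, dvr, duz, dur, "v")
        aPv = aP + 2.0 * mu * g.V / np.maximum(g.rc, 1e-300) ** 2

        # residuals of the unrelaxed equations
        def resid(aPx, bx, phi):
            r = bx - aPx * phi
            r[:-1, :] -= aE[:-1, :] * phi[1:, :]
            r[1:, :] -= aW[1:, :] * phi[:-1, :]
            r[:, :-1] -= aN[:, :-1] * phi[:, 1:]
            r[:, 1:] -= aS[:, 1:] * phi[:, :-1]
            return float(np.abs(r).sum())
        res_u = resid(aPu, b_u, u) / scale_mom
        res_v = resid(aPv, b_v, v) / scale_mom
        imbalance = Fz[1:, :] - Fz[:-1, :] + Fr[:, 1:] - Fr[:, :-1]
        res_m = float(np.abs(imbalance).sum()) / scale_mass
        history.append({"iter": it, "u": res_u, "v": res_v, "mass": res_m})
        if it > 0:
            r0 = history[0]
            if (not np.isfinite(res_u + res_v + res_m)
                    or res_u > params.divergence_factor * max(r0["u"], 1.0)):
                raise SolverDivergence(
                    f"residual growth at iteration {it}", history)
        if max(res_u, res_v, res_m) < params.tolerance and it > 1:
            converged = True
            break

        # implicit under-relaxation
        alpha = params.relax_u
        aPu_r = aPu / alpha
        aPv_r = aPv / alpha
        u_new = _spsolve_structured(aPu_r, aE, aW, aN, aS,
                                    b_u + (1 - alpha) / alpha * aPu * u)
        v_new = _spsolve_structured(aPv_r, aE, aW, aN, aS,
                                    b_v + (1 - alpha) / alpha * aPv * v)
        u, v = u_new, v_new

        # ---- Rhie-Chow face fluxes
        Du_cell = g.V / aPu_r
        Dv_cell = g.V / aPv_r
        # internal axial faces
        Df = 0.5 * (Du_cell[1:, :] + Du_cell[:-1, :])
        ubar = 0.5 * (u[1:, :] + u[:-1, :])
        gpz_f = 0.5 * (gpz[1:, :] + gpz[:-1, :])
        gpr_f = 0.5 * (gpr[1:, :] + gpr[:-1, :])
        pdiff = (p[1:, :] - p[:-1, :]) - (gpz_f * g.de_z + gpr_f * g.de_r)
        Fz[1:-1, :] = rho * (ubar * g.Az[1:-1, :] - Df * g.gdiff_e * pdiff)
        # outlet faces: extrapolated velocity
        Fz[-1, :] = rho * u[-1, :] * g.Az[-1, :]
        # internal radial surfaces
        Dfn = 0.5 * (Dv_cell[:, 1:] + Dv_cell[:, :-1])
        uf = 0.5 * (u[:, 1:] + u[:, :-1])
        vf = 0.5 * (v[:, 1:] + v[:, :-1])
        conv = uf * g.Sn_z[:, 1:-1] + vf * g.Sn_r[:, 1:-1]
        gpz_f = 0.5 * (gpz[:, 1:] + gpz[:, :-1])
        gpr_f = 0.5 * (gpr[:, 1:] + gpr[:, :-1])
        pdiff = (p[:, 1:] - p[:, :-1]) - (gpz_f * g.dn_z + gpr_f * g.dn_r)
        Fr[:, 1:-1] = rho * (conv - Dfn * g.gdiff_n * pdiff)
        Fr[:, -1] = F_wall
        Fr[:, 0] = 0.0

        # ---- pressure correction
        ae_p = np.zeros((nz, nr)); aw_p = np.zeros((nz, nr))
        an_p = np.zeros((nz, nr)); as_p = np.zeros((nz, nr))
        ap_p = np.zeros((nz, nr))
        ce = rho * Df * g.gdiff_e
        cn = rho * Dfn * g.gdiff_n
        ae_p[:-1, :] = -ce; aw_p[1:, :] = -ce
        ap_p[:-1, :] += ce; ap_p[1:, :] += ce
        an_p[:, :-1] = -cn; as_p[:, 1:] = -cn
        ap_p[:, :-1] += cn; ap_p[:, 1:] += cn
        # outlet: p' = 0 Dirichlet
        c_out = rho * Du_cell[-1, :] * g.gdiff_out
        ap_p[-1, :] += c_out
        rhs = -(Fz[1:, :] - Fz[:-1, :] + Fr[:, 1:] - Fr[:, :-1])
        pc = _spsolve_structured(ap_p, ae_p, aw_p, an_p, as_p, rhs)

        # corrections
        p = p + params.relax_p * pc
        Fz[1:-1, :] -= ce * (pc[1:, :] - pc[:-1, :])
        Fz[-1, :] -= c_out * (0.0 - pc[-1, :])
        Fr[:, 1:-1] -= cn * (pc[:, 1:] - pc[:, :-1])
        gpcz, gpcr = g.gradient(pc, phi_out=np.zeros(nr))
        u = u - Du_cell * gpcz
        v = v - Dv_cell * gpcr

    field_ = FlowField(mesh=mesh, u=u, v=v, p=p,
                       mu_eff=mu, face_flux_z=Fz / rho, converged=converged,
                       residual_history=history, reynolds=reynolds)
    if raise_on_nonconvergence and not converged:
        raise SolverDivergence(
            f"not converged after {len(history)} iterations "
            f"(last residuals {history[-1]})", history)
    return field_


# ---------------------------------------------------------------------------
# wall shear
# ---------------------------------------------------------------------------

def wall_shear(field: FlowField, rheology: Optional[Rheology] = None) -> np.ndarray:
    """Wall shear stress profile along the wall arc, Pa.

    tau_w = mu(gdot_w) |du_t/dn| at the wall, with the normal derivative
    from one-sided second-order differencing across the two wall-adjacent
    graded layers (no-slip value at the wall itself).
    """
    if not field.converged:
        raise ValueError("wall shear requires a converged field")
    g = _Grid(field.mesh)
    nzv, nrv = g.wall_nz, g.wall_nr
    tz, tr = nrv, -nzv  # tangent (downstream-oriented: nr>0 => tz>0)
    ut1 = field.u[:, -1] * tz + field.v[:, -1] * tr
    ut2 = field.u[:, -2] * tz + field.v[:, -2] * tr
    # normal distances of the two wall-adjacent cell centers
    y1 = (g.wall_mid[:, 0] - g.zc[:, -1]) * nzv + (g.wall_mid[:, 1] - g.rc[:, -1]) * nrv
    y2 = (g.wall_mid[:, 0] - g.zc[:, -2]) * nzv + (g.wall_mid[:, 1] - g.rc[:, -2]) * nrv
    dudn = (y2 ** 2 * ut1 - y1 ** 2 * ut2) / (y1 * y2 * (y2 - y1))
    gdot = np.abs(dudn)
    mu_w = field.mu_eff[:, -1] if rheology is None else rheology.viscosity(gdot)
    return np.abs(mu_w * dudn)
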