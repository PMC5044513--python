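"""Steady incompressible laminar flow with porous (Brinkman) regions.

The solver discretizes the stationary momentum/continuity pair

    -mu lap(u) + (mu/kappa) u + rho (u.grad) u + grad p = 0,   div u = 0

on the staggered marker-and-cell grid of :class:`perfusim.geometry.StructuredMesh`:
velocity components live on cell faces, pressure at cell centers, so discrete
continuity (and hence global mass conservation) holds to linear-solver
precision.  Porous regions contribute a Darcy drag mu/kappa on faces adjacent
to porous cells (Brinkman closure).  The convective term is lagged (Picard
iteration with under-relaxation, first-order upwind); at the creeping-to-
transitional Reynolds numbers of perfusion chambers (Re ~ 10) a handful of
iterations converge.

Boundary conditions: prescribed parabolic (or plug) inflow on inlet faces,
no-slip walls and gas membranes, and zero-stress outlets at reference
pressure 0 (which also pins the pressure level).

A separate axisymmetric solver handles fully developed pipe flow through the
cylindrical inlet ports, where the 2D planar section cannot represent the
circular cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ChamberGeometry, StructuredMesh
from .physics import FluidProperties, InvalidParameterError

__all__ = [
    "FlowBC",
    "FlowSolution",
    "ShearStressProfile",
    "FlowDiagnostics",
    "PipeFlowSolution",
    "solve_flow",
    "solve_pipe_flow",
    "wall_shear",
    "cell_level_shear",
    "flow_diagnostics",
    "poiseuille_profile",
]

LAMINAR_RE_LIMIT = 2000.0


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FlowBC:
    """Inlet flow rate (3D volumetric, m^3/s) and profile shape.

    The 3D rate is mapped to the planar 2D rate q = Q / extrusion_depth and
    split over the geometry's inlets per its ``inlet_split``.
    """

    flow_rate: float  # m^3/s
    profile: str = "parabolic"  # or "plug"

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise InvalidParameterError("flow rate must be non-negative")
        if self.profile not in ("parabolic", "plug"):
            raise InvalidParameterError("profile must be 'parabolic' or 'plug'")


@dataclass
class FlowSolution:
    mesh: StructuredMesh
    fluid: FluidProperties
    bc: FlowBC
    u: np.ndarray  # (ny, nx+1) x-velocity at vertical faces
    v: np.ndarray  # (ny+1, nx) y-velocity at horizontal faces
    p: np.ndarray  # (ny, nx) pressure, NaN in solid
    residuals: list  # Picard update norms
    inflow: float  # 2D rate m^2/s
    outflow: float

    @property
    def mass_error(self) -> float:
        if self.inflow == 0:
            return 0.0
        return abs(self.inflow - self.outflow) / abs(self.inflow)

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return uc, vc

    def speed(self) -> np.ndarray:
        uc, vc = self.cell_velocity()
        s = np.hypot(uc, vc)
        s[~self.mesh.fluid] = np.nan
        return s


@dataclass
class ShearStressProfile:
    boundary: str
    arclength: np.ndarray  # m, along the tagged boundary
    tau: np.ndarray  # Pa, magnitude

    def median(self) -> float:
        return float(np.median(self.tau)) if self.tau.size else 0.0


@dataclass
class FlowDiagnostics:
    reynolds_inlet: float
    peak_speed: float
    recirculation_fraction: float


def _inlet_profiles(mesh: StructuredMesh, geom: ChamberGeometry, bc: FlowBC) -> dict:
    """Per-inlet face velocities (signed, inward) matching each inlet's 2D rate."""
    q_total = bc.flow_rate / geom.extrusion_depth
    out = {}
    for tag, frac in geom.inlet_split.items():
        faces = mesh.boundary_faces.get(tag, np.empty((0, 4), int))
        if faces.shape[0] == 0:
            raise SolverError(f"no mesh faces tagged {tag!r}")
        q = q_total * frac
        axis = faces[0, 0]
        width = mesh.dy if axis == 0 else mesh.dx
        # faces of one inlet are contiguous; coordinate across the port
        coord = (faces[:, 1] if axis == 0 else faces[:, 2]).astype(float)
        xi = (coord - coord.min() + 0.5) / (coord.max() - coord.min() + 1.0)  # in (0,1)
        if bc.profile == "parabolic":
            shape = xi * (1.0 - xi)
        else:
            shape = np.ones_like(xi)
        shape_sum = shape.sum() * width
        speeds = np.zeros_like(shape) if q == 0 else q * shape / shape_sum
        out[tag] = (faces, speeds * faces[:, 3])  # signed inward
    return out


def _face_drag(mesh: StructuredMesh, mu: float) -> tuple[np.ndarray, np.ndarray]:
    """mu/kappa at u- and v-faces (average of adjacent cells' inverse permeability)."""
    inv_k = np.zeros((mesh.ny, mesh.nx))
    for name, porous in mesh.geometry.porous.items():
        inv_k[mesh.region_mask(name)] = 1.0 / porous.permeability
    drag_u = np.zeros((mesh.ny, mesh.nx + 1))
    drag_u[:, 1:-1] = 0.5 * (inv_k[:, :-1] + inv_k[:, 1:])
    drag_u[:, 0] = inv_k[:, 0]
    drag_u[:, -1] = inv_k[:, -1]
    drag_v = np.zeros((mesh.ny + 1, mesh.nx))
    drag_v[1:-1, :] = 0.5 * (inv_k[:-1, :] + inv_k[1:, :])
    drag_v[0, :] = inv_k[0, :]
    drag_v[-1, :] = inv_k[-1, :]
    return mu * drag_u, mu * drag_v


def solve_flow(
    mesh: StructuredMesh,
    fluid: FluidProperties,
    bc: FlowBC,
    max_picard: int = 60,
    tol: float = 1e-8,
    relax: float = 0.7,
    include_convection: bool = True,
) -> FlowSolution:
    """Solve the steady Stokes–Brinkman / Navier–Stokes system on ``mesh``."""
    geom = mesh.geometry
    re = _inlet_reynolds(geom, fluid, bc)
    if re > LAMINAR_RE_LIMIT:
        raise SolverError(f"inlet Reynolds {re:.0f} exceeds the laminar limit {LAMINAR_RE_LIMIT}")

    ny, nx, dx, dy = mesh.ny, mesh.nx, mesh.dx, mesh.dy
    mu = fluid.viscosity
    F = mesh.fluid

    # --- classify faces -------------------------------------------------
    # codes: -1 inactive/Dirichlet-0, >=0 unknown index; Dirichlet values kept
    Fpad = np.zeros((ny + 2, nx + 2), dtype=bool)
    Fpad[1:-1, 1:-1] = F

    u_dir = np.zeros((ny, nx + 1))  # Dirichlet values (inlets; walls are 0)
    v_dir = np.zeros((ny + 1, nx))
    u_isdir = np.ones((ny, nx + 1), dtype=bool)
    v_isdir = np.ones((ny + 1, nx), dtype=bool)
    u_isout = np.zeros((ny, nx + 1), dtype=bool)
    v_isout = np.zeros((ny + 1, nx), dtype=bool)

    both_u = Fpad[1:-1, :-1] & Fpad[1:-1, 1:]  # (ny, nx+1)
    u_isdir[both_u[:, :]] = False
    both_v = Fpad[:-1, 1:-1] & Fpad[1:, 1:-1]  # (ny+1, nx)
    v_isdir[both_v[:, :]] = False

    for tag, faces in mesh.boundary_faces.items():
        if not tag.startswith("outlet"):
            continue
        for axis, j, i, sign in faces:
            if axis == 0:
                u_isdir[j, i] = False
                u_isout[j, i] = True
            else:
                v_isdir[j, i] = False
                v_isout[j, i] = True
    for tag, (faces, speeds) in _inlet_profiles(mesh, geom, bc).items():
        for (axis, j, i, sign), s in zip(faces, speeds):
            if axis == 0:
                u_dir[j, i] = s
            else:
                v_dir[j, i] = s

    u_unknown = (~u_isdir)
    v_unknown = (~v_isdir)
    u_id = -np.ones((ny, nx + 1), dtype=int)
    v_id = -np.ones((ny + 1, nx), dtype=int)
    u_id[u_unknown] = np.arange(u_unknown.sum())
    nu_ = int(u_unknown.sum())
    v_id[v_unknown] = nu_ + np.arange(v_unknown.sum())
    nv_ = int(v_unknown.sum())
    p_id = -np.ones((ny, nx), dtype=int)
    p_id[F] = nu_ + nv_ + np.arange(F.sum())
    np_ = int(F.sum())
    ntot = nu_ + nv_ + np_

    drag_u, drag_v = _face_drag(mesh, mu)

    rows, cols, vals = [], [], []
    rhs = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def u_neighbor(r, j, i, coeff):
        """Add coefficient for u[j,i]; folds Dirichlet values into rhs and
        mirrors across tangential walls (no-slip) handled by caller."""
        if 0 <= j < ny and 0 <= i <= nx and u_id[j, i] >= 0:
            add(r, u_id[j, i], coeff)
        elif 0 <= j < ny and 0 <= i <= nx:
            rhs[r] -= coeff * u_dir[j, i]
        # out of range: caller must not request

    def v_neighbor(r, j, i, coeff):
        if 0 <= j <= ny and 0 <= i < nx and v_id[j, i] >= 0:
            add(r, v_id[j, i], coeff)
        elif 0 <= j <= ny and 0 <= i < nx:
            rhs[r] -= coeff * v_dir[j, i]

    # --- u-momentum -----------------------------------------------------
    for j in range(ny):
        for i in range(nx + 1):
            r = u_id[j, i]
            if r < 0:
                continue
            diag = drag_u[j, i]
            if u_isout[j, i]:
                # zero normal gradient ghost + outside pressure 0
                inor = i - 1 if i > 0 and Fpad[j + 1, i] else i + 1
                u_neighbor(r, j, inor, -mu / dx**2)
                diag += mu / dx**2
                pj = p_id[j, i - 1] if (i > 0 and Fpad[j + 1, i]) else p_id[j, i]
                sgn = 1.0 if (i > 0 and Fpad[j + 1, i]) else -1.0
                add(r, pj, -sgn / dx)  # (p_out - p_in)/dx with p_out = 0
            else:
                # x-neighbors (normal direction): both cells fluid here
                u_neighbor(r, j, i - 1, -mu / dx**2)
                u_neighbor(r, j, i + 1, -mu / dx**2)
                diag += 2.0 * mu / dx**2
                add(r, p_id[j, i], 1.0 / dx)
                add(r, p_id[j, i - 1], -1.0 / dx)
            # y-neighbors (tangential): quadratic no-slip ghost beyond walls
            for jj, step in ((j - 1, -1), (j + 1, +1)):
                if 0 <= jj < ny and (u_id[jj, i] >= 0 or u_dir[jj, i] != 0.0 or
                                     (Fpad[jj + 1, i] or Fpad[jj + 1, i + 1])):
                    # neighbor face exists next to at least one fluid cell
                    if u_id[jj, i] >= 0:
                        add(r, u_id[jj, i], -mu / dy**2)
                    else:
                        rhs[r] -= -mu / dy**2 * u_dir[jj, i]
                    diag += mu / dy**2
                else:
                    # wall at half a cell: ghost u_g = (u_opp - 6 u)/3 makes the
                    # viscous term exact for a parabola vanishing at the wall
                    jop = j - step
                    if 0 <= jop < ny and (u_id[jop, i] >= 0 or
                                          Fpad[jop + 1, i] or Fpad[jop + 1, i + 1]):
                        diag += 3.0 * mu / dy**2
                        if u_id[jop, i] >= 0:
                            add(r, u_id[jop, i], -mu / (3.0 * dy**2))
                        else:
                            rhs[r] -= -mu / (3.0 * dy**2) * u_dir[jop, i]
                    else:
                        diag += 2.0 * mu / dy**2  # single-row gap: mirror ghost
            add(r, r, diag)

    # --- v-momentum -----------------------------------------------------
    for j in range(ny + 1):
        for i in range(nx):
            r = v_id[j, i]
            if r < 0:
                continue
            diag = drag_v[j, i]
            if v_isout[j, i]:
                jnor = j - 1 if j > 0 and Fpad[j, i + 1] else j + 1
                v_neighbor(r, jnor, i, -mu / dy**2)
                diag += mu / dy**2
                pj = p_id[j - 1, i] if (j > 0 and Fpad[j, i + 1]) else p_id[j, i]
                sgn = 1.0 if (j > 0 and Fpad[j, i + 1]) else -1.0
                add(r, pj, -sgn / dy)
            else:
                v_neighbor(r, j - 1, i, -mu / dy**2)
                v_neighbor(r, j + 1, i, -mu / dy**2)
                diag += 2.0 * mu / dy**2
                add(r, p_id[j, i], 1.0 / dy)
                add(r, p_id[j - 1, i], -1.0 / dy)
            for ii, step in ((i - 1, -1), (i + 1, +1)):
                if 0 <= ii < nx and (v_id[j, ii] >= 0 or v_dir[j, ii] != 0.0 or
                                     (Fpad[j, ii + 1] or Fpad[j + 1, ii + 1])):
                    if v_id[j, ii] >= 0:
                        add(r, v_id[j, ii], -mu / dx**2)
                    else:
                        rhs[r] -= -mu / dx**2 * v_dir[j, ii]
                    diag += mu / dx**2
                else:
                    iop = i - step
                    if 0 <= iop < nx and (v_id[j, iop] >= 0 or
                                          Fpad[j, iop + 1] or Fpad[j + 1, iop + 1]):
                        diag += 3.0 * mu / dx**2
                        if v_id[j, iop] >= 0:
                            add(r, v_id[j, iop], -mu / (3.0 * dx**2))
                        else:
                            rhs[r] -= -mu / (3.0 * dx**2) * v_dir[j, iop]
                    else:
                        diag += 2.0 * mu / dx**2
            add(r, r, diag)

    # --- continuity ------------------------------------------------------
    for j in range(ny):
        for i in range(nx):
            r = p_id[j, i]
            if r < 0:
                continue
            for idx, sgn, over in (((j, i + 1), 1.0, dx), ((j, i), -1.0, dx)):
                jj, ii = idx
                if u_id[jj, ii] >= 0:
                    add(r, u_id[jj, ii], sgn / over)
                else:
                    rhs[r] -= sgn / over * u_dir[jj, ii]
            for idx, sgn, over in (((j + 1, i), 1.0, dy), ((j, i), -1.0, dy)):
                jj, ii = idx
                if v_id[jj, ii] >= 0:
                    add(r, v_id[jj, ii], sgn / over)
                else:
                    rhs[r] -= sgn / over * v_dir[jj, ii]

    A = sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(ntot, ntot)))
    lu = spla.splu(A)

    rho = fluid.density
    u = u_dir.copy()
    v = v_dir.copy()
    residuals: list = []
    sol_prev = None
    n_iter = max_picard if (include_convection and bc.flow_rate > 0) else 1
    for it in range(n_iter):
        b = rhs.copy()
        if include_convection and bc.flow_rate > 0 and it >= 0:
            conv_u, conv_v = _convection(u, v, dx, dy, u_isdir | u_isout, v_isdir | v_isout)
            uu = u_id >= 0
            b[u_id[uu]] -= rho * conv_u[uu]
            vv = v_id >= 0
            b[v_id[vv]] -= rho * conv_v[vv]
        sol = lu.solve(b)
        if sol_prev is not None:
            sol = relax * sol + (1.0 - relax) * sol_prev
        unew = u_dir.copy()
        unew[u_id >= 0] = sol[u_id[u_id >= 0]]
        vnew = v_dir.copy()
        vnew[v_id >= 0] = sol[v_id[v_id >= 0]]
        change = max(np.abs(unew - u).max(), np.abs(vnew - v).max())
        scale = max(np.abs(unew).max(), np.abs(vnew).max(), 1e-300)
        residuals.append(change / scale)
        u, v = unew, vnew
        sol_prev = sol
        if residuals[-1] < tol:
            break
    else:
        if include_convection and bc.flow_rate > 0 and residuals[-1] > 1e-4:
            raise SolverError(f"Picard iteration did not converge; history={residuals[-8:]}")

    p = np.full((ny, nx), np.nan)
    if sol_prev is not None:
        p[F] = sol_prev[p_id[F]]

    inflow, outflow = _boundary_rates(mesh, u, v)
    return FlowSolution(mesh=mesh, fluid=fluid, bc=bc, u=u, v=v, p=p,
                        residuals=residuals, inflow=inflow, outflow=outflow)


def _convection(u, v, dx, dy, u_fixed, v_fixed):
    """First-order upwind rho-free convection (u.grad)u at u- and v-faces."""
    ny, nxp = u.shape
    nx = nxp - 1
    conv_u = np.zeros_like(u)
    # v interpolated at u-face corners
    vpad = np.pad(v, ((0, 0), (1, 1)), mode="edge")
    v_at_u = 0.25 * (vpad[:-1, :-1] + vpad[:-1, 1:] + vpad[1:, :-1] + vpad[1:, 1:])  # (ny, nx+1)
    upx = np.pad(u, ((0, 0), (1, 1)), mode="edge")
    dudx_m = (upx[:, 1:-1] - upx[:, :-2]) / dx
    dudx_p = (upx[:, 2:] - upx[:, 1:-1]) / dx
    upy = np.pad(u, ((1, 1), (0, 0)), mode="constant")  # no-slip-ish ghost
    dudy_m = (upy[1:-1, :] - upy[:-2, :]) / dy
    dudy_p = (upy[2:, :] - upy[1:-1, :]) / dy
    conv_u = u * np.where(u > 0, dudx_m, dudx_p) + v_at_u * np.where(v_at_u > 0, dudy_m, dudy_p)
    conv_u[u_fixed] = 0.0

    conv_v = np.zeros_like(v)
    upad = np.pad(u, ((1, 1), (0, 0)), mode="edge")
    u_at_v = 0.25 * (upad[:-1, :-1] + upad[:-1, 1:] + upad[1:, :-1] + upad[1:, 1:])  # (ny+1, nx)
    vpy = np.pad(v, ((1, 1), (0, 0)), mode="edge")
    dvdy_m = (vpy[1:-1, :] - vpy[:-2, :]) / dy
    dvdy_p = (vpy[2:, :] - vpy[1:-1, :]) / dy
    vpxx = np.pad(v, ((0, 0), (1, 1)), mode="constant")
    dvdx_m = (vpxx[:, 1:-1] - vpxx[:, :-2]) / dx
    dvdx_p = (vpxx[:, 2:] - vpxx[:, 1:-1]) / dx
    conv_v = v * np.where(v > 0, dvdy_m, dvdy_p) + u_at_v * np.where(u_at_v > 0, dvdx_m, dvdx_p)
    conv_v[v_fixed] = 0.0
    return conv_u, conv_v


def _boundary_rates(mesh: StructuredMesh, u, v) -> tuple[float, float]:
    """2D inflow and outflow rates (m^2/s) through all boundary faces."""
    inflow = outflow = 0.0
    for tag, faces in mesh.boundary_faces.items():
        for axis, j, i, sign in faces:
            if axis == 0:
                q = u[j, i] * sign * mesh.dy
            else:
                q = v[j, i] * sign * mesh.dx
            if q > 0:
                inflow += q
            else:
                outflow += -q
    return inflow, outflow


def wall_shear(sol: FlowSolution, boundary: str, fluid: FluidProperties | None = None) -> ShearStressProfile:
    """Wall shear stress magnitude along a tagged boundary (Pa).

    Uses a one-sided quadratic fit of the tangential velocity through the
    no-slip wall (second order for parabolic profiles).
    """
    mesh = sol.mesh
    mu = (fluid or sol.fluid).viscosity
    faces = mesh.boundary_faces.get(boundary)
    if faces is None or faces.shape[0] == 0:
        raise InvalidParameterError(f"boundary {boundary!r} has no faces")
    uc, vc = sol.cell_velocity()
    taus, arcl = [], []
    for axis, j, i, sign in faces:
        if axis == 1:  # horizontal wall: tangential velocity is u
            j1 = j if sign > 0 else j - 1
            j2 = j1 + sign
            if not (0 <= j1 < mesh.ny):
                continue
            u1 = uc[j1, i]
            u2 = uc[j2, i] if 0 <= j2 < mesh.ny and mesh.fluid[j2, i] else u1
            h1 = 0.5 * mesh.dy
            tau = mu * abs(9.0 * u1 - u2) / (6.0 * h1)
            arcl.append((i + 0.5) * mesh.dx)
        else:  # vertical wall: tangential velocity is v
            i1 = i if sign > 0 else i - 1
            i2 = i1 + sign
            if not (0 <= i1 < mesh.nx):
                continue
            u1 = vc[j, i1]
            u2 = vc[j, i2] if 0 <= i2 < mesh.nx and mesh.fluid[j, i2] else u1
            h1 = 0.5 * mesh.dx
            tau = mu * abs(9.0 * u1 - u2) / (6.0 * h1)
            arcl.append((j + 0.5) * mesh.dy)
        taus.append(tau)
    order = np.argsort(arcl)
    return ShearStressProfile(boundary=boundary, arclength=np.asarray(arcl)[order],
                              tau=np.asarray(taus)[order])


def cell_level_shear(sol: FlowSolution, region: str) -> np.ndarray:
    """Pore-scale shear estimate inside a homogenized cell compartment (Pa).

    Within a porous region the resolved macroscopic gradients understate what
    cells experience; the standard homogenization estimate is
    tau = mu * u_interstitial / (d_pore / 2) with u_interstitial the
    superficial speed divided by porosity.  Returns the per-cell values.
    """
    mesh = sol.mesh
    porous = mesh.geometry.porous.get(region)
    if porous is None:
        raise InvalidParameterError(f"region {region!r} is not porous")
    mask = mesh.region_mask(region)
    speed = sol.speed()[mask]
    mu = sol.fluid.viscosity
    return mu * (speed / porous.porosity) / (porous.pore_size / 2.0)


def _inlet_reynolds(geom: ChamberGeometry, fluid: FluidProperties, bc: FlowBC) -> float:
    """Inlet Reynolds number from the 3D port diameter and mean pipe speed."""
    res = 0.0
    for tag, frac in geom.inlet_split.items():
        d = geom.port_ids[tag]
        area = np.pi / 4.0 * d**2
        vmean = bc.flow_rate * frac / area
        res = max(res, fluid.density * vmean * d / fluid.viscosity)
    return res


def flow_diagnostics(sol: FlowSolution, geom: ChamberGeometry | None = None) -> FlowDiagnostics:
    geom = geom or sol.mesh.geometry
    re = _inlet_reynolds(geom, sol.fluid, sol.bc)
    speed = sol.speed()
    peak = float(np.nanmax(speed)) if np.isfinite(speed).any() else 0.0
    return FlowDiagnostics(
        reynolds_inlet=re,
        peak_speed=peak,
        recirculation_fraction=_recirculation_fraction(sol),
    )


def _recirculation_fraction(sol: FlowSolution) -> float:
    """Fraction of fluid cells lying off the through-flow streamline band.

    The discrete streamfunction is integrated from the face fluxes (exact for
    a divergence-free MAC field); cells whose streamfunction falls outside
    the range spanned on the inlet faces are in recirculating or stagnant
    zones.
    """
    mesh = sol.mesh
    ny, nx = mesh.ny, mesh.nx
    psi = np.zeros((ny + 1, nx + 1))
    # integrate: psi(j+1,i) - psi(j,i) = u[j,i]*dy ; psi(j,i+1)-psi(j,i) = -v[j,i]*dx
    for j in range(ny):
        psi[j + 1, 0] = psi[j, 0] + sol.u[j, 0] * mesh.dy
    for i in range(nx):
        psi[:, i + 1] = psi[:, i] - sol.v[:, i] * mesh.dx
    rng = psi.max() - psi.min()
    if rng < 1e-30:
        return 0.0
    lo = hi = None
    for tag in mesh.geometry.inlet_split:
        for axis, j, i, sign in mesh.boundary_faces[tag]:
            if axis == 0:
                vals = (psi[j, i], psi[j + 1, i])
            else:
                vals = (psi[j, i], psi[j, i + 1])
            lo = min(vals) if lo is None else min(lo, *vals)
            hi = max(vals) if hi is None else max(hi, *vals)
    pc = 0.25 * (psi[:-1, :-1] + psi[1:, :-1] + psi[:-1, 1:] + psi[1:, 1:])
    tol = 1e-6 * rng
    outside = (pc < lo - tol) | (pc > hi + tol)
    n_fluid = mesh.fluid.sum()
    return float((outside & mesh.fluid).sum() / max(n_fluid, 1))


# ---------------------------------------------------------------------------
# analytic / axisymmetric oracles
# ---------------------------------------------------------------------------

def poiseuille_profile(y: np.ndarray, q2d: float, h: float) -> np.ndarray:
    """Fully developed planar channel profile u(y) = 6 (q/h) (y/h)(1-y/h)."""
    return 6.0 * q2d / h * (y / h) * (1.0 - y / h)


@dataclass
class PipeFlowSolution:
    radius: float
    flow_rate: float
    r: np.ndarray
    u: np.ndarray
    peak_speed: float
    mean_speed: float
    wall_shear: float  # Pa


def solve_pipe_flow(radius: float, flow_rate: float, fluid: FluidProperties | None = None,
                    n: int = 200) -> PipeFlowSolution:
    """Fully developed laminar flow in a circular pipe (axisymmetric).

    Solves mu (1/r) d/dr (r du/dr) = dP/dz with u(R) = 0 and du/dr(0) = 0 by
    a radial finite-volume scheme, scaling the pressure gradient to match the
    prescribed volumetric rate.  The continuum peak is 2 Q / (pi R^2).
    """
    if radius <= 0 or flow_rate < 0:
        raise InvalidParameterError("radius must be positive and flow rate non-negative")
    fluid = fluid or FluidProperties()
    mu = fluid.viscosity
    h = radius / n
    r = (np.arange(n) + 0.5) * h  # cell centers; u defined there
    faces = np.arange(1, n) * h
    # FV: (1/r_i h) [ r_{i+1/2} (u_{i+1}-u_i)/h - r_{i-1/2}(u_i-u_{i-1})/h ] = G/mu
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    for i in range(n):
        fm = faces[i - 1] if i > 0 else 0.0
        fp = faces[i] if i < n - 1 else radius
        if i > 0:
            lower[i - 1] += fm / h
            main[i] -= fm / h
        if i < n - 1:
            upper[i] += fp / h
            main[i] -= fp / h
        else:
            # ghost beyond wall: u(R)=0 -> u_ghost = -u_n (wall at face)
            main[i] -= 2.0 * fp / h
    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    b = r * h / mu  # unit pressure gradient G = 1
    u_unit = spla.spsolve(A, b)
    q_unit = float(np.sum(u_unit * 2.0 * np.pi * r * h))
    scale = 0.0 if q_unit == 0 else flow_rate / q_unit
    u = np.abs(u_unit * scale)
    area = np.pi * radius**2
    # one-sided quadratic through u(R)=0 and cell centers at R-h/2, R-3h/2
    dudr_wall = (9.0 * u[-1] - u[-2]) / (3.0 * h)
    return PipeFlowSolution(
        radius=radius,
        flow_rate=flow_rate,
        r=r,
        u=u,
        peak_speed=float(u[0]),
        mean_speed=flow_rate / area,
        wall_shear=abs(mu * dudr_wall),
    )
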