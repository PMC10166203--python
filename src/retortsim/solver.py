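"""Axisymmetric conjugate heat-transfer solver for in-can sterilization.

Solves the coupled energy / momentum / continuity system on the (r, z)
half-plane of a sealed cylindrical can heated through its wall by the
retort.  The product is a very viscous (mu ~ 30-80 Pa s) temperature-
dependent Newtonian fluid, so the flow is creeping natural convection:
buoyancy from the temperature dependence of density drives a slow
recirculation that moves the slowest-heating zone below the geometric
centre.  The headspace is a stagnant conductive vapor layer.

Discretization: finite volumes on a staggered (MAC) grid.

* energy — backward-Euler, conservative fluxes, harmonic-mean face
  conductivity, first-order upwind advection folded into the implicit
  matrix (unconditionally stable, discrete maximum principle);
* momentum — Stokes form (inertial advection negligible at Re << 1),
  implicit viscous terms (explicit stepping is hopeless at this
  viscosity), Boussinesq-type buoyancy: full rho(T) in the gravity source,
  constant reference density rho(T0) in the time term;
* continuity — enforced exactly by solving momentum and pressure as one
  coupled (saddle-point) system each step; creeping flow makes a split
  projection scheme inaccurate here, see `_stokes_step`.

Boundary conditions: the thin metal wall is thermally transparent, so the
bottom, side and top take the retort temperature directly (Dirichlet); a
Robin film-coefficient option and a fully insulated option exist for
sensitivity and conservation checks.  The axis is a symmetry line; the
puree free surface is a no-penetration, free-slip lid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import j0, j1, jn_zeros

from .geometry import AxiMesh
from .lethality import LethalityConfig, LethalityField, accumulate
from .properties import ThermoPhysicalProperties
from .schedule import RetortSchedule, retort_temperature

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "StateField",
    "SimulationResult",
    "initialize_state",
    "advance",
    "simulate",
    "analytic_cylinder_temperature",
    "SolverFailure",
    "InstabilityError",
]


class SolverFailure(RuntimeError):
    """The linear solves did not produce a usable state."""


class InstabilityError(SolverFailure):
    """Temperature left the maximum-principle bounds; reduce dt."""


@dataclass(frozen=True)
class HeadspaceProperties:
    """Constant properties of the stagnant vapor layer under the lid."""

    conductivity: float = 0.03   # W/(m K)
    density: float = 0.8         # kg/m^3
    specific_heat: float = 2000.0  # J/(kg K)


@dataclass
class SolverConfig:
    """Everything `advance`/`simulate` need besides the schedule.

    mode: "convection" (full buoyant flow) or "conduction" (u frozen at 0).
    boundary: "dirichlet" wall at the retort temperature, "robin" with an
    external film coefficient ``film_coefficient`` (W/m^2 K), or
    "insulated" (zero-flux; conservation tests).
    """

    mesh: AxiMesh
    properties: ThermoPhysicalProperties
    mode: str = "convection"
    dt: float = 1.0                    # s
    gravity: float = 9.81              # m/s^2
    initial_temperature: float = 341.15  # K
    snapshot_interval: float = 600.0   # s
    boundary: str = "dirichlet"
    film_coefficient: float | None = None  # W/(m^2 K), boundary == "robin"
    headspace: HeadspaceProperties = field(default_factory=HeadspaceProperties)
    max_dt_halvings: int = 6
    divergence_tol: float = 1e-6       # s^-1, volume-weighted RMS
    maximum_principle_tol: float = 0.5  # K
    seed: int | None = None  # reserved for stochastic extensions; unused
    _disc: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("conduction", "convection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.boundary not in ("dirichlet", "robin", "insulated"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.boundary == "robin" and not self.film_coefficient:
            raise ValueError("boundary='robin' requires film_coefficient")
        lo, hi = self.properties.valid_range
        if not (lo <= self.initial_temperature <= hi):
            raise ValueError(
                f"initial_temperature {self.initial_temperature} K outside the "
                f"property valid range [{lo}, {hi}] K"
            )


@dataclass
class StateField:
    """Fields on the staggered mesh at one instant.

    T lives at cell centres (nr, nz); u_r at radial faces (nr+1, n_puree);
    u_z at axial faces (nr, n_puree+1); P at puree cell centres.
    """

    T: np.ndarray
    u_r: np.ndarray
    u_z: np.ndarray
    P: np.ndarray
    time: float = 0.0

    def max_speed(self) -> float:
        return max(float(np.abs(self.u_r).max(initial=0.0)),
                   float(np.abs(self.u_z).max(initial=0.0)))


@dataclass
class SimulationResult:
    """Output of a full process simulation."""

    snapshots: list            # [StateField], snapshot_interval cadence
    snapshot_times: np.ndarray
    probe_positions: list      # [(r, z)]
    probe_times: np.ndarray    # (nt,)
    probe_temperatures: np.ndarray  # (n_probes, nt), K
    lethality: LethalityField
    realized_schedule: RetortSchedule
    fmin_history: np.ndarray   # (nt,), min accumulated F over puree, min
    speed_history: np.ndarray  # (nt,), max |u|, m/s
    config: SolverConfig


# ----------------------------------------------------------------------
# discretization operators (cached per config)
# ----------------------------------------------------------------------

class _Discretization:
    """Precomputed mesh arrays shared by the energy and Stokes assemblies."""

    def __init__(self, config: SolverConfig):
        mesh = config.mesh
        self.mesh = mesh
        self.nzp = mesh.n_puree_rows
        self.dr, self.dz = mesh.dr, mesh.dz
        self.r_f = mesh.r_edges          # (nr+1,)
        self.r_c = mesh.r_centers        # (nr,)
        # face areas
        self.A_r = 2.0 * np.pi * self.r_f * self.dz   # (nr+1,) radial faces
        self.A_z = 2.0 * np.pi * self.r_c * self.dr   # (nr,) axial faces
        self.vol = mesh.cell_volumes
        self.rho_ref = config.properties.density(config.initial_temperature)

    # -- divergence of the staggered velocity field over puree cells -----
    def divergence(self, u_r: np.ndarray, u_z: np.ndarray) -> np.ndarray:
        nzp = self.nzp
        rad = (self.r_f[1:, None] * u_r[1:, :] - self.r_f[:-1, None] * u_r[:-1, :])
        rad /= self.r_c[:, None] * self.dr
        ax = (u_z[:, 1:] - u_z[:, :-1]) / self.dz
        return rad + ax  # (nr, nzp)


def _get_disc(config: SolverConfig) -> _Discretization:
    if config._disc is None or config._disc.mesh is not config.mesh:
        config._disc = _Discretization(config)
    return config._disc


# ----------------------------------------------------------------------
# material fields
# ----------------------------------------------------------------------

def _material_fields(config: SolverConfig, T: np.ndarray):
    """Per-cell conductivity and volumetric heat capacity (puree + vapor)."""
    mesh, hs = config.mesh, config.headspace
    puree = mesh.puree_mask
    Tp = np.clip(T, *config.properties.valid_range)  # guard polynomial tails
    k = np.where(puree, np.polyval(config.properties.conductivity_coeffs, Tp),
                 hs.conductivity)
    rhocp = np.where(
        puree,
        np.polyval(config.properties.density_coeffs, Tp) * config.properties.specific_heat,
        hs.density * hs.specific_heat,
    )
    return k, rhocp


# ----------------------------------------------------------------------
# energy step: implicit conduction + implicit upwind advection
# ----------------------------------------------------------------------

def _energy_step(disc, config, T_old, u_r, u_z, T_wall, dt):
    mesh = config.mesh
    nr, nz = mesh.nr, mesh.nz
    nzp = disc.nzp
    dr, dz = disc.dr, disc.dz
    k, rhocp = _material_fields(config, T_old)
    C = rhocp * disc.vol / dt  # (nr, nz)

    def harm(a, b):
        return 2.0 * a * b / (a + b)

    idx = np.arange(nr * nz).reshape(nr, nz)
    rows, cols, vals = [], [], []
    b = (C * T_old).ravel().copy()
    diag = C.ravel().copy()

    def couple(ia, ja, ib, jb, G):
        """Symmetric conductive coupling G between cells a and b."""
        a = idx[ia, ja].ravel(); bb = idx[ib, jb].ravel(); g = G.ravel()
        rows.extend(a); cols.extend(bb); vals.extend(-g)
        rows.extend(bb); cols.extend(a); vals.extend(-g)
        np.add.at(diag, a, g)
        np.add.at(diag, bb, g)

    # interior radial faces i = 1..nr-1
    if nr > 1:
        G = disc.A_r[1:nr, None] * harm(k[:-1, :], k[1:, :]) / dr
        couple(np.arange(0, nr - 1)[:, None], np.arange(nz)[None, :],
               np.arange(1, nr)[:, None], np.arange(nz)[None, :], G)
    # interior axial faces j = 1..nz-1
    G = disc.A_z[:, None] * harm(k[:, :-1], k[:, 1:]) / dz
    couple(np.arange(nr)[:, None], np.arange(0, nz - 1)[None, :],
           np.arange(nr)[:, None], np.arange(1, nz)[None, :], G)

    # boundary faces (wall r=R; bottom z=0; top z=H)
    if config.boundary != "insulated":
        if config.boundary == "robin":
            h = config.film_coefficient
            Gw = disc.A_r[nr] / (dr / (2.0 * k[nr - 1, :]) + 1.0 / h)
            Gb = disc.A_z / (dz / (2.0 * k[:, 0]) + 1.0 / h)
            Gt = disc.A_z / (dz / (2.0 * k[:, nz - 1]) + 1.0 / h)
        else:
            Gw = disc.A_r[nr] * k[nr - 1, :] / (dr / 2.0)
            Gb = disc.A_z * k[:, 0] / (dz / 2.0)
            Gt = disc.A_z * k[:, nz - 1] / (dz / 2.0)
        for cells, G in (
            (idx[nr - 1, :], Gw), (idx[:, 0], Gb), (idx[:, nz - 1], Gt)
        ):
            np.add.at(diag, cells, G)
            np.add.at(b, cells, G * T_wall)

    # Advection through puree faces, conservative: implicit first-order
    # upwind plus an explicit flux-limited (van Leer TVD) deferred
    # correction evaluated at T_old.  At this grid the cell Peclet number
    # exceeds 1, so plain upwind would add numerical diffusion comparable
    # to the physical conductivity; the limited correction recovers
    # second-order accuracy in smooth regions while the implicit upwind
    # matrix keeps the M-matrix (boundedness) property.
    if config.mode == "convection":

        def limiter(theta):
            return (theta + np.abs(theta)) / (1.0 + np.abs(theta))

        def face_advection(Q, L, R, rcpL, rcpR, T_upup_p, T_upup_m, has_uu_p, has_uu_m):
            """One family of faces: Q > 0 flows L -> R, Q < 0 flows R -> L."""
            Qp = np.maximum(Q, 0.0); Qm = np.minimum(Q, 0.0)
            tL = T_old.ravel()[L.ravel()].reshape(L.shape)
            tR = T_old.ravel()[R.ravel()].reshape(R.shape)
            # implicit upwind part
            np.add.at(diag, L.ravel(), (rcpL * Qp).ravel())
            rows.extend(L.ravel()); cols.extend(R.ravel())
            vals.extend((rcpL * Qm).ravel())
            np.add.at(diag, R.ravel(), (-rcpR * Qm).ravel())
            rows.extend(R.ravel()); cols.extend(L.ravel())
            vals.extend((-rcpR * Qp).ravel())
            # explicit limited anti-diffusive correction (deferred)
            dT = tR - tL
            eps = 1e-30
            theta_p = np.where(has_uu_p, (tL - T_upup_p) / (dT + eps), 0.0)
            theta_m = np.where(has_uu_m, (tR - T_upup_m) / (-dT + eps), 0.0)
            corr = (Qp * 0.5 * limiter(theta_p) * dT
                    + Qm * 0.5 * limiter(theta_m) * (-dT))
            np.add.at(b, L.ravel(), (-rcpL * corr).ravel())
            np.add.at(b, R.ravel(), (rcpR * corr).ravel())

        # radial faces i=1..nr-1 within puree rows
        Qr = u_r[1:nr, :nzp] * disc.A_r[1:nr, None]       # (nr-1, nzp)
        L = idx[0:nr - 1, 0:nzp]; R = idx[1:nr, 0:nzp]
        Tuu_p = np.zeros_like(Qr); Tuu_m = np.zeros_like(Qr)
        Tuu_p[1:, :] = T_old[0:nr - 2, 0:nzp]   # far-upwind for Q > 0
        Tuu_m[:-1, :] = T_old[2:nr, 0:nzp]      # far-upwind for Q < 0
        has_p = np.zeros_like(Qr, dtype=bool); has_p[1:, :] = True
        has_m = np.zeros_like(Qr, dtype=bool); has_m[:-1, :] = True
        face_advection(Qr, L, R, rhocp[0:nr - 1, 0:nzp], rhocp[1:nr, 0:nzp],
                       Tuu_p, Tuu_m, has_p, has_m)
        # axial faces j=1..nzp-1
        Qz = u_z[:, 1:nzp] * disc.A_z[:, None]            # (nr, nzp-1)
        L = idx[:, 0:nzp - 1]; R = idx[:, 1:nzp]
        Tuu_p = np.zeros_like(Qz); Tuu_m = np.zeros_like(Qz)
        Tuu_p[:, 1:] = T_old[:, 0:nzp - 2]
        Tuu_m[:, :-1] = T_old[:, 2:nzp]
        has_p = np.zeros_like(Qz, dtype=bool); has_p[:, 1:] = True
        has_m = np.zeros_like(Qz, dtype=bool); has_m[:, :-1] = True
        face_advection(Qz, L, R, rhocp[:, 0:nzp - 1], rhocp[:, 1:nzp],
                       Tuu_p, Tuu_m, has_p, has_m)

    n = nr * nz
    rows.extend(range(n)); cols.extend(range(n)); vals.extend(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    T_new = spla.spsolve(A, b)
    if not np.all(np.isfinite(T_new)):
        raise SolverFailure("energy solve produced non-finite temperatures")
    return T_new.reshape(nr, nz)


# ----------------------------------------------------------------------
# coupled Stokes solve (momentum + continuity)
# ----------------------------------------------------------------------

def _viscosity_cells(config, T):
    """Viscosity at puree cell centres (nr, nzp)."""
    nzp = config.mesh.n_puree_rows
    Tp = np.clip(T[:, :nzp], *config.properties.valid_range)
    return np.polyval(config.properties.viscosity_coeffs, Tp)


def _stokes_step(disc, config, state, dt):
    """One implicit step of the creeping-flow momentum + continuity system.

    The velocity and pressure are solved together as a saddle-point system
    (momentum rows with the discrete pressure gradient, continuity rows
    with the discrete divergence).  A projection split is avoided on
    purpose: at mu ~ 30 Pa s the viscous operator dominates the time term
    so completely that split schemes leave O(1e-4 m/s) spurious currents
    in hydrostatically balanced states; the coupled solve keeps a uniform
    buoyancy field exactly quiescent and the divergence at solver
    precision.  One pressure value is pinned (its continuity row is
    implied by the others in a closed container).
    """
    mesh = config.mesh
    nr, nzp = mesh.nr, disc.nzp
    dr, dz = disc.dr, disc.dz
    r_f, r_c = disc.r_f, disc.r_c
    rho_ref = disc.rho_ref
    mu = _viscosity_cells(config, state.T)           # (nr, nzp)
    Tp = np.clip(state.T[:, :nzp], *config.properties.valid_range)
    rho = np.polyval(config.properties.density_coeffs, Tp)

    nur = (nr - 1) * nzp
    nuz = nr * (nzp - 1)
    ncell = nr * nzp
    off_uz = nur
    off_p = nur + nuz
    ntot = off_p + ncell
    ridx = lambda i, j: (i - 1) * nzp + j            # u_r face (i=1..nr-1)
    zidx = lambda i, j: off_uz + i * (nzp - 1) + (j - 1)  # u_z face (j=1..nzp-1)
    pidx = lambda i, j: off_p + i * nzp + j

    rows, cols, vals = [], [], []
    b = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    def add_arr(r, c, v):
        rows.extend(np.atleast_1d(r)); cols.extend(np.atleast_1d(c))
        vals.extend(np.atleast_1d(v))

    # ---- u_r momentum rows (i = 1..nr-1, j = 0..nzp-1) -----------------
    # corner viscosities at (r_f[i], z_f[j]) for i=1..nr-1, j=1..nzp-1
    mu_cor = 0.25 * (mu[:-1, :-1] + mu[1:, :-1] + mu[:-1, 1:] + mu[1:, 1:])
    diag_r = np.full((nr - 1, nzp), rho_ref / dt)
    b[:nur] = (rho_ref / dt) * state.u_r[1:nr, :].ravel()
    for i in range(1, nr):
        cR = r_c[i] * mu[i, :] / (r_f[i] * dr * dr)
        cL = r_c[i - 1] * mu[i - 1, :] / (r_f[i] * dr * dr)
        m = ridx(i, np.arange(nzp))
        if i + 1 < nr:
            add_arr(m, ridx(i + 1, np.arange(nzp)), -cR)
        diag_r[i - 1, :] += cR        # wall/axis neighbours are zero
        if i - 1 >= 1:
            add_arr(m, ridx(i - 1, np.arange(nzp)), -cL)
        diag_r[i - 1, :] += cL
        mu_f = 0.5 * (mu[i - 1, :] + mu[i, :])
        diag_r[i - 1, :] += mu_f / (r_f[i] ** 2)   # geometric sink
        for j in range(nzp):
            mm = ridx(i, j)
            if j + 1 < nzp:
                cU = mu_cor[i - 1, j] / (dz * dz)
                add(mm, ridx(i, j + 1), -cU)
                diag_r[i - 1, j] += cU
            # j+1 == nzp: free-slip at the puree surface -> zero flux
            if j - 1 >= 0:
                cD = mu_cor[i - 1, j - 1] / (dz * dz)
                add(mm, ridx(i, j - 1), -cD)
                diag_r[i - 1, j] += cD
            else:
                mu_w = 0.5 * (mu[i - 1, 0] + mu[i, 0])
                diag_r[i - 1, j] += 2.0 * mu_w / (dz * dz)  # bottom no-slip
            # pressure gradient (p[i,j] - p[i-1,j]) / dr
            add(mm, pidx(i, j), 1.0 / dr)
            add(mm, pidx(i - 1, j), -1.0 / dr)
    add_arr(np.arange(nur), np.arange(nur), diag_r.ravel())

    # ---- u_z momentum rows (i = 0..nr-1, j = 1..nzp-1) -----------------
    diag_z = np.full((nr, nzp - 1), rho_ref / dt)
    b[off_uz:off_p] = (rho_ref / dt) * state.u_z[:, 1:nzp].ravel()
    rho_face = 0.5 * (rho[:, :-1] + rho[:, 1:])      # (nr, nzp-1)
    b[off_uz:off_p] += ((rho_ref - rho_face) * config.gravity).ravel()
    for i in range(nr):
        m = zidx(i, np.arange(1, nzp))
        if i + 1 < nr:
            cR = r_f[i + 1] * mu_cor[i, :] / (r_c[i] * dr * dr)
            add_arr(m, zidx(i + 1, np.arange(1, nzp)), -cR)
            diag_z[i, :] += cR
        else:
            mu_w = 0.5 * (mu[nr - 1, :-1] + mu[nr - 1, 1:])
            diag_z[i, :] += 2.0 * r_f[nr] * mu_w / (r_c[i] * dr * dr)  # wall
        if i >= 1:
            cL = r_f[i] * mu_cor[i - 1, :] / (r_c[i] * dr * dr)
            add_arr(m, zidx(i - 1, np.arange(1, nzp)), -cL)
            diag_z[i, :] += cL
        # i == 0: axis, zero radial flux (r_f[0] = 0)
        for j in range(1, nzp):
            mm = zidx(i, j)
            cU = mu[i, j] / (dz * dz)
            cD = mu[i, j - 1] / (dz * dz)
            if j + 1 < nzp:
                add(mm, zidx(i, j + 1), -cU)
            diag_z[i, j - 1] += cU    # j+1 == nzp: u_z = 0 at surface
            if j - 1 >= 1:
                add(mm, zidx(i, j - 1), -cD)
            diag_z[i, j - 1] += cD    # j-1 == 0: u_z = 0 at bottom
            # pressure gradient (p[i,j] - p[i,j-1]) / dz
            add(mm, pidx(i, j), 1.0 / dz)
            add(mm, pidx(i, j - 1), -1.0 / dz)
    add_arr(np.arange(off_uz, off_p), np.arange(off_uz, off_p), diag_z.ravel())

    # ---- continuity rows (one per cell; cell (0,0) pinned to p = 0) ----
    for i in range(nr):
        for j in range(nzp):
            row = pidx(i, j)
            if i == 0 and j == 0:
                add(row, pidx(0, 0), 1.0)
                continue
            cr = 1.0 / (r_c[i] * dr)
            if i + 1 < nr:
                add(row, ridx(i + 1, j), r_f[i + 1] * cr)
            if i >= 1:
                add(row, ridx(i, j), -r_f[i] * cr)
            if j + 1 < nzp:
                add(row, zidx(i, j + 1), 1.0 / dz)
            if j >= 1:
                add(row, zidx(i, j), -1.0 / dz)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(ntot, ntot))
    x = spla.spsolve(sp.csc_matrix(A), b)
    if not np.all(np.isfinite(x)):
        raise SolverFailure("Stokes solve produced non-finite velocities")
    u_r = np.zeros((nr + 1, nzp))
    u_r[1:nr, :] = x[:nur].reshape(nr - 1, nzp)
    u_z = np.zeros((nr, nzp + 1))
    u_z[:, 1:nzp] = x[off_uz:off_p].reshape(nr, nzp - 1)
    P = x[off_p:].reshape(nr, nzp)
    return u_r, u_z, P


def _divergence_rms(disc, u_r, u_z) -> float:
    """Volume-weighted RMS of the discrete divergence, s^-1."""
    div = disc.divergence(u_r, u_z)
    w = disc.vol[:, :disc.nzp]
    return float(np.sqrt((w * div ** 2).sum() / w.sum()))


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def initialize_state(config: SolverConfig) -> StateField:
    """Uniform initial temperature, quiescent fluid, reference pressure."""
    mesh = config.mesh
    nzp = mesh.n_puree_rows
    return StateField(
        T=np.full((mesh.nr, mesh.nz), config.initial_temperature),
        u_r=np.zeros((mesh.nr + 1, nzp)),
        u_z=np.zeros((mesh.nr, nzp + 1)),
        P=np.zeros((mesh.nr, nzp)),
        time=0.0,
    )


def _bounds(config: SolverConfig, schedule: RetortSchedule):
    lo = min(config.initial_temperature, schedule.cooling_water_temperature)
    hi = max(config.initial_temperature, schedule.max_hold_temperature)
    tol = config.maximum_principle_tol
    return lo - tol, hi + tol


def advance(state: StateField, schedule: RetortSchedule,
            config: SolverConfig, dt: float | None = None) -> StateField:
    """Advance one time step of length ``dt`` (default ``config.dt``).

    On a maximum-principle violation the step is retried with halved
    sub-steps, up to ``config.max_dt_halvings`` times.
    """
    dt = config.dt if dt is None else dt
    disc = _get_disc(config)
    lo, hi = _bounds(config, schedule)
    for halvings in range(config.max_dt_halvings + 1):
        sub = dt / (2 ** halvings)
        nsub = 2 ** halvings
        s = state
        ok = True
        for _ in range(nsub):
            s = _advance_once(s, schedule, config, disc, sub)
            if s.T.min() < lo or s.T.max() > hi:
                ok = False
                break
        if ok:
            if halvings:
                logger.warning("step at t=%.0f s needed dt/%d", state.time, nsub)
            return s
    raise InstabilityError(
        f"temperature left [{lo:.2f}, {hi:.2f}] K at t = {state.time:.1f} s "
        f"even at dt/{2 ** config.max_dt_halvings}; reduce dt"
    )


def _advance_once(state, schedule, config, disc, dt):
    t_new = state.time + dt
    T_wall = retort_temperature(schedule, t_new)
    if config.mode == "convection":
        u_r, u_z, P = _stokes_step(disc, config, state, dt)
        rms = _divergence_rms(disc, u_r, u_z)
        if rms > config.divergence_tol:
            raise SolverFailure(
                f"divergence RMS {rms:.3e} s^-1 exceeds tolerance "
                f"{config.divergence_tol:.1e} after the Stokes solve "
                f"(t = {t_new:.1f} s)"
            )
    else:
        u_r, u_z, P = state.u_r, state.u_z, state.P
    T = _energy_step(disc, config, state.T, u_r, u_z, T_wall, dt)
    return StateField(T=T, u_r=u_r, u_z=u_z, P=P, time=t_new)


def interp_temperature(mesh: AxiMesh, T: np.ndarray, r: float, z: float) -> float:
    """Bilinear interpolation of a cell-centre field, clamped at the rim.

    Clamping at the axis is consistent with the symmetry condition
    dT/dr = 0 at r = 0 (error O(dr^2))."""
    rc, zc = mesh.r_centers, mesh.z_centers
    i = int(np.clip(np.searchsorted(rc, r) - 1, 0, mesh.nr - 2))
    j = int(np.clip(np.searchsorted(zc, z) - 1, 0, mesh.nz - 2))
    fr = np.clip((r - rc[i]) / (rc[i + 1] - rc[i]), 0.0, 1.0)
    fz = np.clip((z - zc[j]) / (zc[j + 1] - zc[j]), 0.0, 1.0)
    return float(
        (1 - fr) * (1 - fz) * T[i, j] + fr * (1 - fz) * T[i + 1, j]
        + (1 - fr) * fz * T[i, j + 1] + fr * fz * T[i + 1, j + 1]
    )


def simulate(
    config: SolverConfig,
    schedule: RetortSchedule,
    probes: list[tuple[float, float]] | None = None,
    lethality_config: LethalityConfig | None = None,
) -> SimulationResult:
    """Run the full process from t = 0 to the end of the schedule.

    Lethality is co-accumulated every step (trapezoid in time); probe
    temperature series are recorded every step, snapshots at the
    ``snapshot_interval`` cadence.
    """
    mesh = config.mesh
    probes = probes or []
    for (r, z) in probes:
        if not (0.0 <= r <= mesh.geometry.inner_radius
                and 0.0 <= z <= mesh.puree_surface_z):
            raise ValueError(f"probe ({r}, {z}) outside the puree region")
    leth_cfg = lethality_config or LethalityConfig()
    leth = LethalityField(mesh, leth_cfg)
    state = initialize_state(config)

    total = schedule.total_duration
    n_steps = int(math.ceil(total / config.dt - 1e-9))
    times = [0.0]
    probe_T = [[interp_temperature(mesh, state.T, r, z) for (r, z) in probes]]
    fmin_hist = [0.0]
    speed_hist = [0.0]
    snapshots = [state]
    snap_times = [0.0]
    next_snap = config.snapshot_interval

    for step in range(n_steps):
        dt = min(config.dt, total - state.time)
        if dt <= 0:
            break
        T_prev = state.T
        state = advance(state, schedule, config, dt=dt)
        accumulate(leth, state.T, dt, leth_cfg, T_field_prev=T_prev)
        times.append(state.time)
        probe_T.append([interp_temperature(mesh, state.T, r, z) for (r, z) in probes])
        fmin_hist.append(leth.F_min)
        speed_hist.append(state.max_speed())
        if state.time + 1e-9 >= next_snap or step == n_steps - 1:
            snapshots.append(state)
            snap_times.append(state.time)
            while next_snap <= state.time + 1e-9:
                next_snap += config.snapshot_interval

    return SimulationResult(
        snapshots=snapshots,
        snapshot_times=np.asarray(snap_times),
        probe_positions=list(probes),
        probe_times=np.asarray(times),
        probe_temperatures=(np.asarray(probe_T).T if probes
                            else np.zeros((0, len(times)))),
        lethality=leth,
        realized_schedule=schedule,
        fmin_history=np.asarray(fmin_hist),
        speed_history=np.asarray(speed_hist),
        config=config,
    )


# ----------------------------------------------------------------------
# analytic conduction oracle
# ----------------------------------------------------------------------

def analytic_cylinder_temperature(
    r: float, z: float, t: float, alpha: float,
    T_wall: float, T_0: float, R: float, H: float, n_terms: int = 30,
) -> float:
    """Series solution for conduction in a finite cylinder.

    Uniform initial temperature ``T_0``, all surfaces stepped to ``T_wall``
    at t = 0, constant diffusivity ``alpha``: the product of the infinite-
    cylinder Fourier-Bessel series and the slab sine series,

        theta = sum_n 2/(lam_n J1(lam_n)) J0(lam_n r/R) exp(-lam_n^2 Fo_R)
              * sum_m(odd) 4/(m pi) sin(m pi z / H) exp(-(m pi)^2 Fo_H)

    with theta the unaccomplished temperature ratio.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if n_terms < 1:
        raise ValueError("need at least one series term")
    if t == 0.0:
        return T_0
    lam = jn_zeros(0, n_terms)
    radial = (2.0 / (lam * j1(lam))) * j0(lam * r / R) \
        * np.exp(-lam ** 2 * alpha * t / R ** 2)
    m = np.arange(1, 2 * n_terms, 2)  # odd terms only
    axial = (4.0 / (m * np.pi)) * np.sin(m * np.pi * z / H) \
        * np.exp(-(m * np.pi / H) ** 2 * alpha * t)
    theta = radial.sum() * axial.sum()
    return float(T_wall + (T_0 - T_wall) * theta)
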