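"""Surface Navier--Stokes--Cahn--Hilliard dynamics of a two-phase vesicle.

Model
-----
On the fixed sphere the Lo surface fraction ``c`` (order parameter), the
tangential mixture velocity ``u``, the surface pressure ``p`` and the
chemical potential ``mu`` obey

    rho(c) (du/dt + (grad u) u) - div(2 eta(c) Es(u)) + grad p
        = Fe + F_cap + F_chem - gamma u,          div u = 0,
    dc/dt + div(c u) = div(M grad mu),            mu = f0'(c) - eps^2 Lap c,

with the double well ``f0 = 1/4 c^2 (1-c)^2``, degenerate mobility
``M = D c(1-c)``, convex mixtures ``rho(c), eta(c)`` of the phase densities
and surface viscosities, the capillary (line-tension) force
``F_cap = lambda mu grad c`` (the tensor form ``-lambda eps^2
div(grad c ⊗ grad c)`` differs from it by a gradient absorbed into the
pressure), the chemical momentum flux ``F_chem = M theta^2 (grad u) grad mu``
with ``theta^2 = d rho/dc``, and an ambient friction ``gamma u`` modelling
momentum exchange with the surrounding water (the only mechanism that damps
the rigid-rotation mode of a free sphere, for which Es(u) = 0).

Scaling
-------
The solver works in model units: lengths in vesicle radii R, time in units
of the diffusive scale ``tau = R^2 / D``.  All coefficients are converted
from SI once, in :class:`ModelParams.nondim`.  The interface width used by
a simulation is floored at a fixed multiple of the mesh spacing so the
interface profile stays resolved on coarse meshes; the line-tension scale
``lambda`` is calibrated from the physical line tension via the standard
double-well constant ``∫_0^1 sqrt(2 f0) dc = sqrt(2)/12`` at the width
actually used.  Because an absolute time calibration for the experimental
system is not available, times are reported in model units and cross-composition
ratios are the primary observables; the electrostatic force carries one
global dimensionless coupling shared by all compositions (ratio-preserving).

Discretization
--------------
P1 fields on the triangulated sphere (see :mod:`suvphase.geometry`), lumped
mass, operator splitting per time step: a Cahn--Hilliard step (backward
Euler with Newton on ``f0'`` by default, or a linearly stabilized IMEX
variant; advection explicit) followed by a momentum step (implicit in viscosity,
friction and pressure; explicit convection and forces) solved in a
per-vertex tangent basis, which enforces exact pointwise tangentiality.
The Cahn--Hilliard step conserves ``∫ c ds`` to direct-solver round-off by
construction.  An adaptive controller grows and shrinks the time step based
on the order-parameter increment, a CFL bound, and overshoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .composition import MembraneComposition, builtin_composition
from .electrostatics import ElectrostaticEnv, ZETA_SUV_MV, force_density
from .geometry import SphereMesh, SurfaceOperators, build_sphere_mesh, rotation_to_pole

__all__ = [
    "ModelParams",
    "NondimGroups",
    "SimState",
    "TimeController",
    "StepMetrics",
    "SimConfig",
    "Trajectory",
    "NSCHSolver",
    "double_well",
    "double_well_prime",
    "mobility",
    "chemical_potential",
    "initial_state",
    "lattice_mixture",
    "total_free_energy",
    "adapt_dt",
    "simulate",
    "molar_area_density_to_si",
    "SolverDivergence",
]

AVOGADRO = 6.02214076e23
#: calibration constant of the quartic double well: ∫_0^1 sqrt(2 f0) dc
DOUBLE_WELL_CONSTANT = np.sqrt(2.0) / 12.0


class SolverDivergence(RuntimeError):
    """Raised when the adaptive stepper cannot advance at the minimum step."""


def molar_area_density_to_si(value_kg_per_mol_a2: float) -> float:
    """Convert a molar area density in kg/(mol Å^2) to kg/m^2.

    The tabulated phase densities are molar masses per area; dividing by
    Avogadro's number and the Å^2 -> m^2 factor yields a surface mass
    density.
    """
    return value_kg_per_mol_a2 / AVOGADRO / 1e-20


# per composition: rho_lo, rho_ld [kg/(mol Å^2)], eta_lo, eta_ld
# [1e-8 Pa s m] (midpoints of the tabulated ranges), line tension [pN]
# (midpoint).  The homogeneous membrane takes the Ld-phase values.
_PHASE_PROPS = {
    "PAT1": (1401.0, 1172.0, 3.25, 0.3, 1.3),
    "PAT2": (1401.0, 1172.0, 3.065, 0.3, 1.4),
    "PAT3": (1435.0, 1172.0, 6.5, 0.3, 1.5),
    "Homo": (1172.0, 1172.0, 0.3, 0.3, 1.3),
}


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the two-phase membrane model (SI units).

    ``rho_*`` are surface mass densities (kg/m^2), ``eta_*`` surface
    viscosities (Pa s m), ``sigma_gamma`` the line tension (N),
    ``eps_interface`` the phase-boundary width (m), ``D`` the mobility
    scale (m^2/s), ``bulk_friction`` the ambient (membrane--water) drag
    coefficient (Pa s/m), and ``electro_coupling`` the global dimensionless
    calibration of the electrostatic forcing (shared by all compositions,
    hence ratio-preserving; chosen once so the forced dynamics stay in the
    creeping, compact-patch regime).
    """

    rho_lo: float
    rho_ld: float
    eta_lo: float
    eta_ld: float
    sigma_gamma: float
    eps_interface: float = 1.0e-9
    D: float = 1.0e-9                # 1e-5 cm^2/s
    suv_radius: float = 60.0e-9
    bulk_friction: float = 2.0e6
    electro_coupling: float = 3.5e-3

    def __post_init__(self) -> None:
        for name in ("rho_lo", "rho_ld", "eta_lo", "eta_ld", "sigma_gamma",
                     "eps_interface", "D", "suv_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_composition(cls, name: str, **overrides) -> "ModelParams":
        """Tabulated phase properties for Homo/PAT1/PAT2/PAT3 (range midpoints)."""
        try:
            rlo, rld, elo, eld, sg = _PHASE_PROPS[name]
        except KeyError:
            raise KeyError(f"no tabulated phase properties for {name!r}") from None
        base = dict(
            rho_lo=molar_area_density_to_si(rlo),
            rho_ld=molar_area_density_to_si(rld),
            eta_lo=elo * 1e-8,
            eta_ld=eld * 1e-8,
            sigma_gamma=sg * 1e-12,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def theta_sq(self) -> float:
        """d rho / dc = rho_lo - rho_ld (kg/m^2)."""
        return self.rho_lo - self.rho_ld

    @property
    def time_unit_s(self) -> float:
        """One model time unit, tau = R^2 / D, in seconds."""
        return self.suv_radius**2 / self.D

    def nondim(self, eps_hat: float) -> "NondimGroups":
        """Dimensionless groups at interface width ``eps_hat`` (radii)."""
        rho0 = self.rho_ld
        R, D = self.suv_radius, self.D
        lam_si = self.sigma_gamma / (DOUBLE_WELL_CONSTANT * eps_hat * R)
        return NondimGroups(
            rho_lo=self.rho_lo / rho0,
            rho_ld=self.rho_ld / rho0,
            eta_lo=self.eta_lo / (rho0 * D),
            eta_ld=self.eta_ld / (rho0 * D),
            theta_sq=self.theta_sq / rho0,
            lam=lam_si * R**2 / (rho0 * D**2),
            gamma=self.bulk_friction * R**2 / (rho0 * D),
            force_scale=self.electro_coupling * R**3 / (rho0 * D**2),
            eps_hat=eps_hat,
            time_unit_s=self.time_unit_s,
        )


@dataclass(frozen=True)
class NondimGroups:
    """Model-unit coefficients (length in R, time in R^2/D)."""

    rho_lo: float
    rho_ld: float
    eta_lo: float
    eta_ld: float
    theta_sq: float
    lam: float
    gamma: float
    force_scale: float   # multiplies an SI force density (N/m^2)
    eps_hat: float
    time_unit_s: float

    def rho(self, c: np.ndarray) -> np.ndarray:
        return self.rho_lo * c + self.rho_ld * (1.0 - c)

    def eta(self, c: np.ndarray) -> np.ndarray:
        return self.eta_lo * c + self.eta_ld * (1.0 - c)


# --------------------------------------------------------------------------
# pointwise thermodynamic functions
# --------------------------------------------------------------------------

def double_well(c):
    """Double-well potential f0(c) = 1/4 c^2 (1-c)^2 (wells at 0 and 1)."""
    c = np.asarray(c, dtype=float)
    return 0.25 * c**2 * (1.0 - c) ** 2


def double_well_prime(c):
    """f0'(c) = 1/2 c (1-c)(1-2c)."""
    c = np.asarray(c, dtype=float)
    return 0.5 * c * (1.0 - c) * (1.0 - 2.0 * c)


def mobility(c, D_hat: float = 1.0):
    """Degenerate mobility M = D c(1-c), clipped to [0, 1] first (so any
    overshoot contributes zero mobility)."""
    cc = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
    return D_hat * cc * (1.0 - cc)


def _mobility_reflected(c, D_hat: float = 1.0):
    """Reflected extension |c| |1-c| of the degenerate mobility.

    Inside [0, 1] it coincides with :func:`mobility`.  The continuum model
    never leaves [0, 1]; how the mobility is extended to numerical
    overshoot is a discretization choice.  The clipped extension freezes
    overshoot spikes (zero mobility exactly where excess material sits),
    which destabilizes under-resolved interfaces; the reflected extension
    lets them relax and keeps overshoot at the percent level.  The solver
    uses this extension internally.
    """
    c = np.asarray(c, dtype=float)
    return D_hat * np.abs(c) * np.abs(1.0 - c)


def chemical_potential(ops: SurfaceOperators, eps_hat: float, c: np.ndarray) -> np.ndarray:
    """mu = f0'(c) - eps^2 Lap c on the mesh of ``ops``."""
    mu = double_well_prime(c)
    if eps_hat != 0.0:
        mu = mu - eps_hat**2 * ops.laplace_beltrami(c)
    return mu


# --------------------------------------------------------------------------
# state, controller
# --------------------------------------------------------------------------

@dataclass
class SimState:
    """Order parameter, velocity, pressure and chemical potential at a time."""

    time: float
    c: np.ndarray          # (N,)
    u: np.ndarray          # (N, 3), tangential
    p: np.ndarray          # (N,)
    mu: np.ndarray         # (N,)

    def copy(self) -> "SimState":
        return SimState(self.time, self.c.copy(), self.u.copy(),
                        self.p.copy(), self.mu.copy())


def initial_state(mesh: SphereMesh, a_D: float, seed: int) -> SimState:
    """Bernoulli(a_D) per-vertex order parameter, fluid at rest.

    The initial membrane is a homogeneous mixture at the molecular scale:
    each vertex is assigned pure Lo (c=1) with probability ``a_D``, pure Ld
    otherwise, independently; reproducible under a fixed seed.
    """
    if not 0.0 < a_D < 1.0:
        raise ValueError(f"a_D must lie strictly in (0, 1), got {a_D}")
    rng = np.random.default_rng(seed)
    c = (rng.random(mesh.n_vertices) < a_D).astype(float)
    n = mesh.n_vertices
    return SimState(0.0, c, np.zeros((n, 3)), np.zeros(n), np.zeros(n))


def lattice_mixture(mesh: SphereMesh, a_D: float, seed: int,
                    noise_level: int) -> SimState:
    """Binary mixture drawn on a coarse icosahedral lattice, fluid at rest.

    A scaled-down stand-in for finer-grained mixing noise: exactly
    ``round(a_D * n_cells)`` cells of a level-``noise_level`` icosahedral
    lattice are assigned pure Lo at uniformly random positions and mapped
    to the simulation mesh by nearest cell centre.  Compared with
    vertexwise Bernoulli sampling this preserves the *amplitude* of
    composition fluctuations at a fixed physical scale as the mesh is
    coarsened, so compositions outside the spinodal band (a_D < 0.21)
    retain supercritical nuclei; the realized area fraction equals a_D up
    to cell-area granularity.
    """
    if not 0.0 < a_D < 1.0:
        raise ValueError(f"a_D must lie strictly in (0, 1), got {a_D}")
    from scipy.spatial import cKDTree

    coarse = build_sphere_mesh(noise_level, radius=1.0)
    rng = np.random.default_rng(seed)
    k = int(round(a_D * coarse.n_vertices))
    k = min(max(k, 1), coarse.n_vertices - 1)
    vals = np.zeros(coarse.n_vertices)
    vals[rng.choice(coarse.n_vertices, size=k, replace=False)] = 1.0
    _, idx = cKDTree(coarse.vertices).query(mesh.vertices / mesh.radius)
    c = vals[idx]
    n = mesh.n_vertices
    return SimState(0.0, c, np.zeros((n, 3)), np.zeros(n), np.zeros(n))


@dataclass
class StepMetrics:
    """Per-step quantities driving the adaptive controller."""

    dc_max: float = 0.0
    cfl: float = 0.0
    overshoot: float = 0.0
    rejected: bool = False


@dataclass
class TimeController:
    """Adaptive time-step controller, clamped to [dt_min, dt_max].

    The defaults span the adaptive range 4e-6 up to 4 time units: the
    step shrinks on rejection or large order-parameter
    increments and grows geometrically while increments stay small.
    """

    dt_min: float = 4.0e-6
    dt_max: float = 4.0
    dt0: float = 1.0e-5
    growth: float = 1.3
    shrink: float = 0.5
    tol_dc: float = 0.05
    cfl_max: float = 0.5
    overshoot_max: float = 0.05
    max_rejects: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt0 <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt0 <= dt_max")

    def accepts(self, m: StepMetrics) -> bool:
        return (m.dc_max <= self.tol_dc and m.cfl <= self.cfl_max
                and m.overshoot <= self.overshoot_max)

    def next_dt(self, dt: float, m: StepMetrics,
                allow_growth: bool = True) -> float:
        if m.rejected or not self.accepts(m):
            dt = dt * self.shrink
        elif allow_growth and m.dc_max < 0.5 * self.tol_dc \
                and m.cfl < 0.5 * self.cfl_max:
            dt = dt * self.growth
        return float(np.clip(dt, self.dt_min, self.dt_max))


def adapt_dt(controller: TimeController, dt: float, metrics: StepMetrics) -> float:
    """Next step size given the controller and the last step's metrics."""
    return controller.next_dt(dt, metrics)


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

class NSCHSolver:
    """Operator-split NSCH integrator on a unit-radius sphere mesh.

    Parameters
    ----------
    mesh:
        A :class:`SphereMesh`; the solver treats its radius as the length
        unit (use radius 1 meshes).
    params:
        Physical :class:`ModelParams`.
    eps_hat:
        Interface width in units of the radius.  Default: the physical
        width ``eps_interface / suv_radius`` floored at ``eps_floor_factor``
        mean mesh edges, so the profile is resolved at any refinement.
    """

    def __init__(self, mesh: SphereMesh, params: ModelParams,
                 eps_hat: float | None = None, eps_floor_factor: float = 1.2,
                 include_inertia: bool = True, ch_scheme: str = "newton",
                 stab_S: float = 1.0, pressure_stab: float = 0.2):
        self.mesh = mesh
        self.ops = SurfaceOperators(mesh)
        self.params = params
        h = mesh.mean_edge_length / mesh.radius
        self.h_mean = h
        if eps_hat is None:
            eps_hat = max(params.eps_interface / params.suv_radius,
                          eps_floor_factor * h)
        self.nd = params.nondim(eps_hat)
        self.include_inertia = include_inertia
        if ch_scheme not in ("stabilized", "newton"):
            raise ValueError("ch_scheme must be 'stabilized' or 'newton'")
        self.ch_scheme = ch_scheme
        self.stab_S = stab_S

        m = mesh
        self.Mv = m.vertex_areas
        self.K = self.ops.stiffness
        self._Mv_mat = sp.diags(self.Mv)
        # face quantities
        self.Af = m.face_areas
        self.g = m.hat_gradients          # (F,3,3)
        self.P = m.face_projectors        # (F,3,3)
        self.Pg = np.einsum("fab,fib->fia", self.P, self.g)  # P g_i
        self.tri = m.triangles
        self._build_momentum_structures(pressure_stab)

    # -- Cahn--Hilliard ----------------------------------------------------

    def ch_step(self, state: SimState, dt: float,
                newton_tol: float = 1e-11, newton_maxit: int = 12
                ) -> tuple[np.ndarray, np.ndarray]:
        """One Cahn--Hilliard step; returns (c_new, mu_new).

        Advances ``dc/dt + div(c u) = div(M grad mu)`` with mobility and
        advection lagged at ``c^n`` and the ``eps^2 Lap`` part of the
        chemical potential implicit.  Two treatments of ``f0'`` are
        available:

        * ``"newton"`` (default): backward Euler with ``mu = f0'(c^{n+1})
          - eps^2 Lap c^{n+1}`` solved by Newton iteration — the per-step
          energy minimizer of the gradient flow, strictly dissipative for
          any dt.
        * ``"stabilized"``: the classic linearly implicit scheme
          ``mu = f0'(c^n) + S (c^{n+1} - c^n) - eps^2 Lap c^{n+1}``, energy
          stable for ``S >= max|f0''|/2`` (~0.33 over the admissible
          range; default S=1).  One linear solve per step, cheaper but
          with a larger splitting error at large dt.

        Either way the discrete mass-balance row contains only telescoping
        fluxes, so ``∫ c ds`` is conserved to solver round-off.

        Raises :class:`SolverDivergence` when the solve fails; the
        adaptive controller treats that as a step rejection.
        """
        m, nd = self.mesh, self.nd
        c0, u = state.c, state.u
        N = m.n_vertices
        mob_f = _mobility_reflected(m.face_mean(c0))
        # K_M = G^T diag(A_f M_f) G, assembled like the stiffness
        local = np.einsum("fik,fjk,f->fij", self.g, self.g, self.Af * mob_f)
        rows = np.repeat(self.tri, 3, axis=1).ravel()
        cols = np.tile(self.tri, (1, 3)).ravel()
        K_M = sp.coo_matrix((local.ravel(), (rows, cols)), shape=(N, N)).tocsr()

        # explicit advection, weak form: Adv_i = -sum_f A_f (c u)_f . grad phi_i
        cu_f = m.face_mean(c0)[:, None] * m.face_mean(u)
        contrib = np.einsum("fk,fik,f->fi", cu_f, self.g, self.Af)
        adv = np.zeros(N)
        np.add.at(adv, self.tri.ravel(), contrib.ravel())
        adv = -adv

        eps2 = nd.eps_hat**2
        Mv, MvA = self._Mv_mat, self.Mv

        if self.ch_scheme == "stabilized":
            S = self.stab_S
            sys = sp.bmat(
                [[Mv / dt, K_M], [-(S * Mv + eps2 * self.K), Mv]], format="csc")
            rhs = np.concatenate([
                MvA * c0 / dt - adv,
                MvA * (double_well_prime(c0) - S * c0),
            ])
            try:
                sol = spla.splu(sys, permc_spec="MMD_ATA").solve(rhs)
            except Exception as exc:  # pragma: no cover - backend failure
                raise SolverDivergence(f"Cahn-Hilliard solve failed: {exc}") from exc
            if not np.all(np.isfinite(sol)):
                raise SolverDivergence(
                    "Cahn-Hilliard solve produced non-finite values")
            return sol[:N], sol[N:]

        c = c0.copy()
        mu = double_well_prime(c) - eps2 * self.ops.laplace_beltrami(c)
        for _ in range(newton_maxit):
            r1 = MvA * (c - c0) / dt + adv + K_M @ mu
            r2 = MvA * (mu - double_well_prime(c)) - eps2 * (self.K @ c)
            # residuals in natural units: c-increment and mu
            res = max(np.abs(dt * r1 / MvA).max(), np.abs(r2 / MvA).max())
            if res < newton_tol:
                break
            J21 = -(sp.diags(MvA * (0.5 - 3.0 * c + 3.0 * c**2)) + eps2 * self.K)
            sys = sp.bmat([[Mv / dt, K_M], [J21, Mv]], format="csc")
            try:
                delta = spla.splu(sys, permc_spec="MMD_ATA").solve(
                    -np.concatenate([r1, r2]))
            except Exception as exc:  # pragma: no cover - backend failure
                raise SolverDivergence(f"Cahn-Hilliard solve failed: {exc}") from exc
            if not np.all(np.isfinite(delta)):
                raise SolverDivergence("Cahn-Hilliard Newton produced non-finite values")
            c = c + delta[:N]
            mu = mu + delta[N:]
        else:
            raise SolverDivergence(
                f"Cahn-Hilliard Newton stalled (residual {res:.2e})")
        return c, mu

    # -- momentum ----------------------------------------------------------

    def _build_momentum_structures(self, pressure_stab: float) -> None:
        m = self.mesh
        N, F = m.n_vertices, m.n_faces
        # strain-rate basis tensors Eb[f,i,k] = sym(P e_k g_i^T P)
        Eb = 0.5 * (
            np.einsum("fak,fib->fikab", self.P, self.Pg)
            + np.einsum("fia,fbk->fikab", self.Pg, self.P)
        )
        tri = self.tri
        # reduce to per-vertex tangent coordinates right away: local blocks
        # are 6x6 per face and the assembled matrix lives on 2N dofs
        t1, t2 = m.tangent_basis()
        tb = np.stack([t1, t2], axis=2)            # (N, 3, 2)
        tb_f = tb[tri]                             # (F, 3verts, 3, 2)
        Eb_t = np.einsum("fikab,fikq->fiqab", Eb, tb_f)
        self._visc_local = np.einsum("fiqab,fjrab->fiqjr", Eb_t, Eb_t)
        dof2 = (2 * tri[:, :, None] + np.arange(2)[None, None, :])  # (F,3,2)
        self._visc_rows = np.broadcast_to(
            dof2[:, :, :, None, None], (F, 3, 2, 3, 2)).ravel()
        self._visc_cols = np.broadcast_to(
            dof2[:, None, None, :, :], (F, 3, 2, 3, 2)).ravel()

        # pressure coupling in tangent dofs: b(v, q) = -sum_f A_f q_f div_f(v)
        div_t = np.einsum("f,fik,fikq->fiq", self.Af / 3.0, self.Pg, tb_f)
        rows = np.broadcast_to(tri[:, :, None, None], (F, 3, 3, 2)).ravel()
        cols = np.broadcast_to(dof2[:, None, :, :], (F, 3, 3, 2)).ravel()
        data = np.broadcast_to(-div_t[:, None, :, :], (F, 3, 3, 2)).ravel()
        self._Bt = sp.coo_matrix((data, (rows, cols)), shape=(N, 2 * N)).tocsr()

        # tangent basis transform T (3N x 2N), for moving loads/solutions
        ridx = np.arange(N)
        r = np.concatenate([3 * np.repeat(ridx, 3) + np.tile(np.arange(3), N)] * 2)
        ccol = np.concatenate([2 * np.repeat(ridx, 3),
                               2 * np.repeat(ridx, 3) + 1])
        vals = np.concatenate([t1.ravel(), t2.ravel()])
        self._T = sp.coo_matrix((vals, (r, ccol)), shape=(3 * N, 2 * N)).tocsr()
        self._t1, self._t2 = t1, t2

        # pressure stabilization (Brezzi--Pitkaranta) + mean-value pinning
        eta_ref = 2.0 * max(self.nd.eta_ld, 1e-12)
        delta = pressure_stab * self.h_mean**2 / eta_ref
        self._Sp_base = (delta * self.K + 1e-9 * self._Mv_mat).tocsr()

    def momentum_step(self, state: SimState, dt: float,
                      Fe: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """One semi-implicit momentum step; returns (u_new, p_new).

        Implicit in viscosity, ambient friction, inertia and pressure;
        explicit convection, capillary force, chemical momentum flux and
        the supplied electrostatic force density ``Fe`` (model units,
        tangential, per vertex).  The velocity is expanded in per-vertex
        tangent bases, so the result is pointwise tangential by
        construction; incompressibility holds weakly (stabilized P1--P1).
        """
        m, nd, ops = self.mesh, self.nd, self.ops
        N = m.n_vertices
        c, u = state.c, state.u
        c_f = m.face_mean(c)
        eta_f = nd.eta(np.clip(c_f, 0.0, 1.0))
        rho_v = nd.rho(np.clip(c, 0.0, 1.0))

        data = (self._visc_local
                * (2.0 * eta_f * self.Af)[:, None, None, None, None]).ravel()
        At = sp.coo_matrix((data, (self._visc_rows, self._visc_cols)),
                           shape=(2 * N, 2 * N)).tocsr()
        diag_v = nd.gamma * self.Mv
        if self.include_inertia:
            diag_v = diag_v + rho_v * self.Mv / dt
        At = At + sp.diags(np.repeat(diag_v, 2))

        # explicit loads -------------------------------------------------
        rhs = np.zeros((N, 3))
        if self.include_inertia:
            rhs += (rho_v * self.Mv / dt)[:, None] * u
            # convection  rho (grad u) u, face-wise
            gu = ops.velocity_gradient(u)
            u_f = m.face_mean(u)
            conv = np.einsum("fab,fb->fa", gu, u_f)
            conv *= (nd.rho(np.clip(c_f, 0, 1)) * self.Af / 3.0)[:, None]
            np.subtract.at(rhs, self.tri.ravel(),
                           np.repeat(conv, 3, axis=0).reshape(-1, 3))
        # capillary force  lambda mu grad c
        mu_f = m.face_mean(state.mu)
        gc = ops.gradient(c)
        cap = (nd.lam * mu_f * self.Af / 3.0)[:, None] * gc
        np.add.at(rhs, self.tri.ravel(), np.repeat(cap, 3, axis=0).reshape(-1, 3))
        # chemical momentum flux  M theta^2 (grad u) grad mu
        if nd.theta_sq != 0.0:
            gu = ops.velocity_gradient(u)
            gmu = ops.gradient(state.mu)
            chem = np.einsum("fab,fb->fa", gu, gmu)
            chem *= (_mobility_reflected(c_f) * nd.theta_sq * self.Af / 3.0)[:, None]
            np.add.at(rhs, self.tri.ravel(),
                      np.repeat(chem, 3, axis=0).reshape(-1, 3))
        if Fe is not None:
            rhs += self.Mv[:, None] * Fe

        T = self._T
        Bt = self._Bt
        sys = sp.bmat([[At, Bt.T], [Bt, -self._Sp_base]], format="csc")
        rhs_full = np.concatenate([T.T @ rhs.ravel(), np.zeros(N)])
        try:
            sol = spla.splu(sys, permc_spec="MMD_ATA").solve(rhs_full)
        except Exception as exc:  # pragma: no cover
            raise SolverDivergence(f"momentum solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverDivergence("momentum solve produced non-finite values")
        w = sol[: 2 * N]
        p = sol[2 * N:]
        u_new = (T @ w).reshape(N, 3)
        return u_new, p

    # -- diagnostics -------------------------------------------------------

    def free_energy(self, c: np.ndarray) -> float:
        """Total mixture free energy  lambda ∫ [f0(c) + eps^2/2 |grad c|^2] ds."""
        m, nd = self.mesh, self.nd
        bulk = m.integrate(double_well(c))
        gc = self.ops.gradient(c)
        grad = 0.5 * nd.eps_hat**2 * float(
            self.Af @ np.einsum("fk,fk->f", gc, gc))
        return nd.lam * (bulk + grad)

    def mass(self, c: np.ndarray) -> float:
        return self.mesh.integrate(c)

    def electrostatic_force(self, comp: MembraneComposition,
                            env: ElectrostaticEnv, c: np.ndarray) -> np.ndarray:
        """Tangential electrostatic force density in model units."""
        f_si = force_density(env, comp, c, self.mesh)
        return self.nd.force_scale * f_si

    # -- full step ---------------------------------------------------------

    def step(self, state: SimState, dt: float,
             Fe: np.ndarray | None = None) -> tuple[SimState, StepMetrics]:
        """Attempt one operator-split step (CH then momentum) of size dt."""
        c_new, mu_new = self.ch_step(state, dt)
        trial = SimState(state.time + dt, c_new, state.u, state.p, mu_new)
        u_new, p_new = self.momentum_step(trial, dt, Fe=Fe)
        trial.u, trial.p = u_new, p_new
        umax = float(np.linalg.norm(u_new, axis=1).max())
        metrics = StepMetrics(
            dc_max=float(np.abs(c_new - state.c).max()),
            cfl=dt * umax / self.h_mean,
            overshoot=float(max(np.max(c_new) - 1.0, -np.min(c_new), 0.0)),
        )
        return trial, metrics


def total_free_energy(state: SimState, solver: NSCHSolver) -> float:
    """Free energy of a state under a solver's calibration (model units)."""
    return solver.free_energy(state.c)


# --------------------------------------------------------------------------
# trajectory-level driver
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a one- or two-stage vesicle simulation.

    Stage A runs unforced phase separation from a Bernoulli initial state
    until the equilibrium criterion (a single minority patch with an energy
    plateau) or ``max_steps_a``.  Stage B (optional) rotates the
    equilibrated field so the Ld patch sits at the pole opposite the target
    membrane (the worst case), switches the electrostatic force on, and
    runs until the patch faces the membrane (centroid angle below
    ``face_angle`` sustained for ``window`` accepted steps).
    """

    composition: str = "PAT3"
    mesh_level: int = 3
    seed: int = 1
    a_D: float | None = None
    noise_level: int | None = None        # coarse-lattice mixture; None = vertexwise
    eps_hat: float | None = None
    stage_b: bool = False
    force_on: bool | None = None          # default: on in stage B only
    max_steps_a: int = 4000
    max_steps_b: int = 4000
    window: int = 10
    energy_rtol: float = 1e-4
    face_angle: float = np.pi / 6.0
    component_threshold: float = 0.5
    ch_scheme: str = "newton"
    require_plateau: bool = True      # stage-A stop: demand the energy plateau
    snapshot_every: int = 0
    controller: TimeController = field(default_factory=TimeController)
    param_overrides: dict = field(default_factory=dict)
    zeta_overrides: dict = field(default_factory=dict)

    def build_params(self) -> ModelParams:
        return ModelParams.for_composition(self.composition, **self.param_overrides)


@dataclass
class Trajectory:
    """Accepted-step time series and snapshots of one simulation run."""

    config: SimConfig
    mesh: SphereMesh
    solver: NSCHSolver
    times: np.ndarray
    dts: np.ndarray
    mass: np.ndarray
    energy: np.ndarray
    umax: np.ndarray
    angle: np.ndarray            # Ld centroid angle to the facing pole (rad)
    count: np.ndarray            # minority-phase component count
    stage: np.ndarray            # 'A' / 'B' per accepted step
    snapshots: list
    final: SimState
    rejected_steps: int
    stage_b_start: float | None = None    # time at which stage B begins
    aborted: bool = False

    @property
    def stage_a_mask(self) -> np.ndarray:
        return self.stage == "A"

    @property
    def stage_b_mask(self) -> np.ndarray:
        return self.stage == "B"

    def series_frame(self):
        """Scalar time series as a pandas DataFrame (one row per accepted step)."""
        import pandas as pd

        return pd.DataFrame({
            "time": self.times, "dt": self.dts, "mass": self.mass,
            "energy": self.energy, "umax": self.umax,
            "centroid_angle": self.angle, "component_count": self.count,
            "stage": self.stage,
        })


def _centroid_angle_or_nan(mesh: SphereMesh, c: np.ndarray) -> float:
    from .patch_metrics import ld_centroid_angle

    try:
        return ld_centroid_angle(mesh, c)
    except ValueError:
        return float("nan")


def simulate(config: SimConfig, mesh: SphereMesh | None = None) -> Trajectory:
    """Run a full (one- or two-stage) simulation described by ``config``.

    Homogeneous (single-phase) compositions run with a uniform order
    parameter and no phase separation; patchy compositions start from the
    Bernoulli mixture at their Lo area fraction.
    """
    from .patch_metrics import minority_components

    comp = builtin_composition(config.composition)
    params = config.build_params()
    if mesh is None:
        mesh = build_sphere_mesh(config.mesh_level, radius=1.0)
    solver = NSCHSolver(mesh, params, eps_hat=config.eps_hat,
                        ch_scheme=config.ch_scheme)

    a_D = config.a_D if config.a_D is not None else comp.a_D
    if 0.0 < a_D < 1.0:
        if config.noise_level is not None:
            state = lattice_mixture(mesh, a_D, config.seed, config.noise_level)
        else:
            state = initial_state(mesh, a_D, config.seed)
    else:
        n = mesh.n_vertices
        state = SimState(0.0, np.full(n, float(a_D)), np.zeros((n, 3)),
                         np.zeros(n), np.zeros(n))
    state.mu = chemical_potential(solver.ops, solver.nd.eps_hat, state.c)

    env = None
    force_stage_b = config.force_on if config.force_on is not None else True
    if config.stage_b and force_stage_b:
        zeta_kw = dict(config.zeta_overrides)
        if comp.name in ZETA_SUV_MV:
            env = ElectrostaticEnv.for_composition(comp.name, **zeta_kw)
        elif "zeta_suv" in zeta_kw:
            env = ElectrostaticEnv(**zeta_kw)
        else:
            raise ValueError(
                f"stage B with forcing needs a measured or overridden SUV "
                f"zeta potential for {comp.name!r}")

    ctrl = config.controller
    log: dict[str, list] = {k: [] for k in (
        "times", "dts", "mass", "energy", "umax", "angle", "count", "stage")}
    snapshots: list = []
    rejected_total = 0
    aborted = False
    stage_b_start = None

    def run_stage(state: SimState, tag: str, max_steps: int,
                  Fe_fn, stop_fn) -> SimState:
        nonlocal rejected_total, aborted
        dt = ctrl.dt0
        consecutive_rejects = 0
        cooldown = 0          # accepted steps to wait after a rejection
        accepted = 0
        attempts = 0
        while accepted < max_steps and attempts < 5 * max_steps:
            attempts += 1
            # feed-forward CFL cap from the current velocity field
            umax = float(np.linalg.norm(state.u, axis=1).max())
            if umax > 0:
                dt = float(np.clip(0.9 * ctrl.cfl_max * solver.h_mean / umax,
                                   ctrl.dt_min, dt))
            Fe = Fe_fn(state) if Fe_fn is not None else None
            try:
                trial, metrics = solver.step(state, dt, Fe=Fe)
                ok = ctrl.accepts(metrics)
            except SolverDivergence:
                metrics = StepMetrics(rejected=True)
                ok = False
            if not ok:
                rejected_total += 1
                consecutive_rejects += 1
                cooldown = 3
                if dt <= ctrl.dt_min * (1 + 1e-12) \
                        and consecutive_rejects > ctrl.max_rejects:
                    warnings.warn(
                        f"stage {tag}: no progress at dt_min after "
                        f"{consecutive_rejects} rejections; aborting",
                        RuntimeWarning)
                    aborted = True
                    return state
                metrics.rejected = True
                dt = ctrl.next_dt(dt, metrics)
                continue
            consecutive_rejects = 0
            accepted += 1
            state = trial
            log["times"].append(state.time)
            log["dts"].append(dt)
            log["mass"].append(solver.mass(state.c))
            log["energy"].append(solver.free_energy(state.c))
            log["umax"].append(float(np.linalg.norm(state.u, axis=1).max()))
            log["angle"].append(_centroid_angle_or_nan(mesh, state.c))
            log["count"].append(
                minority_components(mesh, state.c, config.component_threshold))
            log["stage"].append(tag)
            if config.snapshot_every and (len(log["times"]) % config.snapshot_every == 0):
                snapshots.append((state.time, state.c.copy()))
            if stop_fn is not None and stop_fn():
                break
            dt = ctrl.next_dt(dt, metrics, allow_growth=(cooldown == 0))
            cooldown = max(cooldown - 1, 0)
        return state

    # ---- stage A: unforced phase separation ----
    def stage_a_done() -> bool:
        w = config.window
        n = len(log["times"])
        if n < w + 1:
            return False
        counts = log["count"][-(w + 1):]
        if any(k != 1 for k in counts):
            return False
        if not config.require_plateau:
            return True
        e0, e1 = log["energy"][-(w + 1)], log["energy"][-1]
        return abs(e1 - e0) <= config.energy_rtol * max(abs(e0), 1e-300)

    if comp.is_phase_separated or (config.a_D is not None and 0 < a_D < 1):
        state = run_stage(state, "A", config.max_steps_a, None, stage_a_done)
    else:
        state = run_stage(state, "A", min(config.max_steps_a, 50), None, None)

    # ---- stage B: electrostatic reorientation from the worst case ----
    if config.stage_b and not aborted:
        from .patch_metrics import ld_centroid_direction

        d = ld_centroid_direction(mesh, state.c)
        rot = rotation_to_pole(d, (0.0, 0.0, 1.0))
        c_rot = np.clip(mesh.rotate_field(state.c, rot), -0.2, 1.2)
        n = mesh.n_vertices
        state = SimState(state.time, c_rot, np.zeros((n, 3)), np.zeros(n),
                         chemical_potential(solver.ops, solver.nd.eps_hat, c_rot))
        stage_b_start = state.time
        snapshots.append((state.time, state.c.copy()))

        Fe_fn = None
        if env is not None:
            Fe_fn = lambda s: solver.electrostatic_force(comp, env, s.c)

        def stage_b_done() -> bool:
            w = config.window
            angles = [a for a, s in zip(log["angle"], log["stage"]) if s == "B"]
            if len(angles) < w + 1:
                return False
            return all(a < config.face_angle for a in angles[-(w + 1):])

        state = run_stage(state, "B", config.max_steps_b, Fe_fn, stage_b_done)

    snapshots.append((state.time, state.c.copy()))
    return Trajectory(
        config=config, mesh=mesh, solver=solver,
        times=np.array(log["times"]), dts=np.array(log["dts"]),
        mass=np.array(log["mass"]), energy=np.array(log["energy"]),
        umax=np.array(log["umax"]), angle=np.array(log["angle"]),
        count=np.array(log["count"], dtype=int),
        stage=np.array(log["stage"]), snapshots=snapshots, final=state,
        rejected_steps=rejected_total, stage_b_start=stage_b_start,
        aborted=aborted,
    )
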