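"""Zeta-potential electrostatics: surface charge, plane field, surface force.

The target giant vesicle (GUV) is so much larger than the ~120 nm fusing
vesicle (SUV) that it is modelled as an infinite charged plane below the
sphere.  Measured zeta potentials are converted to surface potentials
through the low-potential (linearized Grahame) relation

    Psi0 = zeta * exp(-kappa * x),        sigma = eps_r * eps0 * kappa * Psi0,

with ``kappa`` the inverse Debye length and ``x`` the slip-plane distance.
The plane's field is the infinite-sheet field ``E = sigma_guv / (2 eps0)``,
uniform in space, so the sphere can be held at a fixed stand-off distance.
The SUV's total charge ``Q = sigma_suv * 4 pi R^2`` is distributed over the
sphere according to the Lo/Ld charge split of its composition and converted
into a per-area force directed toward the plane, then projected onto the
local tangent plane (the surface flow is strictly tangential; the normal
component cannot move a rigid sphere held at fixed distance).

Interface units are the ones the quantities are usually quoted in: mV for
potentials, nm^-1 for kappa, nm for lengths.  Outputs are SI (C/m^2, V/m,
C, N/m^2).  Conversions happen at function entry and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import MembraneComposition, charge_fraction_ld

__all__ = [
    "ElectrostaticEnv",
    "surface_potential",
    "surface_charge_density",
    "plane_field",
    "suv_total_charge",
    "force_density",
    "DEFAULT_ZETA_GUV_MV",
    "ZETA_SUV_MV",
]

MV_TO_V = 1e-3
PER_NM_TO_PER_M = 1e9
NM_TO_M = 1e-9

#: Measured mean zeta potentials (mV): DOPC GUVs in sucrose, patchy SUVs in
#: dilute PBS.  Both enter one force calculation together, without a
#: medium correction.
DEFAULT_ZETA_GUV_MV = -8.56
ZETA_SUV_MV = {"PAT1": 18.35, "PAT2": 18.87, "PAT3": 20.41}


@dataclass(frozen=True)
class ElectrostaticEnv:
    """Electrolyte and geometry constants for the SUV-near-plane setup.

    zeta potentials in mV, ``kappa`` in nm^-1, ``slip_x`` and ``suv_radius``
    in nm, ``eps0`` in F/m; ``eps_r`` dimensionless.
    """

    zeta_guv: float = DEFAULT_ZETA_GUV_MV
    zeta_suv: float = ZETA_SUV_MV["PAT3"]
    kappa: float = 10.0 / 7.0
    slip_x: float = 0.24
    eps_r: float = 80.0
    eps0: float = 8.85e-12
    suv_radius: float = 60.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.slip_x < 0 or self.eps_r <= 0 \
                or self.suv_radius <= 0:
            raise ValueError("kappa, eps_r, suv_radius must be positive and "
                             "slip_x non-negative")

    @classmethod
    def for_composition(cls, name: str, **overrides) -> "ElectrostaticEnv":
        """Environment with the measured SUV zeta potential of `name`."""
        if name not in ZETA_SUV_MV:
            raise KeyError(f"no measured SUV zeta potential for {name!r}")
        return cls(zeta_suv=ZETA_SUV_MV[name], **overrides)


def surface_potential(zeta_mv: float, kappa_per_nm: float = 10.0 / 7.0,
                      slip_x_nm: float = 0.24) -> float:
    """Surface potential (mV) from the zeta potential at the slip plane.

    Psi0 = zeta * exp(-kappa x).  With the slip plane at the surface
    (x = 0) the two coincide.
    """
    return zeta_mv * np.exp(-kappa_per_nm * slip_x_nm)


def surface_charge_density(env: ElectrostaticEnv, zeta_mv: float) -> float:
    """Surface charge density (C/m^2) via the linearized Grahame relation.

    sigma = eps_r * eps0 * kappa * Psi0(zeta).  Linear in zeta; the sign
    follows the zeta potential.  Valid for low potentials (|zeta| of a few
    tens of mV); no enforcement is attempted.
    """
    psi0_v = surface_potential(zeta_mv, env.kappa, env.slip_x) * MV_TO_V
    return env.eps_r * env.eps0 * (env.kappa * PER_NM_TO_PER_M) * psi0_v


def plane_field(env: ElectrostaticEnv, sigma_guv: float | None = None) -> float:
    """Field strength (V/m) of the GUV-as-infinite-plane: E = sigma/(2 eps0).

    Uniform in space; the sign is the sign of the GUV charge density, so a
    negative value with a positively charged SUV encodes attraction.
    """
    if sigma_guv is None:
        sigma_guv = surface_charge_density(env, env.zeta_guv)
    return sigma_guv / (2.0 * env.eps0)


def suv_total_charge(env: ElectrostaticEnv) -> float:
    """Total SUV charge (C): Q = sigma_suv * 4 pi R^2.

    Positive for the cationic (PAT) formulations.
    """
    sigma = surface_charge_density(env, env.zeta_suv)
    r_m = env.suv_radius * NM_TO_M
    return sigma * 4.0 * np.pi * r_m**2


def areal_charge_density(env: ElectrostaticEnv, comp: MembraneComposition,
                         c_field: np.ndarray, mesh) -> np.ndarray:
    """Per-vertex charge density (C/m^2) splitting Q between the phases.

    The Ld share ``f_Ld`` of the total charge is spread uniformly over the
    Ld phase and the rest over Lo.  With a diffuse interface the phase
    indicators are the smooth weights ``w_Ld = 1 - c`` and ``w_Lo = c``:

        q(v) = Q * [ f_Ld w_Ld(c_v) / ∫ w_Ld ds
                     + (1 - f_Ld) w_Lo(c_v) / ∫ w_Lo ds ].

    The area-weighted sum of ``q`` recovers Q exactly (same quadrature in
    numerator and normalization).
    """
    c = np.asarray(c_field, dtype=float)
    if c.shape != (mesh.n_vertices,):
        raise ValueError(
            f"c_field has shape {c.shape}, expected ({mesh.n_vertices},)")
    q_total = suv_total_charge(env)
    f_ld = charge_fraction_ld(comp)
    areas_m2 = mesh.vertex_areas * NM_TO_M**2 * (env.suv_radius / mesh.radius)**2
    w_ld = 1.0 - c
    w_lo = c
    int_ld = float(w_ld @ areas_m2)
    int_lo = float(w_lo @ areas_m2)
    q = np.zeros_like(c)
    if int_ld > 0:
        q += f_ld * w_ld / int_ld
    if int_lo > 0:
        q += (1.0 - f_ld) * w_lo / int_lo
    return q_total * q


def force_density(env: ElectrostaticEnv, comp: MembraneComposition,
                  c_field: np.ndarray, mesh,
                  plane_normal: np.ndarray = (0.0, 0.0, 1.0)) -> np.ndarray:
    """Tangential electrostatic force density (N/m^2) per vertex.

    The plane sits below the sphere with outward normal ``plane_normal``
    (default +z).  Each surface patch carries charge density ``q`` and feels
    the uniform force per area ``q * |E|`` directed toward the plane
    (attraction of the cationic SUV to the anionic GUV); that vector is then
    projected onto the sphere's local tangent plane.  The pre-projection
    magnitudes integrate to ``|Q * E|`` by construction.

    Returns an (N, 3) array.
    """
    q = areal_charge_density(env, comp, c_field, mesh)
    e_mag = abs(plane_field(env))
    n_plane = np.asarray(plane_normal, dtype=float)
    n_plane = n_plane / np.linalg.norm(n_plane)
    # attraction: toward the plane, i.e. along -plane_normal
    f_pre = np.outer(q * e_mag, -n_plane)
    normals = mesh.vertex_normals
    f_tan = f_pre - normals * np.sum(f_pre * normals, axis=1, keepdims=True)
    return f_tan
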