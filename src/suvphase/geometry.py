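"""Triangulated sphere and discrete tangential differential operators.

The vesicle surface is a fixed sphere, discretized as an icosahedral
subdivision mesh with all vertices projected onto the sphere.  Scalar and
vector fields live at vertices (P1, piecewise linear); gradients and strain
rates are piecewise constant per triangle.  All surface integrals use lumped
(barycentric) vertex areas, which makes the Cahn--Hilliard mass bookkeeping
exact by construction:

* ``gradient`` of a P1 field is the exact per-face gradient;
* ``divergence`` is the negative adjoint of ``gradient`` with respect to the
  area-weighted inner products, so the discrete Stokes identity
  ``∫ div u ds = 0`` holds to round-off on the closed surface;
* ``laplace_beltrami`` is the resulting Galerkin (cotangent) operator with
  lumped mass;
* ``strain_rate`` is the Boussinesq--Scriven tensor
  ``Es(u) = sym(P ∇u P)`` with ``P`` the face tangent projector; it vanishes
  identically for rigid rotations ``u = ω × x`` (the Killing fields of the
  sphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "SphereMesh",
    "SurfaceOperators",
    "build_sphere_mesh",
    "rotation_to_pole",
    "write_vtk",
    "read_vtk",
]


def build_sphere_mesh(refinement_level: int, radius: float = 60.0) -> "SphereMesh":
    """Icosahedral-subdivision sphere with ``10 * 4**level + 2`` vertices.

    ``radius`` is in nm (default 60 nm, a 120 nm-diameter vesicle).
    """
    if refinement_level < 0:
        raise ValueError("refinement_level must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=refinement_level, radius=radius)
    vertices = np.asarray(tm.vertices, dtype=float)
    # snap exactly onto the sphere
    vertices *= radius / np.linalg.norm(vertices, axis=1, keepdims=True)
    return SphereMesh(
        radius=float(radius),
        vertices=vertices,
        triangles=np.asarray(tm.faces, dtype=np.int64),
        refinement_level=int(refinement_level),
    )


@dataclass
class SphereMesh:
    """Closed, outward-oriented triangulated sphere (genus 0)."""

    radius: float
    vertices: np.ndarray      # (N, 3)
    triangles: np.ndarray     # (F, 3) vertex indices, outward orientation
    refinement_level: int = -1

    def __post_init__(self) -> None:
        r = np.linalg.norm(self.vertices, axis=1)
        if np.max(np.abs(r - self.radius)) > 1e-9 * self.radius:
            raise ValueError("vertices do not lie on the sphere")
        self._build()

    def _build(self) -> None:
        v, f = self.vertices, self.triangles
        x0, x1, x2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        cross = np.cross(x1 - x0, x2 - x0)
        norm = np.linalg.norm(cross, axis=1)
        self.face_areas = 0.5 * norm
        self.face_normals = cross / norm[:, None]
        # enforce outward orientation (trimesh icospheres already are)
        centroids = (x0 + x1 + x2) / 3.0
        if np.mean(np.sum(self.face_normals * centroids, axis=1)) < 0:
            raise ValueError("mesh is not outward-oriented")
        # P1 hat-function gradients: grad lambda_i = n x e_i / (2A),
        # e_i the edge opposite vertex i, oriented so the gradient points
        # toward vertex i.
        twoA = (2.0 * self.face_areas)[:, None]
        n = self.face_normals
        self.hat_gradients = np.stack(
            [
                np.cross(n, x2 - x1) / twoA,
                np.cross(n, x0 - x2) / twoA,
                np.cross(n, x1 - x0) / twoA,
            ],
            axis=1,
        )  # (F, 3 local vertices, 3 xyz)
        # lumped (barycentric) vertex areas
        areas = np.zeros(len(v))
        np.add.at(areas, f.ravel(), np.repeat(self.face_areas / 3.0, 3))
        self.vertex_areas = areas
        self.vertex_normals = v / np.linalg.norm(v, axis=1, keepdims=True)
        self.face_projectors = (
            np.eye(3)[None, :, :] - n[:, :, None] * n[:, None, :]
        )
        self._tree: cKDTree | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def mean_edge_length(self) -> float:
        v, f = self.vertices, self.triangles
        e = np.concatenate([
            v[f[:, 1]] - v[f[:, 0]],
            v[f[:, 2]] - v[f[:, 1]],
            v[f[:, 0]] - v[f[:, 2]],
        ])
        return float(np.linalg.norm(e, axis=1).mean())

    def integrate(self, vertex_field: np.ndarray) -> float:
        """Area-weighted surface integral of a per-vertex scalar field."""
        return float(self.vertex_areas @ np.asarray(vertex_field, dtype=float))

    def face_mean(self, vertex_field: np.ndarray) -> np.ndarray:
        """Average a per-vertex field (scalar or vector) onto faces."""
        return np.asarray(vertex_field)[self.triangles].mean(axis=1)

    def project_tangent(self, u: np.ndarray) -> np.ndarray:
        """Pointwise projection of a per-vertex vector field onto tangent planes."""
        n = self.vertex_normals
        return u - n * np.sum(u * n, axis=1, keepdims=True)

    def tangent_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex orthonormal tangent pair (t1, t2), each (N, 3)."""
        n = self.vertex_normals
        # pick the coordinate axis least aligned with each normal
        a = np.zeros_like(n)
        a[np.arange(len(n)), np.argmin(np.abs(n), axis=1)] = 1.0
        t1 = np.cross(n, a)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(n, t1)
        return t1, t2

    # -- sphere-surface sampling ------------------------------------------

    def sample_field(self, points: np.ndarray, vertex_field: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of a vertex field at surface points.

        ``points`` are positions on (or radially projectable onto) the
        sphere; each is mapped to the triangle its radial ray pierces.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        field = np.asarray(vertex_field, dtype=float)
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
            nv = self.n_vertices
            v2f: list[list[int]] = [[] for _ in range(nv)]
            for fi, tri in enumerate(self.triangles):
                for vi in tri:
                    v2f[vi].append(fi)
            self._vertex_faces = v2f
        dirs = points / np.linalg.norm(points, axis=1, keepdims=True)
        _, nearest = self._tree.query(dirs * self.radius, k=3)
        out = np.empty(len(points) if field.ndim == 1 else (len(points),) + field.shape[1:])
        for i, d in enumerate(dirs):
            cand = {fi for vi in np.atleast_1d(nearest[i]) for fi in self._vertex_faces[vi]}
            best, best_min = None, -np.inf
            for fi in cand:
                tri = self.triangles[fi]
                x0, x1, x2 = self.vertices[tri]
                n = self.face_normals[fi]
                dn = d @ n
                if dn <= 1e-14:
                    continue
                p = (x0 @ n) / dn * d  # ray-plane intersection
                # barycentric via areas
                w0 = np.cross(x1 - p, x2 - p) @ n
                w1 = np.cross(x2 - p, x0 - p) @ n
                w2 = np.cross(x0 - p, x1 - p) @ n
                s = w0 + w1 + w2
                bary = np.array([w0, w1, w2]) / s
                m = bary.min()
                if m > best_min:
                    best_min, best = m, (tri, np.clip(bary, 0.0, 1.0))
            tri, bary = best
            bary = bary / bary.sum()
            out[i] = np.tensordot(bary, field[tri], axes=1)
        return out

    def rotate_field(self, vertex_field: np.ndarray, rot: np.ndarray) -> np.ndarray:
        """Return the field after rotating the configuration by matrix ``rot``.

        The rotated field at vertex x equals the original field at
        ``rot^T x`` (barycentric interpolation on the source mesh).
        """
        src = self.vertices @ rot  # rows: rot^T @ x
        return self.sample_field(src, vertex_field)


def rotation_to_pole(direction: np.ndarray, target=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Rotation matrix carrying unit vector ``direction`` to ``target``."""
    a = np.asarray(direction, dtype=float)
    a = a / np.linalg.norm(a)
    b = np.asarray(target, dtype=float)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-14:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate by pi about any axis orthogonal to a
        axis = np.zeros(3)
        axis[np.argmin(np.abs(a))] = 1.0
        axis -= a * (axis @ a)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


class SurfaceOperators:
    """Discrete tangential calculus on a :class:`SphereMesh`.

    Assembles and caches the sparse P1 stiffness matrix and exposes
    gradient / divergence / Laplace--Beltrami / strain-rate actions on
    per-vertex fields.
    """

    def __init__(self, mesh: SphereMesh):
        self.mesh = mesh
        self._stiffness: sp.csr_matrix | None = None

    # -- first-order operators --------------------------------------------

    def gradient(self, vertex_scalar: np.ndarray) -> np.ndarray:
        """Per-face surface gradient (F, 3) of a per-vertex scalar field."""
        f = np.asarray(vertex_scalar, dtype=float)
        self._check_scalar(f)
        vals = f[self.mesh.triangles]  # (F, 3)
        return np.einsum("fi,fik->fk", vals, self.mesh.hat_gradients)

    def divergence_face(self, face_vec: np.ndarray) -> np.ndarray:
        """Weak divergence at vertices of a per-face vector field.

        Negative adjoint of :meth:`gradient` in the area-weighted inner
        products: ``(div v, phi)_vertex = -(v, grad phi)_face``.
        """
        v = np.asarray(face_vec, dtype=float)
        contrib = np.einsum(
            "fk,fik,f->fi", v, self.mesh.hat_gradients, self.mesh.face_areas
        )
        out = np.zeros(self.mesh.n_vertices)
        np.add.at(out, self.mesh.triangles.ravel(), contrib.ravel())
        return -out / self.mesh.vertex_areas

    def divergence(self, vertex_vec: np.ndarray) -> np.ndarray:
        """Weak surface divergence at vertices of a per-vertex vector field."""
        return self.divergence_face(self.mesh.face_mean(vertex_vec))

    def divergence_pointwise(self, vertex_vec: np.ndarray) -> np.ndarray:
        """Per-face pointwise surface divergence ``tr(P ∇u P)``."""
        g = self.velocity_gradient(vertex_vec)
        return np.einsum("fkk->f", g)

    def velocity_gradient(self, vertex_vec: np.ndarray) -> np.ndarray:
        """Projected per-face velocity gradient ``P (Σ u_i ⊗ ∇λ_i) P``, (F,3,3)."""
        u = np.asarray(vertex_vec, dtype=float)
        if u.shape != (self.mesh.n_vertices, 3):
            raise ValueError(f"expected ({self.mesh.n_vertices}, 3) field, got {u.shape}")
        uv = u[self.mesh.triangles]  # (F, 3, 3comp)
        grad = np.einsum("fia,fik->fak", uv, self.mesh.hat_gradients)
        P = self.mesh.face_projectors
        return np.einsum("fab,fbc,fcd->fad", P, grad, P)

    def strain_rate(self, vertex_vec: np.ndarray, tangent_tol: float = 1e-6) -> np.ndarray:
        """Boussinesq--Scriven strain-rate tensor per face, ``sym(P ∇u P)``.

        Raises if the input has a normal component beyond ``tangent_tol``
        relative to its magnitude.
        """
        u = np.asarray(vertex_vec, dtype=float)
        n = self.mesh.vertex_normals
        un = np.abs(np.sum(u * n, axis=1))
        scale = np.linalg.norm(u, axis=1).max() if len(u) else 0.0
        if scale > 0 and un.max() > tangent_tol * scale:
            raise ValueError("input velocity is not tangential within tolerance")
        g = self.velocity_gradient(u)
        return 0.5 * (g + np.transpose(g, (0, 2, 1)))

    # -- second-order -----------------------------------------------------

    @property
    def stiffness(self) -> sp.csr_matrix:
        """P1 stiffness matrix K with K_ij = Σ_f A_f ∇λ_i · ∇λ_j (cotangent)."""
        if self._stiffness is None:
            m = self.mesh
            # local 3x3 blocks, vectorized over faces
            local = np.einsum(
                "fik,fjk,f->fij", m.hat_gradients, m.hat_gradients, m.face_areas
            )
            rows = np.repeat(m.triangles, 3, axis=1).ravel()
            cols = np.tile(m.triangles, (1, 3)).ravel()
            self._stiffness = sp.coo_matrix(
                (local.ravel(), (rows, cols)),
                shape=(m.n_vertices, m.n_vertices),
            ).tocsr()
        return self._stiffness

    def laplace_beltrami(self, vertex_scalar: np.ndarray) -> np.ndarray:
        """Discrete Laplace--Beltrami of a per-vertex scalar (lumped mass)."""
        f = np.asarray(vertex_scalar, dtype=float)
        self._check_scalar(f)
        return -(self.stiffness @ f) / self.mesh.vertex_areas

    def _check_scalar(self, f: np.ndarray) -> None:
        if f.shape != (self.mesh.n_vertices,):
            raise ValueError(
                f"expected ({self.mesh.n_vertices},) field, got {f.shape}")


def write_vtk(path, mesh: SphereMesh, point_data: dict[str, np.ndarray] | None = None,
              comment: str = "suvphase surface snapshot") -> None:
    """Write the mesh and per-vertex fields as a legacy ASCII VTK polydata file."""
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in v) for v in mesh.vertices]
    f = mesh.triangles
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.17g}" for x in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.17g}" for x in row) for row in arr]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[SphereMesh, dict[str, np.ndarray]]:
    """Read back a mesh + per-vertex fields written by :func:`write_vtk`.

    Supports the subset of legacy ASCII VTK polydata this package emits
    (POINTS, POLYGONS with triangles, scalar/vector POINT_DATA).
    Returns ``(mesh, point_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0

    def grab(prefix):
        nonlocal i
        while i < len(tokens) and not tokens[i].startswith(prefix):
            i += 1
        if i == len(tokens):
            raise ValueError(f"missing {prefix} section in {path}")
        line = tokens[i]
        i += 1
        return line

    n_pts = int(grab("POINTS").split()[1])
    vertices = np.array([tokens[i + k].split() for k in range(n_pts)],
                        dtype=float)
    i += n_pts
    n_faces = int(grab("POLYGONS").split()[1])
    faces = np.array([tokens[i + k].split()[1:] for k in range(n_faces)],
                     dtype=np.int64)
    i += n_faces
    data: dict[str, np.ndarray] = {}
    while i < len(tokens):
        line = tokens[i]
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            data[name] = np.array(tokens[i:i + n_pts], dtype=float)
            i += n_pts
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            i += 1
            data[name] = np.array([tokens[i + k].split()
                                   for k in range(n_pts)], dtype=float)
            i += n_pts
        else:
            i += 1
    radius = float(np.linalg.norm(vertices, axis=1).mean())
    mesh = SphereMesh(radius=radius, vertices=vertices, triangles=faces)
    return mesh, data
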