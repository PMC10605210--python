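"""Observables of the simulated vesicle: patch count, coarsening and
reorientation times, and replicate averaging.

Two times characterize a run.  The *equilibrium time* is when unforced
phase separation has coarsened to a single patch of the minority phase with
the free energy on a plateau.  The *reorientation time* is how long the
charged Ld patch, started at the pole opposite the target membrane (worst
case), takes to swing around and face it — the proxy used for fusion
promotion.  Both are averaged over replicate simulations that differ only
in the random initial mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import SphereMesh

__all__ = [
    "TrajectoryMetrics",
    "minority_components",
    "equilibrium_time",
    "ld_centroid_direction",
    "ld_centroid_angle",
    "reorientation_time",
    "replicate_average",
    "SENTINEL",
]

#: returned when a run never meets a detection criterion
SENTINEL = float("nan")


@dataclass
class TrajectoryMetrics:
    """Summary observables extracted from one trajectory."""

    equilibrium_time: float
    reorientation_time: float
    centroid_angle_series: np.ndarray     # (n, 2) columns: time, angle
    component_count_series: np.ndarray    # (n, 2) columns: time, count

    def __post_init__(self) -> None:
        if np.isfinite(self.reorientation_time) and self.reorientation_time < 0:
            raise ValueError("reorientation_time must be non-negative")


def _edge_list(mesh: SphereMesh) -> np.ndarray:
    t = mesh.triangles
    e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    return e


def minority_components(mesh: SphereMesh, c: np.ndarray,
                        threshold: float = 0.5) -> int:
    """Number of connected components of the minority-phase vertex set.

    The minority phase is whichever of {c > threshold} (Lo) or
    {c < threshold} (Ld) covers the smaller area; adjacency is shared
    triangle edges.  An empty minority set yields 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    c = np.asarray(c, dtype=float)
    if c.shape != (mesh.n_vertices,):
        raise ValueError("field/mesh size mismatch")
    lo_mask = c > threshold
    area_lo = float(mesh.vertex_areas @ lo_mask)
    mask = lo_mask if area_lo <= mesh.total_area - area_lo else (c < threshold)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return 0
    remap = -np.ones(mesh.n_vertices, dtype=int)
    remap[idx] = np.arange(len(idx))
    e = _edge_list(mesh)
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    e = remap[e[keep]]
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                     shape=(len(idx), len(idx)))
    n, _ = connected_components(adj, directed=False)
    return int(n)


def equilibrium_time(trajectory, energy_rtol: float | None = None,
                     window: int | None = None) -> float:
    """Time at which the minority phase coalesced into its final single patch.

    Transient single-patch states (between merge events) must not count,
    so the one-patch state is *confirmed* first: the component count must
    equal 1 at every accepted step of a trailing window of ``window``
    steps whose relative free-energy change is below ``energy_rtol``.
    The reported time is when the confirmed count run began — the moment
    the vesicle reached its equilibrium morphology — not the end of the
    confirmation window, which depends on the step controller rather than
    the dynamics.  Thresholds default to the trajectory's configuration.
    Returns the sentinel (NaN) with a warning if never confirmed.
    """
    cfg = trajectory.config
    w = cfg.window if window is None else window
    rtol = cfg.energy_rtol if energy_rtol is None else energy_rtol
    mask = trajectory.stage_a_mask
    times = trajectory.times[mask]
    counts = trajectory.count[mask]
    energies = trajectory.energy[mask]
    for k in range(w, len(times)):
        if np.all(counts[k - w:k + 1] == 1) and abs(
                energies[k] - energies[k - w]) <= rtol * max(abs(energies[k - w]), 1e-300):
            start = k - w
            while start > 0 and counts[start - 1] == 1:
                start -= 1
            return float(times[start])
    warnings.warn("equilibrium criterion never met; returning sentinel",
                  RuntimeWarning)
    return SENTINEL


def ld_centroid_direction(mesh: SphereMesh, c: np.ndarray,
                          rel_tol: float = 1e-12) -> np.ndarray:
    """Unit direction of the Ld-weighted centroid ∫ (1-c) x ds.

    Raises if the centroid is degenerate (symmetric Ld distribution).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (mesh.n_vertices,):
        raise ValueError("field/mesh size mismatch")
    v = ((1.0 - c) * mesh.vertex_areas) @ mesh.vertices
    norm = np.linalg.norm(v)
    if norm < rel_tol * mesh.radius * mesh.total_area:
        raise ValueError("degenerate Ld centroid (symmetric distribution)")
    return v / norm


def ld_centroid_angle(mesh: SphereMesh, c: np.ndarray) -> float:
    """Angle (rad) between the plane-facing pole -z and the Ld centroid.

    0 when the Ld patch faces the target membrane below the vesicle, pi
    when it sits at the top.
    """
    d = ld_centroid_direction(mesh, c)
    return float(np.arccos(np.clip(-d[2], -1.0, 1.0)))


def reorientation_time(trajectory, face_angle: float | None = None,
                       window: int | None = None) -> float:
    """Time (from stage-B start) until the Ld patch faces the membrane.

    The first accepted-step time at which the centroid angle drops below
    ``face_angle`` and stays below it for the following ``window`` accepted
    steps (or to the end of the run).  A stage-B trajectory that starts
    below the threshold returns 0.  Returns the sentinel (NaN) if the
    angle never settles below the threshold.
    """
    cfg = trajectory.config
    thr = cfg.face_angle if face_angle is None else face_angle
    w = cfg.window if window is None else window
    if trajectory.stage_b_start is None:
        warnings.warn("trajectory has no stage B; returning sentinel",
                      RuntimeWarning)
        return SENTINEL
    mask = trajectory.stage_b_mask
    times = trajectory.times[mask]
    angles = trajectory.angle[mask]
    t0 = trajectory.stage_b_start
    if len(times) == 0:
        warnings.warn("empty stage-B series; returning sentinel", RuntimeWarning)
        return SENTINEL
    # prepend the rotated initial state so a run that starts facing gives 0
    init = next((c for t, c in trajectory.snapshots if t == t0), None)
    if init is not None:
        times = np.concatenate([[t0], times])
        angles = np.concatenate([[ld_centroid_angle(trajectory.mesh, init)], angles])
    below = angles < thr
    for k in np.flatnonzero(below):
        end = min(k + w, len(times) - 1)
        if np.all(below[k:end + 1]):
            return float(times[k] - t0)
    warnings.warn("reorientation criterion never met; returning sentinel",
                  RuntimeWarning)
    return SENTINEL


def trajectory_metrics(trajectory) -> TrajectoryMetrics:
    """Bundle the standard observables of one run."""
    mask_b = trajectory.stage_b_mask
    return TrajectoryMetrics(
        equilibrium_time=equilibrium_time(trajectory),
        reorientation_time=(reorientation_time(trajectory)
                            if trajectory.stage_b_start is not None else SENTINEL),
        centroid_angle_series=np.column_stack(
            [trajectory.times, trajectory.angle]),
        component_count_series=np.column_stack(
            [trajectory.times, trajectory.count]),
    )


def replicate_average(composition: str, n_replicates: int = 5,
                      seeds=None, config=None) -> dict:
    """Mean and standard deviation of both times over replicate runs.

    Runs ``n_replicates`` independent simulations whose seeds default to
    ``master_seed + 0..n-1`` (master seed taken from ``config.seed``).
    Sentinel (never-reached) runs are excluded from the averages and
    counted in the report; if all runs are sentinel for a metric the whole
    call errors.
    """
    from .nsch import SimConfig, simulate

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if config is None:
        config = SimConfig(composition=composition, stage_b=True)
    if seeds is None:
        seeds = [config.seed + i for i in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("len(seeds) must equal n_replicates")

    from dataclasses import replace

    eq, reo, trajs = [], [], []
    for s in seeds:
        traj = simulate(replace(config, composition=composition, seed=s))
        trajs.append(traj)
        eq.append(equilibrium_time(traj))
        if config.stage_b:
            reo.append(reorientation_time(traj))

    def _summary(values):
        arr = np.asarray(values, dtype=float)
        ok = arr[np.isfinite(arr)]
        if len(ok) == 0:
            raise RuntimeError(
                f"all {len(arr)} replicate runs of {composition} hit the "
                "sentinel; no average defined")
        return {
            "mean": float(np.mean(ok)),
            "sd": float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0,
            "n_used": int(len(ok)),
            "n_sentinel": int(len(arr) - len(ok)),
        }

    out = {
        "composition": composition,
        "seeds": list(seeds),
        "equilibrium_time": _summary(eq),
        "trajectories": trajs,
    }
    if config.stage_b:
        out["reorientation_time"] = _summary(reo)
    return out
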