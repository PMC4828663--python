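"""Phase mapping: phase singularities, rotor tracking, density maps.

The instantaneous phase of each node's transmembrane voltage is the
analytic-signal angle theta = atan2(H[v - <v>], v - <v>) computed with
the Hilbert transform over the analysis window.  Phase singularities
(PSs) -- pinwheel points where all phases converge -- are found per mesh
element from the topological charge: the wrapped phase differences summed
around the element's (oriented) vertices equal +/-2 pi at a PS, the sign
giving the chirality.  PSs are tracked frame-to-frame by nearest-centroid
matching under a jump threshold; trajectories outliving 120 ms (the
minimum fibrillatory cycle length) are classified as rotors.  Occurrence
counts are smoothed with inverse-distance-squared weighting and
normalized to give PS/rotor density maps and regional statistics on the
eight LA subdivisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh
from .monodomain import Recording, activation_times

__all__ = [
    "PhaseMovie", "PSTrajectory", "DensityMap", "compute_phase",
    "detect_ps", "detect_ps_movie", "track_ps", "classify_rotors",
    "density_map", "regional_stats",
]


@dataclass
class PhaseMovie:
    theta: np.ndarray            # (T, N) float32 in (-pi, pi]
    t: np.ndarray
    frame_interval: float
    mask: np.ndarray             # (N,) True where phase is defined


@dataclass
class PSTrajectory:
    id: int
    chirality: int
    t: list = field(default_factory=list)          # frame times (ms)
    elements: list = field(default_factory=list)   # triangle indices
    positions: list = field(default_factory=list)  # centroids (mm)

    @property
    def birth(self) -> float:
        return self.t[0]

    @property
    def death(self) -> float:
        return self.t[-1]

    @property
    def duration(self) -> float:
        return self.death - self.birth


def trajectories_to_csv(trajectories, path) -> None:
    """Export tracked PS trajectories as tidy CSV
    (id, t, x, y, z, element, chirality)."""
    rows = []
    for tr in trajectories:
        for t, e, p in zip(tr.t, tr.elements, tr.positions):
            rows.append((tr.id, t, p[0], p[1], p[2], e, tr.chirality))
    pd.DataFrame(rows, columns=["id", "t", "x", "y", "z", "element",
                                "chirality"]).to_csv(path, index=False)


@dataclass
class DensityMap:
    value: np.ndarray            # (M,) normalized to max 1 (or all zero)
    counts: np.ndarray           # raw per-element occurrence counts
    radius_mm: float


def compute_phase(recording: Recording, t_min: float | None = None
                  ) -> PhaseMovie:
    """Hilbert phase of every node over the analysis window.

    Nodes with (numerically) constant signal have undefined phase and are
    masked.  ``t_min`` restricts the window (e.g. post-initiation).
    """
    sel = slice(None) if t_min is None else recording.t >= t_min
    v = recording.frames[sel].astype(np.float64)
    t = recording.t[sel]
    if v.shape[0] < 4:
        raise ValueError("need at least a few frames of activity")
    v = v - v.mean(axis=0, keepdims=True)
    mask = v.std(axis=0) > 1e-6
    theta = np.zeros(v.shape, dtype=np.float32)
    step = 2048  # chunk nodes: hilbert allocates complex copies
    for j0 in range(0, v.shape[1], step):
        blk = v[:, j0:j0 + step]
        theta[:, j0:j0 + step] = np.angle(hilbert(blk, axis=0))
    theta[:, ~mask] = 0.0
    return PhaseMovie(theta, t, recording.frame_interval, mask)


def _wrap(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def detect_ps(phase_frame: np.ndarray, mesh: SurfaceMesh,
              mask: np.ndarray | None = None):
    """Phase singularities in one frame.

    Returns (elements, chirality): triangles whose oriented vertex loop
    winds by +/-2 pi (|sum of wrapped differences| > pi), and the sign.
    Elements touching a masked node are skipped.
    """
    tri = mesh.triangles
    th = phase_frame
    s = (_wrap(th[tri[:, 1]] - th[tri[:, 0]])
         + _wrap(th[tri[:, 2]] - th[tri[:, 1]])
         + _wrap(th[tri[:, 0]] - th[tri[:, 2]]))
    ok = np.abs(s) > np.pi
    if mask is not None:
        ok &= mask[tri].all(axis=1)
    elems = np.flatnonzero(ok)
    return elems, np.sign(s[elems]).astype(int)


def detect_ps_movie(movie: PhaseMovie, mesh: SurfaceMesh):
    """Per-frame PS detections: list of (elements, chirality) tuples."""
    return [detect_ps(movie.theta[k], mesh, movie.mask)
            for k in range(len(movie.t))]


def track_ps(detections, mesh: SurfaceMesh, times=None,
             max_jump_mm: float = 5.0, frame_interval: float = 1.0):
    """Greedy frame-to-frame matching of PS detections into trajectories.

    Matches minimize centroid distance, require equal chirality and
    distance <= ``max_jump_mm``; unmatched detections are births,
    unmatched previous PSs deaths.
    """
    cents = mesh.centroids
    if times is None:
        times = frame_interval * np.arange(len(detections))
    trajs: list[PSTrajectory] = []
    active: list[PSTrajectory] = []
    next_id = 0
    for k, (elems, chir) in enumerate(detections):
        t = times[k]
        pos = cents[elems]
        unmatched = list(range(len(elems)))
        new_active = []
        if active and len(elems):
            pairs = []
            for ai, tr in enumerate(active):
                d = np.linalg.norm(pos - tr.positions[-1], axis=1)
                for di in range(len(elems)):
                    if chir[di] == tr.chirality and d[di] <= max_jump_mm:
                        pairs.append((d[di], ai, di))
            used_a, used_d = set(), set()
            for d, ai, di in sorted(pairs):
                if ai in used_a or di in used_d:
                    continue
                used_a.add(ai); used_d.add(di)
                tr = active[ai]
                tr.t.append(t)
                tr.elements.append(int(elems[di]))
                tr.positions.append(pos[di])
                new_active.append(tr)
            unmatched = [di for di in range(len(elems)) if di not in used_d]
        for di in unmatched:
            tr = PSTrajectory(next_id, int(chir[di]), [t],
                              [int(elems[di])], [pos[di]])
            next_id += 1
            trajs.append(tr)
            new_active.append(tr)
        active = new_active
    return trajs


def classify_rotors(trajectories, min_duration_ms: float = 120.0):
    """Trajectories outliving the minimum fibrillatory cycle length."""
    return [tr for tr in trajectories if tr.duration > min_duration_ms]


def density_map(trajectories, mesh: SurfaceMesh, radius_mm: float = 5.0,
                eps_mm2: float | None = None) -> DensityMap:
    """Inverse-distance-squared smoothed, normalized occurrence density."""
    counts = np.zeros(mesh.n_triangles)
    for tr in trajectories:
        for e in tr.elements:
            counts[e] += 1.0
    value = np.zeros_like(counts)
    if counts.any():
        if eps_mm2 is None:
            eps_mm2 = float(np.mean(mesh.edge_lengths) ** 2)
        cents = mesh.centroids
        occupied = np.flatnonzero(counts)
        tree = cKDTree(cents[occupied])
        neigh = tree.query_ball_point(cents, r=radius_mm)
        for i, js in enumerate(neigh):
            if js:
                src = occupied[js]
                d2 = ((cents[src] - cents[i]) ** 2).sum(axis=1)
                value[i] = (counts[src] / (d2 + eps_mm2)).sum()
        value /= value.max()
    return DensityMap(value, counts, radius_mm)


def regional_stats(trajectories, rotors, recording: Recording,
                   mesh: SurfaceMesh, smoothed: DensityMap | None = None,
                   fibrosis_density=None, t_min: float | None = None
                   ) -> pd.DataFrame:
    """Per-subdivision statistics (mean/SD PS and rotor counts per time
    point, per-vertex average cycle length, normalized densities).

    Returns a tidy frame with one row per subdivision 1-8; unactivated
    subdivisions have NaN cycle lengths.
    """
    times = recording.t if t_min is None else \
        recording.t[recording.t >= t_min]
    nT = len(times)
    ps_c = np.zeros((nT, 8))
    rot_c = np.zeros((nT, 8))
    tidx = {round(float(tt), 6): k for k, tt in enumerate(times)}

    def accumulate(trajs, out):
        for tr in trajs:
            for tt, e in zip(tr.t, tr.elements):
                k = tidx.get(round(float(tt), 6))
                if k is not None:
                    out[k, mesh.subdivision[e] - 1] += 1

    accumulate(trajectories, ps_c)
    accumulate(rotors, rot_c)

    amap = activation_times(recording)
    node_cl = amap.mean_cycle_length()
    node_sub = mesh.node_subdivision()

    if smoothed is None:
        smoothed = density_map(trajectories, mesh)
    rows = []
    sub_mean_density = np.zeros(8)
    for s in range(1, 9):
        m = mesh.subdivision == s
        sub_mean_density[s - 1] = smoothed.value[m].mean() if m.any() else 0.0
    mx = sub_mean_density.max()
    norm_ps = sub_mean_density / mx if mx > 0 else sub_mean_density
    for s in range(1, 9):
        cls = node_cl[(node_sub == s) & np.isfinite(node_cl)]
        rows.append({
            "subdivision": s,
            "ps_mean": ps_c[:, s - 1].mean(),
            "ps_sd": ps_c[:, s - 1].std(),
            "rotor_mean": rot_c[:, s - 1].mean(),
            "cl_mean_ms": cls.mean() if len(cls) else np.nan,
            "cl_min_ms": cls.min() if len(cls) else np.nan,
            "ps_density_norm": norm_ps[s - 1],
        })
    df = pd.DataFrame(rows)
    if fibrosis_density is not None:
        df["fibrosis_density_norm"] = np.asarray(fibrosis_density, float)
    return df
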