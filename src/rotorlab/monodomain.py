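"""Monodomain reaction-diffusion solver on the triangulated surface.

The transmembrane voltage obeys

    dV/dt = div( D grad V ) - I_ion/Cm' - I_stim/Cm',

with a per-triangle anisotropic diffusion tensor D = D_l f f^T +
D_t (I - f f^T) built from longitudinal/transverse conductivities
sigma_{l,t} (S/m) via D = sigma / (beta * C_m), beta the surface-to-volume
ratio and C_m the membrane capacitance per area.  Space is discretized
with linear (P1) finite elements and a lumped mass matrix; no-flux
boundaries are natural, so split (fibrotic) edges block flux simply by
their lost adjacency.  Time stepping is operator splitting: tabulated
Rush-Larsen for the ionic model, explicit diffusion (default dt 20 us).

Ablated elements are floored to 0.001 S/m in both directions, the
non-conducting-but-non-zero convention that avoids a singular tensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from . import ionic
from .geometry import SurfaceMesh, REGION_PV, REGION_LAA, REGION_LA_BODY

__all__ = [
    "SIGMA_FLOOR", "ConductivityField", "Stimulus", "Recording",
    "ActivationMap", "default_conductivity", "sigma_to_diffusivity",
    "assemble_diffusion", "node_params_from_regions", "run_simulation",
    "apply_lesion", "activation_times", "couple_layers", "measure_cv",
]

SIGMA_FLOOR = 0.001          # S/m, lesions / non-conducting elements
BETA_PER_M = 1.4e5           # surface-to-volume ratio (1/m)
CM_F_PER_M2 = 0.01           # membrane capacitance (F/m^2)

#: default longitudinal conductivity (S/m), calibrated so a planar wave in
#: non-fibrotic pAF-remodeled LA-body tissue at 0.5 mm resolution conducts
#: at ~70 cm/s along fibers; transverse = /4 giving a ~2:1 velocity ratio.
DEFAULT_SIGMA_L = 0.25
DEFAULT_SIGMA_T = 0.0625


def sigma_to_diffusivity(sigma_s_per_m):
    """Conductivity (S/m) -> diffusivity (mm^2/ms)."""
    return np.asarray(sigma_s_per_m) / (BETA_PER_M * CM_F_PER_M2) * 1e3


@dataclass
class ConductivityField:
    sigma_l: np.ndarray          # (M,) S/m
    sigma_t: np.ndarray
    ablated: np.ndarray          # (M,) bool

    def __post_init__(self):
        self.sigma_l = np.maximum(np.asarray(self.sigma_l, float),
                                  SIGMA_FLOOR)
        self.sigma_t = np.maximum(np.asarray(self.sigma_t, float),
                                  SIGMA_FLOOR)
        self.ablated = np.asarray(self.ablated, bool)

    def copy(self):
        return ConductivityField(self.sigma_l.copy(), self.sigma_t.copy(),
                                 self.ablated.copy())


def default_conductivity(mesh: SurfaceMesh, sigma_l: float = DEFAULT_SIGMA_L,
                         sigma_t: float = DEFAULT_SIGMA_T):
    m = mesh.n_triangles
    return ConductivityField(np.full(m, sigma_l), np.full(m, sigma_t),
                             np.zeros(m, bool))


def apply_lesion(cond: ConductivityField, lesion) -> ConductivityField:
    """Floor conductivity of lesion elements (idempotent)."""
    elements = np.asarray(getattr(lesion, "elements", lesion), dtype=np.int64)
    out = cond.copy()
    if elements.size == 0:
        warnings.warn("empty lesion: conductivity unchanged")
        return out
    out.sigma_l[elements] = SIGMA_FLOOR
    out.sigma_t[elements] = SIGMA_FLOOR
    out.ablated[elements] = True
    return out


# ---------------------------------------------------------------------------
# FEM assembly

def assemble_diffusion(mesh: SurfaceMesh, cond: ConductivityField):
    """P1 stiffness/lumped-mass; returns csr A with dV/dt|diff = -A V."""
    pts = mesh.nodes
    tris = mesh.triangles
    areas = mesh.areas
    if (areas < 1e-12).any():
        raise ValueError("degenerate triangle (area < 1e-12 mm^2)")
    Dl = sigma_to_diffusivity(cond.sigma_l)
    Dt = sigma_to_diffusivity(cond.sigma_t)

    p0, p1, p2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    e1 = p1 - p0
    e2 = p2 - p0
    # local orthonormal in-plane frame
    u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    nrm = np.cross(e1, e2)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    v = np.cross(nrm, u)
    # 2D vertex coords in local frame
    x = np.zeros((len(tris), 3, 2))
    x[:, 1, 0] = (e1 * u).sum(1)
    x[:, 2, 0] = (e2 * u).sum(1)
    x[:, 2, 1] = (e2 * v).sum(1)
    # P1 gradients: grad phi_i = rot90 of opposite edge / 2A
    grads = np.empty((len(tris), 3, 2))
    for i in range(3):
        a, b = x[:, (i + 1) % 3], x[:, (i + 2) % 3]
        d = b - a
        grads[:, i, 0] = -d[:, 1]
        grads[:, i, 1] = d[:, 0]
    grads /= (2.0 * areas)[:, None, None]
    # fiber in local 2D
    f2 = np.stack([(mesh.fiber * u).sum(1), (mesh.fiber * v).sum(1)], axis=1)
    nf = np.linalg.norm(f2, axis=1, keepdims=True)
    f2 = np.where(nf > 1e-12, f2 / np.maximum(nf, 1e-30),
                  np.array([1.0, 0.0]))
    # D = Dt I + (Dl - Dt) f f^T
    Dmat = np.empty((len(tris), 2, 2))
    Dmat[:, 0, 0] = Dt + (Dl - Dt) * f2[:, 0] ** 2
    Dmat[:, 1, 1] = Dt + (Dl - Dt) * f2[:, 1] ** 2
    Dmat[:, 0, 1] = Dmat[:, 1, 0] = (Dl - Dt) * f2[:, 0] * f2[:, 1]

    dg = np.einsum("tab,tib->tia", Dmat, grads)
    ke = np.einsum("tia,tja->tij", dg, grads) * areas[:, None, None]

    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = sparse.coo_matrix((ke.ravel(), (rows, cols)),
                          shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    mass = np.zeros(mesh.n_nodes)
    np.add.at(mass, tris.ravel(), np.repeat(areas / 3.0, 3))
    A = sparse.diags(1.0 / mass) @ K
    return A.tocsr(), mass


def node_params_from_regions(mesh: SurfaceMesh, params_by_class=None,
                             laa_as_body: bool = False) -> np.ndarray:
    """Per-node (N, 12) ionic parameter array from triangle region labels.

    A node touching any PV-sleeve triangle takes PV parameters, then LAA,
    then LA-body (mitral-rim triangles use body parameters).
    """
    if params_by_class is None:
        params_by_class = {
            "LA_body": ionic.make_region_params("LA_body"),
            "PV": ionic.make_region_params("PV"),
            "LAA": ionic.make_region_params("LAA"),
        }
    body = params_by_class["LA_body"].to_array()
    out = np.tile(body, (mesh.n_nodes, 1))
    is_pv = np.isin(mesh.region, list(REGION_PV.values()))
    pv_nodes = np.unique(mesh.triangles[is_pv])
    laa_nodes = np.unique(mesh.triangles[mesh.region == REGION_LAA])
    if not laa_as_body and len(laa_nodes):
        out[laa_nodes] = params_by_class["LAA"].to_array()
    if len(pv_nodes):
        out[pv_nodes] = params_by_class["PV"].to_array()
    return out


# ---------------------------------------------------------------------------
# stimuli and recordings

@dataclass(frozen=True)
class Stimulus:
    """Transmembrane current injection (pA/pF, inward negative)."""

    t_start: float
    duration: float = 2.0
    amplitude: float = -40.0
    nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


def disc_nodes(mesh: SurfaceMesh, center, radius_mm: float = 1.0):
    """Node indices within a disc -- the default stimulus footprint."""
    c = np.asarray(center, dtype=float)
    if c.size == 2:
        c = np.append(c, 0.0)
    d = np.linalg.norm(mesh.nodes - c, axis=1)
    idx = np.flatnonzero(d <= radius_mm)
    if idx.size == 0:
        idx = np.array([int(np.argmin(d))])
    return idx


@dataclass
class Recording:
    frames: np.ndarray           # (T, N) float32, mV
    t: np.ndarray                # (T,) ms
    frame_interval: float
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self):
        return len(self.t)

    def save(self, path):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frames", data=self.frames, compression="gzip")
            fh.create_dataset("t", data=self.t)
            fh.attrs["frame_interval"] = self.frame_interval
            for k, vv in self.meta.items():
                fh.attrs[f"meta_{k}"] = vv

    @classmethod
    def load(cls, path):
        import h5py
        with h5py.File(path, "r") as fh:
            meta = {k[5:]: fh.attrs[k] for k in fh.attrs if
                    k.startswith("meta_")}
            return cls(fh["frames"][...], fh["t"][...],
                       float(fh.attrs["frame_interval"]), meta)

    def concat(self, other: "Recording") -> "Recording":
        return Recording(np.vstack([self.frames, other.frames]),
                         np.concatenate([self.t, other.t]),
                         self.frame_interval, {**self.meta, **other.meta})


class SimulationBlowupError(RuntimeError):
    def __init__(self, t_last):
        super().__init__(f"non-finite voltage; last good time {t_last} ms")
        self.t_last = t_last


@njit(cache=True)
def _tissue_loop(states, params, indptr, indices, data, dt, n_steps, t0,
                 stim_t0, stim_t1, stim_amp, stim_ptr, stim_nodes,
                 inf_t, rl_t, cur_t, rec_every, rec_frames):
    n = states.shape[0]
    stim = np.zeros(n)
    diff = np.empty(n)
    rec_i = 0
    for step in range(n_steps):
        t = t0 + step * dt
        stim[:] = 0.0
        for s in range(len(stim_t0)):
            if stim_t0[s] <= t < stim_t1[s]:
                for k in range(stim_ptr[s], stim_ptr[s + 1]):
                    stim[stim_nodes[k]] += stim_amp[s]
        # diffusion term at step start
        for i in range(n):
            acc = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                acc += data[jj] * states[indices[jj], 0]
            diff[i] = acc
        ionic.step_states(states, params, stim, dt, inf_t, rl_t, cur_t)
        for i in range(n):
            states[i, 0] -= dt * diff[i]
        if (step + 1) % rec_every == 0:
            ok = True
            for i in range(n):
                rec_frames[rec_i, i] = states[i, 0]
                if not np.isfinite(states[i, 0]):
                    ok = False
            rec_i += 1
            if not ok:
                return step + 1
    return n_steps


def run_simulation(A, params_per_node, duration_ms, *, dt_us: float = 20.0,
                   stimuli=(), states=None, t0: float = 0.0,
                   record_interval_ms: float = 1.0, tables=None):
    """Integrate the monodomain system for ``duration_ms``.

    ``A`` is the assembled diffusion operator (csr), ``params_per_node``
    an (N, 12) ionic parameter array.  Returns (Recording, final_states);
    pass ``states`` / ``t0`` to continue a previous run (e.g. after
    applying a lesion).  Deterministic for fixed inputs.
    """
    n = A.shape[0]
    dt = dt_us * 1e-3
    if states is None:
        states = np.tile(ionic.CRN_INIT, (n, 1))
    else:
        states = np.ascontiguousarray(states)
    params = np.ascontiguousarray(params_per_node)
    if tables is None:
        tables = ionic.build_tables(dt)
    inf_t, rl_t, cur_t = tables

    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(record_interval_ms / dt)))
    n_frames = n_steps // rec_every
    frames = np.empty((n_frames, n), dtype=np.float32)

    st0 = np.array([s.t_start for s in stimuli], dtype=float)
    st1 = np.array([s.t_end for s in stimuli], dtype=float)
    samp = np.array([s.amplitude for s in stimuli], dtype=float)
    sptr = np.zeros(len(stimuli) + 1, dtype=np.int64)
    for k, s in enumerate(stimuli):
        sptr[k + 1] = sptr[k] + len(s.nodes)
    snodes = (np.concatenate([np.asarray(s.nodes, np.int64)
                              for s in stimuli])
              if stimuli else np.empty(0, np.int64))

    done = _tissue_loop(states, params, A.indptr, A.indices, A.data, dt,
                        n_steps, t0, st0, st1, samp, sptr, snodes,
                        inf_t, rl_t, cur_t, rec_every, frames)
    t = t0 + dt * rec_every * (1 + np.arange(n_frames))
    if done < n_steps:
        raise SimulationBlowupError(t0 + done * dt)
    rec = Recording(frames, t, record_interval_ms * 1.0,
                    {"dt_us": dt_us, "t0": t0})
    return rec, states


# ---------------------------------------------------------------------------
# activation analysis

@dataclass
class ActivationMap:
    """Upward threshold-crossing times per node."""

    events_node: np.ndarray      # (K,) node index of each crossing
    events_t: np.ndarray         # (K,) crossing time, ms (interpolated)
    n_nodes: int
    threshold: float = -40.0

    def per_node(self) -> list:
        order = np.argsort(self.events_node, kind="stable")
        nn, tt = self.events_node[order], self.events_t[order]
        bounds = np.searchsorted(nn, np.arange(self.n_nodes + 1))
        return [tt[bounds[i]:bounds[i + 1]] for i in range(self.n_nodes)]

    def first_lat(self, after_ms: float = -np.inf) -> np.ndarray:
        """First crossing per node after ``after_ms``; NaN if unactivated."""
        lat = np.full(self.n_nodes, np.nan)
        m = self.events_t >= after_ms
        nn, tt = self.events_node[m], self.events_t[m]
        order = np.argsort(tt, kind="stable")[::-1]
        lat[nn[order]] = tt[order]
        return lat

    def mean_cycle_length(self) -> np.ndarray:
        """Per-node mean interval between successive activations (NaN with
        fewer than two activations)."""
        out = np.full(self.n_nodes, np.nan)
        for i, tt in enumerate(self.per_node()):
            if len(tt) >= 2:
                out[i] = np.mean(np.diff(tt))
        return out


def activation_times(recording: Recording, threshold_mv: float = -40.0,
                     blanking_ms: float = 5.0) -> ActivationMap:
    """Upward crossings of the threshold, linearly interpolated between
    frames; repeated crossings within ``blanking_ms`` are merged."""
    f = recording.frames
    below = f[:-1] < threshold_mv
    above = f[1:] >= threshold_mv
    fi, ni = np.nonzero(below & above)
    v0 = f[fi, ni].astype(float)
    v1 = f[fi + 1, ni].astype(float)
    frac = (threshold_mv - v0) / np.maximum(v1 - v0, 1e-12)
    tt = recording.t[fi] + frac * recording.frame_interval
    # blanking: drop crossings following a previous one too closely
    order = np.lexsort((tt, ni))
    ni, tt = ni[order], tt[order]
    keep = np.ones(len(tt), bool)
    if len(tt):
        same = ni[1:] == ni[:-1]
        close = np.diff(tt) < blanking_ms
        keep[1:] = ~(same & close)
    return ActivationMap(ni[keep], tt[keep], f.shape[1], threshold_mv)


# ---------------------------------------------------------------------------
# bilayer coupling and calibration helpers

def couple_layers(A_endo, A_epi, g_link_per_ms: float):
    """Resistively couple two node-matched layers.

    Returns a (2N, 2N) operator for the stacked system where each node i
    receives g * (V_other - V_self).  With large g the layers converge to
    a common monolayer solution; with g = 0 they are independent.
    """
    n = A_endo.shape[0]
    if A_epi.shape[0] != n:
        raise ValueError("layers must have matched node counts")
    g = float(g_link_per_ms)
    I = sparse.identity(n, format="csr")
    top = sparse.hstack([A_endo + g * I, -g * I])
    bot = sparse.hstack([-g * I, A_epi + g * I])
    return sparse.vstack([top, bot]).tocsr()


def measure_cv(length_mm=20.0, width_mm=4.0, h_mm=0.5, sigma_l=DEFAULT_SIGMA_L,
               sigma_t=DEFAULT_SIGMA_T, along_fiber=True, dt_us=20.0,
               params: ionic.IonicParams | None = None):
    """Planar-wave conduction velocity (cm/s) on a uniform strip."""
    from .geometry import build_sheet, SurfaceMesh as SM
    nodes, tris, _ = build_sheet((length_mm, width_mm), h_mm, jitter=0.0)
    fib = np.tile([1.0, 0.0, 0.0], (len(tris), 1))
    mesh = SM(nodes, tris, fib, np.zeros(len(tris), np.int64),
              np.ones(len(tris), np.int64))
    if not along_fiber:
        sigma_l, sigma_t = sigma_t, sigma_l  # propagate across fibers
    cond = ConductivityField(np.full(len(tris), sigma_l),
                             np.full(len(tris), sigma_t),
                             np.zeros(len(tris), bool))
    A, _ = assemble_diffusion(mesh, cond)
    p = (params or ionic.make_region_params("LA_body")).to_array()
    pn = np.tile(p, (len(nodes), 1))
    stim = Stimulus(1.0, 2.0, -40.0, np.flatnonzero(nodes[:, 0] < 1.0))
    rec, _ = run_simulation(A, pn, 60.0, dt_us=dt_us, stimuli=[stim],
                            record_interval_ms=0.5)
    amap = activation_times(rec)
    lat = amap.first_lat()
    mid = np.abs(nodes[:, 1] - width_mm / 2) < h_mm
    xa, xb = 0.3 * length_mm, 0.7 * length_mm
    ia = np.flatnonzero(mid & (np.abs(nodes[:, 0] - xa) < h_mm))
    ib = np.flatnonzero(mid & (np.abs(nodes[:, 0] - xb) < h_mm))
    ta = np.nanmean(lat[ia])
    tb = np.nanmean(lat[ib])
    if not np.isfinite(ta) or not np.isfinite(tb) or tb <= ta:
        return np.nan
    dx = np.mean(nodes[ib, 0]) - np.mean(nodes[ia, 0])
    return (dx / (tb - ta)) * 100.0  # mm/ms -> cm/s
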