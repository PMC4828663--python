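"""Virtual radiofrequency-ablation lesion geometry on the surface mesh.

Three lesion families:

* anatomical lines -- PV-isolation rings, a roof line joining the two
  superior rings, and a mitral line joining the left ring to the mitral
  boundary;
* PS-guided small lesions -- circles, perforated circles (gaps let
  wavefronts through so the scar cannot anchor a new reentry), lines and
  crosses, 0.5-1.5 cm in diameter/length, placed at density-map maxima;
* streamlining -- 4-8 lines that follow the gradient of the sinus local
  activation time (LAT) from the (earliest LA LAT + 10 ms) isochrone to
  the mitral boundary, confining propagation to sinus-like lanes.

Lesions are sets of triangles whose conductivity the solver floors to
0.001 S/m.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import SurfaceMesh, REGION_PV, REGION_MITRAL_RIM

__all__ = [
    "LesionSet", "LesionError", "pvi_ring", "geodesic_line", "lesion_shape",
    "place_by_density", "streamline_lines", "nonlesion_components",
    "lat_gradient", "extract_isochrone",
]

LESION_SHAPES = ("pvi_ring", "roof_line", "mitral_line", "circle",
                 "perforated_circle", "line", "cross", "streamline")
SIZE_RANGE_CM = (0.5, 1.5)


class LesionError(ValueError):
    pass


@dataclass
class LesionSet:
    name: str
    shape: str
    elements: np.ndarray
    center: np.ndarray | None = None
    size_cm: float | None = None
    width_mm: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape not in LESION_SHAPES:
            raise LesionError(f"unknown lesion shape {self.shape!r}")
        if self.shape in ("circle", "perforated_circle", "line", "cross"):
            if not (SIZE_RANGE_CM[0] - 1e-9 <= self.size_cm
                    <= SIZE_RANGE_CM[1] + 1e-9):
                raise LesionError("PS-guided lesion size must be "
                                  "0.5-1.5 cm")
        self.elements = np.unique(np.asarray(self.elements, np.int64))

    def to_dict(self) -> dict:
        return {"name": self.name, "shape": self.shape,
                "elements": self.elements.tolist(),
                "center": None if self.center is None
                else np.asarray(self.center).tolist(),
                "size_cm": self.size_cm, "width_mm": self.width_mm}

    @classmethod
    def from_dict(cls, d: dict) -> "LesionSet":
        d = dict(d)
        if d.get("center") is not None:
            d["center"] = np.asarray(d["center"])
        d.pop("meta", None)
        return cls(**d)


def save_lesions(lesions, path) -> None:
    """Serialize a list of lesion sets as JSON (named element lists)."""
    with open(path, "w") as fh:
        json.dump([l.to_dict() for l in np.atleast_1d(lesions)], fh)


def load_lesions(path) -> list[LesionSet]:
    with open(path) as fh:
        return [LesionSet.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# connectivity helpers

def _tri_adjacency(mesh: SurfaceMesh, keep: np.ndarray):
    """Sparse adjacency of kept triangles across shared edges."""
    et = mesh.edge_tri
    inner = (et[:, 0] >= 0) & (et[:, 1] >= 0)
    a, b = et[inner, 0], et[inner, 1]
    ok = keep[a] & keep[b]
    a, b = a[ok], b[ok]
    n = mesh.n_triangles
    g = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    return g + g.T


def nonlesion_components(mesh: SurfaceMesh, lesion_elements,
                         within: np.ndarray | None = None) -> np.ndarray:
    """Component label per triangle on the conducting (non-lesion)
    subgraph; lesion triangles (and triangles outside ``within``) get
    label -1."""
    keep = np.ones(mesh.n_triangles, bool) if within is None \
        else np.asarray(within, bool).copy()
    keep[np.asarray(lesion_elements, np.int64)] = False
    _, lab = connected_components(_tri_adjacency(mesh, keep),
                                  directed=False)
    lab = lab.astype(np.int64)
    lab[~keep] = -1
    # relabel compactly over kept triangles
    u = np.unique(lab[keep])
    remap = {v: i for i, v in enumerate(u)}
    out = np.array([remap[v] if v >= 0 else -1 for v in lab])
    return out


def _connected(mesh, lesion_elements, tris_a, tris_b) -> bool:
    lab = nonlesion_components(mesh, lesion_elements)
    la = set(lab[tris_a]) - {-1}
    lb = set(lab[tris_b]) - {-1}
    return bool(la & lb)


# ---------------------------------------------------------------------------
# anatomical lesions

def pvi_ring(mesh: SurfaceMesh, pv_label: str, width_mm: float = 2.0
             ) -> LesionSet:
    """Closed ablation band encircling a PV ostium.

    The band sits just outside the PV sleeve annulus; construction is
    verified by checking that no conducting path remains between sleeve
    and LA body.
    """
    if width_mm <= 0:
        raise LesionError("ring width must be positive")
    cfg = mesh.config
    if cfg is None or pv_label not in cfg.ostia:
        raise LesionError(f"mesh has no ostium {pv_label!r}")
    cx, cy = cfg.ostia[pv_label]
    # band starts just inside the sleeve rim so no conducting sliver is
    # left between sleeve and ring
    r0 = cfg.ostium_radius_mm + cfg.pv_sleeve_mm - 0.5 * cfg.edge_length_mm
    cent = mesh.centroids
    d = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
    elems = np.flatnonzero((d >= r0) & (d <= r0 + max(width_mm,
                                                      2.5 * cfg.edge_length_mm)))
    les = LesionSet(f"PVI_{pv_label}", "pvi_ring", elems,
                    np.array([cx, cy]), width_mm=width_mm)
    sleeve = np.flatnonzero(mesh.region == REGION_PV[pv_label])
    far = np.flatnonzero((mesh.region == 0)
                         & (np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
                            > r0 + width_mm + 4.0))
    if _connected(mesh, elems, sleeve, far):
        raise LesionError(f"PVI ring around {pv_label} is not closed")
    return les


def _graph_path(mesh: SurfaceMesh, p_start, p_end):
    """Shortest node path (Dijkstra on edges), then straightened."""
    g = nx.Graph()
    lens = mesh.edge_lengths
    for (a, b), l in zip(mesh.edges, lens):
        g.add_edge(int(a), int(b), weight=float(l))
    tree = cKDTree(mesh.nodes[:, :2])
    s = int(tree.query(np.asarray(p_start)[:2])[1])
    e = int(tree.query(np.asarray(p_end)[:2])[1])
    try:
        path = nx.shortest_path(g, s, e, weight="weight")
    except nx.NetworkXNoPath:
        raise LesionError("endpoints are not connected on the mesh")
    pts = mesh.nodes[path].copy()
    # straighten: Laplacian smoothing of interior points (endpoints fixed);
    # on a flat or gently curved sheet this converges to the geodesic
    for _ in range(200):
        if len(pts) < 3:
            break
        pts[1:-1] = 0.5 * (pts[:-2] + pts[2:])
    return pts


def _rasterize_polyline(mesh: SurfaceMesh, pts, width_mm):
    """Triangles whose centroid lies within width/2 of the polyline
    (always at least one-element wide)."""
    cent = mesh.centroids
    half = max(width_mm / 2.0, 0.75 * float(np.mean(mesh.edge_lengths)))
    dmin = np.full(mesh.n_triangles, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        L2 = (ab * ab).sum()
        if L2 < 1e-18:
            d = np.linalg.norm(cent - a, axis=1)
        else:
            s = ((cent - a) @ ab / L2).clip(0.0, 1.0)
            d = np.linalg.norm(cent - (a + s[:, None] * ab), axis=1)
        np.minimum(dmin, d, out=dmin)
    return np.flatnonzero(dmin <= half)


def geodesic_line(mesh: SurfaceMesh, p_start, p_end, width_mm: float = 2.0,
                  name: str = "line", shape: str = "roof_line") -> LesionSet:
    """Ablation band along the shortest surface path between two points."""
    pts = _graph_path(mesh, p_start, p_end)
    elems = _rasterize_polyline(mesh, pts, width_mm)
    if len(elems) == 0:
        raise LesionError("empty lesion band")
    return LesionSet(name, shape, elems, width_mm=width_mm,
                     meta={"path_length_mm":
                           float(np.linalg.norm(np.diff(pts, axis=0),
                                                axis=1).sum())})


# ---------------------------------------------------------------------------
# PS-guided small lesions

def lesion_shape(mesh: SurfaceMesh, center, shape: str, size_cm: float,
                 width_mm: float = 2.0, n_gaps: int = 4,
                 gap_mm: float = 2.0, name: str | None = None) -> LesionSet:
    """Parameterized small lesion centred at ``center`` (mm).

    circle: closed annulus of the given diameter; perforated_circle: the
    same with ``n_gaps`` symmetric gaps of ``gap_mm`` so the non-lesion
    tissue stays globally connected; line: straight band along x; cross:
    two orthogonal bands.
    """
    c = np.asarray(center, float)[:2]
    cent = mesh.centroids
    size_mm = size_cm * 10.0
    dx, dy = cent[:, 0] - c[0], cent[:, 1] - c[1]
    d = np.hypot(dx, dy)
    half_w = max(width_mm / 2.0, 0.75 * float(np.mean(mesh.edge_lengths)))
    if shape in ("circle", "perforated_circle"):
        r = size_mm / 2.0
        on = np.abs(d - r) <= half_w
        if shape == "perforated_circle":
            ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
            gap_half = (gap_mm / 2.0) / max(r, 1e-9)  # radians
            for k in range(n_gaps):
                a0 = 2 * np.pi * k / n_gaps
                da = np.abs(np.mod(ang - a0 + np.pi, 2 * np.pi) - np.pi)
                on &= ~(da <= gap_half)
        elems = np.flatnonzero(on)
    elif shape == "line":
        elems = np.flatnonzero((np.abs(dy) <= half_w)
                               & (np.abs(dx) <= size_mm / 2.0))
    elif shape == "cross":
        arm1 = (np.abs(dy) <= half_w) & (np.abs(dx) <= size_mm / 2.0)
        arm2 = (np.abs(dx) <= half_w) & (np.abs(dy) <= size_mm / 2.0)
        elems = np.flatnonzero(arm1 | arm2)
    else:
        raise LesionError(f"unknown PS-guided shape {shape!r}")
    if len(elems) == 0:
        raise LesionError("lesion lies entirely off-mesh")
    # clipped construction: realized lesion area well below the nominal
    # band area means part of the shape fell outside the mesh
    band_w = 2.0 * half_w
    r = size_mm / 2.0
    if shape in ("circle", "perforated_circle"):
        expected = 2.0 * np.pi * r * band_w
        if shape == "perforated_circle":
            expected *= max(0.0, 1.0 - n_gaps * gap_mm / (2 * np.pi * r))
    elif shape == "line":
        expected = size_mm * band_w
    else:
        expected = 2.0 * size_mm * band_w - band_w ** 2
    if mesh.areas[elems].sum() < 0.6 * expected:
        warnings.warn("lesion clipped at the mesh boundary")
    return LesionSet(name or f"{shape}_{size_cm:g}cm", shape, elems,
                     np.append(c, 0.0), size_cm, width_mm)


def place_by_density(dmap, mesh: SurfaceMesh, subdivision: int) -> np.ndarray:
    """Centroid of the maximum-density element in a subdivision (ties ->
    lowest element index; all-zero -> geometric centroid, with warning)."""
    m = np.flatnonzero(mesh.subdivision == subdivision)
    vals = dmap.value[m]
    if vals.max() <= 0:
        warnings.warn(f"no PS density in subdivision {subdivision}; "
                      "using its geometric centroid")
        w = mesh.areas[m]
        return (mesh.centroids[m] * w[:, None]).sum(0) / w.sum()
    return mesh.centroids[m[int(np.argmax(vals))]]


# ---------------------------------------------------------------------------
# streamlining

def lat_gradient(mesh: SurfaceMesh, lat: np.ndarray) -> np.ndarray:
    """Per-triangle gradient (P1) of a node field; NaN rows where any
    vertex is unactivated."""
    tris = mesh.triangles
    p = mesh.nodes[tris]
    v = lat[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2)
    a2 = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.maximum(a2, 1e-30)
    g = ((v[:, 1] - v[:, 0])[:, None] * np.cross(e2, n)
         + (v[:, 2] - v[:, 0])[:, None] * np.cross(n, e1))
    g /= np.maximum(a2, 1e-30)
    g[~np.isfinite(v).all(axis=1)] = np.nan
    return g


def extract_isochrone(mesh: SurfaceMesh, lat: np.ndarray, level_ms: float):
    """Ordered point chain(s) where the LAT field crosses a level."""
    e = mesh.edges
    la, lb = lat[e[:, 0]], lat[e[:, 1]]
    ok = np.isfinite(la) & np.isfinite(lb)
    cross = ok & (np.minimum(la, lb) <= level_ms) \
        & (np.maximum(la, lb) > level_ms)
    idx = np.flatnonzero(cross)
    if len(idx) == 0:
        raise LesionError(f"no isochrone at {level_ms} ms")
    w = (level_ms - la[idx]) / (lb[idx] - la[idx])
    pts = (mesh.nodes[e[idx, 0]] * (1 - w)[:, None]
           + mesh.nodes[e[idx, 1]] * w[:, None])
    # order by chaining nearest neighbours
    order = [0]
    used = np.zeros(len(pts), bool)
    used[0] = True
    tree = cKDTree(pts)
    while used.sum() < len(pts):
        d, js = tree.query(pts[order[-1]], k=min(8, len(pts)))
        nxt = next((int(j) for j in np.atleast_1d(js) if not used[j]), None)
        if nxt is None:
            nxt = int(np.flatnonzero(~used)[0])
        order.append(nxt)
        used[nxt] = True
    return pts[order]


def streamline_lines(mesh: SurfaceMesh, lat: np.ndarray, n_lines: int = 4,
                     width_mm: float = 2.0, seed_offset_ms: float = 10.0,
                     step_mm: float = 0.5, max_len_mm: float = 200.0,
                     boundary: str = "mitral") -> list[LesionSet]:
    """Ablation lines along the sinus activation gradient.

    Seeds are spaced evenly by arc length along the isochrone
    ``seed_offset_ms`` after the earliest LA activation; each path is
    integrated along the normalized interpolated LAT gradient (first
    order, fixed step) until it reaches the mitral boundary, then
    rasterized into a band.  Raises for paths that never reach it.
    """
    if n_lines < 2:
        raise LesionError("need at least two streamlines")
    lat = np.asarray(lat, float)
    level = np.nanmin(lat) + seed_offset_ms
    chain = extract_isochrone(mesh, lat, level)
    s = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(chain, axis=0), axis=1))])
    targets = s[-1] * (np.arange(n_lines) + 0.5) / n_lines
    seeds = np.stack([np.interp(targets, s, chain[:, k]) for k in range(3)],
                     axis=1)

    grad = lat_gradient(mesh, lat)
    cent = mesh.centroids
    tree = cKDTree(cent)
    # termination: stepping off the mesh (walked out through the outer
    # boundary) or entering the labelled mitral rim
    mitral = set(int(b) for b in
                 np.flatnonzero(mesh.region == REGION_MITRAL_RIM)) \
        if boundary == "mitral" else set(int(b) for b in
                                         np.asarray(boundary, np.int64))
    off_mesh = 1.3 * float(np.mean(mesh.edge_lengths))

    lesions = []
    for li, p0 in enumerate(seeds):
        path = [p0.copy()]
        p = p0.copy()
        last_dir = None
        n_steps = int(max_len_mm / step_mm)
        reached = False
        for _ in range(n_steps):
            tri = int(tree.query(p)[1])
            g = grad[tri]
            if not np.isfinite(g).all() or np.linalg.norm(g) < 1e-9:
                if last_dir is None:
                    raise LesionError(f"streamline {li} starts on a "
                                      "plateau")
                d = last_dir  # continue straight across the plateau
            else:
                d = g / np.linalg.norm(g)
                if last_dir is not None and np.dot(d, last_dir) < 0:
                    d = -d  # keep marching monotonically
            p = p + step_mm * d
            last_dir = d
            path.append(p.copy())
            tri = int(tree.query(p)[1])
            if tri in mitral or np.linalg.norm(cent[tri] - p) > off_mesh:
                reached = True
                break
        if not reached:
            raise LesionError(f"streamline {li} did not reach the mitral "
                              f"boundary within {max_len_mm} mm")
        elems = _rasterize_polyline(mesh, np.asarray(path), width_mm)
        lesions.append(LesionSet(f"streamline_{li}", "streamline", elems,
                                 p0, width_mm=width_mm))
    return lesions
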