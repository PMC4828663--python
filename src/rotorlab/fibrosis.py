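"""Stochastic interstitial fibrosis on the atrial surface.

Mesh-element edges are selected as fibrotic with probability proportional
to the local enhancement (LGE) likelihood and to their alignment with the
fiber direction: an edge parallel to fibers is four times more likely to
be selected than a perpendicular one, via the weight

    w(theta) = 4 cos^2(theta) + sin^2(theta),

where theta is the acute angle between the edge and the fiber.  Each edge
draws u ~ U(0,1) and is selected iff alpha * w * L > u, with L the edge's
LGE likelihood and alpha a global weighting constant.  alpha is calibrated
so the median total length of connected fibrotic-edge components hits a
target (670 um, the reported scale of interstitial fibrosis in aging
atrial bundles).  Selected edges are then *split* -- nodes duplicated so
triangles on opposite sides decouple -- which imposes no-flux
microstructural barriers in the downstream monodomain solve.  Triangles
with all three edges selected are removed from the mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import SurfaceMesh

__all__ = [
    "FibrosisMap", "CalibrationError", "edge_selection_weight",
    "edge_fiber_angles", "edge_lge", "select_fibrotic_edges",
    "calibrate_alpha", "split_edges",
]

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when the target median cluster length is unreachable."""


@dataclass
class FibrosisMap:
    selected: np.ndarray           # (E,) bool
    alpha: float
    seed: int
    removed_elements: np.ndarray   # triangle indices with all 3 edges selected
    component_edges: list          # list of edge-index arrays
    component_lengths_um: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def median_component_um(self) -> float:
        if len(self.component_lengths_um) == 0:
            return 0.0
        return float(np.median(self.component_lengths_um))

    def components_to_csv(self, path) -> None:
        """Export the component-length table (one row per connected
        fibrotic-edge component)."""
        import pandas as pd
        pd.DataFrame({
            "component": np.arange(len(self.component_lengths_um)),
            "n_edges": [len(g) for g in self.component_edges],
            "length_um": self.component_lengths_um,
        }).to_csv(path, index=False)


def edge_selection_weight(theta):
    """Anisotropic selection weight 4 cos^2 + sin^2 for theta in [0, pi/2]."""
    theta = np.asarray(theta, dtype=float)
    if (theta < -1e-12).any() or (theta > np.pi / 2 + 1e-12).any():
        raise ValueError("theta must be an acute angle in [0, pi/2]")
    w = 4.0 * np.cos(theta) ** 2 + np.sin(theta) ** 2
    return float(w) if w.ndim == 0 else w


def edge_fiber_angles(mesh: SurfaceMesh) -> np.ndarray:
    """Acute angle between each edge and the local fiber direction.

    The local fiber is the sign-aligned average of the two adjacent
    triangles' fibers (one triangle's on the boundary).
    """
    et = mesh.edge_tri
    f1 = mesh.fiber[et[:, 0]]
    f2 = np.where((et[:, 1] >= 0)[:, None], mesh.fiber[et[:, 1].clip(0)], f1)
    sign = np.where((f1 * f2).sum(axis=1) < 0, -1.0, 1.0)
    f = f1 + sign[:, None] * f2
    f /= np.maximum(np.linalg.norm(f, axis=1, keepdims=True), 1e-30)
    ev = mesh.nodes[mesh.edges[:, 1]] - mesh.nodes[mesh.edges[:, 0]]
    ev /= np.maximum(np.linalg.norm(ev, axis=1, keepdims=True), 1e-30)
    c = np.abs((ev * f).sum(axis=1)).clip(0.0, 1.0)
    return np.arccos(c)


def edge_lge(mesh: SurfaceMesh, lge) -> np.ndarray:
    """Per-edge likelihood: mean over adjacent triangles."""
    v = np.asarray(lge.value if hasattr(lge, "value") else lge, dtype=float)
    et = mesh.edge_tri
    l1 = v[et[:, 0]]
    l2 = np.where(et[:, 1] >= 0, v[et[:, 1].clip(0)], l1)
    return 0.5 * (l1 + l2)


def _component_lengths(edges, n_nodes, lengths_mm, sel):
    """Component edge-index groups and total lengths (um) of the selected
    subgraph (edges connected through shared nodes)."""
    if len(sel) == 0:
        return [], np.empty(0)
    e = edges[sel]
    g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                   shape=(n_nodes, n_nodes))
    _, nodelab = connected_components(g + g.T, directed=False)
    elab = nodelab[e[:, 0]]
    uniq, inv = np.unique(elab, return_inverse=True)
    lens = np.bincount(inv, weights=lengths_mm[sel]) * 1000.0
    order = np.argsort(inv, kind="stable")
    starts = np.searchsorted(inv[order], np.arange(len(uniq)))
    groups = np.split(sel[order], starts[1:])
    return groups, lens


def select_fibrotic_edges(mesh: SurfaceMesh, lge, alpha: float,
                          seed: int = 0) -> FibrosisMap:
    """Stochastic edge selection: alpha * w(theta) * L > u ~ U(0,1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    w = edge_selection_weight(edge_fiber_angles(mesh))
    L = edge_lge(mesh, lge)
    rng = np.random.default_rng(seed)
    u = rng.random(len(mesh.edges))
    selected = alpha * w * L > u
    removed = np.flatnonzero(selected[mesh.tri_edges].all(axis=1))
    groups, lens = _component_lengths(mesh.edges, mesh.n_nodes,
                                      mesh.edge_lengths,
                                      np.flatnonzero(selected))
    return FibrosisMap(selected, float(alpha), int(seed), removed,
                       groups, lens)


def _mean_median_um(mesh, lge, alpha, seeds, wL=None, lengths=None) -> float:
    if wL is None:
        wL = edge_selection_weight(edge_fiber_angles(mesh)) \
            * edge_lge(mesh, lge)
    if lengths is None:
        lengths = mesh.edge_lengths
    meds = []
    for s in seeds:
        u = np.random.default_rng(s).random(len(wL))
        sel = np.flatnonzero(alpha * wL > u)
        _, lens = _component_lengths(mesh.edges, mesh.n_nodes, lengths, sel)
        if len(lens):
            meds.append(np.median(lens))
    return float(np.mean(meds)) if meds else 0.0


def calibrate_alpha(mesh: SurfaceMesh, lge, target_median_um: float = 670.0,
                    seed: int = 0, n_seeds: int = 20, tol_um: float = 50.0,
                    max_iter: int = 40) -> tuple[float, float]:
    """Bisect alpha until the seed-averaged median component length hits
    the target.  Returns (alpha, achieved_median_um)."""
    L = edge_lge(mesh, lge)
    if not (L > 0).any():
        raise CalibrationError("LGE likelihood is zero everywhere")
    if target_median_um <= 0:
        raise ValueError("target must be positive")
    seeds = seed + np.arange(n_seeds)
    wL = edge_selection_weight(edge_fiber_angles(mesh)) * L
    lengths = mesh.edge_lengths

    def f(a):
        return _mean_median_um(mesh, lge, a, seeds, wL, lengths)

    lo, flo = 1e-3, f(1e-3)
    hi = 0.5
    fhi = f(hi)
    while fhi < target_median_um and hi < 1e4:
        hi *= 2.0
        fhi = f(hi)
    if fhi < target_median_um:
        raise CalibrationError(
            f"target {target_median_um} um unreachable; median saturates at "
            f"{fhi:.0f} um (range [{flo:.0f}, {fhi:.0f}])")
    if flo > target_median_um + tol_um:
        raise CalibrationError(
            f"target {target_median_um} um below achievable minimum "
            f"{flo:.0f} um")

    alpha, achieved = hi, fhi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # alpha spans decades; bisect in log space
        fmid = f(mid)
        if abs(fmid - target_median_um) <= tol_um * 0.5:
            return float(mid), fmid
        if fmid < target_median_um:
            lo = mid
        else:
            hi = mid
        alpha, achieved = mid, fmid
        if hi / lo < 1.0005:
            break
    if abs(achieved - target_median_um) > tol_um:
        raise CalibrationError(
            f"calibration stalled at median {achieved:.0f} um "
            f"(target {target_median_um} +/- {tol_um})")
    return float(alpha), achieved


# ---------------------------------------------------------------------------
# edge splitting (no-flux clefts)

def _cycle_closing_edges(mesh: SurfaceMesh, sel: np.ndarray) -> np.ndarray:
    """Edge ids whose removal breaks all cycles of the selected subgraph
    (non-tree edges of a spanning forest)."""
    idx = np.flatnonzero(sel)
    parent = np.arange(mesh.n_nodes)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    closers = []
    for e in idx:
        a, b = mesh.edges[e]
        ra, rb = find(a), find(b)
        if ra == rb:
            closers.append(e)
        else:
            parent[ra] = rb
    return np.asarray(closers, dtype=np.int64)


def split_edges(mesh: SurfaceMesh, fibmap: FibrosisMap) -> SurfaceMesh:
    """Duplicate nodes along fibrotic paths so that triangles on opposite
    sides of a selected edge no longer share them (open clefts).

    Around every node the fan of incident triangles is cut at each
    selected interior edge; each resulting sector keeps its own copy of
    the node.  At a cleft tip (a single cut in a cyclic fan) the fan is
    divided geometrically by the cleft line, so an isolated interior split
    edge duplicates both of its endpoints.  Selected edges that would
    close a loop (fully disconnecting an island) are left un-split and
    logged.  Triangles flagged as removed are dropped.  Coordinates are
    unchanged, so total surface area is conserved exactly.
    """
    selected = fibmap.selected.copy()
    if not selected.any() and len(fibmap.removed_elements) == 0:
        return mesh

    closers = _cycle_closing_edges(mesh, selected)
    if len(closers):
        log.info("leaving %d loop-closing fibrotic edges un-split to avoid "
                 "disconnecting enclosed patches", len(closers))
        selected[closers] = False

    keep_tri = np.ones(mesh.n_triangles, dtype=bool)
    keep_tri[fibmap.removed_elements] = False

    tris = mesh.triangles.copy()
    edges = mesh.edges
    # incident (triangle, corner) lists per node, removed triangles excluded
    tri_ids = np.repeat(np.arange(mesh.n_triangles), 3)
    corner = np.tile(np.arange(3), mesh.n_triangles)
    nodes_flat = mesh.triangles.ravel()
    live = keep_tri[tri_ids]
    order = np.argsort(nodes_flat[live], kind="stable")
    nf, ti, co = nodes_flat[live][order], tri_ids[live][order], \
        corner[live][order]
    starts = np.searchsorted(nf, np.arange(mesh.n_nodes))
    ends = np.searchsorted(nf, np.arange(mesh.n_nodes), side="right")

    # split set: selected, interior (two live adjacent triangles)
    et = mesh.edge_tri
    live_adj = np.where(et >= 0, keep_tri[et.clip(0)], False)
    split = selected & live_adj.all(axis=1)

    # per-node incident split edges
    node_split: dict[int, list[int]] = {}
    for e in np.flatnonzero(split):
        a, b = edges[e]
        node_split.setdefault(int(a), []).append(e)
        node_split.setdefault(int(b), []).append(e)

    new_coords: list[np.ndarray] = []
    next_id = mesh.n_nodes

    for v, sedges in node_split.items():
        fan_t = ti[starts[v]:ends[v]]
        fan_c = co[starts[v]:ends[v]]
        if len(fan_t) <= 1:
            continue
        pos = {int(t): k for k, t in enumerate(fan_t)}
        # union-find over fan triangles; join across non-split shared edges
        par = list(range(len(fan_t)))

        def find(x):
            while par[x] != x:
                par[x] = par[par[x]]
                x = par[x]
            return x

        cut_edges = set(int(e) for e in sedges)
        for k, t in enumerate(fan_t):
            for eid in mesh.tri_edges[t]:
                if int(eid) in cut_edges:
                    continue
                a, b = edges[eid]
                if a != v and b != v:
                    continue
                o1, o2 = et[eid]
                if o1 < 0 or o2 < 0:
                    continue
                other = int(o2) if int(o1) == t else int(o1)
                if other in pos:
                    ra, rb = find(k), find(pos[other])
                    if ra != rb:
                        par[ra] = rb
        roots = [find(k) for k in range(len(fan_t))]
        groups: dict[int, list[int]] = {}
        for k, r in enumerate(roots):
            groups.setdefault(r, []).append(k)
        if len(groups) == 1 and len(sedges) == 1:
            # cleft tip inside a cyclic fan: divide geometrically by the
            # cleft line so the slit is open at its ends
            e = sedges[0]
            a, b = edges[e]
            w = int(b) if int(a) == v else int(a)
            d = mesh.nodes[w] - mesh.nodes[v]
            nvec = mesh.normals[fan_t[0]]
            side = {}
            for k, t in enumerate(fan_t):
                c = mesh.nodes[mesh.triangles[t]].mean(axis=0) \
                    - mesh.nodes[v]
                side[k] = np.dot(np.cross(d, c), nvec) >= 0
            groups = {0: [k for k in side if side[k]],
                      1: [k for k in side if not side[k]]}
            groups = {r: g for r, g in groups.items() if g}
        if len(groups) <= 1:
            continue
        group_list = sorted(groups.values(), key=lambda g: min(g))
        for g in group_list[1:]:
            new_coords.append(mesh.nodes[v])
            for k in g:
                tris[fan_t[k], fan_c[k]] = next_id
            next_id += 1

    nodes = (np.vstack([mesh.nodes, np.array(new_coords)])
             if new_coords else mesh.nodes.copy())
    tris = tris[keep_tri]
    used = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = SurfaceMesh(nodes[used], remap[tris], mesh.fiber[keep_tri].copy(),
                      mesh.region[keep_tri].copy(),
                      mesh.subdivision[keep_tri].copy(), mesh.config)
    return out
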