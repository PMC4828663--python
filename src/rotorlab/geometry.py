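"""Synthetic left-atrial surface geometry.

Builds a triangulated monolayer stand-in for a patient-derived left atrium:
a flat (optionally domed) sheet with four circular pulmonary-vein (PV)
ostium holes, a mitral boundary, a per-triangle fiber field with an abrupt
~90 deg rotation across each PV rim, an LGE (late-gadolinium-enhancement)
likelihood field whose per-subdivision normalized densities match
configurable targets, and the eight posterior/anterior analysis
subdivisions used for regional rotor statistics.

Coordinates are millimetres.  The posterior half of the sheet is y < Ly/2
(subdivisions 1-4, left to right), the anterior half y >= Ly/2
(subdivisions 5-8).
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GeometryError",
    "GeometryConfig",
    "SurfaceMesh",
    "LgeLikelihood",
    "build_la_surface",
    "build_sheet",
    "build_lge_map",
    "assign_subdivisions",
    "validate_mesh",
    "write_vtk",
    "read_vtk",
]

# region label codes (per triangle)
REGION_LA_BODY = 0
REGION_PV = {"RSPV": 1, "RIPV": 2, "LSPV": 3, "LIPV": 4}
REGION_LAA = 5
REGION_MITRAL_RIM = 6
REGION_NAMES = {
    0: "LA_body", 1: "PV1_RSPV", 2: "PV2_RIPV", 3: "PV3_LSPV",
    4: "PV4_LIPV", 5: "LAA", 6: "mitral_rim",
}

# printed population-average normalized fibrosis densities, subdivisions 1-8
DEFAULT_LGE_TARGETS = (0.84, 0.28, 1.0, 0.57, 0.42, 0.35, 0.25, 0.20)


class GeometryError(ValueError):
    """Invalid geometric configuration (overlapping ostia, bad targets...)."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic LA surface.

    ``edge_length_mm`` is the target *mean* edge length; the structured
    grid spacing is chosen so the mean over axis + diagonal edges hits it.
    ``ostia`` maps PV names to (x, y) centres; ``ostium_radius_mm`` is the
    hole radius, ``pv_sleeve_mm`` the width of the PV-labelled annulus
    around each hole where fibers are rotated by 90 degrees, and
    ``fiber_band_mm`` the width of the transition band outside the sleeve
    over which the rotation decays back to the body direction.
    """

    size_mm: tuple[float, float] = (50.0, 50.0)
    edge_length_mm: float = 0.5
    ostia: dict = field(default_factory=lambda: {
        # two posterior (y < Ly/2: RIPV/LIPV inferior) and two anterior
        "RIPV": (37.5, 12.5), "LIPV": (12.5, 12.5),
        "RSPV": (37.5, 37.5), "LSPV": (12.5, 37.5),
    })
    ostium_radius_mm: float = 4.0
    pv_sleeve_mm: float = 3.0
    fiber_band_mm: float = 2.0
    fiber_base_deg: float = 0.0
    laa_center: tuple[float, float] = (4.0, 46.0)
    laa_radius_mm: float = 4.0
    mitral_rim_mm: float = 1.5
    jitter: float = 0.15           # interior node jitter, fraction of grid h
    dome_height_mm: float = 0.0    # 0 = flat sheet; >0 lifts to a shell
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_mm"] = list(self.size_mm)
        d["laa_center"] = list(self.laa_center)
        d["ostia"] = {k: list(v) for k, v in self.ostia.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        d = dict(d)
        for key in ("size_mm", "laa_center"):
            if key in d:
                d[key] = tuple(d[key])
        if "ostia" in d:
            d["ostia"] = {k: tuple(v) for k, v in d["ostia"].items()}
        return cls(**d)

    def save(self, path) -> None:
        """Write as YAML (or JSON if the path ends in .json)."""
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GeometryConfig":
        with open(path) as fh:
            d = (json.load(fh) if str(path).endswith(".json")
                 else yaml.safe_load(fh))
        return cls.from_dict(d)


@dataclass
class SurfaceMesh:
    """Triangulated manifold-with-boundary surface with per-triangle data."""

    nodes: np.ndarray              # (N, 3) float, mm
    triangles: np.ndarray          # (M, 3) int, consistently CCW in xy
    fiber: np.ndarray              # (M, 3) unit vectors in triangle plane
    region: np.ndarray             # (M,) int codes, see REGION_NAMES
    subdivision: np.ndarray        # (M,) int in 1..8 (0 = unassigned)
    config: GeometryConfig | None = None

    # ---- derived connectivity (computed lazily, invalidated by copy) ----
    _edges: np.ndarray | None = None
    _edge_tri: np.ndarray | None = None
    _tri_edges: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def _build_edges(self) -> None:
        t = self.triangles
        raw = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        key = np.sort(raw, axis=1)
        edges, inv = np.unique(key, axis=0, return_inverse=True)
        self._edges = edges
        # edge -> adjacent triangles (up to 2; -1 where absent)
        edge_tri = np.full((len(edges), 2), -1, dtype=np.int64)
        tri_ids = np.tile(np.arange(len(t)), 3)
        order = np.argsort(inv, kind="stable")
        einv, tids = inv[order], tri_ids[order]
        starts = np.searchsorted(einv, np.arange(len(edges)))
        ends = np.searchsorted(einv, np.arange(len(edges)), side="right")
        for e in range(len(edges)):
            adj = tids[starts[e]:ends[e]]
            if len(adj) > 2:
                raise GeometryError(f"non-manifold edge {edges[e]}")
            edge_tri[e, :len(adj)] = adj
        self._edge_tri = edge_tri
        self._tri_edges = inv.reshape(3, len(t)).T  # (M,3) edge ids per tri

    @property
    def edges(self) -> np.ndarray:
        """Unique node-index pairs (E, 2), sorted within each pair."""
        if self._edges is None:
            self._build_edges()
        return self._edges

    @property
    def edge_tri(self) -> np.ndarray:
        """(E, 2) adjacent triangle ids per edge, -1 for boundary edges."""
        if self._edge_tri is None:
            self._build_edges()
        return self._edge_tri

    @property
    def tri_edges(self) -> np.ndarray:
        """(M, 3) edge ids of each triangle."""
        if self._tri_edges is None:
            self._build_edges()
        return self._tri_edges

    @property
    def edge_lengths(self) -> np.ndarray:
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    @property
    def normals(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered node loops of each boundary (mitral/outer + PV holes)."""
        bmask = self.edge_tri[:, 1] < 0
        bedges = self.edges[bmask]
        if len(bedges) == 0:
            return []
        # edge-consuming walk: terminates even on degenerate slit
        # boundaries (each boundary edge is traversed exactly once)
        incident: dict[int, list[int]] = {}
        for k, (a, b) in enumerate(bedges):
            incident.setdefault(int(a), []).append(k)
            incident.setdefault(int(b), []).append(k)
        used = np.zeros(len(bedges), bool)
        loops = []
        for k0 in range(len(bedges)):
            if used[k0]:
                continue
            used[k0] = True
            start, cur = int(bedges[k0, 0]), int(bedges[k0, 1])
            loop = [start, cur]
            while cur != start:
                nxt = next((k for k in incident[cur] if not used[k]), None)
                if nxt is None:
                    break
                used[nxt] = True
                a, b = bedges[nxt]
                cur = int(b) if int(a) == cur else int(a)
                if cur != start:
                    loop.append(cur)
            loops.append(np.asarray(loop))
        return loops

    def node_subdivision(self) -> np.ndarray:
        """Per-node subdivision label (from an arbitrary incident triangle)."""
        lab = np.zeros(self.n_nodes, dtype=np.int64)
        for c in range(3):
            lab[self.triangles[:, c]] = self.subdivision
        return lab

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.nodes.copy(), self.triangles.copy(),
                           self.fiber.copy(), self.region.copy(),
                           self.subdivision.copy(), self.config)


@dataclass
class LgeLikelihood:
    """Per-triangle enhancement likelihood in [0, 1]."""

    value: np.ndarray
    targets: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.value, dtype=float)
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("LGE likelihood must lie in [0, 1]")
        self.value = np.clip(v, 0.0, 1.0)


# ---------------------------------------------------------------------------
# construction

def _grid_spacing(target_mean_edge: float) -> float:
    # mean over {h, h, h*sqrt2} edge populations (2 axis : 1 diagonal)
    return target_mean_edge * 3.0 / (2.0 + np.sqrt(2.0))


def build_sheet(size_mm=(50.0, 50.0), edge_length_mm=0.5, jitter=0.15,
                dome_height_mm=0.0, seed=0):
    """Plain rectangular sheet (no holes): nodes, triangles, grid spacing.

    Triangulation is a structured grid with alternating diagonals so the
    mesh carries no global diagonal bias.  Interior nodes are jittered
    (seeded) to break the lattice-degenerate edge-length distribution.
    """
    if edge_length_mm <= 0:
        raise GeometryError("edge-length target must be > 0")
    h = _grid_spacing(edge_length_mm)
    lx, ly = size_mm
    nx, ny = int(round(lx / h)) + 1, int(round(ly / h)) + 1
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])

    rng = np.random.default_rng(seed)
    interior = ((nodes[:, 0] > 1e-9) & (nodes[:, 0] < lx - 1e-9)
                & (nodes[:, 1] > 1e-9) & (nodes[:, 1] < ly - 1e-9))
    jit = (rng.random((interior.sum(), 2)) - 0.5) * 2 * jitter * h
    nodes[interior, :2] += jit

    def nid(i, j):
        return j * nx + i

    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append((a, b, c)); tris.append((a, c, d))
            else:
                tris.append((a, b, d)); tris.append((b, c, d))
    tris = np.asarray(tris, dtype=np.int64)

    if dome_height_mm > 0:
        # gentle ellipsoidal lift; zero on the outer boundary
        sx = np.sin(np.pi * nodes[:, 0] / lx)
        sy = np.sin(np.pi * nodes[:, 1] / ly)
        nodes[:, 2] = dome_height_mm * sx * sy
    return nodes, tris, h


def _fiber_rotation_deg(xy: np.ndarray, cfg: GeometryConfig) -> np.ndarray:
    """Fiber rotation (deg) at points: 90 inside each PV sleeve, decaying
    linearly to 0 across the transition band, 0 in the LA body."""
    rot = np.zeros(len(xy))
    r_out = cfg.ostium_radius_mm + cfg.pv_sleeve_mm
    for _, c in cfg.ostia.items():
        d = np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1])
        inside = d <= r_out
        band = (d > r_out) & (d <= r_out + cfg.fiber_band_mm)
        rot[inside] = 90.0
        rot[band] = np.maximum(
            rot[band], 90.0 * (1.0 - (d[band] - r_out) / cfg.fiber_band_mm))
    return rot


def build_la_surface(config: GeometryConfig | None = None) -> SurfaceMesh:
    """Generate the synthetic LA surface per the configuration.

    Raises :class:`GeometryError` when ostia overlap each other, overlap
    the LAA patch, or touch the outer (mitral) boundary.
    """
    cfg = config or GeometryConfig()
    lx, ly = cfg.size_mm
    r_hole = cfg.ostium_radius_mm
    r_pv = r_hole + cfg.pv_sleeve_mm

    centers = list(cfg.ostia.values())
    for idx, (x, y) in enumerate(centers):
        if not (r_hole < x < lx - r_hole and r_hole < y < ly - r_hole):
            raise GeometryError(f"ostium {idx} touches the domain boundary")
        for x2, y2 in centers[idx + 1:]:
            if np.hypot(x - x2, y - y2) <= 2 * r_hole:
                raise GeometryError("overlapping PV ostia")

    nodes, tris, _h = build_sheet(cfg.size_mm, cfg.edge_length_mm,
                                  cfg.jitter, cfg.dome_height_mm, cfg.seed)
    cent = nodes[tris].mean(axis=1)

    # punch the PV ostium holes
    keep = np.ones(len(tris), dtype=bool)
    for x, y in centers:
        keep &= np.hypot(cent[:, 0] - x, cent[:, 1] - y) > r_hole
    tris = tris[keep]
    # drop isolated nodes, reindex
    used = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes, tris = nodes[used], remap[tris]
    cent = nodes[tris].mean(axis=1)

    # region labels (precedence PV > LAA > mitral rim > body)
    region = np.full(len(tris), REGION_LA_BODY, dtype=np.int64)
    bdist = np.minimum(np.minimum(cent[:, 0], lx - cent[:, 0]),
                       np.minimum(cent[:, 1], ly - cent[:, 1]))
    region[bdist < cfg.mitral_rim_mm] = REGION_MITRAL_RIM
    dlaa = np.hypot(cent[:, 0] - cfg.laa_center[0],
                    cent[:, 1] - cfg.laa_center[1])
    region[dlaa <= cfg.laa_radius_mm] = REGION_LAA
    for name, c in cfg.ostia.items():
        d = np.hypot(cent[:, 0] - c[0], cent[:, 1] - c[1])
        region[d <= r_pv] = REGION_PV[name]

    # fibers: base direction rotated by the PV-rim rotation field, then
    # projected into each triangle's plane
    rot = np.deg2rad(_fiber_rotation_deg(cent[:, :2], cfg)
                     + cfg.fiber_base_deg)
    f = np.column_stack([np.cos(rot), np.sin(rot), np.zeros(len(rot))])
    p = nodes[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    f -= (f * n).sum(axis=1, keepdims=True) * n
    f /= np.linalg.norm(f, axis=1, keepdims=True)

    mesh = SurfaceMesh(nodes, tris, f, region,
                       np.zeros(len(tris), dtype=np.int64), cfg)
    return assign_subdivisions(mesh)


def assign_subdivisions(mesh: SurfaceMesh) -> SurfaceMesh:
    """Label every triangle with a subdivision 1-8.

    Posterior half (y below the mid-line) gets 1-4 by x quartile, the
    anterior half 5-8; this mirrors the 4 + 4 posterior/anterior layout
    used for regional rotor statistics.  Idempotent.
    """
    cent = mesh.centroids
    x0, x1 = mesh.nodes[:, 0].min(), mesh.nodes[:, 0].max()
    ymid = 0.5 * (mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max())
    q = np.clip(((cent[:, 0] - x0) / (x1 - x0) * 4).astype(int), 0, 3)
    sub = q + 1
    sub[cent[:, 1] >= ymid] += 4
    mesh.subdivision = sub.astype(np.int64)
    return mesh


# ---------------------------------------------------------------------------
# LGE likelihood field

def subdivision_density(values: np.ndarray, subdivision: np.ndarray,
                        areas: np.ndarray | None = None) -> np.ndarray:
    """Per-subdivision mean of a per-triangle field, normalized by the
    maximum across the eight subdivisions."""
    means = np.zeros(8)
    for s in range(1, 9):
        m = subdivision == s
        if m.any():
            means[s - 1] = (np.average(values[m], weights=None if areas is None
                                       else areas[m]))
    mx = means.max()
    return means / mx if mx > 0 else means


def build_lge_map(mesh: SurfaceMesh,
                  targets=DEFAULT_LGE_TARGETS,
                  seed: int = 0,
                  n_bumps: int = 30,
                  peak_mean: float = 0.45,
                  tol: float = 0.02) -> LgeLikelihood:
    """Smooth random likelihood field matching per-subdivision densities.

    A sum of seeded Gaussian bumps is rescaled, subdivision by subdivision,
    so that the normalized per-subdivision densities (mean over triangles /
    max across subdivisions) match ``targets`` within ``tol``.
    ``peak_mean`` sets the absolute mean likelihood of the densest
    subdivision (the one with target 1.0).
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (8,):
        raise ValueError("need 8 per-subdivision targets")
    if (targets < 0).any() or (targets > 1).any():
        raise ValueError("targets must lie in [0, 1]")
    if not np.isclose(targets.max(), 1.0):
        raise ValueError("at least one target must equal 1.0")

    rng = np.random.default_rng(seed)
    cent = mesh.centroids
    lo, hi = cent[:, :2].min(axis=0), cent[:, :2].max(axis=0)
    raw = np.zeros(mesh.n_triangles)
    for _ in range(n_bumps):
        c = lo + rng.random(2) * (hi - lo)
        s = 4.0 + 8.0 * rng.random()
        a = 0.3 + 0.7 * rng.random()
        d2 = ((cent[:, 0] - c[0]) ** 2 + (cent[:, 1] - c[1]) ** 2)
        raw += a * np.exp(-d2 / (2 * s * s))
    raw /= raw.max()
    raw += 0.05  # floor so no subdivision has an identically-zero mean

    value = np.zeros_like(raw)
    sub = mesh.subdivision
    for s in range(1, 9):
        m = sub == s
        if not m.any():
            continue
        want = peak_mean * targets[s - 1]
        v = raw[m] * (want / raw[m].mean() if raw[m].mean() > 0 else 0.0)
        # clipping at 1 lowers the mean; compensate iteratively
        for _ in range(8):
            v = np.clip(v, 0.0, 1.0)
            cur = v.mean()
            if want <= 0 or abs(cur - want) < 1e-4 * max(want, 1e-9):
                break
            v = np.clip(v * (want / max(cur, 1e-12)), 0.0, 1.0)
        value[m] = v

    achieved = subdivision_density(value, sub)
    if np.abs(achieved - targets).max() > tol:
        raise ValueError(
            f"could not match LGE density targets: achieved {achieved}")
    return LgeLikelihood(value, tuple(targets))


# ---------------------------------------------------------------------------
# validation and IO

def validate_mesh(mesh: SurfaceMesh) -> dict:
    """Structural checks; raises GeometryError on violation.

    Returns a summary dict with node/edge/triangle counts, boundary-loop
    count and Euler characteristic (V - E + F = 2 - 2g - b for an
    orientable surface with b boundary loops; 1 - holes for a disk).
    """
    tris = np.sort(mesh.triangles, axis=1)
    if len(np.unique(tris, axis=0)) != len(tris):
        raise GeometryError("duplicate triangles")
    if not np.isin(np.arange(mesh.n_nodes), mesh.triangles).all():
        raise GeometryError("isolated nodes present")
    et = mesh.edge_tri  # raises on >2 adjacency
    # boundary components: closed rims (outer boundary, ostia) have all
    # even boundary-degrees; fibrotic clefts appear as open slit chains
    loops = mesh.boundary_loops()
    bmask = et[:, 1] < 0
    bdeg = np.bincount(mesh.edges[bmask].ravel(), minlength=mesh.n_nodes)
    closed = int(sum(1 for l in loops if len(l) >= 3
                     and not (bdeg[l] % 2).any()))
    chi = mesh.n_nodes - len(mesh.edges) + mesh.n_triangles
    if (np.abs((mesh.fiber * mesh.normals).sum(axis=1)) > 1e-9).any():
        raise GeometryError("fiber vectors leave the triangle plane")
    if not np.allclose(np.linalg.norm(mesh.fiber, axis=1), 1.0):
        raise GeometryError("fiber vectors are not unit length")
    return {"nodes": mesh.n_nodes, "edges": len(mesh.edges),
            "triangles": mesh.n_triangles, "boundary_loops": closed,
            "boundary_chains": len(loops) - closed,
            "euler_characteristic": int(chi)}


def write_vtk(mesh: SurfaceMesh, path, cell_data: dict | None = None) -> None:
    """Write the mesh as legacy-VTK ASCII with per-triangle data arrays."""
    buf = _io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nrotorlab surface\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    np.savetxt(buf, mesh.nodes, fmt="%.9g")
    m = mesh.n_triangles
    buf.write(f"CELLS {m} {4 * m}\n")
    np.savetxt(buf, np.column_stack(
        [np.full(m, 3, dtype=np.int64), mesh.triangles]), fmt="%d")
    buf.write(f"CELL_TYPES {m}\n")
    buf.write("\n".join(["5"] * m) + "\n")
    buf.write(f"CELL_DATA {m}\n")
    buf.write("VECTORS fiber double\n")
    np.savetxt(buf, mesh.fiber, fmt="%.9g")
    arrays = {"region": mesh.region, "subdivision": mesh.subdivision}
    arrays.update(cell_data or {})
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        typ = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        fmt = "%d" if typ == "int" else "%.9g"
        buf.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
        np.savetxt(buf, arr.reshape(-1, 1), fmt=fmt)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_vtk(path) -> tuple[SurfaceMesh, dict]:
    """Read a mesh written by :func:`write_vtk`; returns (mesh, extras)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def until(prefix):
        nonlocal i
        while not tokens[i].startswith(prefix):
            i += 1
        return tokens[i].split()

    hdr = until("POINTS")
    n = int(hdr[1]); i += 1
    nodes = np.loadtxt(tokens[i:i + n]).reshape(n, 3); i += n
    hdr = until("CELLS")
    m = int(hdr[1]); i += 1
    cells = np.loadtxt(tokens[i:i + m], dtype=np.int64).reshape(m, 4)
    tris = cells[:, 1:]; i += m
    until("VECTORS"); i += 1
    fiber = np.loadtxt(tokens[i:i + m]).reshape(m, 3); i += m
    data = {}
    while True:
        try:
            hdr = until("SCALARS")
        except IndexError:
            break
        name, typ = hdr[1], hdr[2]
        i += 2
        arr = np.loadtxt(tokens[i:i + m],
                         dtype=np.int64 if typ == "int" else float)
        data[name] = arr.reshape(m)
        i += m
    region = data.pop("region", np.zeros(m, dtype=np.int64))
    sub = data.pop("subdivision", np.zeros(m, dtype=np.int64))
    return SurfaceMesh(nodes, tris, fiber, region.astype(np.int64),
                       sub.astype(np.int64)), data
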