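"""Reusable desk-scale experiment scenarios.

The reentry scenario induces a sustained spiral wave on a uniform
pAF-remodeled LA-body sheet by cross-field S1-S2 stimulation: a short S1
train from the left edge (rate-adapting the action potential downward so
the reentrant wavelength fits the sheet), then a perpendicular half-field
S2 timed into the vulnerable tail of the last S1 beat.  The S2 timing is
derived at run time from a cheap 1-D strip probe of the same substrate
(the repolarization time at the sheet centre), not hard-coded, so it
adapts to parameter or resolution changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ionic
from . import monodomain as md
from .geometry import SurfaceMesh, build_sheet

__all__ = ["SpiralScenario", "make_remodeled_sheet", "s2_timing_probe",
           "induce_spiral", "mean_reentry_cl"]

S1_CL_MS = 250.0         # S1 train cycle length (rate adaptation)
S1_N_BEATS = 4
S2_OFFSET_MS = 2.0       # S2 delay after centre -65 mV repolarization


@dataclass
class SpiralScenario:
    mesh: SurfaceMesh
    A: object                    # assembled diffusion operator
    params: np.ndarray           # per-node ionic parameters
    recording: md.Recording
    states: np.ndarray
    t_s2: float
    dt_us: float


def make_remodeled_sheet(size_mm=(50.0, 50.0), edge_length_mm=0.5,
                         seed: int = 1, sigma_l=md.DEFAULT_SIGMA_L,
                         sigma_t=md.DEFAULT_SIGMA_T):
    """Uniform pAF-remodeled LA-body sheet with fibers along y."""
    nodes, tris, _ = build_sheet(size_mm, edge_length_mm, jitter=0.15,
                                 seed=seed)
    # fibers run along y: the S1 wave from the left edge propagates in the
    # slow transverse direction, stretching its repolarizing tail so the
    # S2 cross-shock can pivot inside the sheet
    mesh = SurfaceMesh(nodes, tris, np.tile([0.0, 1.0, 0.0], (len(tris), 1)),
                       np.zeros(len(tris), np.int64),
                       np.ones(len(tris), np.int64))
    cond = md.ConductivityField(np.full(len(tris), sigma_l),
                                np.full(len(tris), sigma_t),
                                np.zeros(len(tris), bool))
    A, _ = md.assemble_diffusion(mesh, cond)
    p = ionic.make_region_params("LA_body").to_array()
    params = np.tile(p, (mesh.n_nodes, 1))
    return mesh, A, params, cond


def s2_timing_probe(edge_length_mm=0.5, length_mm=50.0, dt_us=25.0,
                    s1_cl=S1_CL_MS, n_beats=S1_N_BEATS, tables=None):
    """Centre -65 mV repolarization time of the last S1 beat, measured on
    a thin strip of the same substrate (planar symmetry makes the strip
    equivalent to the full sheet for S1 timing)."""
    nodes, tris, _ = build_sheet((length_mm, 3.0), edge_length_mm,
                                 jitter=0.0)
    strip = SurfaceMesh(nodes, tris,
                        np.tile([0.0, 1.0, 0.0], (len(tris), 1)),
                        np.zeros(len(tris), np.int64),
                        np.ones(len(tris), np.int64))
    A, _ = md.assemble_diffusion(strip, md.default_conductivity(strip))
    p = ionic.make_region_params("LA_body").to_array()
    pn = np.tile(p, (len(nodes), 1))
    left = np.flatnonzero(nodes[:, 0] < 3.0 * edge_length_mm)
    s1t = 1.0 + s1_cl * np.arange(n_beats)
    stims = [md.Stimulus(t, 2.0, -40.0, left) for t in s1t]
    rec, _ = md.run_simulation(A, pn, s1t[-1] + 350.0, dt_us=dt_us,
                               stimuli=stims, record_interval_ms=2.0,
                               tables=tables)
    c = int(np.argmin(np.abs(nodes[:, 0] - length_mm / 2)
                      + np.abs(nodes[:, 1] - 1.5)))
    vm = rec.frames[:, c]
    i0 = np.searchsorted(rec.t, s1t[-1])
    seg = vm[i0:]
    up = int(np.argmax(seg > -40))
    k = up + int(np.argmax(seg[up:] < -65.0))
    return float(rec.t[i0 + k]), s1t


def induce_spiral(duration_post_s2_ms: float = 2400.0, seed: int = 1,
                  size_mm=(50.0, 50.0), edge_length_mm: float = 0.5,
                  dt_us: float = 25.0, record_interval_ms: float = 2.0
                  ) -> SpiralScenario:
    """Cross-field S1-S2 induction of a reentrant spiral.

    S1: planar train from the left edge (CL 250 ms x 4 beats).  S2: the
    lower half-sheet, ``S2_OFFSET_MS`` after the centre repolarizes to
    -65 mV, breaking along the refractory tail of the last S1 beat.
    """
    tables = ionic.build_tables(dt_us * 1e-3)
    t65, s1t = s2_timing_probe(edge_length_mm, size_mm[0], dt_us,
                               tables=tables)
    t_s2 = t65 + S2_OFFSET_MS
    mesh, A, params, _ = make_remodeled_sheet(size_mm, edge_length_mm, seed)
    nodes = mesh.nodes
    left = np.flatnonzero(nodes[:, 0] < 3.0 * edge_length_mm)
    lower = np.flatnonzero(nodes[:, 1] < size_mm[1] / 2.0)
    stims = [md.Stimulus(t, 2.0, -40.0, left) for t in s1t]
    stims.append(md.Stimulus(t_s2, 2.0, -40.0, lower))
    rec, states = md.run_simulation(
        A, params, t_s2 + duration_post_s2_ms, dt_us=dt_us, stimuli=stims,
        record_interval_ms=record_interval_ms, tables=tables)
    return SpiralScenario(mesh, A, params, rec, states, t_s2, dt_us)


def mean_reentry_cl(recording: md.Recording, mesh: SurfaceMesh,
                    t_min: float, sample_points=None,
                    min_beats: int = 3) -> float:
    """Mean activation cycle length (ms) over sample nodes.

    Cycle lengths are intervals between successive -40 mV upstrokes after
    ``t_min``; nodes with fewer than ``min_beats`` intervals are skipped.
    """
    if sample_points is None:
        lo = mesh.nodes[:, :2].min(axis=0)
        hi = mesh.nodes[:, :2].max(axis=0)
        fr = [(0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75),
              (0.5, 0.1), (0.1, 0.5)]
        sample_points = [lo + np.array(f) * (hi - lo) for f in fr]
    amap = md.activation_times(recording)
    per = amap.per_node()
    cls = []
    for pt in sample_points:
        i = int(np.argmin(np.linalg.norm(mesh.nodes[:, :2]
                                         - np.asarray(pt)[:2], axis=1)))
        tt = per[i]
        tt = tt[tt >= t_min]
        if len(tt) >= min_beats + 1:
            cls.append(np.mean(np.diff(tt)))
    if len(cls) < 4:
        raise RuntimeError("reentry did not persist at enough sample nodes")
    return float(np.mean(cls))
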