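import numpy as np
import pytest

from rotorlab import geometry as geo
from rotorlab import phase as ph
from rotorlab.monodomain import Recording


def vortex_field(xy, centers, chirs):
    """Analytic multi-vortex phase field sum_k c_k * atan2(y-yk, x-xk)."""
    th = np.zeros(len(xy))
    for (cx, cy), c in zip(centers, chirs):
        th = th + c * np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
    return ph._wrap(th)


def min_edge_distance(mesh, centers):
    """Distance from each centre to the nearest mesh edge segment."""
    a = mesh.nodes[mesh.edges[:, 0]][:, :2]
    b = mesh.nodes[mesh.edges[:, 1]][:, :2]
    ab = b - a
    L2 = (ab * ab).sum(axis=1)
    out = []
    for c in np.atleast_2d(centers):
        s = ((c - a) * ab).sum(axis=1) / np.maximum(L2, 1e-30)
        proj = a + np.clip(s, 0, 1)[:, None] * ab
        out.append(np.linalg.norm(proj - c, axis=1).min())
    return np.array(out)


def brute_force_winding(mesh, centers, chirs, n_samples=400):
    """Independent oracle: numerically integrate the continuous phase
    gradient around each triangle's perimeter, sampling densely."""
    out = {}
    for ti, tri in enumerate(mesh.triangles):
        pts = mesh.nodes[tri][:, :2]
        per = []
        for k in range(3):
            a, b = pts[k], pts[(k + 1) % 3]
            s = np.linspace(0, 1, n_samples // 3, endpoint=False)
            per.append(a + s[:, None] * (b - a))
        per = np.vstack(per)
        th = vortex_field(per, centers, chirs)
        w = ph._wrap(np.diff(np.concatenate([th, th[:1]]))).sum()
        charge = int(np.round(w / (2 * np.pi)))
        if charge != 0:
            out[ti] = charge
    return out


@pytest.fixture(scope="module")
def sheet64():
    nodes, tris, _ = geo.build_sheet((32.0, 32.0), 0.7, jitter=0.1, seed=3)
    return geo.SurfaceMesh(nodes, tris,
                           np.tile([1.0, 0, 0], (len(tris), 1)),
                           np.zeros(len(tris), np.int64),
                           np.ones(len(tris), np.int64))


class TestComputePhase:
    def test_sinusoid_linear_phase(self):
        t = np.arange(0, 400.0, 1.0)
        om = 2 * np.pi / 100.0
        v = 20 * np.sin(om * t) - 60.0
        rec = Recording(np.tile(v[:, None], (1, 4)).astype(np.float32),
                        t, 1.0)
        mov = ph.compute_phase(rec)
        un = np.unwrap(mov.theta[:, 0].astype(float))
        mid = slice(50, 350)  # away from Hilbert edge effects
        slope = np.polyfit(t[mid], un[mid], 1)[0]
        assert slope == pytest.approx(om, rel=0.01)

    def test_constant_signal_masked(self):
        t = np.arange(0, 100.0, 1.0)
        frames = np.full((len(t), 3), -80.0, np.float32)
        frames[:, 1] = -80.0 + 10 * np.sin(t / 10)
        mov = ph.compute_phase(Recording(frames, t, 1.0))
        assert not mov.mask[0] and mov.mask[1] and not mov.mask[2]

    def test_paced_train_one_cycle_per_beat(self):
        from rotorlab import ionic
        t, vm, _ = ionic.pace_single_cell(
            ionic.make_region_params("LA_body"), 400.0, 6, sample_ms=1.0)
        rec = Recording(np.tile(vm[:, None], (1, 3)).astype(np.float32),
                        t, 1.0)
        mov = ph.compute_phase(rec)
        un = np.unwrap(mov.theta[:, 0].astype(float))
        # 6 beats -> total progression close to 6 * 2pi (edges trimmed)
        total = un[-50] - un[50]
        assert total == pytest.approx(2 * np.pi * 6, rel=0.2)


class TestDetect:
    def test_single_vortex_location_and_chirality(self, sheet64):
        c = (16.3, 15.8)
        th = vortex_field(sheet64.nodes[:, :2], [c], [+1])
        elems, chir = ph.detect_ps(th, sheet64)
        assert len(elems) == 1
        assert chir[0] == +1
        assert np.linalg.norm(sheet64.centroids[elems[0]][:2] - c) < 1.5

    def test_planar_ramp_no_ps(self, sheet64):
        th = ph._wrap(0.5 * sheet64.nodes[:, 0])
        elems, _ = ph.detect_ps(th, sheet64)
        assert len(elems) == 0

    def test_opposite_pair_nets_zero(self, sheet64):
        th = vortex_field(sheet64.nodes[:, :2], [(10, 16), (22, 16)],
                          [+1, -1])
        elems, chir = ph.detect_ps(th, sheet64)
        assert len(elems) == 2
        assert chir.sum() == 0

    def test_masked_nodes_skip_elements(self, sheet64):
        th = vortex_field(sheet64.nodes[:, :2], [(16, 16)], [+1])
        mask = np.ones(sheet64.n_nodes, bool)
        near = np.linalg.norm(sheet64.nodes[:, :2] - [16, 16], axis=1) < 2
        mask[near] = False
        elems, _ = ph.detect_ps(th, sheet64, mask)
        assert len(elems) == 0

    def test_oracle_agreement_100_random_fields(self, sheet64):
        """Detector matches brute-force perimeter winding integration on
        100 random vortex placements (count and chirality)."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            k = rng.integers(1, 4)
            centers = 4 + 24 * rng.random((k, 2))
            # keep vortices apart and off mesh edges (a centre lying on
            # an edge makes the containing triangle ill-defined for both
            # detector and oracle)
            if k > 1 and np.min(
                [np.linalg.norm(a - b) for i, a in enumerate(centers)
                 for b in centers[i + 1:]]) < 4.0:
                continue
            if min_edge_distance(sheet64, centers).min() < 0.05:
                continue
            chirs = rng.choice([-1, 1], k)
            th = vortex_field(sheet64.nodes[:, :2], centers, chirs)
            elems, chir = ph.detect_ps(th, sheet64)
            oracle = brute_force_winding(sheet64, centers, chirs)
            assert set(elems) == set(oracle), f"trial {trial}"
            for e, c in zip(elems, chir):
                assert oracle[e] == c, f"trial {trial}"

    def test_net_charge_equals_sum_of_chiralities(self, sheet64):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.integers(1, 4)
            centers = 6 + 20 * rng.random((k, 2))
            chirs = rng.choice([-1, 1], k)
            th = vortex_field(sheet64.nodes[:, :2], centers, chirs)
            _, chir = ph.detect_ps(th, sheet64)
            assert chir.sum() == chirs.sum()


class TestTracking:
    def _detections(self, seq):
        """seq: list of lists of (element, chirality)."""
        return [(np.array([e for e, _ in fr], dtype=int),
                 np.array([c for _, c in fr], dtype=int)) for fr in seq]

    def test_stationary_ps_single_trajectory(self, sheet64):
        det = self._detections([[(100, 1)]] * 10)
        trajs = ph.track_ps(det, sheet64, frame_interval=1.0)
        assert len(trajs) == 1
        assert trajs[0].duration == pytest.approx(9.0)

    def test_jump_beyond_threshold_splits(self, sheet64):
        far = int(np.argmax(np.linalg.norm(
            sheet64.centroids - sheet64.centroids[100], axis=1)))
        det = self._detections([[(100, 1)]] * 5 + [[(far, 1)]] * 5)
        trajs = ph.track_ps(det, sheet64, max_jump_mm=5.0)
        assert len(trajs) == 2

    def test_chirality_never_mixes(self, sheet64):
        det = self._detections([[(100, 1)], [(100, -1)]])
        trajs = ph.track_ps(det, sheet64)
        assert len(trajs) == 2

    def test_meandering_vortex_path_recovered(self, sheet64):
        """Analytic vortex moving on a circle is tracked as a single
        trajectory within one element diameter of the true path."""
        t = np.arange(60.0)
        cx = 16 + 5 * np.cos(2 * np.pi * t / 60)
        cy = 16 + 5 * np.sin(2 * np.pi * t / 60)
        dets = []
        for x, y in zip(cx, cy):
            th = vortex_field(sheet64.nodes[:, :2], [(x, y)], [+1])
            dets.append(ph.detect_ps(th, sheet64))
        trajs = ph.track_ps(dets, sheet64, max_jump_mm=5.0, times=t)
        assert len(trajs) == 1
        el_diam = 2.0 * sheet64.edge_lengths.max()
        pos = np.array(trajs[0].positions)[:, :2]
        err = np.linalg.norm(pos - np.column_stack([cx, cy]), axis=1)
        assert err.max() < el_diam


class TestRotorsAndDensity:
    def test_rotor_duration_boundary(self, sheet64):
        short = ph.PSTrajectory(0, 1, [0.0, 119.0], [1, 1],
                                [np.zeros(3)] * 2)
        over = ph.PSTrajectory(1, 1, [0.0, 121.0], [1, 1],
                               [np.zeros(3)] * 2)
        assert ph.classify_rotors([short, over]) == [over]
        assert ph.classify_rotors([]) == []

    def test_single_site_density_peak(self, sheet64):
        tr = ph.PSTrajectory(0, 1, list(range(20)), [500] * 20,
                             [sheet64.centroids[500]] * 20)
        dm = ph.density_map([tr], sheet64, radius_mm=5.0)
        assert dm.value[500] == 1.0
        d = np.linalg.norm(sheet64.centroids - sheet64.centroids[500],
                           axis=1)
        near, farther = dm.value[(d > 1) & (d < 2)], dm.value[(d > 3)
                                                              & (d < 4)]
        assert near.mean() > farther.mean()

    def test_two_equal_sites_both_max(self, sheet64):
        a, b = 200, int(np.argmax(np.linalg.norm(
            sheet64.centroids - sheet64.centroids[200], axis=1)))
        trs = [ph.PSTrajectory(0, 1, list(range(10)), [a] * 10,
                               [sheet64.centroids[a]] * 10),
               ph.PSTrajectory(1, 1, list(range(10)), [b] * 10,
                               [sheet64.centroids[b]] * 10)]
        dm = ph.density_map(trs, sheet64)
        assert dm.value[a] == pytest.approx(dm.value[b], rel=0.01)
        assert dm.value.max() == 1.0

    def test_doubling_counts_leaves_map_unchanged(self, sheet64):
        tr = ph.PSTrajectory(0, 1, list(range(10)), [321] * 10,
                             [sheet64.centroids[321]] * 10)
        tr2 = ph.PSTrajectory(1, 1, list(range(20)), [321] * 20,
                              [sheet64.centroids[321]] * 20)
        d1 = ph.density_map([tr], sheet64).value
        d2 = ph.density_map([tr2], sheet64).value
        assert np.allclose(d1, d2)

    def test_empty_density_all_zero(self, sheet64):
        dm = ph.density_map([], sheet64)
        assert not dm.value.any()


class TestRegionalStats:
    def _periodic_recording(self, mesh, cl=185.0):
        t = np.arange(0, 1000.0, 1.0)
        vm = np.where((t % cl) < 80.0, 10.0, -80.0)
        frames = np.tile(vm[:, None], (1, mesh.n_nodes)).astype(np.float32)
        return Recording(frames, t, 1.0)

    def test_cycle_length_uniform(self, sheet64):
        m = geo.assign_subdivisions(sheet64.copy())
        rec = self._periodic_recording(m)
        df = ph.regional_stats([], [], rec, m)
        assert np.allclose(df["cl_mean_ms"], 185.0, atol=1.0)
        assert np.allclose(df["cl_min_ms"], 185.0, atol=1.0)

    def test_single_ps_in_one_subdivision(self, sheet64):
        m = geo.assign_subdivisions(sheet64.copy())
        rec = self._periodic_recording(m)
        e = int(np.flatnonzero(m.subdivision == 3)[0])
        tr = ph.PSTrajectory(0, 1, list(rec.t), [e] * len(rec.t),
                             [m.centroids[e]] * len(rec.t))
        df = ph.regional_stats([tr], [tr], rec, m)
        assert df.loc[df.subdivision == 3, "ps_mean"].item() \
            == pytest.approx(1.0, abs=0.01)
        assert (df.loc[df.subdivision != 3, "ps_mean"] == 0).all()
        assert df["ps_density_norm"].max() == 1.0

    def test_unactivated_subdivision_nan_cl(self, sheet64):
        m = geo.assign_subdivisions(sheet64.copy())
        rec = self._periodic_recording(m)
        quiet = m.node_subdivision() == 5
        rec.frames[:, quiet] = -80.0
        df = ph.regional_stats([], [], rec, m)
        assert np.isnan(df.loc[df.subdivision == 5, "cl_mean_ms"]).all()


def test_trajectory_csv_export(tmp_path, flat_sheet):
    import pandas as pd
    tr = ph.PSTrajectory(0, 1, [0.0, 1.0], [5, 6],
                         [flat_sheet.centroids[5], flat_sheet.centroids[6]])
    p = tmp_path / "traj.csv"
    ph.trajectories_to_csv([tr], p)
    df = pd.read_csv(p)
    assert list(df.columns) == ["id", "t", "x", "y", "z", "element",
                                "chirality"]
    assert len(df) == 2
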