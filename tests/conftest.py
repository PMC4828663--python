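import numpy as np
import pytest

from rotorlab import geometry as geo


@pytest.fixture(scope="session")
def la_mesh():
    """Default synthetic LA surface (50x50 mm, 0.5 mm mean edge)."""
    return geo.build_la_surface()


@pytest.fixture(scope="session")
def lge_map(la_mesh):
    return geo.build_lge_map(la_mesh, seed=0)


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse LA surface for fast structural tests."""
    cfg = geo.GeometryConfig(size_mm=(40.0, 40.0), edge_length_mm=1.0,
                             ostia={"RIPV": (30.0, 10.0), "LIPV": (10.0, 10.0),
                                    "RSPV": (30.0, 30.0), "LSPV": (10.0, 30.0)},
                             ostium_radius_mm=3.0, pv_sleeve_mm=2.0,
                             laa_center=(3.0, 37.0), laa_radius_mm=3.0,
                             seed=0)
    return geo.build_la_surface(cfg)


@pytest.fixture(scope="session")
def flat_sheet():
    """Plain 20x20 mm sheet mesh (no holes), x-aligned fibers."""
    nodes, tris, h = geo.build_sheet((20.0, 20.0), 0.5, jitter=0.0)
    return geo.SurfaceMesh(nodes, tris,
                           np.tile([1.0, 0.0, 0.0], (len(tris), 1)),
                           np.zeros(len(tris), np.int64),
                           np.ones(len(tris), np.int64))


@pytest.fixture(scope="session")
def spiral_scenario():
    """Sustained cross-field reentry on the remodeled sheet (expensive;
    shared by the rotor-cycle-length and streamlining-termination tests)."""
    from rotorlab import scenarios
    return scenarios.induce_spiral(seed=1)
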