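import numpy as np
import pytest
from shapely.geometry import LineString

from lumpanel.geo_network import RoadSegment, build_network


def make_grid_segments(n: int = 10, spacing: float = 100.0, accessible=None):
    """(n+1)x(n+1) lattice of straight segments of length ``spacing``."""
    segs = []
    sid = 0
    for i in range(n + 1):
        for j in range(n + 1):
            x, y = i * spacing, j * spacing
            if i < n:
                segs.append(
                    RoadSegment(f"h{sid:05d}", LineString([(x, y), (x + spacing, y)]))
                )
                sid += 1
            if j < n:
                segs.append(
                    RoadSegment(f"v{sid:05d}", LineString([(x, y), (x, y + spacing)]))
                )
                sid += 1
    if accessible is not None:
        segs = [
            RoadSegment(s.segment_id, s.geometry, accessible=accessible(k))
            for k, s in enumerate(segs)
        ]
    return segs


@pytest.fixture(scope="session")
def grid_network():
    """10x10 grid of 100-m edges: 121 nodes, 220 edges."""
    return build_network(make_grid_segments(10, 100.0))


@pytest.fixture(scope="session")
def straight_road_network():
    """Single isolated 3000-m straight road."""
    return build_network([RoadSegment("r0", LineString([(0.0, 0.0), (3000.0, 0.0)]))])


@pytest.fixture(scope="session")
def cross_network():
    """Two perpendicular 2000-m segments crossing at the origin node."""
    segs = [
        RoadSegment("ew_w", LineString([(-1000.0, 0.0), (0.0, 0.0)])),
        RoadSegment("ew_e", LineString([(0.0, 0.0), (1000.0, 0.0)])),
        RoadSegment("ns_s", LineString([(0.0, -1000.0), (0.0, 0.0)])),
        RoadSegment("ns_n", LineString([(0.0, 0.0), (0.0, 1000.0)])),
    ]
    return build_network(segs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
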