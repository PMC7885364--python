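"""Independent oracles used to check the implementation.

Each helper here recomputes a quantity by a deliberately different route
(rasterization, brute-force graph subdivision, closed-form OLS) and must
stay independent of the code paths it validates.
"""

from __future__ import annotations

import math

import numpy as np
import shapely


def raster_area(geom, cell: float = 0.5) -> float:
    """Polygon area by counting cell centers inside, cell size in meters."""
    minx, miny, maxx, maxy = geom.bounds
    xs = np.arange(minx + cell / 2, maxx, cell)
    ys = np.arange(miny + cell / 2, maxy, cell)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return float(inside.sum()) * cell * cell


def raster_class_areas(buffer_geom, parcels, cell: float = 0.5) -> dict[str, float]:
    """Per-class overlap areas between a buffer and labelled parcels."""
    minx, miny, maxx, maxy = buffer_geom.bounds
    xs = np.arange(minx + cell / 2, maxx, cell)
    ys = np.arange(miny + cell / 2, maxy, cell)
    gx, gy = np.meshgrid(xs, ys)
    px, py = gx.ravel(), gy.ravel()
    in_buf = shapely.contains_xy(buffer_geom, px, py)
    px, py = px[in_buf], py[in_buf]
    areas: dict[str, float] = {}
    for parcel in parcels:
        hit = shapely.contains_xy(parcel.geometry, px, py)
        if hit.any():
            areas[parcel.class_label] = (
                areas.get(parcel.class_label, 0.0) + float(hit.sum()) * cell * cell
            )
    return areas


def subdivided_reach_length(
    segments: list[tuple[tuple, tuple]], origin: tuple, d: float, step: float = 1.0
) -> float:
    """Total reachable network length by Dijkstra on a 1-m subdivision.

    ``segments`` are straight ((x0, y0), (x1, y1)) pieces.  The graph is
    rebuilt from scratch here (plain dict adjacency + heapq) so the result
    does not depend on the package's graph machinery.
    """
    import heapq

    nodes: dict[tuple, int] = {}
    adj: dict[int, list[tuple[int, float]]] = {}

    def node_id(pt) -> int:
        key = (round(pt[0], 6), round(pt[1], 6))
        if key not in nodes:
            nodes[key] = len(nodes)
            adj[nodes[key]] = []
        return nodes[key]

    for (x0, y0), (x1, y1) in segments:
        length = math.hypot(x1 - x0, y1 - y0)
        n = max(1, int(round(length / step)))
        pts = [(x0 + (x1 - x0) * i / n, y0 + (y1 - y0) * i / n) for i in range(n + 1)]
        for a, b in zip(pts[:-1], pts[1:]):
            ia, ib = node_id(a), node_id(b)
            w = math.hypot(b[0] - a[0], b[1] - a[1])
            adj[ia].append((ib, w))
            adj[ib].append((ia, w))

    # snap origin to nearest node
    src = min(nodes, key=lambda k: math.hypot(k[0] - origin[0], k[1] - origin[1]))
    dist = {nodes[src]: 0.0}
    heap = [(0.0, nodes[src])]
    while heap:
        du, u = heapq.heappop(heap)
        if du > dist.get(u, math.inf) or du > d:
            continue
        for v, w in adj[u]:
            alt = du + w
            if alt <= d and alt < dist.get(v, math.inf):
                dist[v] = alt
                heapq.heappush(heap, (alt, v))

    total = 0.0
    for u, nbrs in adj.items():
        for v, w in nbrs:
            if u < v and u in dist and v in dist:
                total += w
    return total


def entropy_direct(shares: np.ndarray, n_classes: int) -> float:
    """Normalized entropy evaluated straight from the definition."""
    p = np.asarray(shares, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(n_classes))


def fe_within_slope(x_dev: np.ndarray, y: np.ndarray, person: np.ndarray) -> float:
    """Fixed-effects (within) estimator: OLS of demeaned y on x deviations."""
    import pandas as pd

    df = pd.DataFrame({"x": x_dev, "y": y, "p": person})
    ydev = df["y"] - df.groupby("p")["y"].transform("mean")
    return float(np.sum(df["x"] * ydev) / np.sum(df["x"] ** 2))


def between_means_slope(x: np.ndarray, y: np.ndarray, person: np.ndarray) -> float:
    """Between estimator: OLS of person-mean y on person-mean x."""
    import pandas as pd

    df = pd.DataFrame({"x": x, "y": y, "p": person})
    pm = df.groupby("p").mean()
    xc = pm["x"] - pm["x"].mean()
    return float(np.sum(xc * pm["y"]) / np.sum(xc**2))


def rubin_by_hand(estimates, within_variances):
    """Rubin's rules evaluated directly from the formulas."""
    m = len(estimates)
    qbar = sum(estimates) / m
    ubar = sum(within_variances) / m
    b = sum((q - qbar) ** 2 for q in estimates) / (m - 1) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    return qbar, total
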