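"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a pipeline decision from first principles with a
different algorithm/library than the implementation uses:

* ternary equilibrium: bracketed root of the untransformed mass-balance in
  free protein (vs the closed-form cubic);
* Voronoi cell areas: iterative half-plane clipping with shapely (vs
  scipy's qhull tessellation + shoelace);
* neighbour counts: dense O(n^2) pairwise distances;
* cluster partitions: connected components of the full distance-threshold
  graph in networkx (equal to Delaunay-edge-cut components because the
  Delaunay triangulation contains the Euclidean minimum spanning tree);
* single-site ITC bound concentration: bracketed root in free ligand.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon, box


def ternary_bound_fraction(P_t, L_t, K_L, I_t, K_I):
    """Probe-bound fraction from a bracketed solve of the mass balance."""

    def residual(P):
        return P + P * L_t / (K_L + P) + P * I_t / (K_I + P) - P_t

    P = brentq(residual, 0.0, P_t, xtol=1e-300, rtol=8.9e-16)
    return P / (K_L + P)


def halfplane_voronoi_areas(points: np.ndarray, bound: float = 1e6) -> np.ndarray:
    """Voronoi cell area per point by half-plane clipping; inf if unbounded.

    Starts from a huge bounding box and intersects, in distance order, the
    half-plane nearer to the point than to each neighbour; stops once the
    next neighbour is more than twice the current maximal vertex distance
    away (such neighbours cannot cut the cell). A cell still touching the
    outer box is unbounded.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    tree = cKDTree(points)
    big = 4.0 * bound
    areas = np.empty(n)
    outer = box(
        points[:, 0].min() - bound, points[:, 1].min() - bound,
        points[:, 0].max() + bound, points[:, 1].max() + bound,
    )
    for i, p in enumerate(points):
        dists, idx = tree.query(p, k=n)
        cell = outer
        for d, j in zip(dists[1:], idx[1:]):
            verts = np.asarray(cell.exterior.coords)
            r_max = np.max(np.hypot(verts[:, 0] - p[0], verts[:, 1] - p[1]))
            if d > 2.0 * r_max:
                break
            q = points[j]
            u = (q - p) / np.hypot(*(q - p))
            v = np.array([-u[1], u[0]])
            m = 0.5 * (p + q)
            half = Polygon(
                [m + big * v, m - big * v, m - big * v - big * u, m + big * v - big * u]
            )
            cell = cell.intersection(half)
        minx, miny, maxx, maxy = cell.bounds
        o_minx, o_miny, o_maxx, o_maxy = outer.bounds
        eps = 1e-6
        if (
            minx <= o_minx + eps or miny <= o_miny + eps
            or maxx >= o_maxx - eps or maxy >= o_maxy - eps
        ):
            areas[i] = np.inf
        else:
            areas[i] = cell.area
    return areas


def neighbor_counts_bruteforce(points: np.ndarray, radius: float) -> np.ndarray:
    """Number of *other* points within the (inclusive) radius, O(n^2)."""
    d = cdist(points, points)
    return (d <= radius).sum(axis=1) - 1


def distance_graph_partition(points: np.ndarray, cutoff: float, min_size: int):
    """Clusters as components of the complete distance-threshold graph."""
    import networkx as nx

    n = len(points)
    d = cdist(points, points)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= cutoff:
                g.add_edge(i, j)
    return {
        frozenset(c) for c in nx.connected_components(g) if len(c) >= min_size
    }


def itc_bound_bruteforce(sites: float, ligand_total: float, kd: float) -> float:
    """Bound concentration from a bracketed solve in free ligand."""
    if ligand_total == 0.0:
        return 0.0

    def residual(x_free):
        return x_free + sites * x_free / (kd + x_free) - ligand_total

    x = brentq(residual, 0.0, ligand_total, xtol=1e-300, rtol=8.9e-16)
    return sites * x / (kd + x)
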