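"""d-STORM cluster quantification: filtering, segmentation, molecule counting.

The pipeline reproduces a published sequential analysis of single-molecule
localization tables of RAD51 at DNA-damage sites:

1. discard localizations with < 1,000 detected photons or with a
   localization precision worse than 20 nm;
2. discard localizations whose local density, estimated as the inverse of
   their 2-D Voronoi polygon area, falls below 5e-5 nm^-2;
3. discard isolated detections with fewer than 20 neighbours within 100 nm;
4. compute the Delaunay triangulation of the survivors, drop edges longer
   than 20 nm, and take connected components as clusters, discarding
   components with fewer than 3 localizations;
5. estimate the number of labelled molecules per cluster by dividing its
   localization count by epsilon, the expected number of localizations per
   isolated secondary antibody, calibrated from a sparse single-antibody
   field.

Note on the precision filter direction: localizations with precision values
*larger* (worse) than the 20 nm threshold are discarded. The filter is
configurable via :class:`FilterConfig`.

Localization tables are plain pandas DataFrames with columns
``x_nm, y_nm, photons, precision_nm`` (see :mod:`rad51quant.io`). Each
stage returns a row-subset of its input with the original index preserved,
so filter decisions are traceable back to raw rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree
from scipy.stats import kruskal, rankdata, studentized_range

__all__ = [
    "REQUIRED_COLUMNS",
    "FilterConfig",
    "ClusterSet",
    "AntibodyCalibration",
    "GroupComparison",
    "validate_localizations",
    "filter_photons_precision",
    "voronoi_density_filter",
    "neighbor_count_filter",
    "delaunay_cluster",
    "calibrate_epsilon",
    "count_molecules",
    "cluster_metrics",
    "compare_groups",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("x_nm", "y_nm", "photons", "precision_nm")


def validate_localizations(table: pd.DataFrame) -> pd.DataFrame:
    """Check the localization-table schema; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"localization table is missing columns: {missing}")
    for col in REQUIRED_COLUMNS:
        if table[col].size and not np.issubdtype(table[col].dtype, np.number):
            bad = table[col].iloc[0]
            raise ValueError(
                f"column {col!r} must be numeric (first value: {bad!r})"
            )
    if np.any(table["precision_nm"].to_numpy() <= 0) and len(table):
        raise ValueError("localization precision must be > 0")
    return table


@dataclass(frozen=True)
class FilterConfig:
    """Pipeline thresholds; defaults are the published analysis values.

    min_photons: photon-count cut (localizations with fewer are discarded).
    max_precision_nm: precision cut; *worse* (larger) values are discarded.
    min_density_per_nm2: minimum inverse-Voronoi-polygon-area density.
    neighbor_radius_nm / min_neighbors: a detection needs at least
        ``min_neighbors`` other detections within the radius (inclusive).
    edge_cut_nm: Delaunay edges strictly longer than this are removed.
    min_cluster_size: connected components smaller than this are discarded.
    """

    min_photons: float = 1000.0
    max_precision_nm: float = 20.0
    min_density_per_nm2: float = 5e-5
    neighbor_radius_nm: float = 100.0
    min_neighbors: int = 20
    edge_cut_nm: float = 20.0
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        positives = (
            "min_photons",
            "max_precision_nm",
            "min_density_per_nm2",
            "neighbor_radius_nm",
            "min_neighbors",
            "edge_cut_nm",
            "min_cluster_size",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"FilterConfig.{name} must be > 0")


@dataclass
class ClusterSet:
    """Segmented clusters over a (filtered) localization table.

    ``labels`` assigns each row of ``table`` a cluster id (0..k-1) or -1 for
    unclustered noise. Molecule counts are attached by
    :func:`count_molecules`. ``stage_log`` records survivor counts for each
    pipeline stage that produced this set.
    """

    table: pd.DataFrame
    labels: np.ndarray
    config: FilterConfig
    stage_log: dict = field(default_factory=dict)
    epsilon: float | None = None
    molecules: pd.Series | None = None  # per-cluster real-valued count

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if self.labels.size else 0

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.arange(self.n_clusters)

    def sizes(self) -> pd.Series:
        """Localization count per cluster, indexed by cluster id."""
        lab = self.labels[self.labels >= 0]
        return (
            pd.Series(lab).value_counts().sort_index().rename("n_locs")
            if lab.size
            else pd.Series(dtype=int, name="n_locs")
        )

    def members(self, cluster_id: int) -> pd.Index:
        """Original row indices of the members of one cluster."""
        return self.table.index[self.labels == cluster_id]


@dataclass(frozen=True)
class AntibodyCalibration:
    """Expected localizations per labelled antibody (epsilon >= 1)."""

    epsilon: float
    source_sizes: tuple
    estimator: str = "median"

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")


# ---------------------------------------------------------------------------
# sequential filters
# ---------------------------------------------------------------------------

def filter_photons_precision(
    table: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Keep rows with photons >= min_photons and precision <= max_precision."""
    validate_localizations(table)
    keep = (table["photons"].to_numpy() >= cfg.min_photons) & (
        table["precision_nm"].to_numpy() <= cfg.max_precision_nm
    )
    return table.loc[keep]


def _voronoi_cell_areas(points: np.ndarray) -> np.ndarray:
    """Voronoi polygon area per input point; unbounded cells get inf."""
    vor = Voronoi(points)
    areas = np.full(len(points), np.inf)
    for i, region_index in enumerate(vor.point_region):
        region = vor.regions[region_index]
        if len(region) == 0 or -1 in region:
            continue
        verts = vor.vertices[region]
        # cells are convex: order vertices by angle about the centroid
        centre = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - centre[1], verts[:, 0] - centre[0]))
        v = verts[order]
        x, y = v[:, 0], v[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def voronoi_density_filter(
    table: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Keep rows whose Voronoi-cell density is at least ``min_density_per_nm2``.

    The tessellation is computed on the rows of ``table`` only (each stage
    sees its predecessor's survivors). Unbounded cells have zero density and
    are always removed. Degenerate inputs (< 4 points, or all collinear)
    have no 2-D tessellation: the filter returns an empty table and warns.
    """
    validate_localizations(table)
    if len(table) < 4:
        warnings.warn(
            "Voronoi density filter: fewer than 4 points, tessellation "
            "undefined; removing all rows",
            stacklevel=2,
        )
        return table.iloc[0:0]
    pts = table[["x_nm", "y_nm"]].to_numpy()
    try:
        areas = _voronoi_cell_areas(pts)
    except QhullError:
        warnings.warn(
            "Voronoi density filter: degenerate (collinear) input; "
            "removing all rows",
            stacklevel=2,
        )
        return table.iloc[0:0]
    max_area = 1.0 / cfg.min_density_per_nm2
    return table.loc[areas <= max_area]


def neighbor_count_filter(
    table: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Keep rows with >= min_neighbors other rows within the radius.

    The boundary is inclusive (a neighbour exactly at the radius counts);
    the point itself is excluded from its own neighbour count.
    """
    validate_localizations(table)
    if len(table) == 0:
        return table
    pts = table[["x_nm", "y_nm"]].to_numpy()
    tree = cKDTree(pts)
    counts = tree.query_ball_point(
        pts, r=cfg.neighbor_radius_nm, return_length=True
    ) - 1  # self
    return table.loc[counts >= cfg.min_neighbors]


# ---------------------------------------------------------------------------
# segmentation and counting
# ---------------------------------------------------------------------------

def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edges (i, j) of the Delaunay triangulation."""
    tri = Delaunay(points)
    edges = np.vstack(
        [tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]
    )
    edges.sort(axis=1)
    return np.unique(edges, axis=0)


def delaunay_cluster(
    table: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> ClusterSet:
    """Segment localizations into clusters via Delaunay edge cutting.

    Clusters are the connected components of the graph of Delaunay edges
    with Euclidean length <= ``edge_cut_nm`` (edges strictly longer are
    removed); components with fewer than ``min_cluster_size`` members are
    labelled noise (-1). Cluster ids are contiguous, ordered by first row
    occurrence.
    """
    validate_localizations(table)
    n = len(table)
    if n < 3:
        return ClusterSet(table=table, labels=np.full(n, -1), config=cfg)
    pts = table[["x_nm", "y_nm"]].to_numpy()
    try:
        edges = _delaunay_edges(pts)
    except QhullError:
        warnings.warn(
            "Delaunay clustering: degenerate (collinear) input; no clusters",
            stacklevel=2,
        )
        return ClusterSet(table=table, labels=np.full(n, -1), config=cfg)
    lengths = np.hypot(
        pts[edges[:, 0], 0] - pts[edges[:, 1], 0],
        pts[edges[:, 0], 1] - pts[edges[:, 1], 1],
    )
    keep = edges[lengths <= cfg.edge_cut_nm]
    graph = sparse.coo_matrix(
        (np.ones(len(keep)), (keep[:, 0], keep[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    labels = np.full(n, -1)
    next_id = 0
    sizes = np.bincount(comp)
    seen: dict[int, int] = {}
    for row, c in enumerate(comp):
        if sizes[c] < cfg.min_cluster_size:
            continue
        if c not in seen:
            seen[c] = next_id
            next_id += 1
        labels[row] = seen[c]
    return ClusterSet(table=table, labels=labels, config=cfg)


def calibrate_epsilon(
    calibration_table: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
    estimator: str = "median",
) -> AntibodyCalibration:
    """Estimate epsilon from a field of spatially isolated single antibodies.

    The calibration field is processed with the same photon/precision filter
    and the same Delaunay segmentation (edge cut and minimum size) as the
    main pipeline, so that epsilon reflects the same detection losses. The
    density and neighbour filters are *not* applied: they are designed for
    crowded damage-site fields and would reject every isolated antibody,
    whose handful of localizations can never accumulate 20 neighbours.

    epsilon is the median cluster size by default (robust to the heavy
    right tail of blinking counts); pass ``estimator="mean"`` for the mean.
    """
    filtered = filter_photons_precision(calibration_table, cfg)
    clusters = delaunay_cluster(filtered, cfg)
    sizes = clusters.sizes().to_numpy()
    if sizes.size == 0:
        raise ValueError("no calibration clusters found in the calibration field")
    if estimator == "median":
        eps = float(np.median(sizes))
    elif estimator == "mean":
        eps = float(np.mean(sizes))
    else:
        raise ValueError("estimator must be 'median' or 'mean'")
    return AntibodyCalibration(
        epsilon=max(eps, 1.0), source_sizes=tuple(int(s) for s in sizes),
        estimator=estimator,
    )


def count_molecules(clusters: ClusterSet, cal: AntibodyCalibration) -> ClusterSet:
    """Estimate molecules per cluster as localization count / epsilon.

    The real-valued estimate is kept for statistics; a rounded display value
    (never below 1 for a non-empty cluster) is available from
    :func:`cluster_metrics`.
    """
    if cal.epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    sizes = clusters.sizes()
    molecules = (sizes / cal.epsilon).rename("n_mol")
    return replace(clusters, epsilon=cal.epsilon, molecules=molecules)


def cluster_metrics(clusters: ClusterSet) -> pd.DataFrame:
    """Per-cluster shape and count metrics.

    Columns: n_locs, x_c, y_c (centroid), extent_nm (range of projections
    on the principal axis), anisotropy (major/minor axis spread ratio; inf
    for collinear clusters), extended (extent > 200 nm), and when molecule
    counts have been attached, n_mol and n_mol_rounded.
    """
    if clusters.n_clusters == 0:
        raise ValueError("cluster set is empty")
    pts = clusters.table[["x_nm", "y_nm"]].to_numpy()
    records = []
    for cid in clusters.cluster_ids:
        sub = pts[clusters.labels == cid]
        centroid = sub.mean(axis=0)
        centred = sub - centroid
        cov = centred.T @ centred / len(sub)
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, -1]
        proj = centred @ major
        extent = float(proj.max() - proj.min())
        minor_sd = np.sqrt(max(evals[0], 0.0))
        major_sd = np.sqrt(max(evals[1], 0.0))
        anisotropy = major_sd / minor_sd if minor_sd > 0 else np.inf
        records.append(
            {
                "cluster_id": int(cid),
                "n_locs": int(len(sub)),
                "x_c": float(centroid[0]),
                "y_c": float(centroid[1]),
                "extent_nm": extent,
                "anisotropy": float(anisotropy),
                "extended": extent > 200.0,
            }
        )
    metrics = pd.DataFrame.from_records(records).set_index("cluster_id")
    if clusters.molecules is not None:
        metrics["n_mol"] = clusters.molecules
        metrics["n_mol_rounded"] = np.maximum(
            1, np.rint(clusters.molecules).astype(int)
        )
    return metrics


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Kruskal-Wallis test with Tukey-Kramer-adjusted pairwise comparisons."""

    h_statistic: float
    p_value: float
    df: int
    alpha: float
    summaries: pd.DataFrame
    pairwise: pd.DataFrame
    message: str = ""

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.pairwise.empty:
            return []
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


def _box_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    return {
        "n": int(values.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()),
        "whisker_high": float(in_hi.max()),
        "mean": float(values.mean()),
    }


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Compare per-cluster molecule-count distributions across conditions.

    Kruskal-Wallis H (tie-corrected) across all groups, followed by
    pairwise comparisons of group mean ranks with Tukey-Kramer familywise
    adjustment: the pair statistic |dR| / sqrt(S^2/2 (1/n_a + 1/n_b)) is
    referred to the studentized range distribution with k groups and
    infinite degrees of freedom, where S^2 is the tie-corrected pooled rank
    variance N(N+1)/12 * (1 - sum(t^3 - t)/(N^3 - N)). This mirrors the
    behaviour of common post-Kruskal-Wallis multiple-comparison routines.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")

    summaries = pd.DataFrame({k: _box_summary(v) for k, v in data.items()}).T
    pooled = np.concatenate([data[k] for k in names])
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            h_statistic=np.nan,
            p_value=np.nan,
            df=len(names) - 1,
            alpha=alpha,
            summaries=summaries,
            pairwise=pd.DataFrame(
                columns=[
                    "group_a", "group_b", "rank_diff", "se", "q", "p_adj",
                    "significant",
                ]
            ),
            message="H undefined: all observations identical across groups",
        )

    h, p = kruskal(*[data[k] for k in names])

    ranks = rankdata(pooled)
    sizes = np.array([data[k].size for k in names])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = {
        k: ranks[bounds[i]: bounds[i + 1]].mean() for i, k in enumerate(names)
    }
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n_total ** 3 - n_total)
    s2 = n_total * (n_total + 1) / 12.0 * (1.0 - tie_term)

    k_groups = len(names)
    rows = []
    for i in range(k_groups):
        for j in range(i + 1, k_groups):
            a, b = names[i], names[j]
            diff = mean_ranks[a] - mean_ranks[b]
            se = np.sqrt(s2 * 0.5 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(diff) / se
            p_adj = float(studentized_range.sf(q, k_groups, np.inf))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "rank_diff": float(diff),
                    "se": float(se),
                    "q": float(q),
                    "p_adj": p_adj,
                    "significant": p_adj <= alpha,
                }
            )
    return GroupComparison(
        h_statistic=float(h),
        p_value=float(p),
        df=k_groups - 1,
        alpha=alpha,
        summaries=summaries,
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    table: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
    cal: AntibodyCalibration | None = None,
) -> tuple[ClusterSet, dict]:
    """Run the full sequential pipeline and return (clusters, stage log).

    Stage order: photon/precision filter -> Voronoi density filter ->
    neighbour-count filter -> Delaunay clustering -> molecule counting
    (when a calibration is supplied). Each stage consumes only the previous
    stage's survivors. Deterministic: no randomness anywhere.
    """
    validate_localizations(table)
    log: dict = {"input": int(len(table))}
    with warnings.catch_warnings():
        if len(table) == 0:
            warnings.simplefilter("ignore")
        t1 = filter_photons_precision(table, cfg)
        log["photon_precision"] = int(len(t1))
        t2 = voronoi_density_filter(t1, cfg) if len(t1) else t1
        log["voronoi_density"] = int(len(t2))
        t3 = neighbor_count_filter(t2, cfg)
        log["neighbor_count"] = int(len(t3))
        clusters = delaunay_cluster(t3, cfg)
    log["clustered_localizations"] = int(np.sum(clusters.labels >= 0))
    log["n_clusters"] = clusters.n_clusters
    if cal is not None:
        clusters = count_molecules(clusters, cal)
        log["epsilon"] = cal.epsilon
    clusters.stage_log = log
    return clusters, log
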