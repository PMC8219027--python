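"""Localization filtering, segmentation, and molecule counting."""

import numpy as np
import pandas as pd
import pytest

from rad51quant import (
    AntibodyCalibration,
    ClusterSet,
    ClusterSpec,
    FilterConfig,
    calibrate_epsilon,
    cluster_metrics,
    count_molecules,
    delaunay_cluster,
    filter_photons_precision,
    neighbor_count_filter,
    run_pipeline,
    simulate_localizations,
    voronoi_density_filter,
)

from oracles import (
    distance_graph_partition,
    halfplane_voronoi_areas,
    neighbor_counts_bruteforce,
)

CFG = FilterConfig()


def make_table(xy, photons=2000.0, precision=10.0):
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = len(xy)
    return pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "photons": np.broadcast_to(photons, n).astype(float),
            "precision_nm": np.broadcast_to(precision, n).astype(float),
        }
    )


def blob(center, n, radius=15.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    return make_table(
        np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)]),
        **kw,
    )


class TestPhotonPrecisionFilter:
    def test_rule_application(self):
        table = make_table(
            [[0, 0], [1, 1], [2, 2], [3, 3]],
            photons=[1500, 500, 1500, 999],
            precision=[10, 10, 25, 19],
        )
        kept = filter_photons_precision(table, CFG)
        assert list(kept.index) == [0]

    def test_boundary_inclusive(self):
        table = make_table([[0, 0]], photons=1000, precision=20.0)
        assert len(filter_photons_precision(table, CFG)) == 1

    def test_empty_table(self):
        table = make_table(np.empty((0, 2)))
        assert len(filter_photons_precision(table, CFG)) == 0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        n = 10000
        table = make_table(
            rng.uniform(0, 1000, (n, 2)),
            photons=rng.lognormal(np.log(1200), 0.6, n),
            precision=rng.uniform(5, 30, n),
        )
        kept = filter_photons_precision(table, CFG)
        expected = [
            i
            for i in range(n)
            if table.photons[i] >= 1000 and table.precision_nm[i] <= 20
        ]
        assert list(kept.index) == expected

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            filter_photons_precision(pd.DataFrame({"x_nm": [1.0]}), CFG)


class TestVoronoiDensityFilter:
    def test_square_lattice_interior_kept(self):
        # 50 nm grid: interior cell area 2,500 nm^2 -> density 4e-4 >> 5e-5
        xs, ys = np.meshgrid(np.arange(12) * 50.0, np.arange(12) * 50.0)
        table = make_table(np.column_stack([xs.ravel(), ys.ravel()]))
        kept = voronoi_density_filter(table, CFG)
        interior = [
            i
            for i, (x, y) in enumerate(zip(xs.ravel(), ys.ravel()))
            if 0 < x < 550 and 0 < y < 550
        ]
        assert set(interior) <= set(kept.index)

    def test_sparse_points_all_removed(self):
        pts = np.array([[0, 0], [2000, 0], [0, 2000], [2000, 2000], [1000, 1000]])
        kept = voronoi_density_filter(make_table(pts), CFG)
        assert len(kept) == 0

    def test_matches_halfplane_oracle(self):
        table, _ = simulate_localizations(
            ClusterSpec(n_clusters=4, background_density_per_nm2=2e-7), seed=5
        )
        table = table.iloc[:400].reset_index(drop=True)
        kept = voronoi_density_filter(table, CFG)
        areas = halfplane_voronoi_areas(table[["x_nm", "y_nm"]].to_numpy())
        expected = set(np.nonzero(areas <= 1.0 / CFG.min_density_per_nm2)[0])
        assert set(kept.index) == expected

    def test_degenerate_inputs_warn_and_empty(self):
        with pytest.warns(UserWarning):
            out = voronoi_density_filter(make_table([[0, 0], [1, 1]]), CFG)
        assert len(out) == 0
        collinear = make_table([[0, 0], [10, 0], [20, 0], [30, 0], [40, 0]])
        with pytest.warns(UserWarning):
            out = voronoi_density_filter(collinear, CFG)
        assert len(out) == 0


class TestNeighborCountFilter:
    def test_isolated_point_removed(self):
        table = make_table([[0, 0], [5000, 5000]])
        assert len(neighbor_count_filter(table, CFG)) == 0

    def test_dense_disc_all_kept(self):
        table = blob((0, 0), 25, radius=25.0, seed=1)
        assert len(neighbor_count_filter(table, CFG)) == 25

    def test_matches_quadratic_bruteforce(self):
        table, _ = simulate_localizations(
            ClusterSpec(n_clusters=5, background_density_per_nm2=3e-7), seed=9
        )
        kept = neighbor_count_filter(table, CFG)
        counts = neighbor_counts_bruteforce(
            table[["x_nm", "y_nm"]].to_numpy(), CFG.neighbor_radius_nm
        )
        assert list(kept.index) == list(np.nonzero(counts >= CFG.min_neighbors)[0])


class TestDelaunayCluster:
    def test_two_separated_blobs(self):
        table = pd.concat(
            [blob((0, 0), 10, seed=1), blob((500, 0), 10, seed=2)],
            ignore_index=True,
        )
        cs = delaunay_cluster(table, CFG)
        assert cs.n_clusters == 2
        assert sorted(cs.sizes()) == [10, 10]

    def test_pair_below_min_size_dropped(self):
        table = make_table([[0, 0], [5, 0]])
        cs = delaunay_cluster(table, CFG)
        assert cs.n_clusters == 0

    def test_chain_splits_at_gap(self):
        # near-collinear chain, 15 nm spacing: one cluster; a 25 nm gap
        # splits it in two
        x = np.arange(50) * 15.0
        y = np.where(np.arange(50) % 2 == 0, 0.0, 1.0)
        chain = make_table(np.column_stack([x, y]))
        cs = delaunay_cluster(chain, CFG)
        assert cs.n_clusters == 1 and cs.sizes().iloc[0] == 50
        x2 = x.copy()
        x2[25:] += 10.0  # widen one gap from 15 to 25 nm
        cs2 = delaunay_cluster(make_table(np.column_stack([x2, y])), CFG)
        assert cs2.n_clusters == 2

    def test_matches_distance_graph_partition(self):
        table, _ = simulate_localizations(
            ClusterSpec(n_clusters=6, background_density_per_nm2=2e-7), seed=11
        )
        cs = delaunay_cluster(table.reset_index(drop=True), CFG)
        ours = {
            frozenset(np.nonzero(cs.labels == cid)[0])
            for cid in range(cs.n_clusters)
        }
        # Delaunay-edge-cut components equal full distance-graph components
        # (the triangulation contains the Euclidean MST)
        expected = distance_graph_partition(
            table[["x_nm", "y_nm"]].to_numpy(), CFG.edge_cut_nm, CFG.min_cluster_size
        )
        assert ours == expected

    def test_collinear_warns_no_clusters(self):
        table = make_table([[0, 0], [10, 0], [20, 0], [30, 0]])
        with pytest.warns(UserWarning):
            cs = delaunay_cluster(table, CFG)
        assert cs.n_clusters == 0


class TestCalibration:
    def test_exact_singletons(self):
        tables = [blob((i * 2000.0, 0), 8, radius=10.0, seed=i) for i in range(10)]
        cal = calibrate_epsilon(pd.concat(tables, ignore_index=True), CFG)
        assert cal.epsilon == 8.0

    def test_median_of_sizes(self):
        sizes = [4, 6, 8, 10, 12]
        tables = [
            blob((i * 2000.0, 0), s, radius=10.0, seed=i)
            for i, s in enumerate(sizes)
        ]
        cal = calibrate_epsilon(pd.concat(tables, ignore_index=True), CFG)
        assert cal.epsilon == 8.0
        assert sorted(cal.source_sizes) == sizes

    def test_geometric_blinking_recovered(self):
        spec = ClusterSpec(
            n_clusters=500,
            molecules_per_cluster_range=(1, 1),
            localizations_per_molecule_mean=8.0,
            background_density_per_nm2=0.0,
        )
        table, _ = simulate_localizations(spec, seed=21)
        cal = calibrate_epsilon(table, CFG)
        assert abs(cal.epsilon - 8.0) / 8.0 <= 0.25

    def test_no_clusters_raises(self):
        with pytest.raises(ValueError, match="calibration"):
            calibrate_epsilon(make_table([[0, 0], [5000, 5000]]), CFG)


class TestCountMolecules:
    def test_division_and_floor_guard(self):
        table = pd.concat(
            [blob((0, 0), 40, seed=1), blob((3000, 0), 3, radius=5.0, seed=2)],
            ignore_index=True,
        )
        cs = delaunay_cluster(table, CFG)
        cal = AntibodyCalibration(epsilon=8.0, source_sizes=())
        counted = count_molecules(cs, cal)
        metrics = cluster_metrics(counted)
        by_size = metrics.sort_values("n_locs")
        assert by_size.n_mol.iloc[-1] == pytest.approx(5.0)
        assert by_size.n_mol_rounded.iloc[0] == 1  # 3/8 rounds up to the floor of 1


class TestClusterMetrics:
    def test_collinear_extent_flagged_extended(self):
        table = make_table([[0, 0], [150, 0], [300, 0]])
        cs = ClusterSet(table=table, labels=np.array([0, 0, 0]), config=CFG)
        m = cluster_metrics(cs)
        assert m.extent_nm.iloc[0] == pytest.approx(300.0)
        assert bool(m.extended.iloc[0])
        assert np.isinf(m.anisotropy.iloc[0])

    def test_isotropic_disc_near_unit_anisotropy(self):
        table = blob((0, 0), 400, radius=50.0, seed=3)
        cs = ClusterSet(table=table, labels=np.zeros(400, dtype=int), config=CFG)
        m = cluster_metrics(cs)
        assert m.anisotropy.iloc[0] == pytest.approx(1.0, abs=0.15)
        assert not bool(m.extended.iloc[0])

    def test_filament_extent_recovered(self):
        spec = ClusterSpec(
            n_clusters=5,
            cluster_shape="filament",
            molecules_per_cluster_range=(30, 50),
            filament_length_nm=400.0,
            filament_width_nm=30.0,
            background_density_per_nm2=0.0,
            min_separation_nm=1500.0,
        )
        rels = []
        for seed in range(5):
            table, truth = simulate_localizations(spec, seed=seed)
            clusters, _ = run_pipeline(table)
            m = cluster_metrics(clusters)
            for _, row in truth.clusters.iterrows():
                d = np.hypot(m.x_c - row.x_c, m.y_c - row.y_c)
                rels.append(abs(m.extent_nm[d.idxmin()] - 400.0) / 400.0)
        assert np.median(rels) < 0.15


class TestPipeline:
    def test_empty_input(self):
        clusters, log = run_pipeline(make_table(np.empty((0, 2))), CFG)
        assert clusters.n_clusters == 0
        assert log["input"] == 0 and log["n_clusters"] == 0

    def test_composition_equals_manual_stages(self):
        table, _ = simulate_localizations(ClusterSpec(n_clusters=5), seed=2)
        cal = AntibodyCalibration(epsilon=10.0, source_sizes=())
        clusters, log = run_pipeline(table, CFG, cal)
        t1 = filter_photons_precision(table, CFG)
        t2 = voronoi_density_filter(t1, CFG)
        t3 = neighbor_count_filter(t2, CFG)
        manual = count_molecules(delaunay_cluster(t3, CFG), cal)
        assert np.array_equal(clusters.labels, manual.labels)
        assert clusters.table.equals(manual.table)
        assert log["photon_precision"] == len(t1)
        assert log["voronoi_density"] == len(t2)
        assert log["neighbor_count"] == len(t3)

    def test_stages_return_row_subsets(self):
        table, _ = simulate_localizations(ClusterSpec(n_clusters=3), seed=4)
        t1 = filter_photons_precision(table, CFG)
        t2 = voronoi_density_filter(t1, CFG)
        t3 = neighbor_count_filter(t2, CFG)
        assert set(t1.index) <= set(table.index)
        assert set(t2.index) <= set(t1.index)
        assert set(t3.index) <= set(t2.index)

    def test_determinism(self):
        table, _ = simulate_localizations(ClusterSpec(n_clusters=4), seed=6)
        a, log_a = run_pipeline(table, CFG)
        b, log_b = run_pipeline(table, CFG)
        assert np.array_equal(a.labels, b.labels)
        assert log_a == log_b

    def test_threshold_monotonicity(self):
        table, _ = simulate_localizations(ClusterSpec(n_clusters=5), seed=8)
        base = FilterConfig()
        stricter = [
            FilterConfig(min_photons=1500),
            FilterConfig(max_precision_nm=15.0),
            FilterConfig(min_density_per_nm2=1e-4),
            FilterConfig(min_neighbors=30),
        ]
        _, log0 = run_pipeline(table, base)
        for cfg in stricter:
            _, log = run_pipeline(table, cfg)
            assert log["neighbor_count"] <= log0["neighbor_count"]
        # a larger edge cut never increases the cluster count on a fixed set
        t3 = neighbor_count_filter(
            voronoi_density_filter(filter_photons_precision(table, base), base), base
        )
        n_40 = delaunay_cluster(t3, FilterConfig(edge_cut_nm=40.0)).n_clusters
        n_20 = delaunay_cluster(t3, base).n_clusters
        assert n_40 <= n_20

    def test_counting_exact_given_segmentation(self):
        # with dispersion-free blinking the counting stage itself is exact:
        # segmenting the raw field recovers every planted count perfectly
        # (the sequential density filter, by contrast, erodes cluster
        # peripheries and biases full-pipeline counts slightly low)
        spec = ClusterSpec(
            molecules_per_cluster_range=(5, 10),
            localizations_per_molecule_mean=8.0,
            localizations_per_molecule_dispersion=0.0,
            background_density_per_nm2=0.0,
        )
        cal_spec = ClusterSpec(
            n_clusters=50,
            molecules_per_cluster_range=(1, 1),
            localizations_per_molecule_mean=8.0,
            localizations_per_molecule_dispersion=0.0,
            photon_median=5000.0,
            photon_sigma_log=0.1,
            background_density_per_nm2=0.0,
        )
        errors = []
        for seed in range(5):
            table, truth = simulate_localizations(spec, seed=seed)
            cal_table, _ = simulate_localizations(cal_spec, seed=100 + seed)
            cal = calibrate_epsilon(cal_table, CFG)
            assert cal.epsilon == 8.0
            counted = count_molecules(delaunay_cluster(table, CFG), cal)
            m = cluster_metrics(counted)
            for _, row in truth.clusters.iterrows():
                d = np.hypot(m.x_c - row.x_c, m.y_c - row.y_c)
                errors.append(m.n_mol[d.idxmin()] - row.n_molecules)
        # not exactly zero: the minimum-size rule occasionally drops a
        # 1-2-localization satellite split off a cluster
        assert np.mean(errors) == pytest.approx(0.0, abs=0.1)
        assert np.median(np.abs(errors)) == 0.0
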