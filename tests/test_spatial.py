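import numpy as np
import pandas as pd
import pytest

from phylogeokit.distances import DistanceMatrix, geographic_matrix, jaccard_matrix
from phylogeokit.io import SampleTable
from phylogeokit.ordination import ClusterAssignment
from phylogeokit.simulate import SimulationConfig, simulate_aflp, simulate_landscape
from phylogeokit.spatial import (
    DistanceBasedRDA,
    anosim,
    anosim_pairwise,
    dbrda,
    ibd_cluster_report,
)

from conftest import distance_matrix_from_points


class TestAnosim:
    def test_maximal_separation_r_one(self):
        # all between-distances exceed all within-distances
        D = np.array(
            [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], float
        )
        res = anosim(
            DistanceMatrix(list("abcd"), D), np.array([1, 1, 2, 2]),
            n_permutations=999, seed=0,
        )
        assert res.r == pytest.approx(1.0)
        # hand ranks: within {1.5, 1.5}, between {4.5 x4}; R = (4.5-1.5)/3
        assert res.mean_within_rank == pytest.approx(1.5)
        assert res.mean_between_rank == pytest.approx(4.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(16, 2))
        D = distance_matrix_from_points(pts)
        labels = np.repeat([1, 2], 8)
        r1 = anosim(D, labels, n_permutations=99, seed=3).r
        D2 = DistanceMatrix(D.labels, np.sqrt(D.values))
        r2 = anosim(D2, labels, n_permutations=99, seed=3).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(3, 1, (10, 2))])
        D = distance_matrix_from_points(pts)
        labels = [1] * 8 + [2] * 10
        mine = anosim(D, np.array(labels), n_permutations=999, seed=0)
        ref = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(D.values, D.labels),
            grouping=[str(l) for l in labels],
            permutations=0,
        )
        assert mine.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_group_size_validation(self):
        D = DistanceMatrix(list("abc"), np.array(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(D, np.array([1, 2, 2]), n_permutations=9)

    def test_pairwise_geometry(self):
        rng = np.random.default_rng(2)
        # groups 1 and 2 disjoint, group 3 overlaps group 2
        pts = np.vstack(
            [
                rng.normal(0, 0.5, (8, 2)),
                rng.normal((10, 0), 0.5, (8, 2)),
                rng.normal((10.5, 0), 0.5, (8, 2)),
            ]
        )
        D = distance_matrix_from_points(pts)
        labels = np.repeat([1, 2, 3], 8)
        table = anosim_pairwise(D, labels, n_permutations=199, seed=0)
        table = table.set_index(["group_a", "group_b"])
        assert table.loc[(1, 2), "R"] == pytest.approx(1.0)
        assert table.loc[(2, 3), "R"] < table.loc[(1, 2), "R"]
        assert (table["p_corrected"] >= table["p_raw"] - 1e-12).all()

    def test_pairwise_null_no_spurious_hits(self):
        # random labels on one point cloud: corrected p rarely < 0.05
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            pts = rng.normal(size=(18, 2))
            D = distance_matrix_from_points(pts)
            labels = rng.permutation(np.repeat([1, 2, 3], 6))
            table = anosim_pairwise(D, labels, n_permutations=99, seed=rep)
            if (table["p_corrected"] < 0.05).any():
                hits += 1
        assert hits <= max(2, int(0.06 * n_rep) + 2)


class TestDbrda:
    def test_ols_oracle_univariate(self):
        import statsmodels.api as sm

        y = np.array([0.0, 1.0, 2.0, 4.0])
        x = np.array([0.0, 1.0, 2.0, 3.0])
        D = DistanceMatrix(list("abcd"), np.abs(y[:, None] - y[None, :]))
        res = dbrda(D, x, n_permutations=99, seed=0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.pseudo_f == pytest.approx(ols.fvalue, abs=1e-8)
        assert res.proportion_explained == pytest.approx(ols.rsquared, abs=1e-8)

    def test_multivariate_rda_oracle(self):
        # Euclidean response distances: pseudo-F equals classical RDA F
        rng = np.random.default_rng(3)
        n = 20
        Y = rng.normal(size=(n, 3))
        X = rng.normal(size=(n, 2))
        D = distance_matrix_from_points(Y)
        res = dbrda(D, X, n_permutations=99, seed=0)
        # classical RDA: F = (SS_fit/m) / (SS_res/(n-m-1)) on centred Y
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        H = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
        ss_fit = np.trace(H @ Yc @ Yc.T)
        ss_tot = np.trace(Yc @ Yc.T)
        f = (ss_fit / 2) / ((ss_tot - ss_fit) / (n - 3))
        assert res.pseudo_f == pytest.approx(f, abs=1e-8)
        assert res.proportion_explained == pytest.approx(ss_fit / ss_tot, abs=1e-8)

    def test_trace_additivity(self, small_bundle):
        D = jaccard_matrix(small_bundle["markers"])
        coords = small_bundle["samples"].coordinates()
        res = dbrda(D, coords, n_permutations=49, seed=1)
        # fitted + residual traces recover the total variation
        assert res.trace_fitted <= res.trace_total + 1e-8
        assert 0.0 <= res.proportion_explained <= 1.0

    def test_permutation_reproducible(self):
        rng = np.random.default_rng(5)
        D = distance_matrix_from_points(rng.normal(size=(15, 2)))
        X = rng.normal(size=15)
        p1 = dbrda(D, X, n_permutations=199, seed=9).p_value
        p2 = dbrda(D, X, n_permutations=199, seed=9).p_value
        assert p1 == p2

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(6)
        D = distance_matrix_from_points(rng.normal(size=(10, 2)))
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank-deficient"):
            DistanceBasedRDA(D, X)

    def test_partial_removes_covariate_signal(self):
        # response depends only on z; after partialling z out, x explains ~0
        rng = np.random.default_rng(8)
        n = 30
        z = rng.normal(size=n)
        x = z + rng.normal(0, 0.1, n)  # x nearly collinear with z
        y = 2 * z + rng.normal(0, 0.1, n)
        D = DistanceMatrix(
            [f"i{i}" for i in range(n)], np.abs(y[:, None] - y[None, :])
        )
        res = dbrda(D, x, Z=z, n_permutations=199, seed=0)
        full = dbrda(D, x, n_permutations=199, seed=0)
        assert res.proportion_explained < 0.05
        assert full.proportion_explained > 0.5
        assert res.p_value > 0.05


class TestIbdClusterReport:
    def _samples_from_landscape(self, samples):
        return samples

    def test_pure_ibd_single_cluster(self):
        conf = SimulationConfig(
            seed=21, n_clusters=1, n_individuals=40, n_localities=30,
            n_loci=150, ibd_gradient_strength=0.004, admixture_zone_width=0.0,
            ldd_rate=0.0, n_env_selected_loci=0,
        )
        land = simulate_landscape(conf)
        markers, samples, _ = simulate_aflp(land, conf)
        D = jaccard_matrix(markers)
        labels = ClusterAssignment.from_array(
            markers.individual_ids, np.ones(40, int)
        )
        report = ibd_cluster_report(D, samples, labels, n_permutations=199, seed=0)
        assert report["clusters_given_space"] is None
        assert report["ibd"].p_value < 0.05

    def test_island_model_clusters_dominate(self):
        conf = SimulationConfig(
            seed=22, n_clusters=3, n_individuals=45, n_localities=30,
            n_loci=150, ibd_gradient_strength=0.0, admixture_zone_width=0.0,
            ldd_rate=0.0, n_env_selected_loci=0,
        )
        land = simulate_landscape(conf)
        markers, samples, truth = simulate_aflp(land, conf)
        D = jaccard_matrix(markers)
        labels = ClusterAssignment.from_array(
            markers.individual_ids, truth["cluster_true"]
        )
        report = ibd_cluster_report(D, samples, labels, n_permutations=199, seed=1)
        assert (
            report["clusters_given_space"].proportion_explained
            > report["ibd"].proportion_explained
        )
        per = report["per_cluster"]
        assert (per["n"] >= 4).all()

    def test_small_cluster_skipped(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        D = distance_matrix_from_points(pts)
        samples = SampleTable(
            pd.DataFrame(
                {
                    "individual_id": D.labels,
                    "locality_id": D.labels,
                    "latitude": 35 + 0.01 * pts[:, 0],
                    "longitude": 24 + 0.01 * pts[:, 1],
                }
            )
        )
        labels = ClusterAssignment.from_array(
            D.labels, [1] * 8 + [2] * 2
        )
        with pytest.warns(UserWarning, match="skipped"):
            report = ibd_cluster_report(D, samples, labels, n_permutations=49, seed=0)
        per = report["per_cluster"].set_index("cluster")
        assert np.isnan(per.loc[2, "pseudo_F"])
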