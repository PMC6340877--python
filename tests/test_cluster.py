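"""PCA embedding and PAM k-medoids clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vafshape.cluster import (
    assign_new_sample,
    choose_k_diagnostics,
    cluster_cohort,
    exhaustive_kmedoids,
    fit_kmedoids,
    fit_pca,
    kmedoids_cost,
    load_model,
    save_model,
)
from vafshape.shape_params import ShapeParams


def _params(rows, prefix="S"):
    return [
        ShapeParams(f"{prefix}{i}", m_peak=r[0], m_count=r[1], m_math=r[2])
        for i, r in enumerate(rows)
    ]


class TestPCA:
    def test_explained_fractions_sum_to_one(self, rng):
        params = _params(rng.uniform(0, 1, size=(50, 3)))
        model, _ = fit_pca(params)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_isotropic_features_split_variance_equally(self, rng):
        params = _params(rng.normal(0, 1, size=(10_000, 3)))
        model, _ = fit_pca(params)
        assert model.explained_variance_fraction == pytest.approx(
            [1 / 3] * 3, abs=0.03
        )

    def test_collinear_data_loads_on_first_component(self, rng):
        t = rng.normal(0, 1, size=80)
        params = _params(np.column_stack([t, 2 * t, -t]))
        model, _ = fit_pca(params, standardize=False)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        params = _params(rng.uniform(0, 1, size=(40, 3)))
        model, _ = fit_pca(params)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_zero_variance_feature_error_names_feature(self):
        rows = [(0.1, 3.0, 0.2), (0.2, 3.0, 0.3), (0.3, 3.0, 0.1),
                (0.15, 3.0, 0.25)]
        with pytest.raises(ValueError, match="m_count"):
            fit_pca(_params(rows))

    def test_transform_reproduces_training_scores(self, rng):
        params = _params(rng.uniform(0, 1, size=(30, 3)))
        model, coords = fit_pca(params)
        again = model.transform(np.array([p.as_array() for p in params]))
        assert np.allclose(coords, again)


class TestPAM:
    def test_line_instance_brute_force_optimum(self):
        points = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        model = fit_kmedoids(points, k=2)
        assert sorted(points[model.medoid_indices].ravel()) == [1.0, 11.0]
        assert model.cost == pytest.approx(4.0)

    def test_k_equals_n_zero_cost(self, rng):
        points = rng.uniform(0, 1, size=(5, 2))
        model = fit_kmedoids(points, k=5)
        assert model.cost == pytest.approx(0.0)
        assert sorted(model.medoid_indices) == list(range(5))

    def test_duplicate_points_tie_resolves_to_first(self):
        points = np.array([[1.0, 1.0], [1.0, 1.0]])
        model = fit_kmedoids(points, k=1)
        assert model.cost == pytest.approx(0.0)
        assert model.medoid_indices == [0]

    def test_matches_exhaustive_optimum_on_small_instances(self):
        """PAM's local optimum equals the global optimum on every random
        instance with n <= 8, k <= 3 (100 instances)."""
        rng = np.random.default_rng(1234)
        for trial in range(100):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, min(3, n - 1) + 1))
            points = rng.uniform(-5, 5, size=(n, 2))
            model = fit_kmedoids(points, k=k)
            _, best_cost = exhaustive_kmedoids(points, k)
            assert model.cost == pytest.approx(best_cost, rel=1e-10), (
                f"trial {trial}: PAM {model.cost} vs optimum {best_cost}"
            )

    def test_local_optimality_no_single_swap_improves(self, rng):
        points = rng.normal(0, 1, size=(40, 2))
        model = fit_kmedoids(points, k=4)
        medoids = list(model.medoid_indices)
        for i, m in enumerate(medoids):
            for h in range(len(points)):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[i] = h
                assert kmedoids_cost(points, trial) >= model.cost - 1e-9

    def test_labels_stable_under_input_permutation(self, rng):
        points = np.vstack([
            rng.normal(0, 0.3, size=(20, 2)),
            rng.normal(5, 0.3, size=(20, 2)),
            rng.normal((0, 5), 0.3, size=(20, 2)),
        ])
        ids = [f"S{i}" for i in range(60)]
        model_a = fit_kmedoids(points, k=3, sample_ids=ids)
        perm = rng.permutation(60)
        model_b = fit_kmedoids(points[perm], k=3,
                               sample_ids=[ids[i] for i in perm])
        labels_a = np.array([model_a.labels[s] for s in ids])
        labels_b = np.array([model_b.labels[s] for s in ids])
        assert adjusted_rand_score(labels_a, labels_b) == pytest.approx(1.0)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_kmedoids(rng.uniform(0, 1, size=(3, 2)), k=4)


class TestChooseK:
    def test_silhouette_maximal_at_true_k(self, rng):
        blobs = np.vstack([
            rng.normal((0, 0), 0.2, size=(30, 2)),
            rng.normal((6, 0), 0.2, size=(30, 2)),
            rng.normal((3, 6), 0.2, size=(30, 2)),
        ])
        table = choose_k_diagnostics(blobs, k_range=[2, 3, 4, 5])
        best = table.loc[table["mean_silhouette"].idxmax(), "k"]
        assert best == 3

    def test_cost_decreases_with_k_on_single_blob(self, rng):
        points = rng.normal(0, 1, size=(60, 2))
        table = choose_k_diagnostics(points, k_range=[2, 3, 4, 5, 6])
        assert (np.diff(table["cost"]) < 0).all()

    def test_one_row_per_candidate_k(self, rng):
        points = rng.normal(0, 1, size=(30, 2))
        table = choose_k_diagnostics(points, k_range=[3, 4, 5, 6])
        assert list(table["k"]) == [3, 4, 5, 6]


class TestAssignAndPersist:
    def test_medoid_sample_assigned_to_own_cluster(self, cohort_profile):
        params = cohort_profile["params"]
        model = cluster_cohort(params, k=5, seed=0)
        by_id = {p.sample_id: p for p in params}
        for cluster_id, sid in enumerate(model.clusters.medoid_sample_ids, start=1):
            assert assign_new_sample(model.pca, model.clusters, by_id[sid]) == \
                model.clusters.labels[sid]

    def test_equidistant_point_takes_lower_cluster_id(self):
        from vafshape.cluster import ClusterModel, PCAModel

        pca = PCAModel(
            feature_means=np.zeros(3),
            feature_scales=np.ones(3),
            loadings=np.eye(3),
            explained_variance_fraction=np.array([0.5, 0.3, 0.2]),
        )
        clusters = ClusterModel(
            k=2, medoid_indices=[0, 1],
            medoid_coords=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            medoid_sample_ids=["A", "B"],
            labels={"A": 1, "B": 2}, cost=0.0,
        )
        midpoint = ShapeParams("M", m_peak=0.0, m_count=0.0, m_math=0.0)
        assert assign_new_sample(pca, clusters, midpoint) == 1

    def test_model_round_trips_through_json(self, tmp_path, cohort_profile):
        params = cohort_profile["params"][:50]
        model = cluster_cohort(params, k=3, seed=0)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.clusters.labels == model.clusters.labels
        assert np.allclose(back.pca.loadings, model.pca.loadings)
        assert np.allclose(back.clusters.medoid_coords, model.clusters.medoid_coords)


class TestArchetypeRecovery:
    def test_five_archetype_cohort_recovered_with_high_ari(self, cohort_profile):
        """End-to-end: filter + shape + PCA + PAM recovers the generating
        archetype labels (ARI >= 0.8 on the default 500-sample cohort)."""
        params = cohort_profile["params"]
        truth = cohort_profile["truth"]
        model = cluster_cohort(params, k=5, seed=0)
        pred = [model.clusters.labels[p.sample_id] for p in params]
        true = [truth[p.sample_id] for p in params]
        assert adjusted_rand_score(true, pred) >= 0.8

    def test_canonical_ordering_high_burden_first(self, cohort_profile):
        params = cohort_profile["params"]
        model = cluster_cohort(params, k=5, seed=0)
        med_count = {}
        for p in params:
            med_count.setdefault(model.clusters.labels[p.sample_id], []).append(
                p.m_count
            )
        medians = {c: np.median(v) for c, v in med_count.items()}
        assert medians[1] >= medians[3] and medians[2] >= medians[3]

    def test_new_archetype_samples_assigned_to_matching_cluster(
        self, cohort_profile, rng
    ):
        """Fresh archetype-1 simulations land in the cluster that captured
        archetype 1 during fitting, in >= 90% of 200 draws."""
        from vafshape.mf_filter import run_filter_chain
        from vafshape.shape_params import profile_cohort
        from vafshape.synthetic import default_archetype_specs, simulate_sample
        from vafshape.io_formats import ClinicalRecord

        params = cohort_profile["params"]
        truth = cohort_profile["truth"]
        model = cluster_cohort(params, k=5, seed=0)
        # archetype 1's dominant fitted cluster
        from collections import Counter

        arch1_clusters = Counter(
            model.clusters.labels[p.sample_id]
            for p in params if truth[p.sample_id] == 1
        )
        target_cluster = arch1_clusters.most_common(1)[0][0]

        spec = default_archetype_specs()[0]
        hits = 0
        for i in range(200):
            muts, segs, purity = simulate_sample(spec, rng, sample_id="NEW")
            clin = [ClinicalRecord("NEW", "SYNTH", purity, 1.0, 0)]
            chain = run_filter_chain(muts, segs, clin)
            new_params, _ = profile_cohort(chain.vafsets.values())
            assigned = assign_new_sample(model.pca, model.clusters, new_params[0])
            hits += assigned == target_cluster
        assert hits >= 180
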