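"""RBF network components: clustering, widths, activations, weights, training."""

import json

import numpy as np
import pytest

import qgarbf as q
from qgarbf.rbf import RBFModel, _identity_norm


class TestKMeans:
    def test_two_well_separated_pairs(self):
        # any distinct-row initialization on {0,1,9,10} reaches {0.5, 9.5}
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        for seed in range(5):
            centers = q.kmeans_centers(X, 2, seed=seed)
            np.testing.assert_allclose(np.sort(centers.ravel()), [0.5, 9.5])

    def test_single_cluster_is_the_mean(self, rng):
        X = rng.normal(size=(30, 3))
        centers = q.kmeans_centers(X, 1, seed=0)
        np.testing.assert_allclose(centers[0], X.mean(axis=0), atol=1e-12)

    def test_h_equals_n_is_fixed_point_at_rows(self, rng):
        X = rng.normal(size=(8, 2))
        centers = q.kmeans_centers(X, 8, seed=1)
        assert {tuple(c) for c in np.round(centers, 10)} == {
            tuple(r) for r in np.round(X, 10)
        }

    def test_h_beyond_distinct_rows_rejected(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="distinct"):
            q.kmeans_centers(X, 3)

    def test_objective_non_increasing_and_matches_sklearn(self, rng):
        from sklearn.cluster import KMeans

        X = rng.normal(size=(120, 3))

        def inertia(centers):
            d = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
            return d.min(axis=1).sum()

        ours = inertia(q.kmeans_centers(X, 5, seed=0))
        ref = KMeans(n_clusters=5, n_init=10, random_state=0).fit(X).inertia_
        assert ours <= 1.10 * ref  # single-init Lloyd's vs 10 restarts

    def test_assignment_maps_to_nearest_center(self, rng):
        X = rng.normal(size=(60, 2))
        centers = q.kmeans_centers(X, 4, seed=2)
        d = ((X[:, None, :] - centers[None]) ** 2).sum(-1)
        assign = d.argmin(axis=1)
        # each center is the mean of its assigned samples (converged state)
        for j in range(4):
            members = X[assign == j]
            if len(members):
                np.testing.assert_allclose(centers[j], members.mean(axis=0), atol=1e-6)


class TestWidths:
    def test_two_centers_at_distance_two(self):
        sigma = q.default_widths(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(sigma, [1.0, 1.0])

    def test_collinear_three_centers(self):
        sigma = q.default_widths(np.array([[0.0], [1.0], [3.0]]))
        np.testing.assert_allclose(sigma, np.full(3, 3.0 / np.sqrt(6.0)))

    def test_homogeneous_in_scale(self, rng):
        centers = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            q.default_widths(4.0 * centers), 4.0 * q.default_widths(centers)
        )

    def test_single_center_instructs_explicit_spread(self):
        with pytest.raises(ValueError, match="spread"):
            q.default_widths(np.array([[1.0, 1.0]]))


class TestActivations:
    def test_center_hit_gives_one_and_sqrt2_sigma_gives_inv_e(self):
        centers = np.array([[0.0, 0.0]])
        widths = np.array([1.5])
        phi = q.activations(np.array([[0.0, 0.0], [1.5 * np.sqrt(2), 0.0]]), centers, widths)
        np.testing.assert_allclose(phi[:, 0], [1.0, np.exp(-1.0)])

    def test_entries_in_unit_interval(self, rng):
        phi = q.activations(rng.normal(size=(40, 3)), rng.normal(size=(7, 3)), rng.uniform(0.1, 2, 7))
        assert np.all(phi > 0) and np.all(phi <= 1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q.activations(np.zeros((3, 2)), np.zeros((2, 3)), np.ones(2))


class TestFitWeights:
    def test_identity_activations_return_targets(self, rng):
        y = rng.normal(size=6)
        np.testing.assert_allclose(q.fit_weights(np.eye(6), y), y, atol=1e-12)

    def test_square_nonsingular_interpolates(self, rng):
        phi = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        y = rng.normal(size=5)
        w = q.fit_weights(phi, y, ridge=0.0)
        assert np.max(np.abs(phi @ w - y)) < 1e-8

    def test_strong_ridge_shrinks_weights(self, rng):
        phi = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        assert np.linalg.norm(q.fit_weights(phi, y, ridge=1e9)) < 1e-6

    def test_rank_deficiency_handled_via_min_norm(self, caplog):
        phi = np.column_stack([np.ones(4), np.zeros(4)])
        with caplog.at_level("WARNING"):
            w = q.fit_weights(phi, np.ones(4), ridge=0.0)
        assert np.allclose(phi @ w, np.ones(4))
        assert "rank-deficient" in caplog.text


class TestTrainPredict:
    def test_exact_interpolation_h_equals_n(self, rng):
        X = rng.uniform(size=(40, 3))
        y = rng.uniform(size=40)
        cfg = q.RBFConfig(spread=0.5, ridge=0.0)
        model = q.train(X, y, cfg)
        resid = np.abs(q.predict(model, X) - y)
        assert resid.max() < 1e-6

    def test_constant_target_reproduced_between_nodes(self, rng):
        # a constant is representable when the nodes sample the range densely
        # relative to the spread; check the interpolant between the nodes
        X = np.sort(rng.uniform(size=(30, 1)), axis=0)
        y = np.full(30, 0.7)
        model = q.train(X, y, q.RBFConfig(spread=0.2, ridge=0.0))
        probe = np.linspace(X.min(), X.max(), 500)[:, None]
        np.testing.assert_allclose(q.predict(model, probe), 0.7, atol=1e-6)

    def test_determinism(self, rng):
        X = rng.uniform(size=(30, 3))
        y = rng.uniform(size=30)
        cfg = q.RBFConfig(hidden_count=10, spread=0.5, seed=9)
        a, b = q.train(X, y, cfg), q.train(X, y, cfg)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_batch_equals_per_row(self, rng):
        X = rng.uniform(size=(15, 3))
        y = rng.uniform(size=15)
        model = q.train(X, y, q.RBFConfig(spread=0.6))
        probe = rng.uniform(size=(8, 3))
        batch = q.predict(model, probe)
        singles = np.array([q.predict(model, row[None, :])[0] for row in probe])
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_prediction_continuous_in_spread(self, rng):
        X = rng.uniform(size=(20, 3))
        y = rng.uniform(size=20)
        probe = rng.uniform(size=(10, 3))
        p1 = q.predict(q.train(X, y, q.RBFConfig(spread=0.7)), probe)
        p2 = q.predict(q.train(X, y, q.RBFConfig(spread=0.7 * (1 + 1e-9))), probe)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_far_from_centers_decays_to_denormalized_zero(self, rng):
        X = rng.uniform(size=(10, 3))
        y = rng.uniform(size=10)
        model = q.train(X, y, q.RBFConfig(spread=0.3))
        far = np.full((1, 3), 100.0)
        assert q.predict(model, far)[0] == pytest.approx(
            model.norm.denormalize(0.0, "pn"), abs=1e-12
        )

    def test_spread_mode_scale_multiplies_self_organizing_width(self, rng):
        X = rng.uniform(size=(12, 3))
        y = rng.uniform(size=12)
        scaled = q.train(X, y, q.RBFConfig(spread=2.0, spread_mode="scale"))
        auto = q.train(X, y, q.RBFConfig(spread="auto"))
        np.testing.assert_allclose(scaled.widths, 2.0 * auto.widths)

    def test_json_round_trip(self, rng):
        X = rng.uniform(size=(9, 3))
        y = rng.uniform(size=9)
        model = q.train(X, y, q.RBFConfig(spread=0.5), norm=_identity_norm(X, y))
        back = RBFModel.from_json(model.to_json())
        probe = rng.uniform(size=(5, 3))
        np.testing.assert_allclose(q.predict(back, probe), q.predict(model, probe))

    def test_format_version_checked(self):
        doc = json.loads(q.train(np.eye(3), np.ones(3), q.RBFConfig(spread=1.0)).to_json())
        doc["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            RBFModel.from_json(json.dumps(doc))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            q.RBFConfig(spread=-1.0)
        with pytest.raises(ValueError):
            q.RBFConfig(spread_mode="other")
        with pytest.raises(ValueError):
            q.RBFConfig(ridge=-1e-3)
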