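"""Quantum and classical genetic search over the spread."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qgarbf as q
from qgarbf.optimizers import RotationPolicy


class TestInitAndMeasure:
    def test_fresh_genes_are_balanced(self):
        pop = q.init_population(5, 8)
        for ch in pop:
            np.testing.assert_allclose(ch.alpha**2, 0.5, atol=1e-15)
            np.testing.assert_allclose(ch.alpha**2 + ch.beta**2, 1.0, atol=1e-15)

    def test_collapsed_qubits_measure_deterministically(self, rng):
        ones = q.QubitChromosome(np.zeros(6), np.ones(6))
        zeros = q.QubitChromosome(np.ones(6), np.zeros(6))
        for _ in range(50):
            assert q.measure(ones, rng).tolist() == [1] * 6
            assert q.measure(zeros, rng).tolist() == [0] * 6

    def test_balanced_qubit_frequency(self, rng):
        ch = q.init_population(1, 1)[0]
        draws = np.array([q.measure(ch, rng)[0] for _ in range(100_000)])
        assert 0.494 <= draws.mean() <= 0.506  # 3.9-sigma binomial band


class TestDecode:
    def test_endpoints_on_spread_range(self):
        assert q.decode([0] * 20, 0.1, 10.0) == pytest.approx(0.1)
        assert q.decode([1] * 20, 0.1, 10.0) == pytest.approx(10.0)

    def test_msb_first_midpoint(self):
        assert q.decode([1, 0, 0, 0], 0.0, 15.0) == pytest.approx(8.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q.decode([], 0.0, 1.0)

    def test_bijection_onto_uniform_grid(self):
        m = 6
        values = [
            q.decode([int(b) for b in format(k, f"0{m}b")], -1.0, 3.0)
            for k in range(2**m)
        ]
        np.testing.assert_allclose(np.diff(values), 4.0 / (2**m - 1), atol=1e-12)
        assert values[0] == -1.0 and values[-1] == pytest.approx(3.0)


class TestFitness:
    def test_identical_vectors_zero(self):
        assert q.fitness([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_mean_square(self):
        assert q.fitness([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_joint_permutation_invariant(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        assert q.fitness(a, b) == pytest.approx(q.fitness(a[perm], b[perm]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q.fitness([], [])


class TestRotate:
    def test_zero_angle_table_leaves_chromosome_unchanged(self):
        ch = q.init_population(1, 5)[0]
        policy = RotationPolicy(delta=0.0)
        out = q.rotate(ch, [0] * 5, [1] * 5, 1.0, 0.5, policy)
        np.testing.assert_array_equal(out.alpha, ch.alpha)

    def test_matching_bits_not_rotated(self):
        ch = q.init_population(1, 4)[0]
        out = q.rotate(ch, [0, 1, 0, 1], [0, 1, 0, 1], 1.0, 0.5)
        np.testing.assert_array_equal(out.beta, ch.beta)

    @settings(max_examples=60, derandomize=True)
    @given(
        phi=st.lists(st.floats(-math.pi, math.pi), min_size=3, max_size=8),
        best=st.integers(0, 1),
    )
    def test_norm_conserved_for_any_amplitudes(self, phi, best):
        phi = np.asarray(phi)
        ch = q.QubitChromosome(np.cos(phi), np.sin(phi))
        out = q.rotate(ch, [1 - best] * len(phi), [best] * len(phi), 2.0, 1.0)
        np.testing.assert_allclose(out.alpha**2 + out.beta**2, 1.0, atol=1e-12)

    def test_repeated_rotation_drives_bit_probability_to_one_monotonically(self):
        ch = q.init_population(1, 1)[0]
        prev = ch.beta[0] ** 2
        for _ in range(100):
            ch = q.rotate(ch, [0], [1], 1.0, 0.5)
            p1 = ch.beta[0] ** 2
            assert p1 >= prev - 1e-12
            prev = p1
        assert prev == pytest.approx(1.0, abs=1e-9)


class TestRunQGA:
    def test_finds_known_quadratic_optimum(self):
        cfg = q.QGAConfig(max_generations=60, stall_generations=60, seed=5)
        value, f, trace = q.run_qga(lambda v: (v - 3.0) ** 2, cfg)
        assert abs(value - 3.0) < 0.05
        assert f == pytest.approx((value - 3.0) ** 2)

    def test_trace_best_fitness_non_increasing(self):
        _, _, trace = q.run_qga(lambda v: (v - 7.0) ** 2, q.QGAConfig(seed=1))
        assert all(b <= a + 1e-15 for a, b in zip(trace.best_fitness, trace.best_fitness[1:]))

    def test_constant_objective_returns_the_constant(self):
        value, f, _ = q.run_qga(lambda v: 4.2, q.QGAConfig(seed=2, max_generations=5))
        assert f == 4.2 and 0.1 <= value <= 10.0

    def test_non_finite_candidates_discarded(self, caplog):
        def objective(v):
            return math.nan if v > 5 else (v - 1.0) ** 2

        with caplog.at_level("WARNING"):
            value, f, _ = q.run_qga(objective, q.QGAConfig(seed=3, max_generations=10))
        assert math.isfinite(f) and value <= 5

    def test_stall_stops_early(self):
        cfg = q.QGAConfig(seed=4, max_generations=500, stall_generations=3)
        _, _, trace = q.run_qga(lambda v: 1.0, cfg)
        assert trace.generations <= 10

    def test_zero_angle_policy_is_stationary(self, rng):
        # all-zero rotation table degenerates the QGA to random search: the
        # population never moves, so per-bit measurement frequency stays 0.5
        policy = RotationPolicy(delta=0.0)
        ch = q.init_population(1, 20)[0]
        freqs = []
        for _ in range(5000):
            bits = q.measure(ch, rng)
            freqs.append(bits.mean())
            ch = q.rotate(ch, bits, 1 - bits, 1.0, 0.5, policy)
        np.testing.assert_allclose(ch.alpha**2, 0.5, atol=1e-12)
        assert abs(np.mean(freqs) - 0.5) < 0.01  # 1e5 bit draws in total


class TestRunGA:
    def test_finds_known_quadratic_optimum(self):
        cfg = q.GAConfig(max_generations=60, stall_generations=60, seed=11)
        value, f, _ = q.run_ga(lambda v: (v - 3.0) ** 2, cfg)
        assert abs(value - 3.0) < 0.1

    def test_elitist_trace_non_increasing(self):
        _, _, trace = q.run_ga(lambda v: math.sin(v) + v * 0.1, q.GAConfig(seed=12))
        assert all(b <= a + 1e-15 for a, b in zip(trace.best_fitness, trace.best_fitness[1:]))

    def test_trace_frame_round_trip(self, tmp_path):
        _, _, trace = q.run_ga(lambda v: (v - 2.0) ** 2, q.GAConfig(seed=13, max_generations=8))
        path = tmp_path / "trace.csv"
        trace.to_frame().to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["generation", "best_fitness", "best_spread"]
        assert len(back) == trace.generations


class TestOptimizeSpread:
    def test_none_uses_config_spread_without_trace(self, small_split):
        res = q.optimize_spread(
            small_split, "rbf", "none", model_config=q.RBFConfig(spread=0.7)
        )
        assert res.spread == 0.7
        assert res.trace is None

    def test_qga_grnn_end_to_end_finite(self, small_split):
        cfg = q.QGAConfig(seed=21, max_generations=15, stall_generations=5)
        res = q.optimize_spread(small_split, "grnn", "qga", opt_config=cfg)
        assert math.isfinite(res.fitness)
        pred = q.grnn_predict(res.model, small_split.X_verify)
        assert np.all(np.isfinite(pred))

    def test_qga_rbf_close_to_grid_oracle(self, small_split):
        # independent oracle: coarse brute-force sweep of the same objective
        from qgarbf.optimizers import _make_objective

        objective, _ = _make_objective(small_split, "rbf", None, "validation")
        grid = np.arange(0.1, 10.0001, 0.05)
        oracle = min(objective(float(s)) for s in grid)
        res = q.optimize_spread(
            small_split, "rbf", "qga",
            opt_config=q.QGAConfig(seed=22, max_generations=40, stall_generations=15),
        )
        assert res.fitness <= 1.05 * oracle

    def test_unknown_family_rejected(self, small_split):
        with pytest.raises(ValueError):
            q.optimize_spread(small_split, "svm", "qga")
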