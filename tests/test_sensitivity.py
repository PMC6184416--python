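import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccekit.ann_model import NetworkSpec, PerceptronWeights
from ccekit.errors import ConfigError, UndefinedMetricError
from ccekit.preprocessing import ModelMatrix
from ccekit.sensitivity import (
    SensitivityResult,
    aggregate_to_factors,
    convergence_report,
    garson,
    rank_factors,
    restart_sensitivity,
)


def weights(W, v, b_h=None, b_o=0.0):
    W = np.asarray(W, dtype=float)
    v = np.asarray(v, dtype=float)
    return PerceptronWeights(
        W=W, b_h=np.zeros(W.shape[1]) if b_h is None else np.asarray(b_h), v=v, b_o=b_o
    )


def garson_oracle(W, v):
    """Literal loop transcription of the connection-weight formula."""
    W, v = np.asarray(W, float), np.asarray(v, float)
    p, h = W.shape
    q = np.zeros(p)
    for i in range(p):
        for j in range(h):
            denom = sum(abs(W[k, j]) for k in range(p))
            if denom == 0:
                continue
            q[i] += (abs(W[i, j]) / denom) * abs(v[j])
    return q / q.sum()


class TestGarson:
    def test_single_hidden_symmetric(self):
        np.testing.assert_allclose(garson(weights([[1.0], [1.0]], [2.0])), [0.5, 0.5])

    def test_identity_patterned(self):
        np.testing.assert_allclose(
            garson(weights([[1.0, 0.0], [0.0, 1.0]], [1.0, 1.0])), [0.5, 0.5]
        )

    def test_hand_worked_two_by_two(self):
        # rows=inputs, cols=hidden; contributions (2/3*1 + 1/2*2, 1/3*1 + 1/2*2)
        q = garson(weights([[2.0, 1.0], [1.0, 1.0]], [1.0, 2.0]))
        np.testing.assert_allclose(q, [5 / 9, 4 / 9])

    def test_single_hidden_node_ignores_output_weight(self):
        W = [[3.0], [1.0]]
        np.testing.assert_allclose(garson(weights(W, [0.1])), garson(weights(W, [-7.0])))
        np.testing.assert_allclose(garson(weights(W, [5.0])), [0.75, 0.25])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        W, v = rng.normal(size=(4, 3)), rng.normal(size=3)
        for c in (2.0, -0.3):
            np.testing.assert_allclose(
                garson(weights(c * W, c * v)), garson(weights(W, v)), atol=1e-12
            )

    def test_all_zero_weights_undefined(self):
        with pytest.raises(UndefinedMetricError):
            garson(weights(np.zeros((2, 2)), np.zeros(2)))

    def test_zero_hidden_node_skipped(self):
        q = garson(weights([[1.0, 0.0], [1.0, 0.0]], [1.0, 9.0]))
        np.testing.assert_allclose(q, [0.5, 0.5])

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_loop_oracle_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(3, 2))
        v = rng.normal(size=2)
        q = garson(weights(W, v))
        assert q.sum() == pytest.approx(1.0, abs=1e-9)
        assert (q >= 0).all()
        np.testing.assert_allclose(q, garson_oracle(W, v), atol=1e-12)


class TestAggregation:
    def test_dummy_columns_sum(self):
        out = aggregate_to_factors(
            np.array([0.1, 0.2, 0.1, 0.6]),
            ["f=a", "f=b", "f=c", "g"],
            {"f=a": "f", "f=b": "f", "f=c": "f", "g": "g"},
        )
        assert out == pytest.approx({"f": 0.4, "g": 0.6})

    def test_identity_map_unchanged(self):
        out = aggregate_to_factors(np.array([0.3, 0.7]), ["a", "b"], {"a": "a", "b": "b"})
        assert out == pytest.approx({"a": 0.3, "b": 0.7})

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=8))
    def test_conservation(self, raw):
        q = np.array(raw) / np.sum(raw)
        cols = [f"c{i}" for i in range(len(q))]
        fmap = {c: ("even" if i % 2 == 0 else "odd") for i, c in enumerate(cols)}
        out = aggregate_to_factors(q, cols, fmap)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unmapped_column_raises(self):
        with pytest.raises(ConfigError):
            aggregate_to_factors(np.array([1.0]), ["c0"], {})


def test_ranking_breaks_ties_lexicographically():
    assert rank_factors({"b": 0.4, "a": 0.4, "c": 0.2}) == ("a", "b", "c")


class TestRestarts:
    def tiny_matrix(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = 2.0 * X[:, 0] + 0.05 * rng.normal(size=n)
        cols = ["x0", "x1", "x2"]
        return ModelMatrix(X=X, y=y, feature_map={c: c for c in cols}, columns=cols)

    def test_single_restart_equals_direct_garson(self):
        from ccekit.ann_model import fit
        from ccekit.sensitivity import model_importances

        matrix = self.tiny_matrix()
        spec = NetworkSpec(seed=11, max_iter=200)
        res = restart_sensitivity(matrix, spec, n_restarts=1, base_seed=11)
        direct = model_importances(fit(matrix, NetworkSpec(seed=11, max_iter=200)))
        assert res.importances == pytest.approx(direct)
        assert res.n_restarts == 1

    def test_deterministic_and_normalized(self):
        matrix = self.tiny_matrix()
        spec = NetworkSpec(max_iter=200)
        a = restart_sensitivity(matrix, spec, n_restarts=4, base_seed=5)
        b = restart_sensitivity(matrix, spec, n_restarts=4, base_seed=5)
        assert a.importances == b.importances
        assert sum(a.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert a.per_restart.apply(sum, axis=1).sub(1).abs().max() < 1e-9

    def test_noise_free_single_driver_always_tops(self):
        """y depends only on x0: every restart ranks x0 first."""
        matrix = self.tiny_matrix(seed=3)
        res = restart_sensitivity(matrix, NetworkSpec(max_iter=300), n_restarts=8, base_seed=0)
        assert (res.per_restart.idxmax(axis=1) == "x0").all()
        assert res.ranking[0] == "x0"


class TestConvergence:
    def result(self, imp, n):
        return SensitivityResult(importances=imp, n_restarts=n, ranking=rank_factors(imp))

    def test_identical_checkpoints_zero_drift(self):
        imp = {"a": 0.6, "b": 0.4}
        report = convergence_report([self.result(imp, 10), self.result(imp, 20)])
        assert report["max_drift"].iloc[1] == 0.0
        assert bool(report["converged"].iloc[1])

    def test_drift_arithmetic_and_threshold(self):
        r1 = self.result({"a": 0.6, "b": 0.4}, 10)
        r2 = self.result({"a": 0.62, "b": 0.38}, 20)
        report = convergence_report([r1, r2], threshold=0.01)
        assert report["max_drift"].iloc[1] == pytest.approx(0.02)
        assert not bool(report["converged"].iloc[1])

    def test_non_increasing_checkpoints_rejected(self):
        r = self.result({"a": 1.0}, 10)
        with pytest.raises(ConfigError):
            convergence_report([r, r])
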