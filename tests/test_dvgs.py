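"""The gradient-similarity valuation loop and its primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import gradval as gv
from gradval.dvgs import _batch_gradient_layers, _per_sample_stats


finite_vectors = arrays(
    np.float64, st.integers(2, 8),
    elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
)


class TestCosineSimilarity:
    def test_identity_and_antipodal(self):
        g = np.array([0.3, -1.2, 4.0])
        assert gv.cosine_similarity(g, g) == pytest.approx(1.0)
        assert gv.cosine_similarity(g, -g) == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        assert gv.cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_zero_norm_convention(self):
        assert gv.cosine_similarity([0.0, 0.0], [1.0, 2.0]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            gv.cosine_similarity([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gv.cosine_similarity([np.nan, 1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True)
    @given(finite_vectors, st.floats(1e-3, 1e3))
    def test_bounds_symmetry_and_scale_invariance(self, a, scale):
        b = np.roll(a, 1) + 1.0
        s = gv.cosine_similarity(a, b)
        assert -1.0 <= s <= 1.0
        assert gv.cosine_similarity(b, a) == pytest.approx(s)
        # positive rescaling of either argument changes nothing
        assert gv.cosine_similarity(a * scale, b) == pytest.approx(s, abs=1e-9)


class TestGradientOps:
    def test_linear_model_gradient_closed_form(self):
        """d/dw (w*x - y)^2 at w=0, x=1, y=2 is -4 (and matches finite
        differences)."""
        m = gv.FeedForwardNet(weights=[np.array([[0.0]])], biases=[np.array([0.0])],
                              activations=["linear"], task_kind="reconstruction")
        m.biases[0] = np.array([0.0])
        spec = gv.LossSpec("mse_reconstruction")
        g = gv.per_sample_gradient(m, np.array([1.0]), np.array([2.0]), spec)
        # gradient over (w, b): dL/dw = 2(wx-y)x = -4, dL/db = -4
        assert g[0] == pytest.approx(-4.0)
        eps = 1e-6
        m.weights[0][0, 0] = eps
        hi = gv.per_sample_loss(m, np.array([[1.0]]), np.array([[2.0]]), spec)[0]
        m.weights[0][0, 0] = -eps
        lo = gv.per_sample_loss(m, np.array([[1.0]]), np.array([[2.0]]), spec)[0]
        assert (hi - lo) / (2 * eps) == pytest.approx(-4.0, rel=1e-6)

    def test_gradient_zero_at_loss_minimum(self):
        m = gv.FeedForwardNet(weights=[np.array([[2.0]])], biases=[np.array([0.0])],
                              activations=["linear"], task_kind="reconstruction")
        g = gv.per_sample_gradient(m, np.array([3.0]), np.array([6.0]),
                                   gv.LossSpec("mse_reconstruction"))
        assert np.allclose(g, 0.0)

    def test_duplicated_sample_gives_identical_gradients(self):
        m = gv.make_mlp(4, 6, 2, seed=0)
        x = np.array([0.5, -1.0, 2.0, 0.0])
        g1 = gv.per_sample_gradient(m, x, 1, gv.LossSpec())
        g2 = gv.per_sample_gradient(m, x.copy(), 1, gv.LossSpec())
        assert np.array_equal(g1, g2)

    def test_batch_of_one_equals_per_sample_gradient(self):
        m = gv.make_mlp(4, 6, 2, seed=0)
        x = np.array([[0.5, -1.0, 2.0, 0.0]])
        y = np.array([1])
        gb = gv.target_batch_gradient(m, x, y, gv.LossSpec())
        gs = gv.per_sample_gradient(m, x[0], 1, gv.LossSpec())
        assert np.allclose(gb, gs)

    def test_class_balanced_batch_gradient_weights_classes_equally(self):
        """3 copies of class-0 sample a plus one class-1 sample b, with
        inverse-frequency weights, must give 0.5*grad(a) + 0.5*grad(b)."""
        m = gv.make_mlp(3, 5, 2, seed=1)
        a = np.array([1.0, 0.0, -1.0])
        b = np.array([-2.0, 0.5, 1.0])
        X = np.stack([a, a, a, b])
        y = np.array([0, 0, 0, 1])
        w = gv.dvgs.balanced_class_weights(y, 2)
        spec = gv.LossSpec("cross_entropy", class_weights=w)
        got = gv.target_batch_gradient(m, X, y, spec)
        ga = gv.per_sample_gradient(m, a, 0, gv.LossSpec())
        gb = gv.per_sample_gradient(m, b, 1, gv.LossSpec())
        assert np.allclose(got, 0.5 * ga + 0.5 * gb)

    def test_unbalanced_duplicate_batch_equals_single_gradient(self):
        m = gv.make_mlp(3, 5, 2, seed=1)
        a = np.array([1.0, 0.0, -1.0])
        X = np.stack([a] * 4)
        got = gv.target_batch_gradient(m, X, np.array([0] * 4), gv.LossSpec())
        assert np.allclose(got, gv.per_sample_gradient(m, a, 0, gv.LossSpec()))

    def test_empty_batch_rejected(self):
        m = gv.make_mlp(3, 5, 2, seed=1)
        with pytest.raises(ValueError):
            gv.target_batch_gradient(m, np.empty((0, 3)), np.array([]), gv.LossSpec())


class TestFastPathOracle:
    def test_layerwise_stats_match_explicit_gradient_matrix(self, small_blobs):
        """The layer-wise dot/norm computation must agree with explicitly
        materialised per-sample gradient vectors to 1e-5 on a 50-sample
        problem (both classification and reconstruction)."""
        X, y = small_blobs.X, small_blobs.y
        for task in ("classification", "reconstruction"):
            if task == "classification":
                model = gv.make_mlp(6, 12, 2, seed=7)
                spec = gv.LossSpec("cross_entropy")
                targets = y
            else:
                model = gv.make_autoencoder(6, 2, seed=7)
                spec = gv.LossSpec("mse_reconstruction")
                targets = X
            ref_layers = _batch_gradient_layers(model, X[:8], targets[:8], spec)
            dots, sqnorms = _per_sample_stats(model, X, targets, spec, ref_layers)
            G = gv.per_sample_gradients(model, X, targets, spec)
            gt = np.concatenate([np.concatenate([gw.ravel(), gb.ravel()])
                                 for gw, gb in ref_layers])
            ref_sq = float(gt @ gt)
            cos_fast = dots / np.sqrt(sqnorms * ref_sq)
            norms = np.linalg.norm(G, axis=1)
            cos_slow = np.array([
                gv.cosine_similarity(G[i], gt) for i in range(len(G))
            ])
            assert np.max(np.abs(cos_fast - cos_slow)) < 1e-5


class TestRunDvgs:
    def test_source_identical_to_target_single_sample_valued_one(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        y = np.array([1])
        cfg = gv.ValuationConfig(n_iterations=10, target_batch_size=1,
                                 record_per_iteration=True)
        dv = gv.run_dvgs(lambda s: gv.make_mlp(4, 8, 2, seed=s), (x, y), (x, y), cfg)
        assert dv.values[0] == pytest.approx(1.0)
        assert np.allclose(dv.per_iteration[0, :, 0], 1.0)

    def test_duplicate_source_samples_get_equal_values(self, small_blobs):
        X, y = small_blobs.X, small_blobs.y
        Xs = np.vstack([X[:10], X[0]])  # sample 0 duplicated at the end
        ys = np.concatenate([y[:10], [y[0]]])
        cfg = gv.ValuationConfig(n_iterations=20, target_batch_size=8)
        dv = gv.run_dvgs(lambda s: gv.make_mlp(6, 10, 2, seed=s),
                         (Xs, ys), (X[10:], y[10:]), cfg)
        assert dv.values[0] == pytest.approx(dv.values[10], abs=1e-12)

    def test_values_bounded_by_cosine_range(self, small_blobs):
        X, y = small_blobs.X, small_blobs.y
        cfg = gv.ValuationConfig(n_iterations=30, target_batch_size=8,
                                 record_per_iteration=True)
        dv = gv.run_dvgs(lambda s: gv.make_mlp(6, 10, 2, seed=s),
                         (X[:30], y[:30]), (X[30:], y[30:]), cfg)
        assert np.all(dv.per_iteration >= -1.0) and np.all(dv.per_iteration <= 1.0)
        assert np.all(dv.values >= -1.0) and np.all(dv.values <= 1.0)

    def test_recording_period_does_not_perturb_trajectory(self, small_blobs):
        """Values recorded with period T must equal the T-th subsample of the
        period-1 record: recording is a pure observation."""
        X, y = small_blobs.X, small_blobs.y
        src, tgt = (X[:25], y[:25]), (X[25:], y[25:])
        factory = lambda s: gv.make_mlp(6, 10, 2, seed=s)  # noqa: E731
        base = gv.ValuationConfig(n_iterations=24, target_batch_size=5,
                                  record_per_iteration=True)
        dv1 = gv.run_dvgs(factory, src, tgt, base)
        for T in (2, 3):
            cfgT = gv.ValuationConfig(n_iterations=24, target_batch_size=5,
                                      similarity_period=T, record_per_iteration=True)
            dvT = gv.run_dvgs(factory, src, tgt, cfgT)
            assert np.allclose(dvT.per_iteration[:, :, 0],
                               dv1.per_iteration[:, ::T, 0], atol=1e-12)

    def test_mismatched_dimensions_rejected(self):
        cfg = gv.ValuationConfig(n_iterations=5, target_batch_size=2)
        with pytest.raises(ValueError):
            gv.run_dvgs(lambda s: gv.make_mlp(3, 4, 2, seed=s),
                        (np.ones((4, 3)), np.zeros(4, dtype=int)),
                        (np.ones((4, 5)), np.zeros(4, dtype=int)), cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            gv.ValuationConfig(n_iterations=10, similarity_period=11)
        with pytest.raises(ValueError):
            gv.ValuationConfig(learning_rate=0.0)


class TestAggregateRuns:
    def test_single_run_unchanged(self):
        dv = gv.DataValues(values=np.array([0.1, 0.2]), n_recorded=5)
        assert gv.aggregate_runs([dv]) is dv

    def test_opposite_runs_cancel(self):
        v = np.array([0.5, -0.2, 0.9])
        a = gv.DataValues(values=v, n_recorded=3)
        b = gv.DataValues(values=-v, n_recorded=3)
        assert np.allclose(gv.aggregate_runs([a, b]).values, 0.0)

    def test_record_count_weighting(self):
        a = gv.DataValues(values=np.array([1.0]), n_recorded=2)
        b = gv.DataValues(values=np.array([0.4]), n_recorded=1)
        out = gv.aggregate_runs([a, b])
        assert out.values[0] == pytest.approx((2 * 1.0 + 1 * 0.4) / 3)

    def test_mismatched_sizes_rejected(self):
        a = gv.DataValues(values=np.array([1.0]), n_recorded=1)
        b = gv.DataValues(values=np.array([1.0, 2.0]), n_recorded=1)
        with pytest.raises(ValueError):
            gv.aggregate_runs([a, b])

    def test_multi_run_equals_manual_aggregation(self, small_blobs):
        X, y = small_blobs.X, small_blobs.y
        src, tgt = (X[:25], y[:25]), (X[25:], y[25:])
        factory = lambda s: gv.make_mlp(6, 10, 2, seed=s)  # noqa: E731
        multi = gv.ValuationConfig(n_iterations=12, target_batch_size=5, n_runs=2,
                                   base_seed=3)
        got = gv.run_dvgs(factory, src, tgt, multi)
        singles = []
        for r in range(2):
            cfg = gv.ValuationConfig(n_iterations=12, target_batch_size=5,
                                     base_seed=3 + r)
            singles.append(gv.run_dvgs(factory, src, tgt, cfg))
        manual = gv.aggregate_runs(singles)
        assert np.allclose(got.values, manual.values)
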