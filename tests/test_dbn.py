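import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pm_gridsense.dbn import (DBNModel, RBMParams, TrainConfig, cd1_update,
                              fine_tune, hidden_activation, logsig,
                              minmax_fit, minmax_fit_apply, network_gradient,
                              pretrain_stack, train_dbn,
                              visible_reconstruction, _forward, _flatten,
                              _unflatten)


# ---------------------------------------------------------------------------
# independent step-by-step oracle for one mean-field CD-1 update

def oracle_logsig(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_cd1(v, W, b, c, lam):
    m, n = W.shape
    ph0 = np.array([oracle_logsig(sum(W[i][j] * v[i] for i in range(m)) + c[j])
                    for j in range(n)])
    v1 = np.array([oracle_logsig(sum(W[i][j] * ph0[j] for j in range(n)) + b[i])
                   for i in range(m)])
    ph1 = np.array([oracle_logsig(sum(W[i][j] * v1[i] for i in range(m)) + c[j])
                    for j in range(n)])
    W2 = W.copy()
    for i in range(m):
        for j in range(n):
            W2[i][j] += lam * (ph0[j] * v[i] - ph1[j] * v1[i])
    b2 = b + lam * (v - v1)
    c2 = c + lam * (ph0 - ph1)
    return W2, b2, c2


class TestNormalization:
    def test_definition_on_simple_column(self):
        xn, p = minmax_fit_apply(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(xn.ravel(), [0.0, 0.5, 1.0])

    def test_apply_then_invert_is_identity(self, rng):
        x = rng.normal(50, 20, (40, 5))
        y = rng.normal(60, 15, 40)
        xn, yn, p = minmax_fit_apply(x, y)
        assert xn.min() >= 0 and xn.max() <= 1
        np.testing.assert_allclose(p.invert_label(yn), y, atol=1e-12)

    def test_constant_column_maps_to_half_with_warning(self):
        x = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        with pytest.warns(UserWarning):
            xn, _ = minmax_fit_apply(x)
        np.testing.assert_allclose(xn[:, 0], 0.5)

    def test_non_finite_rejected_with_column_name(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="BAD"):
            minmax_fit(x, feature_names=["OK", "BAD"])


class TestActivations:
    def test_zero_parameters_give_half(self):
        rbm = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_allclose(hidden_activation(np.ones(3), rbm), 0.5)
        np.testing.assert_allclose(visible_reconstruction(np.ones(2), rbm), 0.5)

    def test_hand_computed_hidden_probability(self):
        W = np.array([[0.5, 0.0], [0.25, 0.0]])
        rbm = RBMParams(W, np.zeros(2), np.array([0.1, 0.0]))
        p = hidden_activation(np.array([1.0, 0.0]), rbm)
        assert p[0] == pytest.approx(1 / (1 + np.exp(-0.6)), abs=1e-12)
        assert p[0] == pytest.approx(0.6457, abs=1e-4)

    def test_monotone_in_hidden_bias(self, rng):
        W = rng.normal(0, 0.5, (4, 3))
        v = rng.random(4)
        lo = hidden_activation(v, RBMParams(W, np.zeros(4), np.zeros(3)))
        hi = hidden_activation(v, RBMParams(W, np.zeros(4), np.ones(3)))
        assert (hi > lo).all()

    def test_transpose_symmetry_without_biases(self, rng):
        W = rng.normal(0, 0.7, (4, 3))
        rbm = RBMParams(W, np.zeros(4), np.zeros(3))
        rbm_t = RBMParams(W.T, np.zeros(3), np.zeros(4))
        for j in range(3):
            h = np.zeros(3); h[j] = 1.0
            np.testing.assert_allclose(visible_reconstruction(h, rbm),
                                       hidden_activation(h, rbm_t), atol=1e-15)

    def test_reconstruction_matches_loop_oracle(self, rng):
        W = rng.normal(0, 0.5, (3, 2))
        b = rng.normal(0, 0.2, 3)
        h = rng.random(2)
        got = visible_reconstruction(h, RBMParams(W, b, np.zeros(2)))
        want = [oracle_logsig(W[i, 0] * h[0] + W[i, 1] * h[1] + b[i])
                for i in range(3)]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        rbm = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            hidden_activation(np.ones(4), rbm)
        with pytest.raises(ValueError):
            visible_reconstruction(np.ones(3), rbm)


class TestCDUpdate:
    def test_zero_rate_leaves_parameters_unchanged(self, rng):
        rbm = RBMParams(rng.normal(0, 0.3, (3, 2)), rng.normal(0, 0.1, 3),
                        rng.normal(0, 0.1, 2))
        out = cd1_update(rng.random((4, 3)), rbm, 0.0)
        np.testing.assert_array_equal(out.W, rbm.W)
        np.testing.assert_array_equal(out.b, rbm.b)
        np.testing.assert_array_equal(out.c, rbm.c)

    def test_self_reconstructing_vector_gives_zero_bias_update(self):
        # with W = 0, b = 0 the mean-field reconstruction of any v is 0.5
        rbm = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        out = cd1_update(np.full((1, 3), 0.5), rbm, 0.7)
        np.testing.assert_allclose(out.b, 0.0, atol=1e-15)

    def test_values_outside_unit_interval_rejected(self):
        rbm = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="normalize"):
            cd1_update(np.array([[0.5, 1.5]]), rbm, 0.1)

    def test_matches_independent_oracle_on_random_instances(self, rng):
        for _ in range(20):
            m, n = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            W = rng.normal(0, 0.5, (m, n))
            b = rng.normal(0, 0.2, m)
            c = rng.normal(0, 0.2, n)
            v = rng.random(m)
            lam = float(rng.uniform(0.01, 0.5))
            out = cd1_update(v[None, :], RBMParams(W.copy(), b.copy(), c.copy()),
                             lam)
            W2, b2, c2 = oracle_cd1(v, W, b, c, lam)
            np.testing.assert_allclose(out.W, W2, atol=1e-10)
            np.testing.assert_allclose(out.b, b2, atol=1e-10)
            np.testing.assert_allclose(out.c, c2, atol=1e-10)

    def test_sampling_mode_is_seeded_and_reproducible(self, rng):
        rbm = RBMParams(rng.normal(0, 0.3, (3, 2)), np.zeros(3), np.zeros(2))
        batch = rng.random((5, 3))
        a = cd1_update(batch, rbm, 0.1, sample_states=True,
                       rng=np.random.default_rng(9))
        b = cd1_update(batch, rbm, 0.1, sample_states=True,
                       rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.W, b.W)


class TestPretrain:
    def test_zero_epochs_returns_seeded_initial_weights(self, rng):
        x = rng.random((30, 6))
        cfg = TrainConfig(cd_epochs=0, seed=3)
        s1, _ = pretrain_stack(x, cfg)
        s2, _ = pretrain_stack(x, cfg)
        assert [r.W.shape for r in s1] == [(6, 12), (12, 24), (24, 36)]
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.W, b.W)
        assert np.all(s1[0].b == 0)

    def test_reconstruction_error_improves_with_training(self, rng):
        x = rng.random((200, 5))
        long, logs = pretrain_stack(x, TrainConfig(cd_epochs=50, seed=1))
        assert logs[0][-1] < logs[0][0]

    def test_identical_seeds_identical_stacks(self, rng):
        x = rng.random((50, 4))
        cfg = TrainConfig(cd_epochs=5, seed=11)
        s1, _ = pretrain_stack(x, cfg)
        s2, _ = pretrain_stack(x, cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.c, b.c)


class TestFineTune:
    def test_linear_target_converges_below_tolerance(self, rng):
        x = rng.random((200, 6))
        y = x @ rng.normal(size=6) + 0.5
        cfg = TrainConfig(cd_epochs=10, max_iterations=200, seed=2)
        m = train_dbn(x, y, cfg)
        assert m.finetune_log[-1] < 1e-4

    def test_final_error_never_exceeds_initial(self, rng):
        x = rng.random((60, 4))
        y = rng.random(60)
        m = train_dbn(x, y, TrainConfig(cd_epochs=5, max_iterations=30, seed=5))
        assert m.finetune_log[-1] <= m.finetune_log[0]

    def test_zero_learning_rate_gradient_mode_is_noop(self, rng):
        x = rng.random((20, 3))
        y = rng.random(20)
        cfg = TrainConfig(cd_epochs=2, fine_tune_method="gradient",
                          bp_learning_rate=1e-30, max_iterations=3, seed=1)
        m = train_dbn(x, y, cfg)
        assert np.allclose(m.finetune_log[0], m.finetune_log[-1], atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.random((5, 3))
        y = rng.random(5)
        Ws = [rng.normal(0, 0.5, (3, 4)), rng.normal(0, 0.5, (4, 2))]
        bs = [rng.normal(0, 0.2, 4), rng.normal(0, 0.2, 2)]
        w_out = rng.normal(0, 0.5, 2)
        b_out = 0.2
        g = network_gradient(x, y, Ws, bs, w_out, b_out)
        theta = _flatten(Ws, bs, w_out, b_out)
        shapes = [W.shape for W in Ws]

        def E(t):
            W_, b_, wo_, bo_ = _unflatten(t, shapes)
            _, yh = _forward(x, W_, b_, wo_, bo_)
            return np.mean((y - yh) ** 2)

        eps = 1e-6
        fd = np.array([(E(theta + eps * np.eye(len(theta))[i])
                        - E(theta - eps * np.eye(len(theta))[i])) / (2 * eps)
                       for i in range(len(theta))])
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-8)
        assert rel.max() < 1e-5

    def test_too_few_samples_rejected(self, rng):
        stack, _ = pretrain_stack(rng.random((12, 3)), TrainConfig(cd_epochs=0))
        with pytest.raises(ValueError):
            fine_tune(stack, rng.random((5, 3)), rng.random(5), TrainConfig(),
                      None)


class TestPredict:
    @pytest.fixture
    def model(self, rng):
        x = rng.random((100, 4)) * 10 + 20
        y = x @ np.array([1.0, -0.5, 2.0, 0.3]) + 5
        return train_dbn(x, y, TrainConfig(cd_epochs=5, max_iterations=80,
                                           seed=4),
                         feature_names=["A", "B", "C", "D"]), x, y

    def test_training_set_rmse_consistency(self, model):
        m, x, y = model
        pred = m.predict(x)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.1 * y.std()

    def test_permuting_records_permutes_outputs(self, model, rng):
        m, x, _ = model
        perm = rng.permutation(len(x))
        np.testing.assert_array_equal(m.predict(x)[perm], m.predict(x[perm]))

    def test_feature_mismatch_rejected_with_names(self, model):
        m, x, _ = model
        with pytest.raises(ValueError, match="A"):
            m.predict(x, feature_names=["A", "B", "D", "C"])

    def test_out_of_range_inputs_extrapolate_finitely(self, model):
        m, x, _ = model
        out = m.predict(x * 3.0)
        assert np.all(np.isfinite(out))


class TestReproducibilityAndSerialization:
    def test_train_predict_path_is_bit_reproducible(self, rng):
        x = rng.random((80, 5))
        y = rng.random(80)
        cfg = TrainConfig(cd_epochs=5, max_iterations=20, seed=21)
        m1 = train_dbn(x.copy(), y.copy(), cfg)
        m2 = train_dbn(x.copy(), y.copy(), cfg)
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_save_load_round_trip_is_bit_exact(self, tmp_path, rng):
        x = rng.random((50, 3)) * 7
        y = rng.random(50) * 100
        m = train_dbn(x, y, TrainConfig(cd_epochs=3, max_iterations=10, seed=8),
                      feature_names=["P", "Q", "R"])
        path = tmp_path / "model.json"
        m.save(path)
        m2 = DBNModel.load(path)
        np.testing.assert_array_equal(m.predict(x), m2.predict(x))
        assert m2.feature_names == ["P", "Q", "R"]
        # the file itself is byte-deterministic
        m2.save(tmp_path / "model2.json")
        assert (tmp_path / "model.json").read_bytes() == \
            (tmp_path / "model2.json").read_bytes()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-30, 30), min_size=1, max_size=8))
def test_logsig_bounds_and_symmetry(xs):
    x = np.array(xs)
    p = logsig(x)
    assert ((p > 0) & (p < 1)).all()
    np.testing.assert_allclose(p + logsig(-x), 1.0, atol=1e-12)
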