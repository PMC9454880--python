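"""Backpropagation correctness (finite-difference oracle), momentum SGD,
the published-literal gradient mode, training determinism and grid search."""

import numpy as np
import pytest

import sqishnet as sq
from sqishnet.training import GRADIENT_MODES, batch_gradients, one_hot

BREAKS = np.array([-2.0, 0.0, 2.0])


def _smooth_instance(rng, topology, margin=0.05, tries=200):
    """Random (params, x, y) whose pre-activations stay away from the
    activation breakpoints, so finite differences are valid."""
    for _ in range(tries):
        params = sq.initialize_params(topology, int(rng.integers(1 << 30)))
        params.b1[:] = rng.normal(0, 0.3, params.b1.shape)
        params.b2[:] = rng.normal(0, 0.3, params.b2.shape)
        x = rng.normal(0, 1.0, topology.n_inputs)
        tr = sq.forward(params, x)
        z = np.concatenate([tr.Z1, tr.Z2])
        if np.min(np.abs(z[:, None] - BREAKS), axis=1).min() > margin \
                and np.max(np.abs(z)) < 1.9:
            y = np.zeros(topology.n_outputs)
            y[rng.integers(topology.n_outputs)] = 1.0
            return params, x, y
    raise AssertionError("could not draw a smooth instance")


def _numerical_gradient(params, x, y, h=1e-6):
    """Central-difference gradient of the loss wrt every parameter."""
    grads = {}
    for name in ("W1", "b1", "W2", "b2"):
        arr = getattr(params, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            lp = sq.squared_error_loss(sq.forward(params, x).A2, y)
            arr[idx] = orig - h
            lm = sq.squared_error_loss(sq.forward(params, x).A2, y)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads["d" + name] = g
    return grads


class TestLoss:
    @pytest.mark.parametrize("a2, y, expected", [
        ([0.2, 0.8], [0.2, 0.8], 0.0),
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([0.5, 0.5], [1.0, 0.0], 0.25),
    ])
    def test_values(self, a2, y, expected):
        assert sq.squared_error_loss(np.array(a2), np.array(y)) \
            == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            sq.squared_error_loss(np.zeros(2), np.zeros(3))


class TestAnalyticGradients:
    def test_output_layer_zero_when_perfect(self):
        p = sq.initialize_params(sq.Topology(4, 3, 2), 0)
        x = np.zeros(4)
        tr = sq.forward(p, x)
        dW2, db2 = sq.output_layer_gradients(tr, tr.A2.copy(), p)
        np.testing.assert_array_equal(dW2, 0.0)
        np.testing.assert_array_equal(db2, 0.0)

    def test_output_layer_zero_in_saturation(self):
        p = sq.NetworkParams(np.zeros((2, 2)), np.zeros(2),
                             np.zeros((2, 2)), np.array([3.0, -3.0]))
        tr = sq.forward(p, np.zeros(2))
        dW2, db2 = sq.output_layer_gradients(tr, np.array([0.0, 1.0]), p)
        np.testing.assert_array_equal(db2, 0.0)

    def test_hidden_layer_dead_region_zero_both_modes(self):
        p = sq.NetworkParams(np.zeros((3, 2)), np.full(2, -3.0),
                             np.ones((2, 2)), np.zeros(2))
        x = np.ones(3)
        tr = sq.forward(p, x)
        for mode in GRADIENT_MODES:
            dW1, db1 = sq.hidden_layer_gradients(tr, np.array([1.0, 0.0]),
                                                 p, x, mode)
            np.testing.assert_array_equal(dW1, 0.0)
            np.testing.assert_array_equal(db1, 0.0)

    def test_unknown_mode_rejected(self):
        p = sq.initialize_params(sq.Topology(2, 2, 2), 0)
        tr = sq.forward(p, np.zeros(2))
        with pytest.raises(ValueError):
            sq.hidden_layer_gradients(tr, np.array([1.0, 0.0]), p,
                                      np.zeros(2), "banana")

    def test_full_gradient_matches_finite_differences(self, rng):
        """Core correctness property: analytic chain-rule gradient equals
        central finite differences on 50 smooth random instances."""
        topo = sq.Topology(5, 3, 2)
        for _ in range(50):
            params, x, y = _smooth_instance(rng, topo)
            num = _numerical_gradient(params, x, y)
            tr = sq.forward(params, x)
            dW2, db2 = sq.output_layer_gradients(tr, y, params)
            dW1, db1 = sq.hidden_layer_gradients(tr, y, params, x)
            np.testing.assert_allclose(dW2, num["dW2"], atol=1e-5)
            np.testing.assert_allclose(db2, num["db2"], atol=1e-5)
            np.testing.assert_allclose(dW1, num["dW1"], atol=1e-5)
            np.testing.assert_allclose(db1, num["db1"], atol=1e-5)

    def test_batch_gradients_average_per_sample(self, rng):
        topo = sq.Topology(4, 3, 2)
        params = sq.initialize_params(topo, 11)
        X = rng.normal(size=(6, 4))
        Y = one_hot(rng.integers(0, 2, 6))
        g = batch_gradients(params, X, Y)
        acc = np.zeros_like(params.W1)
        for i in range(6):
            tr = sq.forward(params, X[i])
            dW1, _ = sq.hidden_layer_gradients(tr, Y[i], params, X[i])
            acc += dW1
        np.testing.assert_allclose(g.dW1, acc / 6, atol=1e-12)


class TestLiteralMode:
    def test_agrees_with_chain_rule_in_shared_regimes(self):
        """On a 1-1-1 network with Z1, Z2 jointly positive in (0,2) or
        jointly negative in (-2,0), the published update equals the chain
        rule."""
        for w1, b1, w2, b2, x in [(0.8, 0.1, 0.9, 0.1, 1.0),     # both +
                                  (0.9, -0.05, 0.4, -0.9, -1.0)]:  # both -
            p = sq.NetworkParams(np.array([[w1]]), np.array([b1]),
                                 np.array([[w2]]), np.array([b2]))
            tr = sq.forward(p, np.array([x]))
            z1, z2 = tr.Z1[0], tr.Z2[0]
            assert (0 < z1 < 2 and 0 < z2 < 2) or \
                   (-2 < z1 < 0 and -2 < z2 < 0), (z1, z2)
            y = np.array([1.0])
            a = sq.hidden_layer_gradients(tr, y, p, np.array([x]), "chain_rule")
            b = sq.hidden_layer_gradients(tr, y, p, np.array([x]),
                                          "paper_literal")
            np.testing.assert_allclose(a[0], b[0], atol=1e-9)
            np.testing.assert_allclose(a[1], b[1], atol=1e-9)

    def test_mixed_signs_zero_in_literal_mode_only(self):
        """Z1 > 0 with Z2 < 0: the published joint conditions zero the
        update while the chain rule does not."""
        p = sq.NetworkParams(np.array([[1.0]]), np.array([0.5]),
                             np.array([[1.0]]), np.array([-3.0]))
        x = np.array([1.0])
        tr = sq.forward(p, x)
        assert tr.Z1[0] > 0 and -2 < tr.Z2[0] < 0
        y = np.array([1.0])
        lit = sq.hidden_layer_gradients(tr, y, p, x, "paper_literal")
        chain = sq.hidden_layer_gradients(tr, y, p, x, "chain_rule")
        np.testing.assert_array_equal(lit[0], 0.0)
        assert np.any(chain[0] != 0.0)


class TestMomentum:
    def _setup(self):
        topo = sq.Topology(3, 2, 2)
        params = sq.initialize_params(topo, 5)
        g = sq.Gradients(np.ones_like(params.W1), np.ones_like(params.b1),
                         np.ones_like(params.W2), np.ones_like(params.b2))
        return params, g, sq.MomentumState.zeros_like(params)

    def test_zero_momentum_is_plain_sgd(self):
        params, g, state = self._setup()
        cfg = sq.TrainingConfig(learning_rate=0.1, momentum=0.0)
        new, _ = sq.momentum_step(params, g, state, cfg)
        np.testing.assert_allclose(new.W1, params.W1 - 0.1)

    def test_first_step_ignores_momentum(self):
        params, g, state = self._setup()
        cfg = sq.TrainingConfig(learning_rate=0.1, momentum=0.9)
        new, _ = sq.momentum_step(params, g, state, cfg)
        np.testing.assert_allclose(new.W1, params.W1 - 0.1)

    def test_velocity_accumulates(self):
        """Two steps at constant gradient: v2 = -lr*g*(1 + mu)."""
        params, g, state = self._setup()
        cfg = sq.TrainingConfig(learning_rate=0.1, momentum=0.9)
        p1, s1 = sq.momentum_step(params, g, state, cfg)
        _, s2 = sq.momentum_step(p1, g, s1, cfg)
        np.testing.assert_allclose(s2.vW1, -0.1 * 1.9 * np.ones_like(g.dW1))


class TestTrain:
    def test_descent_step_reduces_loss(self, rng):
        """Full-batch, small lr, no momentum: one step cannot increase the
        loss on a smooth-region instance."""
        topo = sq.Topology(5, 3, 2)
        params, x, y = _smooth_instance(rng, topo)
        X, Y = x[None, :], y[None, :]
        loss0 = sq.squared_error_loss(sq.forward(params, X).A2, Y)
        g = batch_gradients(params, X, Y)
        cfg = sq.TrainingConfig(learning_rate=1e-2, momentum=0.0)
        new, _ = sq.momentum_step(params, g, sq.MomentumState.zeros_like(params),
                                  cfg)
        loss1 = sq.squared_error_loss(sq.forward(new, X).A2, Y)
        assert loss1 <= loss0 + 1e-12

    def _standardized(self, ds):
        stats = sq.fit_standardizer(ds.X, ds.feature_names)
        return sq.Dataset(sq.apply_standardizer(ds.X, stats), ds.labels,
                          ds.feature_names)

    def test_same_seed_reproduces_params(self, synthetic_dataset):
        ds = self._standardized(synthetic_dataset)
        cfg = sq.TrainingConfig(epochs=3, seed=9)
        p1, h1 = sq.train(ds, config=cfg)
        p2, h2 = sq.train(ds, config=cfg)
        np.testing.assert_array_equal(p1.W1, p2.W1)
        assert h1.loss == h2.loss

    def test_zero_learning_rate_freezes_params(self, synthetic_dataset):
        ds = self._standardized(synthetic_dataset)
        cfg = sq.TrainingConfig(learning_rate=0.0, epochs=2, seed=1)
        init = sq.initialize_params(sq.Topology(30, 5, 2), cfg.seed)
        p, _ = sq.train(ds, config=cfg, init_params=init)
        np.testing.assert_array_equal(p.W1, init.W1)

    def test_history_length_and_learning(self, synthetic_dataset):
        """200 epochs on the separable synthetic defaults reach >= 0.95
        test accuracy and the history spans every epoch."""
        model = sq.SqishNetClassifier.from_dataset(synthetic_dataset)
        res = model.fit(epochs=200, seed=42)
        assert len(res.history.loss) == 200
        assert res.evaluate().accuracy >= 0.95

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ds = sq.Dataset(np.zeros((0, 3)), np.zeros(0, int), ["a", "b", "c"])
            sq.train(ds)


class TestGridSearch:
    def test_cardinality_and_lr_selection(self, synthetic_dataset):
        """lr=0 cannot learn, so the grid picks lr=1/3; 2 candidates run."""
        grid = sq.GridSpec(learning_rates=[0.0, 1.0 / 3.0], momenta=[0.9],
                           batch_sizes=[100], epochs=[30], seed=3)
        best, score, results = sq.grid_search(synthetic_dataset, grid=grid)
        assert len(results) == 2
        assert best.learning_rate == pytest.approx(1.0 / 3.0)
        assert score >= 0.9

    def test_singleton_grid(self, synthetic_dataset):
        grid = sq.GridSpec(learning_rates=[0.2], momenta=[0.5],
                           batch_sizes=[64], epochs=[2], seed=3)
        best, _, results = sq.grid_search(synthetic_dataset, grid=grid)
        assert len(results) == 1
        assert (best.learning_rate, best.momentum) == (0.2, 0.5)

    def test_empty_grid_list_rejected(self):
        with pytest.raises(ValueError):
            sq.GridSpec(learning_rates=[])
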