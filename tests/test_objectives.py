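import numpy as np
import pytest

from tests.conftest import random_softmax
from typemap._autograd import Tensor
from typemap.network import Model, ModelConfig
from typemap.objectives import (LossConfig, assign_pseudo_labels,
                                focal_classification_loss, margin_loss,
                                total_objective, training_surrogate,
                                transfer_coefficients, transfer_loss)


def small_model(d=3, seed=0, **kw):
    cfg = dict(g=6, d=d, n_batches=2, c=4, z=8, hidden_e=10, disc_hidden=5,
               dropout_rate=0.0)
    cfg.update(kw)
    return Model(ModelConfig(**cfg), seed=seed)


class TestLossConfig:
    def test_optimal_defaults(self):
        cfg = LossConfig()
        assert cfg.pseudo_threshold == 0.90
        assert cfg.alpha == 0.5
        assert cfg.beta == 0.5
        assert cfg.gamma == 1.0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            LossConfig(pseudo_threshold=1.0)


class TestFocalLoss:
    def test_gamma_zero_is_weighted_cross_entropy(self, rng):
        p = random_softmax(rng, 5, 3)
        labels = rng.integers(0, 3, size=5)
        w = rng.random(5) + 0.5
        got = focal_classification_loss(Tensor(p), labels, w, focal_gamma=0.0)
        expect = np.mean(w * (-np.log(p[np.arange(5), labels])))
        assert np.isclose(got.item(), expect, rtol=1e-9)

    def test_closed_form_single_cell(self):
        p = np.array([[0.9, 0.1]])
        got = focal_classification_loss(Tensor(p), np.array([0]), np.array([1.0]),
                                        focal_gamma=2.0)
        assert np.isclose(got.item(), 0.01 * (-np.log(0.9)), rtol=1e-9)
        assert np.isclose(got.item(), 1.0536e-3, rtol=1e-3)

    def test_perfect_predictions_zero_loss(self):
        p = np.eye(3)
        labels = np.array([0, 1, 2])
        got = focal_classification_loss(Tensor(p), labels, np.ones(3), focal_gamma=2.0)
        assert got.item() == 0.0

    def test_no_cells_is_zero(self):
        got = focal_classification_loss(Tensor(np.empty((0, 3))), np.array([], int),
                                        np.array([]))
        assert got.item() == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            focal_classification_loss(Tensor(np.eye(2)), np.array([0, 1]),
                                      np.array([1.0, -1.0]))

    def test_nonnegative(self, rng):
        p = random_softmax(rng, 20, 4)
        labels = rng.integers(0, 4, size=20)
        w = rng.random(20) * 2
        got = focal_classification_loss(Tensor(p), labels, w, focal_gamma=2.0)
        assert got.item() >= 0.0


class TestPseudoLabels:
    def test_above_threshold_included(self):
        mask, labels = assign_pseudo_labels(np.array([[0.95, 0.05]]), 0.9)
        assert mask.tolist() == [True]
        assert labels.tolist() == [0]

    def test_boundary_strictly_excluded(self):
        mask, _ = assign_pseudo_labels(np.array([[0.90, 0.10]]), 0.9)
        assert mask.tolist() == [False]

    def test_matches_bruteforce_row_scan(self, rng):
        p = random_softmax(rng, 50, 5)
        mask, labels = assign_pseudo_labels(p, 0.5)
        expect_mask = np.array([max(row) > 0.5 for row in p])
        assert np.array_equal(mask, expect_mask)
        assert np.array_equal(labels, p[expect_mask].argmax(axis=1))

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            assign_pseudo_labels(np.eye(2), 0.0)


def _bruteforce_transfer(model, latent_data, domains, p_rq, w_ct, w_rqcell):
    """Independent triple-loop scalar recomputation of the transfer loss."""
    total = 0.0
    k, d = p_rq.shape
    for j in range(d):
        type_sum = 0.0
        for i in range(k):
            z = latent_data[i]
            h = np.maximum(z @ model.disc[j][0].W.data + model.disc[j][0].b.data, 0)
            prob = 1 / (1 + np.exp(-(h @ model.disc[j][1].W.data
                                     + model.disc[j][1].b.data)))[0]
            bce = -(domains[i] * np.log(prob) + (1 - domains[i]) * np.log(1 - prob))
            type_sum += w_rqcell[i] * p_rq[i, j] * bce
        total += w_ct[j] * type_sum / k
    return total


class TestTransferLoss:
    def test_zero_type_weights_kill_loss_and_gradients(self, rng):
        model = small_model()
        latent = model.encode(rng.standard_normal((4, 6)), np.zeros(4, int))
        loss = transfer_loss(latent, np.array([0, 0, 1, 1]),
                             random_softmax(rng, 4, 3), np.zeros(3),
                             np.ones(4), model)
        assert loss.item() == 0.0
        model.zero_grad()
        loss.backward()
        for p in model.discriminator_parameters() + model.encoder_parameters():
            assert p.grad is None or np.all(p.grad == 0)

    def test_single_cell_bce_at_half(self, rng):
        # one cell, one type, discriminator forced to 0.5: term = w_ct*w*p*log2
        model = small_model(d=1)
        model.disc[0][1].W.data[...] = 0.0
        model.disc[0][1].b.data[...] = 0.0
        latent = model.encode(rng.standard_normal((1, 6)), np.zeros(1, int))
        loss = transfer_loss(latent, np.array([1.0]), np.array([[0.7]]),
                             np.array([0.8]), np.array([0.6]), model)
        assert np.isclose(loss.item(), 0.8 * 0.6 * 0.7 * np.log(2), rtol=1e-9)

    def test_matches_bruteforce_loop(self, rng):
        # 5 cells, 3 types, random everything
        model = small_model()
        latent = model.encode(rng.standard_normal((5, 6)),
                              rng.integers(0, 2, size=5))
        domains = np.array([0, 0, 0, 1, 1], dtype=float)
        p_rq = random_softmax(rng, 5, 3)
        w_ct = rng.random(3)
        w_rqcell = rng.random(5)
        loss = transfer_loss(latent, domains, p_rq, w_ct, w_rqcell, model,
                             use_reversal=False)
        expect = _bruteforce_transfer(model, latent.data, domains, p_rq, w_ct,
                                      w_rqcell)
        assert np.isclose(loss.item(), expect, rtol=1e-6)

    def test_reversal_does_not_change_value(self, rng):
        model = small_model()
        latent = model.encode(rng.standard_normal((4, 6)), np.zeros(4, int))
        args = (np.array([0., 0., 1., 1.]), random_softmax(rng, 4, 3),
                rng.random(3), rng.random(4), model)
        assert np.isclose(transfer_loss(latent, *args, use_reversal=True).item(),
                          transfer_loss(latent, *args, use_reversal=False).item(),
                          rtol=1e-12)

    def test_encoder_gradients_negated_by_reversal(self, rng):
        model = small_model()
        X = rng.standard_normal((6, 6))
        idx = rng.integers(0, 2, size=6)
        domains = np.array([0., 0., 0., 1., 1., 1.])
        p_rq = random_softmax(rng, 6, 3)
        w_ct = rng.random(3) + 0.1
        w_cell = rng.random(6) + 0.1

        def encoder_grads(use_reversal):
            model.zero_grad()
            latent = model.encode(X, idx)
            transfer_loss(latent, domains, p_rq, w_ct, w_cell, model,
                          use_reversal=use_reversal).backward()
            return [p.grad.copy() for p in model.encoder_parameters()]

        with_rev = encoder_grads(True)
        without = encoder_grads(False)
        for a, b in zip(with_rev, without):
            assert np.allclose(a, -b, atol=1e-12)

    def test_discriminator_gradients_unaffected_by_reversal(self, rng):
        model = small_model()
        X = rng.standard_normal((6, 6))
        latent_args = (X, np.zeros(6, int))
        domains = np.array([0., 0., 0., 1., 1., 1.])
        p_rq = random_softmax(rng, 6, 3)
        w_ct = rng.random(3) + 0.1
        w_cell = rng.random(6) + 0.1

        def disc_grads(use_reversal):
            model.zero_grad()
            latent = model.encode(*latent_args)
            transfer_loss(latent, domains, p_rq, w_ct, w_cell, model,
                          use_reversal=use_reversal).backward()
            return [p.grad.copy() for p in model.discriminator_parameters()]

        for a, b in zip(disc_grads(True), disc_grads(False)):
            assert np.allclose(a, b, atol=1e-12)


class TestMarginLoss:
    def test_uniform_wrong_mass_inner_term_is_minus_one(self):
        # wrong-class mass spread uniformly over d-1 classes
        d = 4
        p = np.array([[0.7, 0.1, 0.1, 0.1]])
        w = np.array([1.3])
        loss = margin_loss(Tensor(p), np.array([0]), w, d)
        assert abs(loss.item() - (-1.3)) < 1e-9

    def test_concentrated_wrong_mass_inner_term_is_zero(self):
        p = np.array([[0.6, 0.4, 0.0, 0.0]])
        loss = margin_loss(Tensor(p), np.array([0]), np.array([1.0]), 4)
        assert abs(loss.item()) < 1e-9

    def test_matches_bruteforce_double_loop(self, rng):
        m, d = 4, 4
        p = random_softmax(rng, m, d)
        labels = rng.integers(0, d, size=m)
        w = rng.random(m) + 0.1
        loss = margin_loss(Tensor(p), labels, w, d)
        expect = 0.0
        for i in range(m):
            inner = 0.0
            for j in range(d):
                if j == labels[i]:
                    continue
                q = p[i, j] / (1 - p[i, labels[i]])
                if q > 0:
                    inner += q * np.log(q)
            expect += w[i] * inner / np.log(d - 1)
        expect /= m
        assert np.isclose(loss.item(), expect, rtol=1e-6)

    def test_always_nonpositive(self, rng):
        for _ in range(10):
            m, d = 8, int(rng.integers(2, 6))
            p = random_softmax(rng, m, d)
            labels = rng.integers(0, d, size=m)
            w = rng.random(m) * 2
            assert margin_loss(Tensor(p), labels, w, d).item() <= 1e-12

    def test_d_two_degenerate_normalizer(self):
        # single wrong class: q = 1 identically, inner term 0
        p = np.array([[0.8, 0.2], [0.3, 0.7]])
        loss = margin_loss(Tensor(p), np.array([0, 1]), np.ones(2), 2)
        assert abs(loss.item()) < 1e-9

    def test_d_below_two_rejected(self):
        with pytest.raises(ValueError):
            margin_loss(Tensor(np.ones((1, 1))), np.array([0]), np.ones(1), 1)


class TestTotalObjective:
    def test_only_reference_term_when_coefficients_zero(self):
        cfg = LossConfig(alpha=0.0, beta=0.0, gamma=0.0)
        assert total_objective(1.7, 2.0, 3.0, -1.0, cfg) == 1.7

    def test_default_combination(self):
        cfg = LossConfig()
        got = total_objective(1.0, 2.0, 3.0, -0.5, cfg)
        assert np.isclose(got, 1.0 + 0.5 * 2.0 - 0.5 * 3.0 + 1.0 * (-0.5))

    def test_nan_aborts_with_diagnostics(self):
        with pytest.raises(FloatingPointError, match="L_trans"):
            total_objective(1.0, 0.0, np.nan, 0.0, LossConfig())

    def test_surrogate_discriminator_gradient_is_negated_objective_gradient(self, rng):
        # descending the surrogate moves theta_D up the published objective:
        # d(surrogate)/d theta_D = +beta * dL_trans/d theta_D
        #                        = -d(objective)/d theta_D
        model = small_model()
        X = rng.standard_normal((3, 6))
        idx = np.zeros(3, int)
        domains = np.array([0., 1., 1.])
        p_rq = random_softmax(rng, 3, 3)
        w_ct = rng.random(3) + 0.1
        w_cell = rng.random(3) + 0.1
        cfg = LossConfig()

        model.zero_grad()
        latent = model.encode(X, idx)
        L_trans_grl = transfer_loss(latent, domains, p_rq, w_ct, w_cell, model,
                                    use_reversal=True)
        surrogate = training_surrogate(Tensor(0.0), Tensor(0.0), L_trans_grl,
                                       Tensor(0.0), cfg)
        surrogate.backward()
        analytic = {id(p): p.grad.copy() for p in model.discriminator_parameters()}

        # finite-difference of the raw L_trans wrt a few discriminator params
        eps = 1e-6
        for p in model.discriminator_parameters(0)[:2]:
            flat = p.data.reshape(-1)
            for k in [0, flat.size - 1]:
                orig = flat[k]
                vals = []
                for delta in (eps, -eps):
                    flat[k] = orig + delta
                    lat = model.encode(X, idx)
                    vals.append(transfer_loss(lat, domains, p_rq, w_ct, w_cell,
                                              model, use_reversal=False).item())
                flat[k] = orig
                numeric = (vals[0] - vals[1]) / (2 * eps)
                assert np.isclose(analytic[id(p)].reshape(-1)[k],
                                  cfg.beta * numeric, rtol=1e-4, atol=1e-8)


def test_transfer_coefficients_onehot_vs_softmax(rng):
    labels = np.array([0, 2])
    q = random_softmax(rng, 3, 3)
    r = random_softmax(rng, 2, 3)
    onehot = transfer_coefficients(labels, q, 3, ref_onehot=True, ref_softmax=r)
    assert np.array_equal(onehot[:2], np.eye(3)[labels])
    assert np.array_equal(onehot[2:], q)
    soft = transfer_coefficients(labels, q, 3, ref_onehot=False, ref_softmax=r)
    assert np.array_equal(soft[:2], r)


def test_descent_step_decreases_reference_loss(rng):
    # separable 2-type toy problem: one Adam step on L_r lowers L_r
    from typemap.training import Adam

    model = small_model(d=2)
    X = np.vstack([rng.standard_normal((10, 6)) + 3,
                   rng.standard_normal((10, 6)) - 3])
    labels = np.array([0] * 10 + [1] * 10)
    idx = np.zeros(20, int)

    def compute():
        p = model.predict(model.encode(X, idx))
        return focal_classification_loss(p, labels, np.ones(20), focal_gamma=2.0)

    before = compute()
    opt = Adam(model.parameters(), lr=1e-2)
    model.zero_grad()
    before.backward()
    opt.step()
    assert compute().item() < before.item()
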