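"""Loss identities, SAM/PSAM limit equivalences, metric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import logsumexp

import lesionbag as lb
from lesionbag.autodiff import SGD, Module, Parameter, Tensor
from lesionbag.training import (
    SAMConfig,
    cross_entropy,
    kl_sum,
    metrics_from_scores,
    psam_step,
    reconstruction_loss,
    sam_step,
)


# -- KL / reconstruction loss -----------------------------------------


def test_kl_zero_when_prediction_matches_target():
    target = np.array([[0.5, 0.25, 0.25]])
    pred = Tensor(np.log(target))  # softmax(log p) = p
    kl = kl_sum(target, pred)
    np.testing.assert_allclose(kl.data, 0.0, atol=1e-12)


def test_kl_three_bin_closed_form():
    """Target (0.5, 0.25, 0.25) against uniform logits: the closed-form
    divergence is sum_i t_i (ln t_i - ln(1/3))."""
    t = np.array([0.5, 0.25, 0.25])
    expected = float((t * (np.log(t) - np.log(1.0 / 3.0))).sum())
    kl = kl_sum(t[None], Tensor(np.zeros((1, 3))))
    assert float(kl.data[0]) == pytest.approx(expected, abs=1e-12)
    l_rec, _ = reconstruction_loss(
        t, Tensor(np.zeros(3)), np.full((3, 3), 0.2), Tensor(np.zeros((3, 3)))
    )
    # edge target is uniform -> its KL term is 0 -> L_Rec = log(KL_cti + 1)
    assert float(l_rec.data) == pytest.approx(np.log(expected + 1.0), abs=1e-9)


def test_reconstruction_loss_zero_at_perfect_match():
    c = np.array([0.5, 0.3, 0.2])
    e = np.array([[0.1, 0.2], [0.3, 0.4]])
    e_target = (e + 1e-8) / (e + 1e-8).sum()
    l_rec, parts = reconstruction_loss(
        c, Tensor(np.log(c)), e, Tensor(np.log(e_target).reshape(1, 1, 2, 2))
    )
    assert float(l_rec.data) == pytest.approx(0.0, abs=1e-9)
    assert parts["kl_cti"] == pytest.approx(0.0, abs=1e-12)


def test_reconstruction_loss_monotone_in_each_kl_term(rng):
    """Worsening one reconstruction strictly increases L_Rec."""
    c = rng.random(354) + 0.1
    e = rng.random((10, 10)) + 0.1
    z_good = Tensor(np.log(c / c.sum()))
    base = float(reconstruction_loss(c, z_good, e, Tensor(np.zeros((10, 10))))[0].data)
    z_bad = Tensor(np.log(c / c.sum()) + rng.standard_normal(354))
    worse = float(reconstruction_loss(c, z_bad, e, Tensor(np.zeros((10, 10))))[0].data)
    assert worse > base


def test_reconstruction_loss_shape_mismatch_raises(rng):
    with pytest.raises(ValueError):
        reconstruction_loss(
            rng.random(10), Tensor(rng.random(12)),
            rng.random((4, 4)), Tensor(rng.random((4, 4))),
        )


def test_reconstruction_loss_seed_invariant_when_sigma_vanishes(rng):
    """With sigma -> 0 the sample collapses to mu and L_Rec no longer
    depends on the reparameterization seed."""
    from lesionbag.model import GaussianFeatureField, reparameterized_sample

    mu = Tensor(rng.random(354))
    field = GaussianFeatureField(mu, Tensor(np.full(354, 1e-14)))
    c = rng.random(354) + 0.1
    e = rng.random((6, 6)) + 0.1
    vals = []
    for seed in (0, 1, 2):
        z = reparameterized_sample(field, rng=np.random.default_rng(seed))
        vals.append(
            float(reconstruction_loss(c, z, e, Tensor(np.zeros((6, 6))))[0].data)
        )
    assert max(vals) - min(vals) < 1e-9


# -- total loss -------------------------------------------------------


def test_uniform_logits_cross_entropy_is_log_k():
    logits = Tensor(np.zeros((4, 7)))
    assert float(cross_entropy(logits, np.zeros(4, dtype=int)).data) == pytest.approx(
        np.log(7.0)
    )


def test_total_loss_bundle_identity(rng):
    logits = Tensor(rng.standard_normal((5, 3)))
    targets = rng.integers(0, 3, size=5)
    l_rec = Tensor(np.array(0.37))
    bundle = lb.total_loss(logits, targets, l_rec)
    assert bundle.total == pytest.approx(bundle.l_s + bundle.l_rec, abs=1e-12)
    zero = lb.total_loss(logits, targets, 0.0)
    assert zero.total == pytest.approx(zero.l_s, abs=1e-12)


def test_cross_entropy_against_logsumexp_oracle(rng):
    logits = rng.standard_normal((8, 5))
    targets = rng.integers(0, 5, size=8)
    expected = float(
        np.mean(logsumexp(logits, axis=1) - logits[np.arange(8), targets])
    )
    got = float(cross_entropy(Tensor(logits), targets).data)
    assert got == pytest.approx(expected, abs=1e-12)


def test_cross_entropy_rejects_out_of_range_targets():
    with pytest.raises(ValueError):
        cross_entropy(Tensor(np.zeros((2, 3))), np.array([0, 3]))


# -- SAM / PSAM -------------------------------------------------------


class _Quadratic(Module):
    """L(w) = sum(a * w^2), float64 for exact limit checks."""

    def __init__(self, w0, a):
        super().__init__()
        self.w = Parameter(np.asarray(w0, dtype=np.float64))
        self.a = np.asarray(a, dtype=np.float64)

    def loss(self):
        l = (Tensor(self.a) * self.w * self.w).sum()
        return lb.LossBundle(loss=l, l_s=float(l.data), l_rec=0.0)


def _run_steps(optimizer_kind, rho, n_steps=5, lr=0.05, momentum=0.9,
               psam_fraction=0.5, seed=0):
    model = _Quadratic([1.0, -2.0, 0.5], [1.0, 0.3, 2.0])
    opt = SGD(model.parameters(), lr=lr, momentum=momentum)
    cfg = SAMConfig(rho=rho, psam_fraction=psam_fraction)
    for step in range(n_steps):
        if optimizer_kind == "sgd":
            opt.zero_grad()
            model.loss().loss.backward()
            opt.step()
        elif optimizer_kind == "sam":
            sam_step(model, model.loss, opt, rho)
        else:
            psam_step(model, model.loss, opt, cfg,
                      np.random.default_rng([seed, step]))
    return model.w.data.copy()


def test_sam_rho_zero_equals_sgd_over_five_steps():
    np.testing.assert_allclose(
        _run_steps("sam", rho=0.0), _run_steps("sgd", rho=0.0), atol=1e-7
    )


def test_psam_rho_zero_equals_sgd_regardless_of_partition():
    np.testing.assert_allclose(
        _run_steps("psam", rho=0.0), _run_steps("sgd", rho=0.0), atol=1e-7
    )


def test_psam_fraction_limits_recover_sgd_and_sam():
    np.testing.assert_allclose(
        _run_steps("psam", rho=0.1, psam_fraction=1.0),
        _run_steps("sgd", rho=0.0, n_steps=5),
        atol=1e-7,
    )
    np.testing.assert_allclose(
        _run_steps("psam", rho=0.1, psam_fraction=0.0),
        _run_steps("sam", rho=0.1),
        atol=1e-7,
    )


def test_sam_one_d_quadratic_hand_values():
    """L(w) = w^2 at w = 1 with rho = 0.1: zeta = 0.1, gradient at the
    perturbed point is 2 * 1.1 = 2.2, so w <- 1 - lr * 2.2."""
    model = _Quadratic([1.0], [1.0])
    opt = SGD(model.parameters(), lr=0.1, momentum=0.0)
    sam_step(model, model.loss, opt, rho=0.1)
    assert float(model.w.data[0]) == pytest.approx(1.0 - 0.1 * 2.2, abs=1e-12)


def test_sam_perturbation_norm_equals_rho():
    from lesionbag.training import _grad_norm

    model = _Quadratic([1.0, -2.0, 0.5], [1.0, 0.3, 2.0])
    model.loss().loss.backward()
    grads = [p.grad.copy() for p in model.parameters()]
    norm = _grad_norm(grads)
    rho = 0.25
    zeta = [rho * g / norm for g in grads]
    assert _grad_norm(zeta) == pytest.approx(rho, abs=1e-12)


def test_sam_zero_gradient_skips_perturbation():
    model = _Quadratic([0.0, 0.0], [1.0, 1.0])  # gradient is exactly zero
    opt = SGD(model.parameters(), lr=0.1)
    sam_step(model, model.loss, opt, rho=0.5)
    np.testing.assert_array_equal(model.w.data, [0.0, 0.0])


def test_psam_partition_is_exact_half_and_seeded():
    """The random element partition is an exact 50/50 split (sizes differ
    by at most one) and bit-identical under the same seed."""
    rng = np.random.default_rng(0)
    for total in (10, 11, 101):
        n_general = int(round(0.5 * total))
        assert abs(n_general - (total - n_general)) <= 1
    w1 = _run_steps("psam", rho=0.2, seed=5)
    w2 = _run_steps("psam", rho=0.2, seed=5)
    w3 = _run_steps("psam", rho=0.2, seed=6)
    np.testing.assert_array_equal(w1, w2)
    assert not np.array_equal(w1, w3)


# -- metrics ----------------------------------------------------------


def test_metrics_perfect_predictions():
    labels = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[labels]
    rep = metrics_from_scores(labels, probs, 3)
    assert rep.acc == 100.0 and rep.macro_f1 == 100.0 and rep.macro_auc == 100.0


def test_metrics_two_class_perfect_ranking():
    labels = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.8, 0.3, 0.1])
    probs = np.stack([1 - scores, scores], axis=1)
    rep = metrics_from_scores(labels, probs, 2)
    assert rep.per_class[1]["auc"] == 100.0


def _auc_pair_count(pos_scores, neg_scores):
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos_scores
        for n in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


def test_macro_auc_matches_pairwise_rank_oracle(rng):
    """One-vs-rest AUC equals the brute-force count over (pos, neg) pairs."""
    for _ in range(20):
        labels = rng.integers(0, 3, size=30)
        if len(np.unique(labels)) < 3:
            continue
        probs = rng.random((30, 3))
        probs /= probs.sum(axis=1, keepdims=True)
        rep = metrics_from_scores(labels, probs, 3)
        oracle = np.mean(
            [
                _auc_pair_count(probs[labels == k, k], probs[labels != k, k]) * 100
                for k in range(3)
            ]
        )
        assert rep.macro_auc == pytest.approx(oracle, abs=1e-9)


def test_metrics_match_sklearn_on_random_predictions(rng):
    from sklearn.metrics import accuracy_score, f1_score

    for _ in range(50):
        labels = rng.integers(0, 4, size=40)
        probs = rng.random((40, 4))
        preds = probs.argmax(axis=1)
        rep = metrics_from_scores(labels, probs, 4)
        assert rep.acc == pytest.approx(accuracy_score(labels, preds) * 100)
        assert rep.macro_f1 == pytest.approx(
            f1_score(labels, preds, average="macro", labels=np.arange(4),
                     zero_division=0) * 100
        )


def test_absent_class_excluded_from_macro_auc_with_warning():
    labels = np.array([0, 0, 1, 1])  # class 2 absent
    probs = np.random.default_rng(0).random((4, 3))
    with pytest.warns(UserWarning, match="absent"):
        rep = metrics_from_scores(labels, probs, 3)
    assert np.isfinite(rep.macro_auc)
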