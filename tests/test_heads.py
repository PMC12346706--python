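"""Divergers, Gaussian decoders, reparameterization, gates, classifier."""

from __future__ import annotations

import numpy as np
import pytest

import lesionbag as lb
from lesionbag.autodiff import Tensor
from lesionbag.model import GaussianFeatureField, reparameterized_sample


def _tiny_feature_batch(rng, n=2):
    cfg = lb.TINY_MODEL_CONFIG.backbone
    return Tensor(
        rng.standard_normal((n, cfg.channels, cfg.grid_size, cfg.grid_size)).astype(
            np.float32
        )
    )


# -- divergers --------------------------------------------------------


def test_diverger_preserves_shape_and_is_affine(tiny_model, rng):
    x1 = _tiny_feature_batch(rng)
    x2 = _tiny_feature_batch(rng)
    d = tiny_model.diverger_cti
    y1, y2 = d(x1), d(x2)
    assert y1.shape == x1.shape
    # affinity: D(x1) - D(x2) is linear in x1 - x2 (bias cancels)
    diff = d(Tensor(x1.data - x2.data + np.zeros_like(x1.data))).data - d(
        Tensor(np.zeros_like(x1.data))
    ).data
    np.testing.assert_allclose(y1.data - y2.data, diff, atol=1e-4)


def test_diverger_identity_initialization_passes_through(rng):
    model = lb.build_model(lb.TINY_MODEL_CONFIG, seed=0)
    c = model.config.backbone.channels
    model.diverger_cti.conv.weight.data = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
    model.diverger_cti.conv.bias.data = np.zeros(c, dtype=np.float32)
    x = _tiny_feature_batch(rng)
    np.testing.assert_allclose(model.diverger_cti(x).data, x.data, atol=1e-6)


def test_divergers_do_not_share_parameters(tiny_model):
    a = tiny_model.diverger_cti.conv.weight
    b = tiny_model.diverger_ei.conv.weight
    assert a is not b and not np.array_equal(a.data, b.data)


# -- CTI decoder ------------------------------------------------------


def test_cti_decoder_emits_354_with_positive_sigma(tiny_model, rng):
    field = tiny_model.cti_decoder(_tiny_feature_batch(rng))
    assert field.mu.shape == (2, 354)
    assert field.sigma.shape == (2, 354)
    assert (field.sigma.data > 0).all()


def test_cti_decoder_zero_sigma_branch_gives_unit_sigma(rng):
    model = lb.build_model(lb.TINY_MODEL_CONFIG, seed=1)
    for layer in (model.cti_decoder.log_sigma_branch.fc1,
                  model.cti_decoder.log_sigma_branch.fc2):
        layer.weight.data = np.zeros_like(layer.weight.data)
        layer.bias.data = np.zeros_like(layer.bias.data)
    field = model.cti_decoder(_tiny_feature_batch(rng))
    np.testing.assert_allclose(field.sigma.data, 1.0)


def test_cti_decoder_depends_only_on_pooled_features(tiny_model, rng):
    """Two feature maps with equal spatial means give identical (mu, sigma)."""
    x = _tiny_feature_batch(rng, n=1).data
    shuffled = x[:, :, np.random.default_rng(0).permutation(7), :]
    f1 = tiny_model.cti_decoder(Tensor(x))
    f2 = tiny_model.cti_decoder(Tensor(shuffled))
    np.testing.assert_allclose(f1.mu.data, f2.mu.data, atol=1e-5)
    np.testing.assert_allclose(f1.sigma.data, f2.sigma.data, atol=1e-5)


# -- EI decoder -------------------------------------------------------


def test_ei_decoder_shapes_match_grid(tiny_model, rng):
    x = _tiny_feature_batch(rng)
    field = tiny_model.ei_decoder(x)
    assert field.mu.shape == x.shape
    assert (field.sigma.data > 0).all()


def test_ei_decoder_is_per_cell(tiny_model, rng):
    """1x1 convolutions: editing one grid cell moves (mu, sigma) only there."""
    x = _tiny_feature_batch(rng, n=1).data.copy()
    f1 = tiny_model.ei_decoder(Tensor(x))
    x2 = x.copy()
    x2[0, :, 3, 4] += 1.0
    f2 = tiny_model.ei_decoder(Tensor(x2))
    delta = np.abs(f1.mu.data - f2.mu.data).sum(axis=1)[0]
    changed = delta > 1e-7
    assert changed[3, 4] and changed.sum() == 1


def test_ei_decoder_zero_weights_give_constant_mu(rng):
    model = lb.build_model(lb.TINY_MODEL_CONFIG, seed=2)
    branch = model.ei_decoder.mu_branch
    for conv in (branch.conv1, branch.conv2):
        conv.weight.data = np.zeros_like(conv.weight.data)
    field = model.ei_decoder(_tiny_feature_batch(rng, n=1))
    mu = field.mu.data[0]
    expected = model.ei_decoder.mu_branch.conv2.bias.data[:, None, None]
    np.testing.assert_allclose(mu, np.broadcast_to(expected, mu.shape), atol=1e-7)


# -- reparameterization -----------------------------------------------


def test_reparameterized_sample_eps_zero_is_mu(rng):
    mu = Tensor(rng.standard_normal(10))
    sigma = Tensor(np.full(10, 2.0))
    field = GaussianFeatureField(mu, sigma)
    z = reparameterized_sample(field, eps=np.zeros(10))
    np.testing.assert_array_equal(z.data, mu.data)


def test_reparameterized_sample_sigma_limit(rng):
    mu = Tensor(rng.standard_normal(10))
    field = GaussianFeatureField(mu, Tensor(np.full(10, 1e-12)))
    z = reparameterized_sample(field, rng=np.random.default_rng(0))
    np.testing.assert_allclose(z.data, mu.data, atol=1e-9)


def test_reparameterized_sample_monte_carlo_mean():
    """Mean of 10,000 draws recovers mu within 4 sigma / sqrt(n)."""
    gen = np.random.default_rng(42)
    mu = Tensor(gen.standard_normal(10))
    sigma = Tensor(gen.random(10) + 0.5)
    field = GaussianFeatureField(mu, sigma)
    draw_rng = np.random.default_rng(7)
    draws = np.stack(
        [reparameterized_sample(field, rng=draw_rng).data for _ in range(10_000)]
    )
    tol = 4.0 * sigma.data / np.sqrt(10_000)
    assert (np.abs(draws.mean(axis=0) - mu.data) < tol).all()


def test_reparameterized_sample_reproducible_and_differentiable():
    mu = Tensor(np.zeros(5), requires_grad=True)
    sigma = Tensor(np.ones(5), requires_grad=True)
    field = GaussianFeatureField(mu, sigma)
    z1 = reparameterized_sample(field, rng=np.random.default_rng(3))
    z2 = reparameterized_sample(field, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(z1.data, z2.data)
    z1.sum().backward()
    np.testing.assert_allclose(mu.grad, 1.0)  # dz/dmu = 1
    np.testing.assert_allclose(sigma.grad, z1.data)  # dz/dsigma = eps


def test_non_positive_sigma_rejected():
    with pytest.raises(ValueError, match="positive"):
        GaussianFeatureField(Tensor(np.zeros(3)), Tensor(np.array([1.0, 0.0, 1.0])))


# -- EI upsampler -----------------------------------------------------


def test_upsample_geometry(tiny_model, rng):
    z = _tiny_feature_batch(rng, n=1)
    rec = tiny_model.ei_decoder.upsample(z)
    assert rec.shape == (1, 1, 57, 57)  # (7-1)*8 + 9


def test_upsample_one_hot_footprint(tiny_model):
    """A one-hot grid input can only reach the transposed-conv footprint
    rows/cols [0, patch) at cell (0, 0)."""
    cfg = lb.TINY_MODEL_CONFIG.backbone
    z = np.zeros((1, cfg.channels, cfg.grid_size, cfg.grid_size), dtype=np.float32)
    z[0, :, 0, 0] = 1.0
    zero = tiny_model.ei_decoder.upsample(Tensor(np.zeros_like(z))).data
    one = tiny_model.ei_decoder.upsample(Tensor(z)).data
    delta = np.abs(one - zero)[0, 0]
    assert delta[: cfg.patch_size, : cfg.patch_size].max() > 0
    outside = delta.copy()
    outside[: cfg.patch_size, : cfg.patch_size] = 0
    assert outside.max() == 0


def test_transposed_conv_stage_is_linear(tiny_model, rng):
    tconv = tiny_model.ei_decoder.tconv
    bias = tconv.bias.data.copy()
    tconv.bias.data = np.zeros_like(bias)
    try:
        u = rng.standard_normal((1, 64, 7, 7)).astype(np.float32)
        v = rng.standard_normal((1, 64, 7, 7)).astype(np.float32)
        lhs = tconv(Tensor(2.0 * u + 3.0 * v)).data
        rhs = 2.0 * tconv(Tensor(u)).data + 3.0 * tconv(Tensor(v)).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)
    finally:
        tconv.bias.data = bias


# -- gates ------------------------------------------------------------


def test_gate_zero_weights_give_half(rng):
    model = lb.build_model(lb.TINY_MODEL_CONFIG, seed=3)
    for conv in (model.gate_cti.conv1, model.gate_cti.conv2):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.bias.data = np.zeros_like(conv.bias.data)
    x = _tiny_feature_batch(rng)
    gated, weights = model.gate_cti(x)
    np.testing.assert_allclose(weights.data, 0.5)
    np.testing.assert_allclose(gated.data, 0.5 * x.data, atol=1e-7)


def test_gate_range_and_per_cell_locality(tiny_model, rng):
    x = _tiny_feature_batch(rng, n=1)
    gated, weights = tiny_model.gate_ei(x)
    assert (weights.data > 0).all() and (weights.data < 1).all()
    assert gated.shape == x.shape
    x2 = x.data.copy()
    x2[0, :, 2, 2] += 1.0
    _, w2 = tiny_model.gate_ei(Tensor(x2))
    changed = np.abs(w2.data - weights.data)[0, 0] > 1e-9
    assert changed[2, 2] and changed.sum() == 1


# -- classifier & end-to-end ------------------------------------------


def test_classifier_input_width_is_twice_channels(tiny_model):
    assert tiny_model.classifier.weight.data.shape == (
        2 * lb.TINY_MODEL_CONFIG.backbone.channels,
        lb.TINY_MODEL_CONFIG.n_classes,
    )


def test_n_classes_config():
    cfg = lb.ModelConfig(
        backbone=lb.TINY_CONFIG, n_classes=7, decoder_hidden=8, gate_hidden=8
    )
    model = lb.build_model(cfg, seed=0)
    out = model(Tensor(np.zeros((1, 3, 57, 57), dtype=np.float32)))
    assert out.logits.shape == (1, 7)


def test_logits_decompose_into_per_cell_fc_responses(tiny_model, rng):
    """GAP and the affine FC commute: the image logit equals the mean of
    per-cell FC responses to within 1e-5. This identity underwrites the
    per-patch heatmaps."""
    x = Tensor(rng.random((2, 3, 57, 57)).astype(np.float32))
    tiny_model.eval()
    out = tiny_model(x)
    w = tiny_model.classifier.weight.data
    b = tiny_model.classifier.bias.data
    c = out.x_cti_gated.data.shape[1]
    per_cell = (
        np.einsum("nchw,ck->nkhw", out.x_cti_gated.data, w[:c])
        + np.einsum("nchw,ck->nkhw", out.x_ei_gated.data, w[c:])
        + b[None, :, None, None]
    )
    np.testing.assert_allclose(per_cell.mean(axis=(2, 3)), out.logits.data, atol=1e-5)


def test_forward_deterministic_and_reproducible(tiny_model, rng):
    x = Tensor(rng.random((1, 3, 57, 57)).astype(np.float32))
    tiny_model.eval()
    eps_c = np.zeros((1, 354))
    eps_e = np.zeros((1, 64, 7, 7))
    o1 = tiny_model(x, reconstruct=True, eps_cti=eps_c, eps_ei=eps_e)
    o2 = tiny_model(x, reconstruct=True, eps_cti=eps_c, eps_ei=eps_e)
    np.testing.assert_array_equal(o1.logits.data, o2.logits.data)
    np.testing.assert_array_equal(o1.edge_recon.data, o2.edge_recon.data)


def test_branch_swap_symmetry(rng):
    """Swapping the CTI/EI parameter sets and the concatenation order
    leaves the logits unchanged."""
    model = lb.build_model(lb.TINY_MODEL_CONFIG, seed=9)
    x = Tensor(rng.random((1, 3, 57, 57)).astype(np.float32))
    model.eval()
    base = model(x).logits.data.copy()
    # swap branch modules and the two halves of the classifier weights
    model.diverger_cti, model.diverger_ei = model.diverger_ei, model.diverger_cti
    model.gate_cti, model.gate_ei = model.gate_ei, model.gate_cti
    w = model.classifier.weight.data
    c = w.shape[0] // 2
    model.classifier.weight.data = np.concatenate([w[c:], w[:c]], axis=0)
    swapped = model(x).logits.data
    np.testing.assert_allclose(swapped, base, atol=1e-5)
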