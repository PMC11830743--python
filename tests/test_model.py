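"""Booster-VAE contracts: latents, decoders, loss terms, gradients."""

import dataclasses

import numpy as np
import pytest

from gclspace import nn
from gclspace.config import DEFAULT_ANCHOR, ModelConfig
from gclspace.model import (
    BoosterVAE,
    anatomical_penalty,
    fovea_crop,
    kl_divergence,
    load_checkpoint,
    save_checkpoint,
)
from gclspace.nn import Tensor

TINY = ModelConfig(
    image_px=16, crop_px=8, channels=(2, 3), dense_units=8, dtype="float64"
)


@pytest.fixture(scope="module")
def tiny_model():
    return BoosterVAE(TINY, seed=0)


def test_kl_closed_form():
    assert kl_divergence(np.zeros(3), np.zeros(3)) == 0.0
    assert kl_divergence(np.ones(4), np.zeros(4)) == pytest.approx(2.0)  # 0.5/dim
    # Tensor route agrees with numpy route
    mu = np.array([[0.3, -1.2]])
    lv = np.array([[0.4, -0.7]])
    t = kl_divergence(Tensor(mu), Tensor(lv))
    assert t.item() == pytest.approx(kl_divergence(mu, lv))


def test_kl_matches_monte_carlo():
    """Closed form vs Monte-Carlo estimate of KL(N(mu,s^2) || N(0,1))."""
    rng = np.random.default_rng(0)
    mu = rng.normal(size=5)
    logvar = rng.normal(scale=0.5, size=5)
    sd = np.exp(0.5 * logvar)
    n = 10**6
    z = mu + sd * rng.standard_normal((n, 5))
    log_q = -0.5 * ((z - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    log_p = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
    samples = (log_q - log_p).sum(axis=1)
    mc = samples.mean()
    se = samples.std(ddof=1) / np.sqrt(n)
    assert abs(kl_divergence(mu, logvar) - mc) < 3 * se


def test_anatomical_penalty_zero_at_anchor_and_monotone():
    t = DEFAULT_ANCHOR
    d = np.array([t(0.9), t(1.1)])
    assert anatomical_penalty(d, 0.9, 1.1) == pytest.approx((0.0, 0.0))
    # anchor map increases with the ratio: thinner -> more negative target
    ratios = np.linspace(0.0, 1.5, 20)
    anchors = t(ratios)
    assert np.all(np.diff(anchors) > 0)
    with pytest.raises(ValueError):
        anatomical_penalty(d, -0.1, 1.0)


def test_anchor_constants_place_thinning_left_of_normal():
    """A half-thinned inferior hemifield anchors at <= -3 while the normative
    ratio anchors inside [1, 4] (direct evaluation of the configured map)."""
    from gclspace import annulus
    from gclspace.phantom import normal_template

    template = normal_template()
    prof = annulus.sector_means(template.values_um, template.fovea_px)
    r_inf, r_sup = annulus.hemifield_ratios(prof, DEFAULT_ANCHOR.reference_um)
    assert 1.0 <= DEFAULT_ANCHOR(r_inf) <= 4.0
    assert 1.0 <= DEFAULT_ANCHOR(r_sup) <= 4.0
    assert DEFAULT_ANCHOR(0.5 * r_inf) <= -3.0


def test_encode_interface_contract(tiny_model):
    rng = np.random.default_rng(1)
    code = tiny_model.encode(rng.uniform(0, 100, (16, 16)))
    assert code.d.shape == (2,)
    assert code.b.shape == (8,)
    assert 0 <= code.fovea_px[0] < 16 and 0 <= code.fovea_px[1] < 16
    assert 0.0 <= code.exclude_prob <= 1.0


def test_encode_rejects_wrong_raster(tiny_model):
    with pytest.raises(ValueError, match="resize"):
        tiny_model.encode(np.zeros((32, 32)))


def test_encode_deterministic_at_posterior_mean(tiny_model):
    rng = np.random.default_rng(2)
    m = rng.uniform(0, 100, (16, 16))
    c1, c2 = tiny_model.encode(m), tiny_model.encode(m)
    assert np.array_equal(c1.d, c2.d)
    assert np.array_equal(c1.b, c2.b)


def test_decode_display_deterministic_and_nonnegative(tiny_model):
    d = np.array([1.5, -2.0])
    a = tiny_model.decode_display(d)
    b = tiny_model.decode_display(d)
    assert np.array_equal(a, b)
    assert a.shape == (8, 8)
    assert np.all(a >= 0)


def test_additive_identity_exact(tiny_model):
    """y - y_booster - y_display == 0 elementwise for random codes."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        code = tiny_model.encode(rng.uniform(0, 120, (16, 16)))
        code = dataclasses.replace(code, d=rng.normal(size=2), b=rng.normal(size=8))
        pair = tiny_model.decode_full(code)
        assert np.array_equal(pair.y, pair.y_display + pair.y_booster)


def test_fovea_crop_centering_and_edge_replication():
    values = np.arange(100.0).reshape(10, 10)
    c = fovea_crop(values, (5, 5), 4)
    assert c.shape == (4, 4)
    assert c[2, 2] == values[5, 5]
    edge = fovea_crop(values, (0, 0), 4)
    assert edge.shape == (4, 4)
    assert edge[0, 0] == values[0, 0]  # replicated corner


def _fake_outputs(n, crop, anchors, fovea, logits, dtype=np.float64):
    """Hand-built model outputs for loss-term unit tests."""
    z = lambda *s: Tensor(np.zeros(s, dtype=dtype))
    out = {
        "y_d": Tensor(crop.reshape(n, 1, *crop.shape[1:]).copy()),
        "y": Tensor(crop.reshape(n, 1, *crop.shape[1:]).copy()),
        "mu_d": Tensor(anchors.copy()),
        "logvar_d": z(n, 2),
        "mu_b": z(n, 8),
        "logvar_b": z(n, 8),
        "fovea": Tensor(fovea.copy()),
        "excl_logit": Tensor(logits.copy()),
    }
    return out


def test_losses_zero_at_perfect_solution(tiny_model):
    """Perfect reconstruction, prior-collapsed posterior, anchored latents,
    exact fovea and (saturated) correct flags give ~zero total."""
    n = 3
    crop = np.random.default_rng(4).uniform(0, 1, (n, 8, 8))
    anchors = np.zeros((n, 2))  # anchors at the prior mean, so KL and anat both vanish
    fovea = np.full((n, 2), 0.5)
    qc_bad = np.array([False, False, True])
    logits = np.where(qc_bad, 30.0, -30.0).reshape(n, 1)
    out = _fake_outputs(n, crop, anchors, fovea, logits)
    bundle = tiny_model.compute_losses(out, crop, anchors, fovea, qc_bad)
    assert bundle.total == pytest.approx(0.0, abs=1e-9)
    for name in ("recon_display", "recon_full", "kl_d", "kl_b",
                 "anat_d1", "anat_d2", "fovea_loss", "exclude_loss"):
        assert getattr(bundle, name) >= 0.0


def test_loss_weight_linearity(tiny_model):
    """Doubling the recon_full weight adds exactly one recon_full to total."""
    n = 2
    rng = np.random.default_rng(5)
    crop = rng.uniform(0, 1, (n, 8, 8))
    anchors = rng.normal(size=(n, 2))
    fovea = rng.uniform(0.3, 0.7, (n, 2))
    qc_bad = np.zeros(n, bool)
    logits = rng.normal(size=(n, 1))
    out = _fake_outputs(n, crop + 0.1, anchors + 1.0, fovea + 0.05, logits)

    def total(w):
        o = _fake_outputs(n, crop + 0.1, anchors + 1.0, fovea + 0.05, logits)
        return tiny_model.compute_losses(
            o, crop, anchors, fovea, qc_bad, weights={"recon_full": w}
        )

    b1, b2 = total(1.0), total(2.0)
    assert b2.total - b1.total == pytest.approx(b1.recon_full, rel=1e-6)


def test_poor_quality_samples_only_contribute_exclusion(tiny_model):
    """Flipping everything about a QC-bad sample except its logit leaves the
    loss unchanged."""
    n = 2
    rng = np.random.default_rng(6)
    crop = rng.uniform(0, 1, (n, 8, 8))
    anchors = rng.normal(size=(n, 2))
    fovea = rng.uniform(0.3, 0.7, (n, 2))
    qc_bad = np.array([False, True])
    logits = rng.normal(size=(n, 1))

    def bundle(crop_mod, anchor_mod):
        out = _fake_outputs(n, crop_mod, anchor_mod, fovea, logits)
        return tiny_model.compute_losses(out, crop, anchors, fovea, qc_bad)

    crop_a = crop.copy()
    crop_b = crop.copy()
    crop_b[1] += 99.0  # wreck the bad sample's reconstruction
    anch_b = anchors.copy()
    anch_b[1] += 50.0
    assert bundle(crop_a, anchors).total == pytest.approx(
        bundle(crop_b, anch_b).total, rel=1e-9
    )


def test_nonfinite_loss_diagnostic_names_term(tiny_model):
    n = 1
    crop = np.full((n, 8, 8), np.nan)
    anchors = np.zeros((n, 2))
    fovea = np.full((n, 2), 0.5)
    out = _fake_outputs(n, crop, anchors, fovea, np.zeros((n, 1)))
    with pytest.raises(FloatingPointError, match="recon"):
        tiny_model.compute_losses(out, crop, anchors, fovea, np.zeros(n, bool))


def test_total_loss_gradient_matches_finite_differences():
    """End-to-end gradient of the full weighted loss vs central differences,
    for every parameter of a tiny float64 model."""
    cfg = ModelConfig(image_px=8, crop_px=4, channels=(2,), dense_units=6,
                      dtype="float64")
    model = BoosterVAE(cfg, seed=1)
    rng = np.random.default_rng(7)
    for p in model.parameters():  # move off zero-init ReLU kinks: generic point
        p.data = p.data + rng.normal(0.0, 0.05, p.data.shape)
    maps = rng.uniform(20, 110, (2, 8, 8))
    crop = model.normalize(rng.uniform(20, 110, (2, 4, 4)))
    anchors = rng.normal(size=(2, 2))
    fovea = rng.uniform(0.2, 0.8, (2, 2))
    qc_bad = np.array([False, True])

    def loss_value():
        out = model.forward(model.normalize(maps))
        return model.compute_losses(out, crop, anchors, fovea, qc_bad).total

    out = model.forward(model.normalize(maps))
    bundle = model.compute_losses(out, crop, anchors, fovea, qc_bad)
    bundle.total_tensor.backward()

    eps = 1e-6
    for p in model.parameters():
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        idx = np.arange(flat.size)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            fp = loss_value()
            flat[i] = orig - eps
            fm = loss_value()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            got = grad.ravel()[i]
            denom = max(abs(num), abs(got), 1e-3)
            assert abs(got - num) / denom < 1e-4


def test_checkpoint_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, tiny_model)
    loaded = load_checkpoint(path)
    assert loaded.cfg == tiny_model.cfg
    rng = np.random.default_rng(8)
    m = rng.uniform(0, 100, (16, 16))
    a, b = tiny_model.encode(m), loaded.encode(m)
    assert np.array_equal(a.d, b.d)
    assert np.array_equal(a.b, b.b)
    assert a.exclude_prob == b.exclude_prob
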