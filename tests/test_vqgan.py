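"""Autoencoder contracts: shapes, quantization, losses, straight-through
gradients, adversarial patch logits and training progress."""

from __future__ import annotations

import numpy as np
import pytest

from histosynth import nn
from histosynth.data import ImageTile
from histosynth.errors import InvalidArgument
from histosynth.synthetic import generate_dataset, generate_tile, PHENOTYPE_BANK
from histosynth.vqgan import (
    Codebook,
    VQGAN,
    VqGanLossReport,
    desk_vqgan_config,
    load_vqgan,
    patch_discriminate,
    quantize,
    train_vqgan,
    vqvae_loss,
)


@pytest.fixture(scope="module")
def model(tiny_vqgan):
    return tiny_vqgan[0]


# -- encode / decode ------------------------------------------------------------


def test_encode_shape_follows_downsample_factor(model):
    tile = generate_tile(PHENOTYPE_BANK[0], 16, seed=0)
    z = model.encode(tile)
    assert z.shape == (4, 4, model.config.codebook_dim)
    tile32 = generate_tile(PHENOTYPE_BANK[0], 32, seed=0)
    assert model.encode(tile32).shape == (8, 8, model.config.codebook_dim)


def test_encode_rejects_indivisible_sizes(model):
    tile = ImageTile(np.zeros((18, 18, 3)))
    with pytest.raises(InvalidArgument, match="factor 4"):
        model.encode(tile)


def test_encode_decode_deterministic(model):
    tile = generate_tile(PHENOTYPE_BANK[1], 16, seed=3)
    z1, z2 = model.encode(tile), model.encode(tile)
    np.testing.assert_array_equal(z1, z2)
    q = quantize(z1, model.codebook)
    r1, r2 = model.decode(q), model.decode(q)
    np.testing.assert_array_equal(r1.pixels, r2.pixels)


def test_decode_output_contract(model, rng):
    d = model.config.codebook_dim
    for _ in range(5):
        grid = rng.normal(size=(4, 4, d)) * 3
        out = model.decode(grid)
        assert out.size == 16
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
    with pytest.raises(InvalidArgument):
        model.decode(rng.normal(size=(4, 4, d + 1)))


# -- quantization ---------------------------------------------------------------


def test_quantize_exact_match_and_hand_example():
    cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
    # vector equal to a codebook row maps there with zero distance
    grid = np.array([[[1.0, 1.0]]])
    q = quantize(grid, cb)
    assert q.indices[0, 0] == 1
    np.testing.assert_array_equal(q.embedded[0, 0], [1.0, 1.0])
    # (0.9, 0.8): squared distances 1.45 vs 0.05 -> row 1
    q2 = quantize(np.array([[[0.9, 0.8]]]), cb)
    assert q2.indices[0, 0] == 1


def test_quantize_idempotent_and_tie_break(rng):
    cb = Codebook(rng.normal(size=(7, 3)))
    grid = rng.normal(size=(5, 5, 3))
    q = quantize(grid, cb)
    q2 = quantize(q.embedded, cb)
    np.testing.assert_array_equal(q.embedded, q2.embedded)
    # exact tie between two identical rows resolves to the lower index
    cb_tie = Codebook(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 5.0]]))
    assert quantize(np.array([[[1.0, 0.1]]]), cb_tie).indices[0, 0] == 0


def test_quantize_matches_exhaustive_scan(rng):
    for _ in range(20):
        k = int(rng.integers(2, 100))
        cb = Codebook(rng.normal(size=(k, 4)))
        grid = rng.normal(size=(3, 3, 4))
        q = quantize(grid, cb)
        for i in range(3):
            for j in range(3):
                dists = [np.sum((grid[i, j] - row) ** 2) for row in cb.vectors]
                assert q.indices[i, j] == int(np.argmin(dists))


def test_quantize_dimension_mismatch(rng):
    with pytest.raises(InvalidArgument):
        quantize(rng.normal(size=(2, 2, 3)), Codebook(rng.normal(size=(4, 5))))


# -- loss report ----------------------------------------------------------------


def test_vqvae_loss_perfect_autoencoding_is_zero(model):
    tile = generate_tile(PHENOTYPE_BANK[0], 16, seed=0)
    cb = model.codebook
    z = np.stack([cb.vectors[0]] * 16).reshape(4, 4, cb.dim)
    q = quantize(z, cb)
    rep = vqvae_loss(tile, tile, z, q, beta=0.2)
    assert rep.l_rec == rep.l_cb == rep.l_commit == 0.0
    assert rep.total == 0.0


def test_vqvae_loss_closed_form_and_beta_scaling(rng):
    x = ImageTile(np.zeros((8, 8, 3)))
    x_hat = ImageTile(np.full((8, 8, 3), 0.1))
    cb = Codebook(np.zeros((2, 2)) + np.array([[0.0], [10.0]]))
    z = np.full((2, 2, 2), 0.5)
    q = quantize(z, cb)
    rep = vqvae_loss(x, x_hat, z, q, beta=0.2)
    assert rep.l_rec == pytest.approx(0.01)
    assert rep.l_commit == pytest.approx(0.25)  # z at 0.5, nearest row at 0
    rep0 = vqvae_loss(x, x_hat, z, q, beta=0.0)
    assert rep.total - rep0.total == pytest.approx(0.2 * rep.l_commit)


def test_loss_report_total_is_weighted_sum(rng):
    rep = VqGanLossReport(
        l_rec=0.3, l_cb=0.1, l_commit=0.5, beta=0.2,
        l_perceptual=0.7, l_adv_g=-0.2, lambda_perc=1.0, lambda_adv=0.5,
    )
    manual = 0.3 + 0.1 + 0.2 * 0.5 + 1.0 * 0.7 + 0.5 * (-0.2)
    assert rep.total == pytest.approx(manual, rel=1e-6)


def test_straight_through_gradient_is_identity(model):
    """d(scalar(z_q))/d(z_e) equals the gradient computed as if z_q == z_e."""
    d = model.config.codebook_dim
    z = nn.Tensor(np.random.default_rng(0).normal(size=(1, d, 1, 1)), requires_grad=True)
    z_q, _, _ = model.quantize_st(z)
    w = np.arange(1.0, d + 1.0).reshape(1, d, 1, 1)
    (z_q * nn.Tensor(w)).sum().backward()
    np.testing.assert_allclose(z.grad, w)  # identity pass-through


# -- discriminator --------------------------------------------------------------


def test_patch_logit_map_is_patchwise(tiny_vqgan):
    _, disc, _ = tiny_vqgan
    tile = generate_tile(PHENOTYPE_BANK[0], 16, seed=0)
    logits = patch_discriminate(tile, disc)
    assert logits.ndim == 2 and logits.size > 1
    np.testing.assert_array_equal(logits, patch_discriminate(tile, disc))


def test_adversarial_loss_equals_per_patch_mean(tiny_vqgan):
    _, disc, _ = tiny_vqgan
    tile = generate_tile(PHENOTYPE_BANK[2], 16, seed=1)
    logits = patch_discriminate(tile, disc)
    hinge_total = np.mean(np.maximum(0.0, 1.0 - logits))
    acc = 0.0
    for v in logits.ravel():
        acc += max(0.0, 1.0 - v)
    assert hinge_total == pytest.approx(acc / logits.size, rel=1e-12)


# -- training -------------------------------------------------------------------


def test_training_reduces_reconstruction_loss(tiny_vqgan):
    _, _, history = tiny_vqgan
    assert history[-1].l_rec < history[0].l_rec


def test_trained_model_beats_untrained_on_heldout(tiny_vqgan, tiny_vqgan_config):
    model, _, _ = tiny_vqgan
    untrained = VQGAN(tiny_vqgan_config)
    heldout = generate_dataset(3, 4, size=16, seed=99, preset_indices=[0, 6, 2])

    def mse(m):
        errs = []
        for t in heldout.tiles:
            rec = m.reconstruct(t)
            errs.append(np.mean((rec.pixels - t.pixels) ** 2))
        return float(np.mean(errs))

    assert mse(model) < 0.8 * mse(untrained)


def test_codebook_is_used_not_collapsed(tiny_vqgan, tiny_dataset):
    model, _, _ = tiny_vqgan
    cb = model.codebook
    used = set()
    for tile in tiny_dataset.tiles[:12]:
        used |= set(np.unique(quantize(model.encode(tile), cb).indices))
    assert len(used) > 1


def test_checkpoint_resume_reproduces_training(tmp_path, tiny_dataset, tiny_vqgan_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_vqgan_config, epochs=2)
    _, _, hist_full = train_vqgan(tiny_dataset, cfg, out_dir=tmp_path / "full")

    cfg1 = dataclasses.replace(cfg, epochs=1)
    train_vqgan(tiny_dataset, cfg1, out_dir=tmp_path / "half")
    cfg2 = dataclasses.replace(cfg, epochs=2)
    _, _, hist_resumed = train_vqgan(
        tiny_dataset, cfg2,
        out_dir=tmp_path / "resumed",
        resume_from=tmp_path / "half" / "vqgan_checkpoint.npz",
    )
    assert hist_resumed[1].l_rec == pytest.approx(hist_full[1].l_rec, rel=1e-9)


def test_checkpoint_roundtrip_preserves_model(tmp_path, tiny_dataset, tiny_vqgan_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_vqgan_config, epochs=1)
    model, _, _ = train_vqgan(tiny_dataset, cfg, out_dir=tmp_path)
    loaded = load_vqgan(tmp_path / "vqgan_checkpoint.npz")
    tile = tiny_dataset[0]
    np.testing.assert_array_equal(model.encode(tile), loaded.encode(tile))


def test_empty_dataset_rejected(tiny_vqgan_config):
    from histosynth.data import TileDataset

    with pytest.raises(InvalidArgument):
        train_vqgan(TileDataset(tiles=[], ids=[]), tiny_vqgan_config)
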