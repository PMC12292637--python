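"""Diffusion math (schedule, forward marginal, reverse step), the
conditional denoiser, phase training and fidelity scoring."""

from __future__ import annotations

import numpy as np
import pytest

from histosynth.clustering import ClusterHead
from histosynth.errors import InvalidArgument
from histosynth.diffusion import (
    DenoiserUNet,
    LatentNormalizer,
    NoiseSchedule,
    TrainPhase,
    conditional_fidelity,
    denoise_loss,
    desk_diffusion_config,
    desk_phases,
    default_phases,
    make_linear_schedule,
    p_sample_step,
    q_sample,
    sample,
    train_ldm,
)


# -- schedule -------------------------------------------------------------------


def test_linear_schedule_hand_example():
    s = make_linear_schedule(2, 0.1, 0.3)
    np.testing.assert_allclose(s.betas, [0.1, 0.3])
    np.testing.assert_allclose(s.alphas, [0.9, 0.7])
    np.testing.assert_allclose(s.alpha_bars, [0.9, 0.63])


def test_single_step_schedule():
    s = make_linear_schedule(1, 0.05, 0.05)
    assert s.T == 1
    assert s.alpha_bars[0] == pytest.approx(0.95)


def test_full_scale_schedule_noises_almost_completely():
    s = make_linear_schedule(1000, 1e-4, 0.02)
    assert s.alpha_bars[-1] < 0.01


def test_schedule_conservation_and_telescoping():
    s = make_linear_schedule(200, 1e-4, 0.05)
    np.testing.assert_allclose(s.alphas + s.betas, 1.0, atol=1e-12)
    ratios = s.alpha_bars[1:] / s.alpha_bars[:-1]
    np.testing.assert_allclose(ratios, s.alphas[1:], atol=1e-12)
    assert np.all(np.diff(s.betas) > 0)
    assert np.all(np.diff(s.alpha_bars) < 0)


def test_schedule_validation():
    with pytest.raises(InvalidArgument):
        make_linear_schedule(0, 0.1, 0.2)
    with pytest.raises(InvalidArgument):
        make_linear_schedule(10, 0.0, 0.2)
    with pytest.raises(InvalidArgument):
        make_linear_schedule(10, 0.3, 0.2)
    with pytest.raises(InvalidArgument):
        NoiseSchedule(np.array([0.1, 1.5]))


# -- forward marginal -----------------------------------------------------------


def test_q_sample_noiseless_branch():
    s = NoiseSchedule(np.array([0.5, 0.5]))  # abar = [0.5, 0.25]
    z = q_sample(np.ones((3, 3, 2)), 2, np.zeros((3, 3, 2)), s)
    np.testing.assert_allclose(z, 0.5)


def test_q_sample_variance_law(rng):
    """Var[z_t] = 1 - abar_t for z0 = 0 and standard-normal noise."""
    s = make_linear_schedule(50, 1e-4, 0.3)
    n = 10_000
    for t in [1, 25, 50]:
        eps = rng.standard_normal((n,))
        z = q_sample(np.zeros(n), t, eps, s)
        target = 1.0 - s.alpha_bars[t - 1]
        se = target * np.sqrt(2.0 / n)  # s.e. of a variance estimate
        assert abs(z.var() - target) < 4 * se


def test_q_sample_terminal_step_decorrelates(rng):
    s = make_linear_schedule(50, 1e-4, 0.3)
    assert s.alpha_bars[-1] < 0.01
    z0 = rng.standard_normal(5000)
    z_T = q_sample(z0, 50, rng.standard_normal(5000), s)
    assert abs(np.corrcoef(z0, z_T)[0, 1]) < 0.2


def test_q_sample_validation(rng):
    s = make_linear_schedule(10, 1e-3, 0.1)
    with pytest.raises(InvalidArgument):
        q_sample(np.zeros(3), 0, np.zeros(3), s)
    with pytest.raises(InvalidArgument):
        q_sample(np.zeros(3), 11, np.zeros(3), s)
    with pytest.raises(InvalidArgument):
        q_sample(np.zeros(3), 1, np.zeros(4), s)


# -- denoise loss ---------------------------------------------------------------


def test_denoise_loss_closed_form_and_symmetry(rng):
    assert denoise_loss(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0
    assert denoise_loss(np.zeros((4, 4)), np.full((4, 4), 0.1)) == pytest.approx(0.01)
    a, b = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
    assert denoise_loss(a, b) == pytest.approx(denoise_loss(b, a))


# -- reverse step ---------------------------------------------------------------


class _ConstNet:
    """A denoiser stub returning a fixed value."""

    latent_dim = 1

    def __init__(self, value):
        self.value = value

    def predict_eps(self, z_t, t, c):
        return np.full_like(np.asarray(z_t, dtype=float), self.value)


def test_p_sample_step_inverts_forward_at_t1():
    """With the true noise, the t=1 reverse mean recovers z0 exactly."""
    s = make_linear_schedule(2, 0.1, 0.3)
    z0, eps = 1.0, 0.5
    z1 = np.sqrt(0.9) * z0 + np.sqrt(0.1) * eps
    out = p_sample_step(
        np.full((1, 1, 1), z1), 1, 0, _ConstNet(eps), s, np.random.default_rng(0)
    )
    assert out[0, 0, 0] == pytest.approx(z0, abs=1e-9)


def test_p_sample_step_random_inversion_property(rng):
    s = make_linear_schedule(7, 1e-3, 0.2)
    z0 = rng.normal(size=(4, 4, 2))
    eps = rng.normal(size=(4, 4, 2))
    z1 = q_sample(z0, 1, eps, s)

    class Oracle:
        latent_dim = 2

        def predict_eps(self, z_t, t, c):
            return eps[None]

    out = p_sample_step(z1, 1, 0, Oracle(), s, rng)
    np.testing.assert_allclose(out, z0, atol=1e-9)


def test_p_sample_step_zero_fixed_point_and_determinism(rng):
    s = make_linear_schedule(5, 1e-3, 0.2)
    out = p_sample_step(np.zeros((2, 2, 1)), 1, 0, _ConstNet(0.0), s, rng)
    np.testing.assert_allclose(out, 0.0)
    a = p_sample_step(np.ones((2, 2, 1)), 3, 0, _ConstNet(0.1), s, np.random.default_rng(5))
    b = p_sample_step(np.ones((2, 2, 1)), 3, 0, _ConstNet(0.1), s, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    with pytest.raises(InvalidArgument):
        p_sample_step(np.ones((2, 2, 1)), 9, 0, _ConstNet(0.0), s, rng)


# -- denoiser network -----------------------------------------------------------


def test_unet_output_shape_and_determinism(rng):
    net = DenoiserUNet(latent_dim=3, n_clusters=4, T=20, base_channels=8, n_down=1, emb_dim=8, seed=0)
    z = rng.normal(size=(2, 4, 4, 3))
    out1 = net.predict_eps(z, np.array([3, 7]), np.array([0, 2]))
    out2 = net.predict_eps(z, np.array([3, 7]), np.array([0, 2]))
    assert out1.shape == z.shape
    np.testing.assert_array_equal(out1, out2)
    with pytest.raises(InvalidArgument):
        net.predict_eps(z, np.array([3, 7]), np.array([0, 9]))


def test_unet_uses_timestep_and_condition(rng):
    net = DenoiserUNet(latent_dim=2, n_clusters=3, T=20, base_channels=8, n_down=1, emb_dim=8, seed=0)
    z = rng.normal(size=(1, 4, 4, 2))
    by_t = net.predict_eps(z, np.array([1]), np.array([0]))
    other_t = net.predict_eps(z, np.array([19]), np.array([0]))
    other_c = net.predict_eps(z, np.array([1]), np.array([1]))
    assert not np.allclose(by_t, other_t)
    assert not np.allclose(by_t, other_c)


# -- sampling -------------------------------------------------------------------


def test_sampling_contract(tiny_vqgan):
    model, _, _ = tiny_vqgan
    d = model.config.codebook_dim
    net = DenoiserUNet(latent_dim=d, n_clusters=2, T=10, base_channels=8, n_down=1, emb_dim=8, seed=0)
    schedule = make_linear_schedule(10, 1e-3, 0.3)
    a = sample(2, 1, net, schedule, model, np.random.default_rng(1), latent_hw=4)
    b = sample(2, 1, net, schedule, model, np.random.default_rng(1), latent_hw=4)
    c = sample(2, 1, net, schedule, model, np.random.default_rng(2), latent_hw=4)
    assert len(a) == 2
    np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
    assert not np.array_equal(a[0].pixels, c[0].pixels)
    for tile in a.tiles:
        assert tile.pixels.min() >= 0.0 and tile.pixels.max() <= 1.0
        assert tile.pixels.shape == (16, 16, 3)


# -- training -------------------------------------------------------------------


def test_training_reduces_denoise_loss(rng):
    latents = np.concatenate(
        [rng.normal(size=(8, 4, 4, 2)) - 2.0, rng.normal(size=(8, 4, 4, 2)) + 2.0]
    )
    conds = np.repeat([0, 1], 8)
    cfg = desk_diffusion_config(T=20, base_channels=8, emb_dim=8, seed=0)
    phases = [TrainPhase("initial", "adam", 3e-3, 40)]
    net, log = train_ldm(latents, conds, phases, cfg)
    assert log[-1]["mse"] < log[0]["mse"]


def test_finetune1_freezes_cluster_head(rng):
    latents = rng.normal(size=(8, 4, 4, 2))
    conds = np.repeat([0, 1], 4)
    feats = rng.normal(size=(8, 3))
    aug = feats + 0.01 * rng.normal(size=(8, 3))
    head = ClusterHead(3, 2, hidden=8, seed=0)
    head.fit_standardizer(feats)
    before = {k: v.copy() for k, v in head.state_dict().items()}
    cfg = desk_diffusion_config(T=10, base_channels=8, emb_dim=8, seed=0)
    phases = [TrainPhase("finetune1", "adam", 1e-3, 3, freeze_cluster_head=True, use_sat=False)]
    train_ldm(latents, conds, phases, cfg, cluster_head=head, features=feats, augmented_features=aug)
    after = head.state_dict()
    for k in before:
        np.testing.assert_array_equal(before[k], after[k])


def test_finetune2_updates_cluster_head(rng):
    latents = rng.normal(size=(8, 4, 4, 2))
    conds = np.repeat([0, 1], 4)
    feats = np.vstack([rng.normal(size=(4, 3)) - 2, rng.normal(size=(4, 3)) + 2])
    aug = feats + 0.5 * rng.normal(size=(8, 3))
    head = ClusterHead(3, 2, hidden=8, seed=0)
    head.fit_standardizer(feats)
    before = head.state_dict()
    cfg = desk_diffusion_config(T=10, base_channels=8, emb_dim=8, seed=0)
    phases = [TrainPhase("finetune2", "adadelta", 1.0, 5)]
    _, log = train_ldm(latents, conds, phases, cfg, cluster_head=head, features=feats, augmented_features=aug)
    changed = any(
        not np.array_equal(before[k], v) for k, v in head.state_dict().items()
    )
    assert changed
    assert any(row["sat_loss"] > 0 for row in log)


def test_memorization_of_single_example(rng):
    """A denoiser trained on one fixed (z_t, t, c, eps) tuple drives its loss
    on that tuple toward zero."""
    from histosynth import nn

    net = DenoiserUNet(latent_dim=2, n_clusters=2, T=10, base_channels=8, n_down=1, emb_dim=8, seed=0)
    z_t = rng.normal(size=(1, 2, 4, 4))
    eps = rng.normal(size=(1, 2, 4, 4))
    opt = nn.Adam(net.parameters(), lr=3e-3)
    t, c = np.array([5]), np.array([1])
    for _ in range(150):
        opt.zero_grad()
        loss = ((net.forward(nn.Tensor(z_t), t, c) - nn.Tensor(eps)) ** 2).mean()
        loss.backward()
        opt.step()
    assert loss.item() < 1e-2


def test_phase_presets_match_protocol():
    paper = default_phases()
    assert [p.name for p in paper] == ["initial", "finetune1", "finetune2"]
    assert [p.epochs for p in paper] == [600, 130, 70]
    assert [p.optimizer for p in paper] == ["adadelta", "adam", "adadelta"]
    assert paper[0].lr == paper[2].lr == 0.003
    assert paper[1].lr == 1e-4
    assert paper[1].freeze_cluster_head and not paper[1].use_sat
    assert not paper[0].freeze_cluster_head and not paper[2].freeze_cluster_head
    desk = desk_phases()
    assert [p.name for p in desk] == ["initial", "finetune1", "finetune2"]
    assert desk[1].freeze_cluster_head


def test_train_ldm_validation(rng):
    cfg = desk_diffusion_config(T=10, seed=0)
    with pytest.raises(InvalidArgument):
        train_ldm(rng.normal(size=(4, 2, 2, 1)), np.zeros(3, dtype=int), desk_phases(), cfg)
    with pytest.raises(InvalidArgument):
        train_ldm(rng.normal(size=(4, 2, 2, 1)), np.zeros(4, dtype=int), [], cfg)


# -- fidelity -------------------------------------------------------------------


class _FixedHead:
    """Cluster-head stub with a constant prediction."""

    def __init__(self, label, K):
        self.label, self.K = label, K

    def predict(self, X):
        from histosynth.clustering import SoftAssignment

        X = np.atleast_2d(X)
        probs = np.zeros((len(X), self.K))
        probs[:, self.label] = 1.0
        return SoftAssignment(probs)


def test_fidelity_perfect_head_and_partition(tiny_vqgan, tiny_dataset):
    model, _, _ = tiny_vqgan
    subset = tiny_dataset.subset(range(6))
    intended = np.zeros(6, dtype=int)
    overall, table = conditional_fidelity(subset, intended, model, _FixedHead(0, 3))
    assert overall == 1.0
    assert table.accuracy.tolist() == [1.0]
    assert int(table.n.sum()) == 6


def test_fidelity_mismatched_head_is_chance_level(tiny_vqgan, tiny_dataset, rng):
    """Random intended IDs against a constant head land at ~1/K."""
    model, _, _ = tiny_vqgan
    K = 4
    n = 24
    subset = tiny_dataset.subset(np.arange(n) % len(tiny_dataset))
    intended = rng.integers(0, K, size=n)
    overall, table = conditional_fidelity(subset, intended, model, _FixedHead(1, K))
    expected = float(np.mean(intended == 1))
    assert overall == pytest.approx(expected)
    assert int(table.n.sum()) == n
    with pytest.raises(InvalidArgument):
        conditional_fidelity(subset, intended[:-1], model, _FixedHead(1, K))


def test_latent_normalizer_roundtrip(rng):
    lat = rng.normal(size=(10, 4, 4, 3)) * 5 + 2
    norm = LatentNormalizer.fit(lat)
    z = norm.normalize(lat)
    np.testing.assert_allclose(z.mean(axis=(0, 1, 2)), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.std(axis=(0, 1, 2)), 1.0, atol=1e-10)
    np.testing.assert_allclose(norm.denormalize(z), lat, atol=1e-10)
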