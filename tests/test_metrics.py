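"""SSIM / MS-SSIM / perceptual-distance behavior, cross-checked against
scikit-image, plus report aggregation and best-k selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.metrics import structural_similarity as sk_ssim

from histosynth import nn
from histosynth.errors import InvalidArgument
from histosynth.metrics import (
    MS_SSIM_WEIGHTS,
    RandomConvExtractor,
    SimilarityReport,
    evaluate_generation,
    feasible_ms_ssim_weights,
    lpips_metric,
    ms_ssim,
    perceptual_distance,
    select_best_cluster_set,
    ssim,
)
from histosynth.reference import reference_similarity_reports
from histosynth.synthetic import generate_dataset
from histosynth.vqgan import perceptual_distance as vqgan_perceptual_distance


def random_image(rng, size=32):
    return rng.random((size, size, 3))


# -- SSIM -----------------------------------------------------------------------


def test_ssim_identity_symmetry_bounds(rng):
    for _ in range(5):
        x, y = random_image(rng), random_image(rng)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)
        assert -1.0 <= ssim(x, y) <= 1.0


def test_ssim_constant_images_closed_form():
    """For constant images the variance terms vanish and SSIM reduces to the
    luminance term (2 m1 m2 + C1) / (m1^2 + m2^2 + C1)."""
    x = np.full((16, 16, 3), 0.5)
    y = np.full((16, 16, 3), 0.25)
    expected = (2 * 0.5 * 0.25 + 1e-4) / (0.25 + 0.0625 + 1e-4)
    assert ssim(x, y) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_ssim_symmetry_and_bounds_property(seed):
    r = np.random.default_rng(seed)
    x, y = r.random((16, 16, 3)), r.random((16, 16, 3))
    s_xy = ssim(x, y)
    assert s_xy == pytest.approx(ssim(y, x), abs=1e-12)
    assert -1.0 <= s_xy <= 1.0


def test_ssim_detects_degradation(rng):
    checker = np.indices((16, 16)).sum(axis=0) % 2
    x = np.repeat(checker[..., None], 3, axis=2).astype(float)
    assert ssim(x, 1.0 - x) < ssim(x, x)


def test_ssim_agrees_with_skimage(rng):
    for _ in range(5):
        x, y = random_image(rng), random_image(rng)
        ours = ssim(x, y)
        theirs = sk_ssim(
            x,
            y,
            channel_axis=2,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
        assert ours == pytest.approx(theirs, abs=5e-4)


def test_ssim_input_validation(rng):
    x = random_image(rng)
    with pytest.raises(InvalidArgument):
        ssim(x, random_image(rng, size=16))
    with pytest.raises(InvalidArgument):
        ssim(x, x, window_size=10)
    with pytest.raises(InvalidArgument):
        ssim(random_image(rng, size=8), random_image(rng, size=8), window_size=11)


# -- MS-SSIM --------------------------------------------------------------------


def test_ms_ssim_identity_and_single_scale_equivalence(rng):
    x, y = random_image(rng), random_image(rng)
    assert ms_ssim(x, x) == pytest.approx(1.0, abs=1e-9)
    assert ms_ssim(x, y, weights=[1.0]) == pytest.approx(ssim(x, y), abs=1e-6)


def test_ms_ssim_weight_handling():
    w3 = feasible_ms_ssim_weights(64, window_size=11)
    assert len(w3) == 3  # 64 -> 32 -> 16 supports 3 scales at window 11
    assert sum(w3) == pytest.approx(1.0)
    np.testing.assert_allclose(
        w3, np.array(MS_SSIM_WEIGHTS[:3]) / sum(MS_SSIM_WEIGHTS[:3])
    )
    rng = np.random.default_rng(0)
    x, y = random_image(rng, 16), random_image(rng, 16)
    with pytest.raises(InvalidArgument):
        ms_ssim(x, y, weights=list(MS_SSIM_WEIGHTS))  # 5 scales infeasible at 16px
    with pytest.raises(InvalidArgument):
        ms_ssim(x, y, weights=[0.5, 0.4])  # weights must sum to 1


def test_ms_ssim_in_unit_interval(rng):
    for _ in range(5):
        x, y = random_image(rng, 64), random_image(rng, 64)
        assert 0.0 <= ms_ssim(x, y) <= 1.0


# -- perceptual distance --------------------------------------------------------


def test_perceptual_distance_identity_symmetry_nonnegative(rng):
    ex = RandomConvExtractor((4, 8), seed=7)
    for _ in range(10):
        x, y = random_image(rng), random_image(rng)
        assert lpips_metric(x, x, ex) == pytest.approx(0.0, abs=1e-12)
        d = lpips_metric(x, y, ex)
        assert d >= 0.0
        assert d == pytest.approx(lpips_metric(y, x, ex), abs=1e-12)


def test_lpips_shares_implementation_with_training_loss(rng):
    ex = RandomConvExtractor((4, 8), seed=7)
    x, y = random_image(rng), random_image(rng)
    assert lpips_metric(x, y, ex) == pytest.approx(
        vqgan_perceptual_distance(x, y, ex), abs=1e-8
    )


def test_perceptual_distance_hand_evaluated_identity_extractor(rng):
    """With a single-channel pass-through layer and unit weights the distance
    is the spatial mean of squared differences of the sign-normalized maps."""

    class PassThrough:
        channel_weights = [np.ones(1)]

        def apply_t(self, x):
            return [x]  # use the raw (N, 1, H, W) map as the only feature

    x2 = np.array([[0.2, -0.4], [0.5, 0.1]])[None, None]
    y2 = np.array([[0.3, 0.7], [-0.2, 0.4]])[None, None]
    from histosynth.metrics import perceptual_distance_t

    got = perceptual_distance_t(nn.Tensor(x2), nn.Tensor(y2), PassThrough()).item()
    nx = x2 / np.sqrt(x2**2 + 1e-10)
    ny = y2 / np.sqrt(y2**2 + 1e-10)
    assert got == pytest.approx(np.mean((nx - ny) ** 2), rel=1e-9)


def test_extractor_is_frozen_and_repeatable(rng):
    ex = RandomConvExtractor((4, 8), seed=7)
    assert ex.frozen
    x = random_image(rng)
    f1 = ex.apply(x)
    f2 = ex.apply(x)
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a, b)
    assert ex.layers == [("conv0", 4), ("conv1", 8)]


# -- paired-set evaluation and selection ----------------------------------------


def test_evaluate_generation_self_comparison_and_aggregation(rng):
    ds = generate_dataset(2, 3, size=16, seed=0)
    ex = RandomConvExtractor((4, 8), seed=7)
    rep = evaluate_generation(ds, ds, k=2, window_size=11, extractor=ex)
    assert rep.ssim_mean == pytest.approx(1.0, abs=1e-9)
    assert rep.ms_ssim_mean == pytest.approx(1.0, abs=1e-9)
    assert rep.lpips_mean == pytest.approx(0.0, abs=1e-12)
    assert rep.n_pairs == len(ds)

    other = generate_dataset(2, 3, size=16, seed=5)
    rep2 = evaluate_generation(other, ds, k=2, window_size=11, extractor=ex)
    manual = np.mean(
        [ssim(a, b, window_size=11) for a, b in zip(other.tiles, ds.tiles)]
    )
    assert rep2.ssim_mean == pytest.approx(manual, rel=1e-12)


def test_evaluate_generation_size_mismatch(rng):
    a = generate_dataset(2, 2, size=16, seed=0)
    b = generate_dataset(2, 3, size=16, seed=0)
    with pytest.raises(InvalidArgument):
        evaluate_generation(a, b)


def test_best_cluster_set_on_published_table_is_14():
    selected, winners = select_best_cluster_set(reference_similarity_reports())
    assert selected == 14
    assert set(winners.values()) == {14}


def test_best_cluster_set_majority_tie_break_and_validation():
    def rep(k, s, ms, lp):
        return SimilarityReport(k=k, ssim_mean=s, ms_ssim_mean=ms, lpips_mean=lp, n_pairs=1)

    # k=10 wins ssim and ms-ssim, k=12 wins lpips -> 10
    assert select_best_cluster_set([rep(10, 0.9, 0.9, 0.5), rep(12, 0.8, 0.8, 0.1)])[0] == 10
    # three metrics won by three different k -> smallest
    r = [rep(10, 0.9, 0.1, 0.5), rep(12, 0.1, 0.9, 0.5), rep(8, 0.1, 0.1, 0.1)]
    assert select_best_cluster_set(r)[0] == 8
    rng = np.random.default_rng(0)
    reports = reference_similarity_reports()
    for _ in range(5):
        shuffled = list(reports)
        rng.shuffle(shuffled)
        assert select_best_cluster_set(shuffled)[0] == 14
    with pytest.raises(InvalidArgument):
        select_best_cluster_set([rep(10, 1, 1, 0), rep(10, 1, 1, 0)])
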