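"""Image-quality metrics: SSIM, MS-SSIM and a learned-feature perceptual distance.

SSIM follows the standard parameterization (Gaussian window of size 11 with
sigma = 1.5, stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with dynamic range
L = 1); it is computed per channel over all valid window positions and
averaged. MS-SSIM combines contrast-structure terms across dyadic scales
with the luminance term at the coarsest scale as a weighted geometric
product; on small images infeasible scales are dropped and the weights
renormalized.

The perceptual distance mirrors the LPIPS construction: feature maps from a
frozen extractor are channel-normalized to unit norm, squared differences
are weighted per channel by non-negative linear weights, averaged over
space and summed over layers. The packaged default extractor is a frozen
random convolutional stack with a fixed seed, so the metric carries no
pretrained-weight dependency; any extractor satisfying the
:class:`FeatureExtractor` contract can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .data import ImageTile, TileDataset
from .errors import InvalidArgument, NumericError

__all__ = [
    "ssim",
    "ms_ssim",
    "MS_SSIM_WEIGHTS",
    "FeatureExtractor",
    "RandomConvExtractor",
    "perceptual_distance",
    "perceptual_distance_t",
    "lpips_metric",
    "SimilarityReport",
    "evaluate_generation",
    "select_best_cluster_set",
]

#: canonical 5-scale MS-SSIM weights
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _pixels(x) -> np.ndarray:
    arr = x.pixels if isinstance(x, ImageTile) else np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _local_stats(a: np.ndarray, win: np.ndarray) -> np.ndarray:
    """Weighted local mean of a 2-D array over all valid window positions."""
    k = win.shape[0]
    windows = sliding_window_view(a, (k, k))
    return np.einsum("ijkl,kl->ij", windows, win)


def _ssim_components(
    x: np.ndarray, y: np.ndarray, window_size: int, sigma: float, k1: float, k2: float
) -> tuple[float, float]:
    """(mean luminance term x cs, mean cs) over channels and window positions."""
    c1 = (k1 * 1.0) ** 2
    c2 = (k2 * 1.0) ** 2
    win = _gaussian_window(window_size, sigma)
    ssim_vals, cs_vals = [], []
    for ch in range(x.shape[2]):
        a, b = x[:, :, ch], y[:, :, ch]
        mu_a = _local_stats(a, win)
        mu_b = _local_stats(b, win)
        var_a = _local_stats(a * a, win) - mu_a**2
        var_b = _local_stats(b * b, win) - mu_b**2
        cov = _local_stats(a * b, win) - mu_a * mu_b
        lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
        cs = (2 * cov + c2) / (var_a + var_b + c2)
        ssim_vals.append((lum * cs).mean())
        cs_vals.append(cs.mean())
    return float(np.mean(ssim_vals)), float(np.mean(cs_vals))


def ssim(x, y, window_size: int = 11, k1: float = 0.01, k2: float = 0.03, sigma: float = 1.5) -> float:
    """Structural similarity of two images in [0, 1], averaged over channels."""
    x, y = _pixels(x), _pixels(y)
    if x.shape != y.shape:
        raise InvalidArgument(f"size mismatch: {x.shape} vs {y.shape}")
    if window_size % 2 == 0 or window_size < 3:
        raise InvalidArgument("window_size must be odd and >= 3")
    if window_size > x.shape[0]:
        raise InvalidArgument(
            f"window_size {window_size} exceeds image size {x.shape[0]}"
        )
    full, _ = _ssim_components(x, y, window_size, sigma, k1, k2)
    return full


def _downsample2(a: np.ndarray) -> np.ndarray:
    h, w = (a.shape[0] // 2) * 2, (a.shape[1] // 2) * 2
    a = a[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def feasible_ms_ssim_weights(size: int, window_size: int = 11, min_size: int = 8) -> list[float]:
    """Default MS-SSIM weights truncated to the scales an image supports.

    Scales that would shrink the image below max(window_size, min_size) are
    dropped and the remaining weights renormalized to sum to 1.
    """
    floor = max(window_size, min_size)
    n = 0
    s = size
    for _ in MS_SSIM_WEIGHTS:
        if s < floor:
            break
        n += 1
        s //= 2
    if n == 0:
        raise InvalidArgument(f"image of size {size} supports no scale at window {window_size}")
    w = np.asarray(MS_SSIM_WEIGHTS[:n])
    return list(w / w.sum())


def ms_ssim(
    x,
    y,
    weights: list[float] | None = None,
    window_size: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
) -> float:
    """Multi-scale SSIM with non-negative per-scale terms.

    ``weights`` must sum to 1 (one weight per scale, finest first); when
    omitted they default to the canonical 5-scale weights truncated to the
    scales the image supports.
    """
    x, y = _pixels(x), _pixels(y)
    if x.shape != y.shape:
        raise InvalidArgument(f"size mismatch: {x.shape} vs {y.shape}")
    if weights is None:
        weights = feasible_ms_ssim_weights(x.shape[0], window_size)
    weights = np.asarray(weights, dtype=np.float64)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise InvalidArgument("MS-SSIM weights must sum to 1")
    n_scales = len(weights)
    if x.shape[0] // 2 ** (n_scales - 1) < window_size:
        raise InvalidArgument(
            f"image of size {x.shape[0]} cannot support {n_scales} scales at window {window_size}"
        )
    result = 1.0
    for s, w in enumerate(weights):
        full, cs = _ssim_components(x, y, window_size, sigma, k1, k2)
        term = full if s == n_scales - 1 else cs  # luminance only at the coarsest scale
        result *= max(term, 0.0) ** w
        if s < n_scales - 1:
            x = np.stack([_downsample2(x[:, :, c]) for c in range(x.shape[2])], axis=2)
            y = np.stack([_downsample2(y[:, :, c]) for c in range(y.shape[2])], axis=2)
    return float(result)


# -- perceptual distance --------------------------------------------------------


@dataclass
class FeatureExtractor:
    """A frozen multi-layer feature extractor with per-channel metric weights.

    ``convs`` maps an (N, 3, H, W) tensor in [-1, 1] through a stack of
    strided convolutions; features are taken after every activation.
    ``channel_weights`` are the non-negative linear weights applied to the
    squared, channel-normalized feature differences.
    """

    convs: list[nn.Conv2d]
    channel_weights: list[np.ndarray]
    frozen: bool = True

    @property
    def layers(self) -> list[tuple[str, int]]:
        return [(f"conv{i}", c.weight.shape[0]) for i, c in enumerate(self.convs)]

    def apply_t(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = []
        h = x
        for conv in self.convs:
            h = nn.silu(conv(h))
            feats.append(h)
        return feats

    def apply(self, image) -> list[np.ndarray]:
        """Feature maps of one image (H x W x 3 in [0, 1]); no gradients."""
        arr = _pixels(image)
        t = nn.Tensor((arr * 2.0 - 1.0).transpose(2, 0, 1)[None])
        return [f.data[0] for f in self.apply_t(t)]


def RandomConvExtractor(
    channels: tuple[int, ...] = (8, 16, 16), seed: int = 1234
) -> FeatureExtractor:
    """The packaged default extractor: a frozen, fixed-seed random conv stack."""
    rng = np.random.default_rng(seed)
    convs = []
    c_in = 3
    for c_out in channels:
        conv = nn.Conv2d(c_in, c_out, 3, rng, stride=2)
        conv.freeze()
        convs.append(conv)
        c_in = c_out
    weights = [np.ones(c) for c in channels]
    return FeatureExtractor(convs=convs, channel_weights=weights)


def _channel_normalize_t(f: nn.Tensor, eps: float = 1e-10) -> nn.Tensor:
    norm = ((f**2).sum(axis=1, keepdims=True) + eps).sqrt()
    return f / norm


def perceptual_distance_t(x: nn.Tensor, y: nn.Tensor, extractor: FeatureExtractor) -> nn.Tensor:
    """Differentiable perceptual distance of (N, 3, H, W) batches in [-1, 1]."""
    fx = extractor.apply_t(x)
    fy = extractor.apply_t(y)
    total = None
    for f_a, f_b, w in zip(fx, fy, extractor.channel_weights):
        diff = _channel_normalize_t(f_a) - _channel_normalize_t(f_b)
        wt = nn.Tensor(np.asarray(w).reshape(1, -1, 1, 1))
        layer = (wt * diff**2).sum(axis=1).mean(axis=(1, 2)).mean()
        total = layer if total is None else total + layer
    return total


def perceptual_distance(x, y, extractor: FeatureExtractor | None = None) -> float:
    """Perceptual distance between two images in [0, 1]; 0 for identical inputs."""
    if extractor is None:
        extractor = _default_extractor()
    xa, ya = _pixels(x), _pixels(y)
    if xa.shape != ya.shape:
        raise InvalidArgument(f"size mismatch: {xa.shape} vs {ya.shape}")
    tx = nn.Tensor((xa * 2 - 1).transpose(2, 0, 1)[None])
    ty = nn.Tensor((ya * 2 - 1).transpose(2, 0, 1)[None])
    val = perceptual_distance_t(tx, ty, extractor).item()
    if not np.isfinite(val):
        raise NumericError("perceptual distance is non-finite")
    return float(val)


_DEFAULT_EXTRACTOR: FeatureExtractor | None = None


def _default_extractor() -> FeatureExtractor:
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = RandomConvExtractor()
    return _DEFAULT_EXTRACTOR


def lpips_metric(x, y, extractor: FeatureExtractor | None = None) -> float:
    """Learned-perceptual distance exposed as an evaluation metric.

    Shares its implementation with the training-time perceptual loss.
    """
    return perceptual_distance(x, y, extractor)


# -- paired-set evaluation ------------------------------------------------------


@dataclass
class SimilarityReport:
    """Mean SSIM / MS-SSIM / perceptual distance over a paired image set."""

    k: int
    ssim_mean: float
    ms_ssim_mean: float
    lpips_mean: float
    n_pairs: int


def evaluate_generation(
    generated: TileDataset,
    references: TileDataset,
    pairing: str = "by-source",
    k: int = 0,
    window_size: int = 11,
    extractor: FeatureExtractor | None = None,
) -> SimilarityReport:
    """Score generated tiles against references under by-source pairing.

    Under ``by-source``, generated[i] must have been conditioned on the
    cluster of references[i]; the three metrics are computed per pair and
    averaged.
    """
    if pairing != "by-source":
        raise InvalidArgument(f"unknown pairing strategy: {pairing!r}")
    if len(generated) != len(references):
        raise InvalidArgument(
            f"by-source pairing needs equal sizes, got {len(generated)} vs {len(references)}"
        )
    if extractor is None:
        extractor = _default_extractor()
    ws = min(window_size, generated[0].size if generated[0].size % 2 else generated[0].size - 1)
    ssims, msssims, lpipss = [], [], []
    for g, r in zip(generated.tiles, references.tiles):
        ssims.append(ssim(g, r, window_size=ws))
        msssims.append(ms_ssim(g, r, window_size=ws))
        lpipss.append(lpips_metric(g, r, extractor))
    return SimilarityReport(
        k=k,
        ssim_mean=float(np.mean(ssims)),
        ms_ssim_mean=float(np.mean(msssims)),
        lpips_mean=float(np.mean(lpipss)),
        n_pairs=len(generated),
    )


def select_best_cluster_set(reports: list[SimilarityReport]) -> tuple[int, dict[str, int]]:
    """Majority vote over (max SSIM, max MS-SSIM, min perceptual distance).

    Returns ``(winning_k, winners)`` with per-metric winners; ties on the
    majority go to the smallest tied k.
    """
    if len(reports) < 2:
        raise InvalidArgument("need at least two reports")
    ks = [r.k for r in reports]
    if len(set(ks)) != len(ks):
        raise InvalidArgument("duplicate k values in reports")
    directions = {"ssim_mean": +1, "ms_ssim_mean": +1, "lpips_mean": -1}
    winners: dict[str, int] = {}
    for name, direction in directions.items():
        best = max(
            range(len(reports)),
            key=lambda i: (direction * getattr(reports[i], name), -ks[i]),
        )
        winners[name] = ks[best]
    counts: dict[int, int] = {}
    for kk in winners.values():
        counts[kk] = counts.get(kk, 0) + 1
    top = max(counts.values())
    selected = min(kk for kk, c in counts.items() if c == top)
    return selected, winners
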