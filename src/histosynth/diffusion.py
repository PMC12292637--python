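"""Denoising diffusion in the autoencoder's latent space, conditioned on cluster IDs.

The forward chain corrupts a clean latent z_0 over T steps with a linear
beta schedule; its closed-form marginal is

    z_t = sqrt(abar_t) z_0 + sqrt(1 - abar_t) eps,   eps ~ N(0, I),

with alpha_t = 1 - beta_t and abar_t the running product (the variance-
preserving form). A conditional U-Net predicts the injected noise from
(z_t, t, c), trained with the plain MSE between true and predicted noise.
Ancestral sampling inverts the chain step by step with the posterior
variance beta_t (1 - abar_{t-1}) / (1 - abar_t); the mean-only step at
t = 1 makes one-step inversion with oracle noise exact.

Training follows a three-phase protocol: a long initial phase (Adadelta),
a finetuning phase that freezes the clustering head and minimizes the
denoising MSE alone (Adam), and a final phase that re-enables the
transformation-consistency (SAT) loss with nothing frozen (Adadelta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .clustering import ClusterHead, _EPS, hard_labels, latent_features
from .data import ImageTile, TileDataset
from .errors import InvalidArgument, NumericError
from .vqgan import VQGAN, quantize

__all__ = [
    "NoiseSchedule",
    "make_linear_schedule",
    "q_sample",
    "denoise_loss",
    "DenoiserUNet",
    "DiffusionConfig",
    "desk_diffusion_config",
    "TrainPhase",
    "default_phases",
    "desk_phases",
    "LatentNormalizer",
    "p_sample_step",
    "sample",
    "sample_batch",
    "train_ldm",
    "conditional_fidelity",
]


@dataclass
class NoiseSchedule:
    """beta_t, alpha_t = 1 - beta_t and the running product abar_t, t = 1..T."""

    betas: np.ndarray

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.betas.ndim != 1 or len(self.betas) < 1:
            raise InvalidArgument("betas must be a non-empty vector")
        if self.betas.min() <= 0.0 or self.betas.max() >= 1.0:
            raise InvalidArgument("betas must lie strictly inside (0, 1)")
        self.alphas = 1.0 - self.betas
        self.alpha_bars = np.cumprod(self.alphas)

    @property
    def T(self) -> int:
        return len(self.betas)

    def _check_t(self, t: int) -> int:
        t = int(t)
        if not 1 <= t <= self.T:
            raise InvalidArgument(f"timestep {t} outside [1, {self.T}]")
        return t


def make_linear_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02) -> NoiseSchedule:
    """Betas linearly spaced from beta_start to beta_end inclusive."""
    if T < 1:
        raise InvalidArgument("T must be >= 1")
    if not 0.0 < beta_start <= beta_end < 1.0:
        raise InvalidArgument("need 0 < beta_start <= beta_end < 1")
    return NoiseSchedule(np.linspace(beta_start, beta_end, T))


def q_sample(z0: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Sample z_t from the forward marginal given clean latent and noise."""
    t = schedule._check_t(t)
    z0 = np.asarray(z0, dtype=np.float64)
    eps = np.asarray(eps, dtype=np.float64)
    if z0.shape != eps.shape:
        raise InvalidArgument("z0 and eps must share a shape")
    ab = schedule.alpha_bars[t - 1]
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


def denoise_loss(eps: np.ndarray, eps_hat: np.ndarray) -> float:
    """Mean squared error between true and predicted noise."""
    eps = np.asarray(eps, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if eps.shape != eps_hat.shape:
        raise InvalidArgument("shape mismatch")
    if not (np.isfinite(eps).all() and np.isfinite(eps_hat).all()):
        raise NumericError("non-finite noise values")
    return float(np.mean((eps - eps_hat) ** 2))


# -- conditional U-Net ----------------------------------------------------------


class _EmbResBlock(nn.Module):
    """Residual block with the (time + class) embedding injected as a channel bias."""

    def __init__(self, ch: int, emb_dim: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(ch, ch, 3, rng)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng)
        self.emb_proj = nn.Linear(emb_dim, ch, rng)

    def forward(self, x: nn.Tensor, emb: nn.Tensor) -> nn.Tensor:
        h = nn.silu(self.conv1(x))
        bias = self.emb_proj(emb).reshape(emb.shape[0], -1, 1, 1)
        h = self.conv2(nn.silu(h + bias))
        return nn.silu(h + x)


class DenoiserUNet(nn.Module):
    """U-Net predicting the injected noise from (z_t, t, c).

    The cluster ID conditions the network through a learned embedding added
    to the sinusoidal timestep embedding and injected into every block.
    """

    def __init__(
        self,
        latent_dim: int,
        n_clusters: int,
        T: int,
        base_channels: int = 16,
        n_down: int = 1,
        emb_dim: int = 16,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.n_clusters = n_clusters
        self.T = T
        self.emb_dim = emb_dim
        self.n_down = n_down
        c = base_channels

        self.class_emb = nn.Parameter(rng.normal(0.0, 0.2, size=(n_clusters, emb_dim)))
        self.emb_fc1 = nn.Linear(emb_dim, emb_dim, rng)
        self.emb_fc2 = nn.Linear(emb_dim, emb_dim, rng)

        self.conv_in = nn.Conv2d(latent_dim, c, 3, rng)
        self.down_blocks = []
        self.down_convs = []
        ch = c
        for _ in range(n_down):
            self.down_blocks.append(_EmbResBlock(ch, emb_dim, rng))
            self.down_convs.append(nn.Conv2d(ch, 2 * ch, 3, rng, stride=2))
            ch *= 2
        self.mid = _EmbResBlock(ch, emb_dim, rng)
        self.up_convs = []
        self.up_merge = []
        self.up_blocks = []
        for _ in range(n_down):
            self.up_convs.append(nn.Conv2d(ch, ch // 2, 3, rng))
            self.up_merge.append(nn.Conv2d(ch, ch // 2, 3, rng))  # after skip concat
            ch //= 2
            self.up_blocks.append(_EmbResBlock(ch, emb_dim, rng))
        self.conv_out = nn.Conv2d(ch, latent_dim, 3, rng)

    def _timestep_embedding(self, t: np.ndarray) -> np.ndarray:
        """Sinusoidal embedding of integer timesteps (1..T)."""
        half = self.emb_dim // 2
        freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
        ang = np.asarray(t, dtype=np.float64)[:, None] * freqs[None, :]
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    def forward(self, z: nn.Tensor, t: np.ndarray, c: np.ndarray) -> nn.Tensor:
        n = z.shape[0]
        c = np.asarray(c, dtype=np.int64)
        if c.min() < 0 or c.max() >= self.n_clusters:
            raise InvalidArgument("condition IDs must lie in [0, n_clusters)")
        onehot = np.zeros((n, self.n_clusters))
        onehot[np.arange(n), c] = 1.0
        emb = nn.Tensor(self._timestep_embedding(t)) + nn.Tensor(onehot) @ self.class_emb
        emb = self.emb_fc2(nn.silu(self.emb_fc1(emb)))

        h = nn.silu(self.conv_in(z))
        skips = []
        for blk, dn in zip(self.down_blocks, self.down_convs):
            h = blk(h, emb)
            skips.append(h)
            h = nn.silu(dn(h))
        h = self.mid(h, emb)
        for up, merge, blk in zip(self.up_convs, self.up_merge, self.up_blocks):
            h = nn.silu(up(nn.upsample_nearest2d(h, 2)))
            h = nn.silu(merge(nn.concatenate([h, skips.pop()], axis=1)))
            h = blk(h, emb)
        return self.conv_out(h)

    def predict_eps(self, z_t: np.ndarray, t, c) -> np.ndarray:
        """Numpy-facing noise prediction for an (N, h, w, d) batch."""
        z = nn.Tensor(np.asarray(z_t).transpose(0, 3, 1, 2))
        t = np.atleast_1d(np.asarray(t))
        c = np.atleast_1d(np.asarray(c))
        out = self.forward(z, t, c)
        return out.data.transpose(0, 2, 3, 1)


# -- configuration --------------------------------------------------------------


@dataclass
class DiffusionConfig:
    """Full-scale defaults: T = 1000 linear schedule, batch 16, a U-Net whose
    bottleneck sits two halvings below the latent grid (32 -> 8)."""

    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    base_channels: int = 32
    n_down: int = 2
    emb_dim: int = 32
    batch_size: int = 16
    mu_sat: float = 1.0
    seed: int = 0


def desk_diffusion_config(**overrides) -> DiffusionConfig:
    # beta_end is raised so that the terminal abar at T = 50 matches the
    # near-total noising the full T = 1000 schedule reaches (abar_T << 1);
    # otherwise ancestral sampling would start from a noise level the
    # denoiser never trained on.
    base = dict(T=50, beta_end=0.3, base_channels=32, n_down=1, emb_dim=16, batch_size=8)
    base.update(overrides)
    return DiffusionConfig(**base)


@dataclass
class LatentNormalizer:
    """Per-channel affine map bringing latents to zero mean, unit variance.

    Diffusion assumes approximately unit-scale data (z_T is exchanged for a
    standard normal); autoencoder latents are not naturally on that scale.
    """

    mu: np.ndarray
    sigma: np.ndarray

    @staticmethod
    def fit(latents: np.ndarray) -> "LatentNormalizer":
        mu = latents.mean(axis=(0, 1, 2))
        sigma = np.maximum(latents.std(axis=(0, 1, 2)), 1e-8)
        return LatentNormalizer(mu=mu, sigma=sigma)

    def normalize(self, z: np.ndarray) -> np.ndarray:
        return (z - self.mu) / self.sigma

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return z * self.sigma + self.mu


@dataclass
class TrainPhase:
    """One stage of the training protocol.

    ``freeze_cluster_head`` pins the clustering network's parameters for the
    phase; ``use_sat`` includes the transformation-consistency loss in the
    objective (the denoising MSE is always present).
    """

    name: str
    optimizer: str
    lr: float
    epochs: int
    freeze_cluster_head: bool = False
    use_sat: bool = True


def default_phases() -> list[TrainPhase]:
    """The full-scale protocol: 600 Adadelta epochs, 130 Adam epochs with the
    clustering head frozen and MSE only, then 70 Adadelta epochs with the
    transformation loss re-enabled."""
    return [
        TrainPhase("initial", "adadelta", 0.003, 600),
        TrainPhase("finetune1", "adam", 1e-4, 130, freeze_cluster_head=True, use_sat=False),
        TrainPhase("finetune2", "adadelta", 0.003, 70),
    ]


def desk_phases(epochs: tuple[int, int, int] = (250, 50, 30)) -> list[TrainPhase]:
    """The same three-phase protocol at desk scale.

    The step multipliers differ from the full-scale ones because the desk
    run takes orders of magnitude fewer optimizer steps; Adadelta keeps its
    role in the initial and final phases with a larger multiplier, and the
    epoch split preserves the full protocol's rough 600:130:70 proportions.
    """
    return [
        TrainPhase("initial", "adadelta", 3.0, epochs[0]),
        TrainPhase("finetune1", "adam", 1e-3, epochs[1], freeze_cluster_head=True, use_sat=False),
        TrainPhase("finetune2", "adadelta", 3.0, epochs[2]),
    ]


# -- sampling -------------------------------------------------------------------


def _p_sample_batch(
    z_t: np.ndarray,
    t: int,
    c: np.ndarray,
    net: DenoiserUNet,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    t = schedule._check_t(t)
    beta = schedule.betas[t - 1]
    alpha = schedule.alphas[t - 1]
    ab = schedule.alpha_bars[t - 1]
    eps_hat = net.predict_eps(z_t, np.full(len(z_t), t), c)
    mu = (z_t - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)
    if t == 1:
        return mu
    ab_prev = schedule.alpha_bars[t - 2]
    sigma = np.sqrt(beta * (1.0 - ab_prev) / (1.0 - ab))
    return mu + sigma * rng.standard_normal(z_t.shape)


def p_sample_step(
    z_t: np.ndarray,
    t: int,
    c: int,
    net: DenoiserUNet,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """One ancestral reverse step for a single (h, w, d) latent."""
    out = _p_sample_batch(
        np.asarray(z_t)[None], t, np.array([int(c)]), net, schedule, rng
    )
    return out[0]


def sample_batch(
    conditions: np.ndarray,
    net: DenoiserUNet,
    schedule: NoiseSchedule,
    model: VQGAN,
    rng: np.random.Generator,
    latent_hw: int,
    quantize_latents: bool = True,
    normalizer: "LatentNormalizer | None" = None,
) -> TileDataset:
    """Ancestral sampling of one tile per entry of ``conditions``.

    The trajectory runs on continuous latents (in normalized space when a
    ``normalizer`` is given, mirroring training); each final z_0 is snapped
    through the codebook (so the decoder always sees a decodable latent)
    and decoded to pixel space.
    """
    conds = np.asarray(conditions, dtype=np.int64)
    n = len(conds)
    z = rng.standard_normal((n, latent_hw, latent_hw, net.latent_dim))
    for t in range(schedule.T, 0, -1):
        z = _p_sample_batch(z, t, conds, net, schedule, rng)
        if not np.isfinite(z).all():
            raise NumericError(f"non-finite latent during sampling at timestep {t}")
    if normalizer is not None:
        z = normalizer.denormalize(z)
    tiles, ids = [], []
    cb = model.codebook
    for i in range(n):
        grid = quantize(z[i], cb).embedded if quantize_latents else z[i]
        tile = model.decode(grid)
        tile.meta["condition"] = int(conds[i])
        tiles.append(tile)
        ids.append(f"gen_{i:05d}_c{int(conds[i]):03d}")
    return TileDataset(tiles=tiles, ids=ids, split="generated")


def sample(
    n: int,
    c: int,
    net: DenoiserUNet,
    schedule: NoiseSchedule,
    model: VQGAN,
    rng: np.random.Generator,
    latent_hw: int | None = None,
    quantize_latents: bool = True,
) -> TileDataset:
    """Generate n tiles conditioned on one cluster ID c."""
    if latent_hw is None:
        raise InvalidArgument("latent_hw (spatial size of the latent grid) is required")
    return sample_batch(
        np.full(n, int(c)), net, schedule, model, rng, latent_hw, quantize_latents
    )


# -- training -------------------------------------------------------------------


def train_ldm(
    latents: np.ndarray,
    conditions: np.ndarray,
    phases: list[TrainPhase],
    config: DiffusionConfig,
    cluster_head: ClusterHead | None = None,
    features: np.ndarray | None = None,
    augmented_features: np.ndarray | None = None,
    net: DenoiserUNet | None = None,
) -> tuple[DenoiserUNet, list[dict]]:
    """Train the denoiser over the phase schedule.

    ``latents`` is (n, h, w, d) of clean latents, ``conditions`` the aligned
    cluster IDs. When a cluster head plus (features, augmented_features) are
    supplied, phases with ``use_sat`` add mu_sat times the SAT loss to the
    objective and the head trains jointly except where a phase freezes it.
    Returns the net and a per-epoch loss log (phase, epoch, mse, sat_loss).
    """
    latents = np.asarray(latents, dtype=np.float64)
    conditions = np.asarray(conditions, dtype=np.int64)
    if latents.ndim != 4:
        raise InvalidArgument("latents must be (n, h, w, d)")
    if len(latents) != len(conditions):
        raise InvalidArgument("latents and conditions must be aligned")
    if not phases:
        raise InvalidArgument("phase list is empty")
    n, h, w, d = latents.shape
    n_clusters = int(conditions.max()) + 1
    schedule = make_linear_schedule(config.T, config.beta_start, config.beta_end)
    if net is None:
        net = DenoiserUNet(
            latent_dim=d,
            n_clusters=n_clusters,
            T=config.T,
            base_channels=config.base_channels,
            n_down=config.n_down,
            emb_dim=config.emb_dim,
            seed=config.seed,
        )
    rng = np.random.default_rng(config.seed + 17)
    z_all = latents.transpose(0, 3, 1, 2)  # (n, d, h, w)
    log: list[dict] = []

    sat_available = (
        cluster_head is not None and features is not None and augmented_features is not None
    )

    for phase in phases:
        params = list(net.parameters())
        if sat_available:
            if phase.freeze_cluster_head:
                cluster_head.freeze()
            else:
                cluster_head.unfreeze()
                if phase.use_sat:
                    params += cluster_head.parameters()
        opt = nn.make_optimizer(phase.optimizer, params, phase.lr)
        for epoch in range(phase.epochs):
            order = rng.permutation(n)
            mse_acc, sat_acc, n_batches = 0.0, 0.0, 0
            for b0 in range(0, n, config.batch_size):
                idx = order[b0 : b0 + config.batch_size]
                z0 = z_all[idx]
                t = rng.integers(1, config.T + 1, size=len(idx))
                eps = rng.standard_normal(z0.shape)
                ab = schedule.alpha_bars[t - 1][:, None, None, None]
                z_t = np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps

                opt.zero_grad()
                eps_hat = net.forward(nn.Tensor(z_t), t, conditions[idx])
                mse = ((eps_hat - nn.Tensor(eps)) ** 2).mean()
                loss = mse
                sat_val = 0.0
                if sat_available and phase.use_sat and not phase.freeze_cluster_head:
                    target = cluster_head.predict(features[idx]).probs
                    logq = cluster_head.log_probs_t(augmented_features[idx])
                    tgt = nn.Tensor(target)
                    kl = (tgt * nn.Tensor(np.log(np.maximum(target, _EPS)))).sum(axis=1) - (
                        tgt * logq
                    ).sum(axis=1)
                    sat = kl.mean()
                    loss = loss + config.mu_sat * sat
                    sat_val = sat.item()
                if not np.isfinite(loss.item()):
                    raise NumericError(f"non-finite loss in phase {phase.name}")
                loss.backward()
                opt.step()
                mse_acc += mse.item()
                sat_acc += sat_val
                n_batches += 1
            log.append(
                {
                    "phase": phase.name,
                    "epoch": epoch,
                    "mse": mse_acc / n_batches,
                    "sat_loss": sat_acc / n_batches,
                }
            )
        if sat_available and phase.freeze_cluster_head:
            cluster_head.unfreeze()
    return net, log


def conditional_fidelity(
    generated: TileDataset,
    intended: np.ndarray,
    model: VQGAN,
    cluster_head: ClusterHead,
    feature_mode: str = "mean-pool",
):
    """Fraction of generated tiles whose re-encoded latent lands in the
    intended cluster, overall and per cluster.

    Returns ``(overall_accuracy, table)`` where the table is a DataFrame
    with columns (cluster, n, n_correct, accuracy).
    """
    import pandas as pd

    intended = np.asarray(intended, dtype=np.int64)
    if len(generated) != len(intended):
        raise InvalidArgument("generated tiles and intended IDs must be aligned")
    cb = model.codebook
    feats = np.stack(
        [
            latent_features(quantize(model.encode(tile), cb), mode=feature_mode)
            for tile in generated.tiles
        ]
    )
    predicted = hard_labels(cluster_head.predict(feats))
    rows = []
    for cl in np.unique(intended):
        mask = intended == cl
        n_correct = int((predicted[mask] == cl).sum())
        rows.append(
            {
                "cluster": int(cl),
                "n": int(mask.sum()),
                "n_correct": n_correct,
                "accuracy": n_correct / int(mask.sum()),
            }
        )
    overall = float((predicted == intended).mean())
    return overall, pd.DataFrame(rows)
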