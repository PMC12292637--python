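"""Vector-quantized adversarial autoencoder for tile compression.

The autoencoder maps a square RGB tile (rescaled to [-1, 1] at the model
boundary) through a strided convolutional encoder to a continuous latent
grid z_e, snaps every grid vector to its nearest codebook row (straight-
through gradients), and decodes back to pixel space. Training combines

    L = L_rec + L_cb + beta * L_commit
        + lambda_perc * L_perceptual + lambda_adv * L_adv

where L_rec is the pixel MSE, L_cb pulls codebook rows toward the (stopped)
encoder outputs, L_commit (weight beta, default 0.2) pulls encoder outputs
toward the (stopped) codebook rows, L_perceptual is the channel-normalized
deep-feature distance and L_adv a hinge adversarial term from a patch-level
discriminator. The discriminator classifies local patches rather than whole
images, so its output is a grid of logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from . import nn
from .data import ImageTile, TileDataset
from .errors import InvalidArgument, NumericError
from .metrics import FeatureExtractor, RandomConvExtractor, perceptual_distance, perceptual_distance_t

__all__ = [
    "Codebook",
    "QuantizedLatent",
    "VqGanLossReport",
    "VQGANConfig",
    "desk_vqgan_config",
    "VQGAN",
    "PatchDiscriminator",
    "encode",
    "quantize",
    "decode",
    "vqvae_loss",
    "patch_discriminate",
    "perceptual_distance",
    "train_vqgan",
]


@dataclass
class Codebook:
    """The learned table of discrete latent embeddings (K_cb x d)."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 2:
            raise InvalidArgument("codebook must be a K x d matrix with K >= 2")
        if not np.isfinite(self.vectors).all():
            raise NumericError("codebook contains non-finite values")

    @property
    def size(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class QuantizedLatent:
    """Nearest-codebook-row snap of a latent grid: indices plus embeddings."""

    indices: np.ndarray
    embedded: np.ndarray


@dataclass
class VqGanLossReport:
    """One evaluation of the composite loss; ``total`` is the weighted sum."""

    l_rec: float
    l_cb: float
    l_commit: float
    beta: float
    l_perceptual: float = 0.0
    l_adv_g: float = 0.0
    l_adv_d: float = 0.0
    lambda_perc: float = 0.0
    lambda_adv: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.l_rec
            + self.l_cb
            + self.beta * self.l_commit
            + self.lambda_perc * self.l_perceptual
            + self.lambda_adv * self.l_adv_g
        )


@dataclass
class VQGANConfig:
    """Hyperparameters; the defaults are the full-scale settings
    (codebook 128 x 16, 128->32 latents, Adam at 1e-4, batch 16, 20 epochs,
    SiLU activations, commitment weight 0.2)."""

    codebook_size: int = 128
    codebook_dim: int = 16
    n_down: int = 2
    base_channels: int = 32
    beta: float = 0.2
    lambda_perc: float = 1.0
    lambda_adv: float = 0.5
    disc_warmup_steps: int = 50
    disc_layers: int = 3
    lr: float = 1e-4
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0
    extractor_channels: tuple[int, ...] = (8, 16, 16)
    extractor_seed: int = 1234

    @property
    def downsample_factor(self) -> int:
        return 2**self.n_down

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def desk_vqgan_config(**overrides) -> VQGANConfig:
    """A configuration small enough to train on one CPU in seconds-to-minutes."""
    base = dict(
        codebook_size=32,
        codebook_dim=8,
        base_channels=12,
        epochs=28,
        batch_size=8,
        lr=2e-3,
        lambda_adv=0.05,
        disc_warmup_steps=60,
        disc_layers=2,
        extractor_channels=(6, 12),
    )
    base.update(overrides)
    return VQGANConfig(**base)


class _Encoder(nn.Module):
    def __init__(self, cfg: VQGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.stem = nn.Conv2d(3, c, 3, rng)
        self.downs = []
        ch = c
        for _ in range(cfg.n_down):
            nxt = min(2 * ch, 4 * c)
            self.downs.append(nn.Conv2d(ch, nxt, 3, rng, stride=2))
            self.downs.append(nn.ResidualBlock(nxt, nxt, rng))
            ch = nxt
        self.head = nn.Conv2d(ch, cfg.codebook_dim, 1, rng, padding=0)
        self.out_channels = ch

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.silu(self.stem(x))
        for i in range(0, len(self.downs), 2):
            h = nn.silu(self.downs[i](h))
            h = self.downs[i + 1](h)
        return self.head(h)


class _Decoder(nn.Module):
    def __init__(self, cfg: VQGANConfig, rng: np.random.Generator, top_channels: int):
        c = cfg.base_channels
        self.stem = nn.Conv2d(cfg.codebook_dim, top_channels, 3, rng)
        self.block = nn.ResidualBlock(top_channels, top_channels, rng)
        self.ups = []
        ch = top_channels
        for _ in range(cfg.n_down):
            nxt = max(ch // 2, c)
            self.ups.append(nn.Conv2d(ch, nxt, 3, rng))
            self.ups.append(nn.ResidualBlock(nxt, nxt, rng))
            ch = nxt
        self.head = nn.Conv2d(ch, 3, 3, rng)

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        h = self.block(nn.silu(self.stem(z)))
        for i in range(0, len(self.ups), 2):
            h = nn.upsample_nearest2d(h, 2)
            h = nn.silu(self.ups[i](h))
            h = self.ups[i + 1](h)
        return self.head(h)


class PatchDiscriminator(nn.Module):
    """Strided conv stack emitting one real/fake logit per receptive patch."""

    def __init__(self, cfg: VQGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.convs = []
        ch = 3
        for i in range(cfg.disc_layers):
            nxt = min(c * 2**i, 4 * c)
            self.convs.append(nn.Conv2d(ch, nxt, 4, rng, stride=2, padding=1))
            ch = nxt
        self.head = nn.Conv2d(ch, 1, 3, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for conv in self.convs:
            h = nn.silu(conv(h))
        return self.head(h)


class VQGAN(nn.Module):
    """Encoder + codebook + decoder; numpy-facing API plus tensor training paths."""

    def __init__(self, config: VQGANConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = _Encoder(config, rng)
        self.decoder = _Decoder(config, rng, self.encoder.out_channels)
        self.codebook_vectors = nn.Parameter(
            rng.normal(0.0, 0.5, size=(config.codebook_size, config.codebook_dim))
        )

    # -- numpy-facing API ----------------------------------------------------

    @property
    def codebook(self) -> Codebook:
        return Codebook(self.codebook_vectors.data.copy())

    def encode(self, tile: ImageTile | np.ndarray) -> np.ndarray:
        """Continuous latent grid (h, w, d) of one tile; h = w = size/factor."""
        arr = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
        factor = self.config.downsample_factor
        if arr.shape[0] % factor:
            raise InvalidArgument(
                f"tile size {arr.shape[0]} not divisible by downsample factor {factor}"
            )
        x = nn.Tensor((arr * 2.0 - 1.0).transpose(2, 0, 1)[None])
        z = self.encoder(x)
        return z.data[0].transpose(1, 2, 0)

    def decode(self, q: QuantizedLatent) -> ImageTile:
        """Decode an embedded latent grid back to a [0, 1] tile (clamped)."""
        grid = np.asarray(q.embedded if isinstance(q, QuantizedLatent) else q)
        if grid.ndim != 3 or grid.shape[2] != self.config.codebook_dim:
            raise InvalidArgument(
                f"latent grid must be h x w x {self.config.codebook_dim}, got {grid.shape}"
            )
        z = nn.Tensor(grid.transpose(2, 0, 1)[None])
        out = self.decoder(z).data[0].transpose(1, 2, 0)
        return ImageTile(np.clip((out + 1.0) * 0.5, 0.0, 1.0))

    def reconstruct(self, tile: ImageTile) -> ImageTile:
        return self.decode(quantize(self.encode(tile), self.codebook))

    # -- tensor paths used in training --------------------------------------

    def encode_t(self, x01: np.ndarray) -> nn.Tensor:
        """Encode an (N, H, W, 3) batch in [0, 1]; returns (N, d, h, w)."""
        x = nn.Tensor((x01 * 2.0 - 1.0).transpose(0, 3, 1, 2))
        return self.encoder(x)

    def quantize_st(self, z_e: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, np.ndarray]:
        """Straight-through quantization of an (N, d, h, w) latent batch.

        Returns (z_q with identity gradient to z_e, the gathered codebook
        rows as a differentiable tensor for the codebook loss, and the index
        grid).
        """
        n, d, h, w = z_e.shape
        flat = z_e.data.transpose(0, 2, 3, 1).reshape(-1, d)
        dist = cdist(flat, self.codebook_vectors.data, metric="sqeuclidean")
        idx = np.argmin(dist, axis=1)
        onehot = np.zeros((flat.shape[0], self.config.codebook_size))
        onehot[np.arange(flat.shape[0]), idx] = 1.0
        gathered = nn.Tensor(onehot) @ self.codebook_vectors  # (M, d), grads to codebook
        zq_data = gathered.data.reshape(n, h, w, d).transpose(0, 3, 1, 2)
        z_q = z_e + nn.Tensor(zq_data - z_e.data)  # straight-through estimator
        return z_q, gathered, idx.reshape(n, h, w)

    def decode_t(self, z_q: nn.Tensor) -> nn.Tensor:
        """Decode an (N, d, h, w) latent batch to [0, 1] pixels (N, 3, H, W)."""
        return (self.decoder(z_q) + 1.0) * 0.5


# -- spec-level operations ------------------------------------------------------


def encode(tile: ImageTile, model: VQGAN) -> np.ndarray:
    return model.encode(tile)


def quantize(latent: np.ndarray, codebook: Codebook) -> QuantizedLatent:
    """Snap each latent grid vector to the nearest codebook row (squared
    Euclidean distance; ties break to the lowest index)."""
    grid = np.asarray(latent, dtype=np.float64)
    if grid.ndim != 3:
        raise InvalidArgument("latent must be an h x w x d grid")
    h, w, d = grid.shape
    if d != codebook.dim:
        raise InvalidArgument(f"latent depth {d} != codebook dim {codebook.dim}")
    dist = cdist(grid.reshape(-1, d), codebook.vectors, metric="sqeuclidean")
    idx = np.argmin(dist, axis=1)
    return QuantizedLatent(
        indices=idx.reshape(h, w),
        embedded=codebook.vectors[idx].reshape(h, w, d),
    )


def decode(q: QuantizedLatent, model: VQGAN) -> ImageTile:
    return model.decode(q)


def vqvae_loss(
    x: ImageTile,
    x_hat: ImageTile,
    z_e: np.ndarray,
    q: QuantizedLatent,
    beta: float,
    l_perceptual: float = 0.0,
    l_adv_g: float = 0.0,
    l_adv_d: float = 0.0,
    lambda_perc: float = 0.0,
    lambda_adv: float = 0.0,
) -> VqGanLossReport:
    """Evaluate the autoencoder loss terms for one (input, reconstruction) pair."""
    if not 0.0 <= beta <= 1.0:
        raise InvalidArgument("beta must lie in [0, 1]")
    xp, xh = x.pixels, x_hat.pixels
    if xp.shape != xh.shape:
        raise InvalidArgument("x and x_hat must have identical shapes")
    z = np.asarray(z_e, dtype=np.float64)
    if not (np.isfinite(xp).all() and np.isfinite(xh).all() and np.isfinite(z).all()):
        raise NumericError("non-finite values in loss inputs")
    l_rec = float(np.mean((xp - xh) ** 2))
    l_cb = float(np.mean((q.embedded - z) ** 2))  # gradient side differs, value same
    l_commit = float(np.mean((z - q.embedded) ** 2))
    return VqGanLossReport(
        l_rec=l_rec,
        l_cb=l_cb,
        l_commit=l_commit,
        beta=beta,
        l_perceptual=l_perceptual,
        l_adv_g=l_adv_g,
        l_adv_d=l_adv_d,
        lambda_perc=lambda_perc,
        lambda_adv=lambda_adv,
    )


def patch_discriminate(tile: ImageTile | np.ndarray, disc: PatchDiscriminator) -> np.ndarray:
    """Patch-level logit map for one tile; more than one cell at model sizes."""
    arr = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
    x = nn.Tensor((arr * 2.0 - 1.0).transpose(2, 0, 1)[None])
    return disc(x).data[0, 0]


# -- training -------------------------------------------------------------------


def _hinge_d(real: nn.Tensor, fake: nn.Tensor) -> nn.Tensor:
    return nn.relu(1.0 - real).mean() + nn.relu(1.0 + fake).mean()


def save_checkpoint(path, model: VQGAN, disc, opt_g, opt_d, epoch, rng, history):
    state = {}
    for k, v in model.state_dict().items():
        state[f"model/{k}"] = v
    for k, v in disc.state_dict().items():
        state[f"disc/{k}"] = v
    for i, (m, v) in enumerate(zip(opt_g.m, opt_g.v)):
        state[f"optg_m/{i}"], state[f"optg_v/{i}"] = m, v
    for i, (m, v) in enumerate(zip(opt_d.m, opt_d.v)):
        state[f"optd_m/{i}"], state[f"optd_v/{i}"] = m, v
    state["optg_t"] = np.array(opt_g.t)
    state["optd_t"] = np.array(opt_d.t)
    state["epoch"] = np.array(epoch)
    state["rng_state"] = np.array(json.dumps(rng.bit_generator.state))
    state["config"] = np.array(json.dumps(asdict(model.config), default=list))
    state["history"] = np.array(json.dumps([asdict(h) for h in history]))
    np.savez(path, **state)


def load_vqgan(path) -> VQGAN:
    """Load a trained autoencoder (without optimizer state) from a checkpoint."""
    with np.load(path, allow_pickle=False) as z:
        cfg_raw = json.loads(str(z["config"]))
        cfg_raw["extractor_channels"] = tuple(cfg_raw["extractor_channels"])
        model = VQGAN(VQGANConfig(**cfg_raw))
        model.load_state_dict(
            {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")}
        )
    return model


def train_vqgan(
    dataset: TileDataset,
    config: VQGANConfig | None = None,
    out_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
) -> tuple[VQGAN, PatchDiscriminator, list[VqGanLossReport]]:
    """Train the autoencoder adversarially and return per-epoch mean losses.

    When ``out_dir`` is given a resumable checkpoint is written after every
    epoch; ``resume_from`` restores model, discriminator, optimizer and RNG
    state so training continues as if uninterrupted.
    """
    if config is None:
        config = desk_vqgan_config()
    if len(dataset) == 0:
        raise InvalidArgument("dataset is empty")
    size = dataset[0].size
    if size % config.downsample_factor:
        raise InvalidArgument(
            f"tile size {size} not divisible by downsample factor {config.downsample_factor}"
        )

    model = VQGAN(config)
    rng = np.random.default_rng(config.seed + 1)
    disc = PatchDiscriminator(config, np.random.default_rng(config.seed + 2))
    extractor = RandomConvExtractor(config.extractor_channels, seed=config.extractor_seed)
    opt_g = nn.Adam(model.parameters(), lr=config.lr)
    opt_d = nn.Adam(disc.parameters(), lr=config.lr)
    start_epoch = 0
    history: list[VqGanLossReport] = []

    if resume_from is not None:
        with np.load(resume_from, allow_pickle=False) as z:
            model.load_state_dict(
                {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")}
            )
            disc.load_state_dict(
                {k[len("disc/"):]: z[k] for k in z.files if k.startswith("disc/")}
            )
            for i in range(len(opt_g.m)):
                opt_g.m[i] = z[f"optg_m/{i}"].copy()
                opt_g.v[i] = z[f"optg_v/{i}"].copy()
            for i in range(len(opt_d.m)):
                opt_d.m[i] = z[f"optd_m/{i}"].copy()
                opt_d.v[i] = z[f"optd_v/{i}"].copy()
            opt_g.t = int(z["optg_t"])
            opt_d.t = int(z["optd_t"])
            start_epoch = int(z["epoch"])
            rng.bit_generator.state = json.loads(str(z["rng_state"]))
            history = [VqGanLossReport(**h) for h in json.loads(str(z["history"]))]

    X = dataset.as_array()
    n = len(dataset)
    step = start_epoch * int(np.ceil(n / config.batch_size))

    for epoch in range(start_epoch, config.epochs):
        order = rng.permutation(n)
        acc = {k: 0.0 for k in ("l_rec", "l_cb", "l_commit", "l_perceptual", "l_adv_g", "l_adv_d")}
        n_batches = 0
        for b0 in range(0, n, config.batch_size):
            batch = X[order[b0 : b0 + config.batch_size]]
            adv_on = step >= config.disc_warmup_steps

            # generator/autoencoder step
            opt_g.zero_grad()
            z_e = model.encode_t(batch)
            z_q, gathered, _ = model.quantize_st(z_e)
            x_hat01 = model.decode_t(z_q)
            x01 = nn.Tensor(batch.transpose(0, 3, 1, 2))
            l_rec = ((x_hat01 - x01) ** 2).mean()
            flat = z_e.reshape(z_e.shape[0], z_e.shape[1], -1).transpose(0, 2, 1).reshape(-1, z_e.shape[1])
            l_cb = ((gathered - flat.detach()) ** 2).mean()
            l_commit = ((flat - gathered.detach()) ** 2).mean()
            x_hat_m = x_hat01 * 2.0 - 1.0
            x_m = nn.Tensor(batch.transpose(0, 3, 1, 2) * 2.0 - 1.0)
            l_perc = perceptual_distance_t(x_hat_m, x_m, extractor)
            loss_g = l_rec + l_cb + config.beta * l_commit + config.lambda_perc * l_perc
            l_adv_g_val = 0.0
            if adv_on:
                l_adv_g = -disc(x_hat_m).mean()
                loss_g = loss_g + config.lambda_adv * l_adv_g
                l_adv_g_val = l_adv_g.item()
            if not np.isfinite(loss_g.item()):
                raise NumericError(f"non-finite generator loss at epoch {epoch}")
            loss_g.backward()
            opt_g.step()

            # discriminator step (hinge)
            l_adv_d_val = 0.0
            if adv_on:
                opt_d.zero_grad()
                loss_d = _hinge_d(disc(x_m), disc(nn.Tensor(x_hat_m.data)))
                loss_d.backward()
                opt_d.step()
                l_adv_d_val = loss_d.item()

            acc["l_rec"] += l_rec.item()
            acc["l_cb"] += l_cb.item()
            acc["l_commit"] += l_commit.item()
            acc["l_perceptual"] += l_perc.item()
            acc["l_adv_g"] += l_adv_g_val
            acc["l_adv_d"] += l_adv_d_val
            n_batches += 1
            step += 1

        history.append(
            VqGanLossReport(
                l_rec=acc["l_rec"] / n_batches,
                l_cb=acc["l_cb"] / n_batches,
                l_commit=acc["l_commit"] / n_batches,
                beta=config.beta,
                l_perceptual=acc["l_perceptual"] / n_batches,
                l_adv_g=acc["l_adv_g"] / n_batches,
                l_adv_d=acc["l_adv_d"] / n_batches,
                lambda_perc=config.lambda_perc,
                lambda_adv=config.lambda_adv,
            )
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            save_checkpoint(
                out_dir / "vqgan_checkpoint.npz", model, disc, opt_g, opt_d, epoch + 1, rng, history
            )
            _write_loss_csv(out_dir / "vqgan_losses.csv", history)

    return model, disc, history


def _write_loss_csv(path, history: list[VqGanLossReport]) -> None:
    import pandas as pd

    rows = [
        {
            "epoch": i,
            "l_rec": h.l_rec,
            "l_cb": h.l_cb,
            "l_commit": h.l_commit,
            "l_perceptual": h.l_perceptual,
            "l_adv_g": h.l_adv_g,
            "l_adv_d": h.l_adv_d,
            "total": h.total,
        }
        for i, h in enumerate(history)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
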