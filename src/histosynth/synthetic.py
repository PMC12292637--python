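"""Synthetic H&E-like tile generator with known phenotype classes.

Real H&E tiles show a handful of coarse visual regimes — dense sheets of
hematoxylin-stained nuclei, eosin-pink stroma, voids and lumina, red-blood-
cell lakes, and tissue/background boundaries. The generator emulates those
regimes with a small parametric model so that every downstream stage
(autoencoding, clustering, conditional generation) can be exercised against
ground-truth classes without any external data:

* background is near-white, as in an over-exposed slide scan;
* voids are carved out of the tissue by thresholding a smooth random field;
* nuclei follow a homogeneous spatial Poisson process over the tissue area
  and are rendered as hematoxylin-hued discs;
* stroma is an eosin-hued band-pass texture;
* a fraction of the tissue is recolored as red blood cells.

Everything is deterministic for a fixed (phenotype, size, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import ImageTile, TileDataset
from .errors import InvalidArgument

__all__ = [
    "SyntheticPhenotype",
    "PHENOTYPE_BANK",
    "BACKGROUND_COLOR",
    "generate_tile",
    "generate_dataset",
]

BACKGROUND_COLOR = np.array([0.97, 0.96, 0.97])

_HEMATOXYLIN = (0.36, 0.21, 0.49)  # purple nuclei
_EOSIN = (0.94, 0.55, 0.65)  # pink stroma
_RBC = (0.78, 0.12, 0.15)  # red blood cells


@dataclass(frozen=True)
class SyntheticPhenotype:
    """Parameters of one synthetic tissue class.

    nucleus_density is the expected number of nuclei per pixel of tissue
    area; void_fraction, stroma_intensity and rbc_fraction are in [0, 1].
    """

    name: str
    nucleus_density: float = 0.01
    nucleus_radius_px: float = 2.0
    void_fraction: float = 0.0
    stroma_intensity: float = 0.5
    rbc_fraction: float = 0.0
    hematoxylin_hue: tuple[float, float, float] = _HEMATOXYLIN
    eosin_hue: tuple[float, float, float] = _EOSIN
    rbc_hue: tuple[float, float, float] = _RBC

    def validate(self) -> None:
        for fname in ("void_fraction", "stroma_intensity", "rbc_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgument(f"{fname}={v} outside [0, 1]")
        if self.nucleus_density < 0:
            raise InvalidArgument("nucleus_density must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise InvalidArgument("nucleus_radius_px must be > 0")
        for hue in (self.hematoxylin_hue, self.eosin_hue, self.rbc_hue):
            if len(hue) != 3 or any(not 0.0 <= c <= 1.0 for c in hue):
                raise InvalidArgument(f"hue {hue} must be an RGB triple in [0, 1]")


# Fourteen presets spanning the phenotype regimes an expert distinguishes in
# H&E tiles of pancreatic-tumor-bearing (KPC) mouse tissue: cell density
# extremes, void patterns, red-blood-cell regions, stroma-rich tumor and
# tissue/background boundaries.
PHENOTYPE_BANK: tuple[SyntheticPhenotype, ...] = (
    SyntheticPhenotype("dense-tumor", nucleus_density=0.020, nucleus_radius_px=2.0,
                       void_fraction=0.0, stroma_intensity=0.35),
    SyntheticPhenotype("sparse-tissue", nucleus_density=0.003, nucleus_radius_px=2.0,
                       void_fraction=0.05, stroma_intensity=0.45),
    SyntheticPhenotype("rbc-parenchyma", nucleus_density=0.008, nucleus_radius_px=2.2,
                       void_fraction=0.0, stroma_intensity=0.40, rbc_fraction=0.35),
    SyntheticPhenotype("large-voids", nucleus_density=0.010, nucleus_radius_px=2.0,
                       void_fraction=0.60, stroma_intensity=0.40),
    SyntheticPhenotype("tumor-with-voids", nucleus_density=0.016, nucleus_radius_px=2.0,
                       void_fraction=0.30, stroma_intensity=0.35),
    SyntheticPhenotype("stroma-rich-tumor", nucleus_density=0.011, nucleus_radius_px=2.0,
                       void_fraction=0.05, stroma_intensity=0.95),
    SyntheticPhenotype("empty-space", nucleus_density=0.002, nucleus_radius_px=2.0,
                       void_fraction=0.90, stroma_intensity=0.20),
    SyntheticPhenotype("dense-tissue", nucleus_density=0.026, nucleus_radius_px=1.6,
                       void_fraction=0.0, stroma_intensity=0.50),
    SyntheticPhenotype("small-voids", nucleus_density=0.012, nucleus_radius_px=2.0,
                       void_fraction=0.20, stroma_intensity=0.45),
    SyntheticPhenotype("rbc-boundary", nucleus_density=0.007, nucleus_radius_px=2.0,
                       void_fraction=0.45, stroma_intensity=0.35, rbc_fraction=0.25),
    SyntheticPhenotype("voids-in-tissue", nucleus_density=0.010, nucleus_radius_px=2.0,
                       void_fraction=0.35, stroma_intensity=0.50),
    SyntheticPhenotype("tissue-edge", nucleus_density=0.006, nucleus_radius_px=2.0,
                       void_fraction=0.50, stroma_intensity=0.25),
    SyntheticPhenotype("normal-parenchyma", nucleus_density=0.009, nucleus_radius_px=2.4,
                       void_fraction=0.02, stroma_intensity=0.60),
    SyntheticPhenotype("organ-edge", nucleus_density=0.005, nucleus_radius_px=2.0,
                       void_fraction=0.70, stroma_intensity=0.30, rbc_fraction=0.10),
)


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """A smooth random field in roughly [0, 1], used for masks."""
    f = gaussian_filter(rng.normal(size=(size, size)), sigma=sigma, mode="wrap")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros_like(f)
    return (f - lo) / (hi - lo)


def generate_tile(phenotype: SyntheticPhenotype, size: int, seed: int) -> ImageTile:
    """Render one synthetic H&E-like tile.

    Deterministic for fixed arguments. The expected number of nuclei is
    ``nucleus_density * (1 - void_fraction) * size**2`` (homogeneous Poisson
    over the tissue area); the realized count is stored in
    ``tile.meta["n_nuclei"]``.
    """
    if size < 8:
        raise InvalidArgument(f"size must be >= 8, got {size}")
    phenotype.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, size]))

    img = np.broadcast_to(BACKGROUND_COLOR, (size, size, 3)).copy()
    if phenotype.void_fraction >= 1.0:
        return ImageTile(img, meta={"n_nuclei": 0, "tissue_fraction": 0.0})

    # Tissue mask: carve voids out of a smooth field at the requested quantile.
    if phenotype.void_fraction > 0.0:
        f = _smooth_field(rng, size, sigma=size / 8.0)
        thresh = np.quantile(f, phenotype.void_fraction)
        tissue = f >= thresh
    else:
        _ = _smooth_field(rng, size, sigma=size / 8.0)  # keep the draw order fixed
        tissue = np.ones((size, size), dtype=bool)

    # Stroma: eosin-hued band-pass texture over tissue.
    noise = rng.normal(size=(size, size))
    band = gaussian_filter(noise, sigma=1.0, mode="wrap") - gaussian_filter(
        noise, sigma=3.0, mode="wrap"
    )
    lo, hi = band.min(), band.max()
    band = (band - lo) / (hi - lo) if hi - lo > 1e-12 else np.zeros_like(band)
    eosin = np.asarray(phenotype.eosin_hue)
    mix = phenotype.stroma_intensity * (0.35 + 0.65 * band)
    tissue_color = (1.0 - mix[..., None]) * BACKGROUND_COLOR + mix[..., None] * eosin
    img[tissue] = tissue_color[tissue]

    # Red blood cells: recolor the reddest quantile of a second smooth field,
    # restricted to tissue.
    if phenotype.rbc_fraction > 0.0:
        g = _smooth_field(rng, size, sigma=size / 10.0)
        vals = g[tissue]
        cut = np.quantile(vals, 1.0 - phenotype.rbc_fraction)
        rbc_mask = tissue & (g >= cut)
        shade = 0.85 + 0.15 * band
        img[rbc_mask] = (shade[rbc_mask, None]) * np.asarray(phenotype.rbc_hue)

    # Nuclei: homogeneous Poisson process over the tissue area.
    mean_count = phenotype.nucleus_density * (1.0 - phenotype.void_fraction) * size * size
    n_nuclei = int(rng.poisson(mean_count))
    tissue_idx = np.flatnonzero(tissue.ravel())
    hema = np.asarray(phenotype.hematoxylin_hue)
    r = phenotype.nucleus_radius_px
    ri = int(np.ceil(r))
    if tissue_idx.size:
        centers = tissue_idx[rng.integers(0, tissue_idx.size, size=n_nuclei)]
        jitter = rng.uniform(-0.5, 0.5, size=(n_nuclei, 2))
        shades = rng.uniform(0.8, 1.1, size=n_nuclei)
        for c, (jy, jx), sh in zip(centers, jitter, shades):
            cy, cx = divmod(int(c), size)
            y0, y1 = max(cy - ri, 0), min(cy + ri + 1, size)
            x0, x1 = max(cx - ri, 0), min(cx + ri + 1, size)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - (cy + jy)) ** 2 + (xx - (cx + jx)) ** 2
            disc = d2 <= r * r
            patch = img[y0:y1, x0:x1]
            patch[disc] = np.clip(sh * hema, 0.0, 1.0)
    else:
        n_nuclei = 0

    img = np.clip(img, 0.0, 1.0)
    return ImageTile(
        img,
        meta={"n_nuclei": n_nuclei, "tissue_fraction": float(tissue.mean())},
    )


def generate_dataset(
    n_classes: int,
    n_per_class: int,
    size: int = 32,
    seed: int = 0,
    phenotypes: list[SyntheticPhenotype] | None = None,
    preset_indices: list[int] | None = None,
    split: str = "train",
) -> TileDataset:
    """Generate a class-balanced labeled dataset of synthetic tiles.

    Classes come from ``phenotypes`` if given, else from ``PHENOTYPE_BANK``
    (optionally re-ordered/selected by ``preset_indices``). Tiles are emitted
    class-by-class, so labels read [0,...,0,1,...,1,...].
    """
    if n_classes < 2:
        raise InvalidArgument("n_classes must be >= 2")
    if n_per_class < 1:
        raise InvalidArgument("n_per_class must be >= 1")
    if phenotypes is None:
        bank = list(PHENOTYPE_BANK)
        if preset_indices is not None:
            bank = [PHENOTYPE_BANK[i] for i in preset_indices]
        if n_classes > len(bank):
            raise InvalidArgument(
                f"n_classes={n_classes} exceeds the preset bank ({len(bank)}); "
                "supply custom phenotypes"
            )
        phenotypes = bank[:n_classes]
    elif n_classes > len(phenotypes):
        raise InvalidArgument("n_classes exceeds the supplied phenotype list")

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, n_classes, n_per_class, size])
    tile_seeds = ss.generate_state(n_classes * n_per_class) >> 1  # keep < 2**31
    tiles, ids, labels = [], [], []
    idx = 0
    for cls in range(n_classes):
        for _ in range(n_per_class):
            tiles.append(generate_tile(phenotypes[cls], size, int(tile_seeds[idx])))
            ids.append(f"tile_{idx:05d}")
            labels.append(cls)
            idx += 1
    return TileDataset(tiles=tiles, ids=ids, true_labels=np.array(labels), split=split)
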