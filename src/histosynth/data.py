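"""Core data containers: RGB image tiles and ordered tile datasets.

Tiles are square, channel-last, floating point in [0, 1]. Conversion to the
symmetric [-1, 1] model range happens only at network boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgument

__all__ = ["ImageTile", "TileDataset"]


@dataclass
class ImageTile:
    """A square RGB tile with pixel values in [0, 1].

    ``meta`` carries generator-side ground truth (e.g. the number of nuclei
    actually rendered) used by recovery tests; it is never required.
    """

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidArgument(f"tile must be H x W x 3, got {self.pixels.shape}")
        h, w, _ = self.pixels.shape
        if h != w:
            raise InvalidArgument(f"tile must be square, got {h}x{w}")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InvalidArgument("pixel values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class TileDataset:
    """An ordered collection of tiles with optional integer class labels."""

    tiles: list[ImageTile]
    ids: list[str]
    true_labels: np.ndarray | None = None
    split: str = "train"

    def __post_init__(self):
        if len(self.ids) != len(self.tiles):
            raise InvalidArgument("ids and tiles must have equal length")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
            if len(self.true_labels) != len(self.tiles):
                raise InvalidArgument("true_labels must match the number of tiles")
            if len(self.true_labels) and self.true_labels.min() < 0:
                raise InvalidArgument("labels must be non-negative")

    def __len__(self) -> int:
        return len(self.tiles)

    def __getitem__(self, i: int) -> ImageTile:
        return self.tiles[i]

    def as_array(self) -> np.ndarray:
        """Stack all tiles into an (n, H, W, 3) array."""
        return np.stack([t.pixels for t in self.tiles])

    def subset(self, idx) -> "TileDataset":
        idx = np.asarray(idx)
        return TileDataset(
            tiles=[self.tiles[i] for i in idx],
            ids=[self.ids[i] for i in idx],
            true_labels=None if self.true_labels is None else self.true_labels[idx],
            split=self.split,
        )
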