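"""Reading and writing tile datasets: PNG folders with a CSV label sidecar.

Layout of a dataset directory::

    <dir>/<id>.png      8-bit RGB, one file per tile
    <dir>/labels.csv    optional, header "id,label"; absent => unlabeled
    <dir>/manifest.json optional provenance (split, size, seed, parameters)

Tiles are ordered by lexicographic id on read, so a write→read round trip
preserves ordering. Pixel values survive the round trip up to 8-bit
quantization (max abs error 1/255).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import ImageTile, TileDataset
from .errors import InvalidFormat

__all__ = ["read_tiles", "write_tiles"]


def write_tiles(dataset: TileDataset, path: str | Path, manifest: dict | None = None) -> None:
    """Write a dataset as 8-bit PNGs plus label sidecar and manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for tile, tid in zip(dataset.tiles, dataset.ids):
        arr = np.clip(np.round(tile.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path / f"{tid}.png")
    if dataset.true_labels is not None:
        pd.DataFrame({"id": dataset.ids, "label": dataset.true_labels}).to_csv(
            path / "labels.csv", index=False
        )
    info = {"split": dataset.split, "n": len(dataset)}
    if manifest:
        info.update(manifest)
    (path / "manifest.json").write_text(json.dumps(info, indent=2, sort_keys=True))


def read_tiles(path: str | Path) -> TileDataset:
    """Read a dataset directory written by :func:`write_tiles` (or any PNG folder)."""
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"})
    if not files:
        raise IOError(f"no image files found in {path}")
    tiles, ids = [], []
    for f in files:
        try:
            with Image.open(f) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except Exception as exc:
            raise IOError(f"cannot read image file {f.name}: {exc}") from exc
        if arr.shape[0] != arr.shape[1]:
            raise InvalidFormat(
                f"tile {f.name} is not square: {arr.shape[1]}x{arr.shape[0]}"
            )
        tiles.append(ImageTile(arr))
        ids.append(f.stem)

    labels = None
    label_file = path / "labels.csv"
    if label_file.exists():
        table = pd.read_csv(label_file, dtype={"id": str, "label": np.int64})
        if list(table.columns) != ["id", "label"]:
            raise InvalidFormat("labels.csv must have header 'id,label'")
        mapping = dict(zip(table["id"], table["label"]))
        try:
            labels = np.array([mapping[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise InvalidFormat(f"labels.csv missing id {exc}") from exc

    split = "train"
    manifest_file = path / "manifest.json"
    if manifest_file.exists():
        split = json.loads(manifest_file.read_text()).get("split", "train")
    return TileDataset(tiles=tiles, ids=ids, true_labels=labels, split=split)
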