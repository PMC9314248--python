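"""Tile extraction from slide images with background filtering.

Slides are cut into fixed-size square tiles on a regular grid at each
magnification level. A pixel counts as background when all three RGB
channels are strictly above a brightness threshold (default 220 in 8-bit
space); tiles whose background fraction exceeds the configured maximum are
excluded. Three modes mirror the dataset roles of the original study:

* ``principal``  — 280-px non-overlapping tiles, background cut at > 0.9,
  at most 300 tiles kept per slide (uniform random, seeded);
* ``supplemental`` — 280-px tiles with 50% overlap, background cut at > 0.7,
  no per-slide cap;
* ``utility`` — 224-px non-overlapping tiles, background cut at > 0.7,
  no cap.

Grid coordinates are 0-based with a top-left origin; a tile occupies the
half-open pixel range [origin, origin + tile_size). Partial tiles at the
right/bottom edges are dropped.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mixture.tiler")

__all__ = ["TilingConfig", "Tile", "TileSet", "detect_background",
           "tile_slide", "write_manifest", "read_manifest"]

_MANIFEST_COLS = ["slide_id", "level", "grid_row", "grid_col",
                  "origin_x", "origin_y", "background_fraction", "path"]


@dataclasses.dataclass(frozen=True)
class TilingConfig:
    tile_size: int = 280
    overlap_fraction: float = 0.0
    background_channel_threshold: int = 220
    max_background_fraction: float = 0.9
    max_tiles_per_slide: int | None = 300
    seed: int = 0

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be > 0")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not 0.0 < self.max_background_fraction <= 1.0:
            raise ValueError("max_background_fraction must lie in (0, 1]")

    @property
    def stride(self) -> int:
        return max(1, int(round(self.tile_size * (1.0 - self.overlap_fraction))))

    @classmethod
    def for_mode(cls, mode: str, tile_size: int | None = None, seed: int = 0
                 ) -> "TilingConfig":
        presets = {
            "principal": dict(tile_size=280, overlap_fraction=0.0,
                              max_background_fraction=0.9, max_tiles_per_slide=300),
            "supplemental": dict(tile_size=280, overlap_fraction=0.5,
                                 max_background_fraction=0.7, max_tiles_per_slide=None),
            "utility": dict(tile_size=224, overlap_fraction=0.0,
                            max_background_fraction=0.7, max_tiles_per_slide=None),
        }
        if mode not in presets:
            raise ValueError(f"unknown tiling mode {mode!r}")
        kw = presets[mode]
        if tile_size is not None:
            kw["tile_size"] = tile_size
        return cls(seed=seed, **kw)


@dataclasses.dataclass
class Tile:
    slide_id: str
    level: str
    grid_row: int
    grid_col: int
    origin_x: int
    origin_y: int
    background_fraction: float = 0.0
    image: np.ndarray | None = None   # payload, (ts, ts, 3) uint8
    path: str = ""

    @property
    def key(self) -> tuple:
        return (self.slide_id, self.level, self.grid_row, self.grid_col)


class TileSet:
    """Ordered tile collection sharing one tiling config."""

    def __init__(self, tiles: Sequence[Tile], config: TilingConfig,
                 manifest_path: str | Path | None = None):
        keys = [t.key for t in tiles]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (slide, level, row, col) tile keys")
        self.tiles = list(tiles)
        self.config = config
        self.manifest_path = str(manifest_path) if manifest_path else None

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self) -> Iterator[Tile]:
        return iter(self.tiles)

    def __getitem__(self, i: int) -> Tile:
        return self.tiles[i]

    def images(self) -> np.ndarray:
        """Stack payloads into (n, ts, ts, 3); all tiles must carry images."""
        return np.stack([t.image for t in self.tiles])

    def subset(self, idx: Sequence[int]) -> "TileSet":
        return TileSet([self.tiles[i] for i in idx], self.config)


def detect_background(tile_image: np.ndarray, threshold: int = 220) -> float:
    """Fraction of pixels whose R, G and B are all strictly above threshold."""
    img = np.asarray(tile_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return float(np.all(img > threshold, axis=2).mean())


def tile_slide(slide_image: np.ndarray, slide_id: str, level: str,
               config: TilingConfig) -> TileSet:
    """Cut one slide level into a filtered, optionally capped TileSet."""
    img = np.asarray(slide_image)
    ts = config.tile_size
    h, w = img.shape[:2]
    if h < ts or w < ts:
        logger.warning("slide %s level %s (%dx%d) smaller than tile size %d",
                       slide_id, level, w, h, ts)
        return TileSet([], config)
    stride = config.stride
    tiles = []
    for r, y in enumerate(range(0, h - ts + 1, stride)):
        for c, x in enumerate(range(0, w - ts + 1, stride)):
            patch = img[y:y + ts, x:x + ts]
            bg = detect_background(patch, config.background_channel_threshold)
            if bg > config.max_background_fraction:
                continue
            tiles.append(Tile(slide_id=slide_id, level=level, grid_row=r,
                              grid_col=c, origin_x=x, origin_y=y,
                              background_fraction=bg, image=patch))
    cap = config.max_tiles_per_slide
    if cap is not None and len(tiles) > cap:
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, hash(slide_id) & 0xFFFF])
        keep = np.sort(rng.choice(len(tiles), size=cap, replace=False))
        tiles = [tiles[i] for i in keep]
    return TileSet(tiles, config)


def write_manifest(tileset: TileSet, path: str | Path) -> Path:
    """TSV manifest: one row per tile plus a config header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = tileset.config
    header = ("#config\ttile_size=%d\toverlap_fraction=%g\t"
              "background_channel_threshold=%d\tmax_background_fraction=%g\t"
              "max_tiles_per_slide=%s\tseed=%d\n" % (
                  cfg.tile_size, cfg.overlap_fraction,
                  cfg.background_channel_threshold, cfg.max_background_fraction,
                  cfg.max_tiles_per_slide, cfg.seed))
    df = pd.DataFrame([{**{k: getattr(t, k) for k in _MANIFEST_COLS[:-1]},
                        "path": t.path} for t in tileset.tiles],
                      columns=_MANIFEST_COLS)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    tileset.manifest_path = str(path)
    return path


def read_manifest(path: str | Path) -> TileSet:
    """Inverse of :func:`write_manifest`; images are not loaded."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#config"):
            raise ValueError(f"{path}: missing #config header line")
        kv = dict(item.split("=", 1) for item in header.strip().split("\t")[1:])
        cfg = TilingConfig(
            tile_size=int(kv["tile_size"]),
            overlap_fraction=float(kv["overlap_fraction"]),
            background_channel_threshold=int(kv["background_channel_threshold"]),
            max_background_fraction=float(kv["max_background_fraction"]),
            max_tiles_per_slide=(None if kv["max_tiles_per_slide"] == "None"
                                 else int(kv["max_tiles_per_slide"])),
            seed=int(kv["seed"]))
        df = pd.read_csv(fh, sep="\t", dtype={"slide_id": str, "level": str,
                                              "path": str}, keep_default_na=False)
    tiles = []
    for i, row in df.iterrows():
        try:
            tiles.append(Tile(slide_id=row["slide_id"], level=row["level"],
                              grid_row=int(row["grid_row"]), grid_col=int(row["grid_col"]),
                              origin_x=int(row["origin_x"]), origin_y=int(row["origin_y"]),
                              background_fraction=float(row["background_fraction"]),
                              path=row["path"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed manifest row {i}: {exc}") from exc
    try:
        return TileSet(tiles, cfg, manifest_path=path)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
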