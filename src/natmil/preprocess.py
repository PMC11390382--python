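"""Tissue segmentation and fixed-size grid tiling of slide rasters.

Segmentation recipe (the standard WSI pipeline): saturation channel in
HSV, Otsu threshold, median filter, morphological closing, and an area
floor that drops specks smaller than a few tile footprints. Tiling cuts
the raster into non-overlapping ``tile_px`` squares on a top-left
anchored grid (trailing partial strips dropped) and keeps tiles whose
tissue coverage clears ``min_tissue_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color, filters, morphology
from skimage.transform import downscale_local_mean

__all__ = [
    "TissueMask", "TileRecord", "TileManifest",
    "segment_tissue", "tile_slide", "materialize_tiles",
]


@dataclass
class TissueMask:
    mask: np.ndarray           # bool, slide dims / downsample_factor
    downsample_factor: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    def tissue_fraction(self) -> float:
        return float(self.mask.mean())

    def at_full_resolution(self, shape) -> np.ndarray:
        """Nearest-neighbour upsample cropped/padded to `shape` (H, W)."""
        f = self.downsample_factor
        up = np.repeat(np.repeat(self.mask, f, axis=0), f, axis=1)
        out = np.zeros(shape, dtype=bool)
        h = min(shape[0], up.shape[0])
        w = min(shape[1], up.shape[1])
        out[:h, :w] = up[:h, :w]
        return out


@dataclass
class TileRecord:
    x: int       # pixel origin, column
    y: int       # pixel origin, row
    row: int     # grid row = y // tile_px
    col: int     # grid col = x // tile_px
    tissue_fraction: float


@dataclass
class TileManifest:
    slide_id: str
    tile_px: int
    records: list

    def __post_init__(self):
        cells = [(r.row, r.col) for r in self.records]
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate grid cells in manifest")
        for r in self.records:
            if r.x % self.tile_px or r.y % self.tile_px:
                raise ValueError("tile origins must be multiples of tile_px")
            if (r.row, r.col) != (r.y // self.tile_px, r.x // self.tile_px):
                raise ValueError("grid coordinates inconsistent with origins")

    def __len__(self):
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "slide_id": self.slide_id, "x": r.x, "y": r.y,
            "row": r.row, "col": r.col, "tissue_fraction": r.tissue_fraction,
        } for r in self.records])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tile_px: int | None = None) -> "TileManifest":
        df = pd.read_csv(path)
        if len(df) == 0:
            raise ValueError("empty manifest CSV")
        slide_id = str(df["slide_id"].iloc[0])
        if tile_px is None:
            nz = df[(df.col > 0) | (df.row > 0)]
            if len(nz):
                r0 = nz.iloc[0]
                tile_px = int(r0.x // r0.col) if r0.col > 0 else int(r0.y // r0.row)
            else:
                tile_px = 256
        recs = [TileRecord(int(r.x), int(r.y), int(r.row), int(r.col),
                           float(r.tissue_fraction)) for r in df.itertuples()]
        return cls(slide_id=slide_id, tile_px=tile_px, records=recs)


def segment_tissue(image: np.ndarray, downsample_factor: int = 1,
                   tile_px: int | None = None,
                   min_area: int | None = None) -> TissueMask:
    """Otsu-on-saturation tissue mask at a stated downsample.

    ``min_area`` defaults to four tile footprints when ``tile_px`` is
    given, else 64 mask pixels. A (near-)uniform image yields an empty
    mask rather than an error.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.dtype != np.float64:
        image = image.astype(np.float64) / 255.0
    f = max(1, int(downsample_factor))
    small = downscale_local_mean(image, (f, f, 1)) if f > 1 else image
    sat = color.rgb2hsv(np.clip(small, 0, 1))[..., 1]
    if float(sat.max() - sat.min()) < 0.05:
        return TissueMask(np.zeros(sat.shape, dtype=bool), f)
    thresh = filters.threshold_otsu(sat)
    mask = sat > thresh
    mask = filters.median(mask, footprint=np.ones((3, 3), dtype=bool))
    mask = morphology.closing(mask, footprint=morphology.disk(2)).astype(bool)
    if min_area is None:
        min_area = 4 * (tile_px // f) ** 2 if tile_px else 64
    mask = morphology.remove_small_objects(mask, max_size=max(0, min_area - 1))
    return TissueMask(mask, f)


def tile_slide(image: np.ndarray, mask: TissueMask, tile_px: int,
               min_tissue_fraction: float = 0.5,
               slide_id: str = "slide") -> TileManifest:
    """Non-overlapping grid tiling over the tissue mask."""
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    gh, gw = h // tile_px, w // tile_px
    full = mask.at_full_resolution((gh * tile_px, gw * tile_px))
    records = []
    if gh and gw:
        frac = full.reshape(gh, tile_px, gw, tile_px).mean(axis=(1, 3))
        for row in range(gh):
            for col in range(gw):
                if frac[row, col] >= min_tissue_fraction:
                    records.append(TileRecord(x=col * tile_px, y=row * tile_px,
                                              row=row, col=col,
                                              tissue_fraction=float(frac[row, col])))
    return TileManifest(slide_id=slide_id, tile_px=tile_px, records=records)


def materialize_tiles(image: np.ndarray, manifest: TileManifest, out_dir):
    """Write each manifest tile as {slide_id}_{row}_{col}.png."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tp = manifest.tile_px
    paths = []
    for r in manifest.records:
        tile = np.asarray(image)[r.y:r.y + tp, r.x:r.x + tp]
        p = out_dir / f"{manifest.slide_id}_{r.row}_{r.col}.png"
        Image.fromarray(tile.astype(np.uint8)).save(p)
        paths.append(p)
    return paths
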