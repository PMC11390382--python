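"""Seeded synthetic slides and feature bags with tile-level ground truth.

Two generators:

* :func:`generate_slide` paints an RGB slide raster on a tile grid —
  near-white background, a connected tissue region, and tumor blobs
  grown by random-walk region growing until exactly ⌊f·n⌋ tiles are
  tumor. Tumor tiles carry a sinusoidal luminance motif with a
  configurable period (default eight tiles).
* :func:`generate_feature_bags` skips images entirely and emits MIL
  feature bags: normal tiles from N(0, I), tumor tiles shifted by a
  fixed vector of length ``class_separation``. With ``cluster=True``
  positive bags hold one contiguous tumor region while negative bags
  (by default) hold the same number of tumor-like *distractor* tiles
  scattered as singletons — so bag-level signal lives in the spatial
  arrangement, emulating the isolated false-positive tiles that defeat
  tile-independent models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bags import FeatureBag

__all__ = [
    "SyntheticSlideSpec", "SyntheticSlide", "SyntheticBagSpec",
    "generate_slide", "generate_feature_bags",
]

_STEPS4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class SyntheticSlideSpec:
    grid_height: int
    grid_width: int
    tile_px: int = 16
    tumor_fraction: float = 0.05
    blob_count: int = 1
    motif_period: float = 8.0
    noise_sd: float = 3.0
    seed: int = 0
    tissue_fraction: float = 0.7  # target tissue coverage (tiles), grown if tumor needs more


@dataclass
class SyntheticSlide:
    image: np.ndarray        # uint8, (gh·tile_px, gw·tile_px, 3)
    tile_labels: np.ndarray  # int, (gh, gw)
    slide_label: int
    tissue_tiles: np.ndarray  # bool, (gh, gw): the painted tissue area
    spec: SyntheticSlideSpec


def _grow_region(rng: np.random.Generator, allowed: np.ndarray,
                 seeds, target: int) -> np.ndarray:
    """Random-walk region growing: connected, irregular, exact size
    (unless the allowed area is exhausted)."""
    h, w = allowed.shape
    region = np.zeros((h, w), dtype=bool)
    frontier: list = []
    queued = np.zeros((h, w), dtype=bool)
    count = 0

    def absorb(r, c):
        nonlocal count
        region[r, c] = True
        count += 1
        for dr, dc in _STEPS4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and allowed[rr, cc] \
                    and not region[rr, cc] and not queued[rr, cc]:
                frontier.append((rr, cc))
                queued[rr, cc] = True

    for r, c in seeds:
        if count >= target:
            break
        if allowed[r, c] and not region[r, c]:
            absorb(r, c)
    while count < target and frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier.pop(i)
        queued[r, c] = False
        if not region[r, c]:
            absorb(r, c)
    return region


def _spread_seeds(rng: np.random.Generator, allowed: np.ndarray, count: int):
    """Pick `count` cells in `allowed`, rejection-sampling for spread."""
    cells = np.argwhere(allowed)
    if len(cells) < count:
        raise ValueError("not enough allowed cells for the requested blobs")
    best, best_score = None, -1.0
    for _ in range(64):
        pick = cells[rng.choice(len(cells), size=count, replace=False)]
        if count == 1:
            return [tuple(pick[0])]
        d = np.abs(pick[:, None, :] - pick[None, :, :]).max(axis=2).astype(float)
        np.fill_diagonal(d, np.inf)
        score = d.min()
        if score > best_score:
            best, best_score = pick, score
    return [tuple(p) for p in best]


def generate_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    gh, gw, tp = spec.grid_height, spec.grid_width, spec.tile_px
    if gh < 4 or gw < 4:
        raise ValueError("grid dims must be >= 4")
    if tp < 8:
        raise ValueError("tile_px must be >= 8")
    if not 0.0 <= spec.tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if spec.tumor_fraction > 0 and spec.blob_count == 0:
        raise ValueError("tumor_fraction > 0 requires blob_count >= 1")
    rng = np.random.default_rng(spec.seed)
    n = gh * gw
    tumor_target = int(np.floor(spec.tumor_fraction * n))

    tissue_target = min(n, max(int(round(spec.tissue_fraction * n)), tumor_target + 4))
    if tumor_target >= n:
        tissue_target = n
    center = (gh // 2, gw // 2)
    tissue = _grow_region(rng, np.ones((gh, gw), dtype=bool), [center], tissue_target)

    labels = np.zeros((gh, gw), dtype=np.int64)
    if tumor_target > 0:
        seeds = _spread_seeds(rng, tissue, min(spec.blob_count, tissue.sum()))
        tumor = np.zeros((gh, gw), dtype=bool)
        per_blob = np.full(len(seeds), tumor_target // len(seeds))
        per_blob[: tumor_target % len(seeds)] += 1
        for s, tgt in zip(seeds, per_blob):
            # keep this blob off cells bordering already-painted blobs so
            # components stay separate when geometry permits
            buffer = ndimage.binary_dilation(tumor, structure=np.ones((3, 3)))
            allowed = tissue & ~buffer
            blob = _grow_region(rng, allowed, [s], int(tgt))
            tumor |= blob
        deficit = tumor_target - int(tumor.sum())
        if deficit > 0:  # geometry blocked a blob; top up from existing tumor
            extra = _grow_region(rng, tissue, [tuple(c) for c in np.argwhere(tumor)],
                                 tumor_target)
            tumor = extra
        labels[tumor] = 1

    image = _render(rng, spec, tissue, labels)
    return SyntheticSlide(image=image, tile_labels=labels,
                          slide_label=int(labels.any()),
                          tissue_tiles=tissue, spec=spec)


def _render(rng, spec, tissue, labels):
    gh, gw, tp = spec.grid_height, spec.grid_width, spec.tile_px
    base = np.full((gh, gw, 3), 245.0)
    base[tissue] = (205.0, 160.0, 185.0)
    base[labels == 1] = (150.0, 105.0, 140.0)
    # periodic luminance motif on tumor tiles (detectable texture trend)
    cols = np.arange(gw)[None, :]
    motif = 25.0 * np.sin(2.0 * np.pi * cols / spec.motif_period)
    base[labels == 1] += np.repeat(motif, gh, axis=0)[labels == 1][:, None]
    img = np.repeat(np.repeat(base, tp, axis=0), tp, axis=1)
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class SyntheticBagSpec:
    n_bags: int
    grid_height: int = 16
    grid_width: int = 16
    d: int = 32
    positive_fraction: float = 0.5
    tumor_fraction: float = 0.05
    cluster: bool = True
    class_separation: float = 4.0
    seed: int = 0
    hard_negatives: bool | None = None  # default: follow `cluster`

    @property
    def hard(self) -> bool:
        return self.cluster if self.hard_negatives is None else self.hard_negatives


def generate_feature_bags(spec: SyntheticBagSpec):
    """Deterministic list of FeatureBags; exactly
    round(positive_fraction · n_bags) bags carry label 1."""
    if spec.n_bags < 2:
        raise ValueError("need n_bags >= 2 to form both classes")
    if spec.d < 2:
        raise ValueError("d must be >= 2")
    if not 0.0 < spec.positive_fraction < 1.0:
        raise ValueError("positive_fraction must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    gh, gw = spec.grid_height, spec.grid_width
    n = gh * gw
    rows, cols = np.divmod(np.arange(n), gw)
    direction = rng.normal(size=spec.d)
    direction /= np.linalg.norm(direction)
    shift = spec.class_separation * direction
    n_pos = int(round(spec.positive_fraction * spec.n_bags))
    tumor_count = max(1, int(np.floor(spec.tumor_fraction * n)))

    bags = []
    for b in range(spec.n_bags):
        positive = b < n_pos
        H = rng.normal(size=(n, spec.d))
        tile_labels = np.zeros(n, dtype=np.int64)
        if positive:
            if spec.cluster:
                seed_cell = (int(rng.integers(gh)), int(rng.integers(gw)))
                region = _grow_region(rng, np.ones((gh, gw), dtype=bool),
                                      [seed_cell], tumor_count)
                idx = np.flatnonzero(region.ravel())
            else:
                idx = rng.choice(n, size=tumor_count, replace=False)
            H[idx] += shift
            tile_labels[idx] = 1
        elif spec.hard:
            # tumor-like distractors, scattered: same marginal tile
            # distribution as a positive bag, different arrangement
            idx = rng.choice(n, size=tumor_count, replace=False)
            H[idx] += shift
        bags.append(FeatureBag(slide_id=f"bag_{b:04d}", H=H, rows=rows,
                               cols=cols, label=int(positive),
                               tile_labels=tile_labels))
    order = rng.permutation(spec.n_bags)
    return [bags[i] for i in order]
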