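"""Two-view contrastive tile embeddings (SimCLR-style).

A small residual convolutional encoder (depth-scalable; the reference
configuration is a ResNet-style stack, the test configuration a toy
three-stage net) is trained with the normalized temperature-scaled
cross-entropy (NT-Xent) loss over augmented view pairs, then frozen to
export per-tile feature vectors as a slide's :class:`FeatureBag`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from ._nn import AdamW, Conv2d, Linear, Module, cosine_schedule
from ._tensor import Tensor, as_tensor, use_dtype
from .bags import FeatureBag

__all__ = [
    "AugmentStrengths", "AugmentedPair", "SimclrConfig", "ConvEncoder",
    "ProjectionHead", "augment", "nt_xent_loss", "train_encoder",
    "extract_features", "save_checkpoint", "load_checkpoint",
]


@dataclass
class AugmentStrengths:
    crop_scale: tuple = (0.6, 1.0)  # area fraction of the random resized crop
    flip_p: float = 0.5
    jitter: float = 0.4             # max relative brightness/contrast/saturation shift
    blur_sigma: tuple = (0.1, 1.2)
    blur_p: float = 0.5

    @classmethod
    def zero(cls) -> "AugmentStrengths":
        return cls(crop_scale=(1.0, 1.0), flip_p=0.0, jitter=0.0,
                   blur_sigma=(0.0, 0.0), blur_p=0.0)


@dataclass
class AugmentedPair:
    view_a: np.ndarray
    view_b: np.ndarray


def _one_view(tile: np.ndarray, rng: np.random.Generator,
              s: AugmentStrengths) -> np.ndarray:
    h, w = tile.shape[:2]
    out = tile.copy()
    # random resized crop (kept square)
    scale = rng.uniform(*s.crop_scale)
    side = max(1, int(round(h * np.sqrt(scale))))
    if side < h:
        r0 = int(rng.integers(h - side + 1))
        c0 = int(rng.integers(w - side + 1))
        out = resize(out[r0:r0 + side, c0:c0 + side], (h, w), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    # flips
    if s.flip_p > 0:
        if rng.random() < s.flip_p:
            out = out[:, ::-1]
        if rng.random() < s.flip_p:
            out = out[::-1, :]
    # colour jitter: brightness, contrast, saturation
    if s.jitter > 0:
        b, c, st = 1.0 + rng.uniform(-s.jitter, s.jitter, size=3)
        out = out * b
        mean = out.mean()
        out = mean + c * (out - mean)
        gray = out.mean(axis=2, keepdims=True)
        out = gray + st * (out - gray)
    # gaussian blur
    if s.blur_p > 0 and rng.random() < s.blur_p:
        sigma = rng.uniform(*s.blur_sigma)
        if sigma > 0:
            out = gaussian_filter(out, sigma=(sigma, sigma, 0))
    return np.ascontiguousarray(np.clip(out, 0.0, 1.0))


def augment(tile: np.ndarray, seed: int,
            strengths: AugmentStrengths | None = None) -> AugmentedPair:
    """Two independently sampled augmentations of one square tile
    (values in [0, 1]); deterministic per seed."""
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 3 or tile.shape[0] != tile.shape[1]:
        raise ValueError("tile must be a square H×H×C array")
    if tile.max() > 1.0 + 1e-9:
        tile = tile / 255.0
    s = strengths if strengths is not None else AugmentStrengths()
    rng = np.random.default_rng(seed)
    return AugmentedPair(_one_view(tile, rng, s), _one_view(tile, rng, s))


def nt_xent_loss(Z, tau: float) -> Tensor:
    """NT-Xent over 2N unit-norm projections where rows (2m, 2m+1) are
    positive pairs: mean over anchors of −log softmax similarity to the
    partner, the anchor itself excluded from the denominator."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    Z = as_tensor(Z)
    m = Z.shape[0]
    if m < 4 or m % 2:
        raise ValueError("need an even batch of at least two pairs")
    sim = (Z @ Z.transpose(1, 0)) * float(1.0 / tau)
    sim = sim + np.diag(np.full(m, -1e9))  # exclude self-similarity
    logp = sim.log_softmax(axis=1)
    pos = np.arange(m) ^ 1
    return -logp[(np.arange(m), pos)].mean()


class _ResBlock(Module):
    def __init__(self, width: int, rng):
        self.conv1 = Conv2d(width, width, 3, 1, 1, rng)
        self.conv2 = Conv2d(width, width, 3, 1, 1, rng)

    def __call__(self, x):
        return x + self.conv2(self.conv1(x).gelu())


class ConvEncoder(Module):
    """Residual convolutional encoder: stride-2 stem, stride-2 stage
    transitions with widening, residual blocks per stage, global average
    pool, and a linear feature head of width ``d_out``."""

    def __init__(self, d_out: int, widths=(8, 16, 32), blocks_per_stage: int = 1,
                 in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_out = d_out
        self.stem = Conv2d(in_channels, widths[0], 3, 2, 1, rng)
        self.stages = []
        prev = widths[0]
        for i, wd in enumerate(widths):
            stage = []
            if i > 0:
                stage.append(Conv2d(prev, wd, 3, 2, 1, rng))
            stage.extend(_ResBlock(wd, rng) for _ in range(blocks_per_stage))
            self.stages.append(stage)
            prev = wd
        self.head = Linear(prev, d_out, rng, sd=float(np.sqrt(2.0 / prev)))

    def features(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) in [0, 1] -> (B, d_out)."""
        y = self.stem(x).gelu()
        for stage in self.stages:
            for layer in stage:
                y = layer(y)
                if isinstance(layer, Conv2d):
                    y = y.gelu()
        pooled = y.mean(axis=(1, 2))
        return self.head(pooled)

    def trainable_parameters(self, freeze_up_to: int | None = None):
        """Parameters excluding stages < ``freeze_up_to`` (and the stem
        when any stage is frozen) — the fine-tune-only-the-top regime."""
        if freeze_up_to is None:
            return self.parameters()
        out = []
        for stage in self.stages[freeze_up_to:]:
            for layer in stage:
                out.extend(layer.parameters())
        out.extend(self.head.parameters())
        return out


class ProjectionHead(Module):
    """Two hidden layers then the projection output."""

    def __init__(self, d_in: int, hidden: int, d_proj: int, seed: int = 0):
        rng = np.random.default_rng(seed + 17)
        self.fc1 = Linear(d_in, hidden, rng, sd=float(np.sqrt(2.0 / d_in)))
        self.fc2 = Linear(hidden, hidden, rng, sd=float(np.sqrt(2.0 / hidden)))
        self.fc3 = Linear(hidden, d_proj, rng, sd=float(np.sqrt(2.0 / hidden)))

    def __call__(self, x: Tensor) -> Tensor:
        z = self.fc3(self.fc2(self.fc1(x).gelu()).gelu())
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        return z / norm


@dataclass
class SimclrConfig:
    d: int = 32                 # feature width (1024 in the reference setup)
    proj_hidden: int = 64
    proj_dim: int = 32
    tau: float = 0.5
    widths: tuple = (8, 16, 32)
    blocks_per_stage: int = 1
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    warmup_frac: float = 0.1
    seed: int = 0
    dtype: str = "float32"
    freeze_up_to: int | None = None  # freeze stages below this index
    strengths: AugmentStrengths = field(default_factory=AugmentStrengths)


def train_encoder(tiles: np.ndarray, config: SimclrConfig):
    """Contrastive pretraining on a stack of square tiles (n, H, W, C).

    Returns (encoder, projection_head, history) where history holds the
    per-epoch mean NT-Xent loss. Deterministic for a fixed config."""
    tiles = np.asarray(tiles, dtype=np.float64)
    if tiles.max() > 1.0 + 1e-9:
        tiles = tiles / 255.0
    n = len(tiles)
    if config.batch_size < 2:
        raise ValueError("batch size must be >= 2")
    if n < 2:
        raise ValueError("need at least two tiles")
    rng = np.random.default_rng(config.seed)
    with use_dtype(config.dtype):
        encoder = ConvEncoder(config.d, config.widths, config.blocks_per_stage,
                              tiles.shape[3], seed=config.seed)
        head = ProjectionHead(config.d, config.proj_hidden, config.proj_dim,
                              seed=config.seed)
        params = encoder.trainable_parameters(config.freeze_up_to) + head.parameters()
        opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
        steps_per_epoch = max(1, n // config.batch_size)
        total = config.epochs * steps_per_epoch
        history, step = [], 0
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            losses = []
            for b in range(steps_per_epoch):
                idx = order[b * config.batch_size:(b + 1) * config.batch_size]
                if len(idx) < 2:
                    continue
                views = []
                for i in idx:
                    pair = augment(tiles[i], seed=int(rng.integers(2 ** 31)),
                                   strengths=config.strengths)
                    views.extend((pair.view_a, pair.view_b))
                x = Tensor(np.stack(views))
                z = head(encoder.features(x))
                loss = nt_xent_loss(z, config.tau)
                opt.zero_grad()
                loss.backward()
                opt.step(lr=cosine_schedule(step, total, config.lr, config.warmup_frac))
                losses.append(float(loss.data))
                step += 1
            history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return encoder, head, history


def extract_features(encoder: ConvEncoder, manifest, tiles: np.ndarray,
                     label: int = 0, batch_size: int = 64) -> FeatureBag:
    """Embed a slide's tiles; ``tiles[i]`` matches ``manifest.records[i]``.
    Rows of H follow (grid_row, grid_col) order."""
    if len(manifest.records) == 0:
        raise ValueError("empty manifest")
    tiles = np.asarray(tiles, dtype=np.float64)
    if tiles.max() > 1.0 + 1e-9:
        tiles = tiles / 255.0
    if len(tiles) != len(manifest.records):
        raise ValueError("tiles must align with manifest records")
    order = np.lexsort(([r.col for r in manifest.records],
                        [r.row for r in manifest.records]))
    feats = []
    for lo in range(0, len(order), batch_size):
        batch = tiles[order[lo:lo + batch_size]]
        feats.append(encoder.features(Tensor(batch)).data)
    H = np.concatenate(feats, axis=0)
    rows = np.asarray([manifest.records[i].row for i in order])
    cols = np.asarray([manifest.records[i].col for i in order])
    return FeatureBag(slide_id=manifest.slide_id, H=H, rows=rows, cols=cols,
                      label=int(label))


def save_checkpoint(path, module: Module, meta: dict | None = None):
    """Parameter archive (.npz) with a JSON sidecar."""
    path = Path(path)
    state = module.state_dict()
    np.savez(path, **state)
    sidecar = dict(meta or {})
    sidecar["n_parameters"] = int(sum(v.size for v in state.values()))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path, module: Module):
    archive = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
    module.load_state_dict({k: archive[k] for k in archive.files})
    return module
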