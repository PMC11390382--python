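"""End-to-end MIL training, evaluation, and the k-sweep / mixer-ablation
experiment harnesses."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import AdamW, cosine_schedule, cross_entropy
from ._tensor import Tensor, use_dtype
from .backbone import MIXERS, _GridCtx
from .bags import FeatureBag
from .metrics import MetricReport, compute_metrics
from .mil import BaselineMilModel, NatMilModel

__all__ = [
    "MilTrainConfig", "TrainResult", "config_hash", "stratified_split",
    "train_natmil", "train_baseline", "evaluate_model", "predict_bags",
    "k_sweep", "ablation_attention_type",
]


@dataclass
class MilTrainConfig:
    dim: int = 32
    depth: int = 1
    heads: int = 2
    k: int = 9
    mlp_ratio: float = 2.0
    layer_scale_init: float = 0.1
    gate_hidden: int = 64
    mixer: str = "neighborhood"
    residual_raw: bool = True
    gate_input: str = "context"
    n_classes: int = 2
    epochs: int = 15
    batch_size: int = 16
    lr: float = 5e-3
    weight_decay: float = 1e-4
    warmup_frac: float = 0.1
    val_frac: float = 0.15
    test_frac: float = 0.15
    patience: int = 10
    seed: int = 0
    dtype: str = "float32"  # training dtype; operators stay float64 elsewhere


@dataclass
class TrainResult:
    model: object
    report: MetricReport
    val_report: MetricReport
    history: list
    splits: dict
    config_hash: str


def config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg) if not isinstance(cfg, dict) else cfg,
                      sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def stratified_split(labels, val_frac: float, test_frac: float,
                     rng: np.random.Generator):
    """Per-class shuffled index split into train/val/test."""
    labels = np.asarray(labels)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_test = int(round(test_frac * n))
        n_val = int(round(val_frac * n))
        test.extend(idx[:n_test])
        val.extend(idx[n_test:n_test + n_val])
        train.extend(idx[n_test + n_val:])
    out = {k: np.sort(np.asarray(v, dtype=np.int64))
           for k, v in (("train", train), ("val", val), ("test", test))}
    if len(np.unique(labels[out["train"]])) < 2:
        raise ValueError("a class is missing from the training split")
    return out


def _stack_bags(bags):
    """Bags sharing one grid/validity layout -> (ctx, X (B,n,d), labels)."""
    sorted_bags = [b.sorted_by_grid() for b in bags]
    first = sorted_bags[0]
    gh = max(b.rows.max() for b in sorted_bags) + 1
    gw = max(b.cols.max() for b in sorted_bags) + 1
    key0 = (tuple(first.rows.tolist()), tuple(first.cols.tolist()))
    for b in sorted_bags[1:]:
        if (tuple(b.rows.tolist()), tuple(b.cols.tolist())) != key0:
            raise ValueError("bags must share one tile-grid layout to be stacked")
    valid = np.zeros((gh, gw), dtype=bool)
    valid[first.rows, first.cols] = True
    ctx = _GridCtx(int(gh), int(gw), valid)
    X = np.stack([b.H for b in sorted_bags])
    y = np.asarray([b.label for b in sorted_bags], dtype=np.int64)
    return ctx, X, y


def _scores(model, ctx, X, batch_size=32):
    probs = []
    for lo in range(0, len(X), batch_size):
        logits, _, _ = model.forward(Tensor(X[lo:lo + batch_size]), ctx)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append((e / e.sum(axis=1, keepdims=True))[:, 1])
    return np.concatenate(probs)


def _fit(model, ctx, X, y, splits, cfg: MilTrainConfig):
    rng = np.random.default_rng(cfg.seed + 1)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    tr = splits["train"]
    steps_per_epoch = max(1, int(np.ceil(len(tr) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    history, best = [], (-np.inf, None, 0)
    step = 0
    for epoch in range(cfg.epochs):
        order = tr[rng.permutation(len(tr))]
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits, _, _ = model.forward(Tensor(X[idx]), ctx)
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr=cosine_schedule(step, total_steps, cfg.lr, cfg.warmup_frac))
            losses.append(float(loss.data))
            step += 1
        val_idx = splits["val"] if len(splits["val"]) else tr
        val_report = compute_metrics(y[val_idx], _scores(model, ctx, X[val_idx]))
        val_auc = val_report.auc if val_report.auc is not None else val_report.acc
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_auc": val_auc, "val_acc": val_report.acc})
        if val_auc > best[0] + 1e-12:
            best = (val_auc, model.state_dict(), epoch)
        elif epoch - best[2] >= cfg.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    return history


def train_natmil(bags, cfg: MilTrainConfig, splits=None) -> TrainResult:
    """Train the neighborhood-context MIL model on feature bags and
    report metrics on the held-out test split."""
    if len(bags) < 4:
        raise ValueError("need at least 4 bags")
    ctx, X, y = _stack_bags(bags)
    if splits is None:
        splits = stratified_split(y, cfg.val_frac, cfg.test_frac,
                                  np.random.default_rng(cfg.seed))
    with use_dtype(cfg.dtype):
        model = NatMilModel(d_in=X.shape[2], dim=cfg.dim, n_classes=cfg.n_classes,
                            depth=cfg.depth, heads=cfg.heads, k=cfg.k,
                            mlp_ratio=cfg.mlp_ratio,
                            layer_scale_init=cfg.layer_scale_init,
                            gate_hidden=cfg.gate_hidden, mixer=cfg.mixer,
                            residual_raw=cfg.residual_raw,
                            gate_input=cfg.gate_input, seed=cfg.seed)
        return _finish(model, ctx, X, y, splits, cfg)


def train_baseline(bags, mode: str, cfg: MilTrainConfig, splits=None) -> TrainResult:
    """Train a context-free pooling baseline under the same protocol."""
    ctx, X, y = _stack_bags(bags)
    if splits is None:
        splits = stratified_split(y, cfg.val_frac, cfg.test_frac,
                                  np.random.default_rng(cfg.seed))
    with use_dtype(cfg.dtype):
        model = BaselineMilModel(d_in=X.shape[2], dim=cfg.dim, mode=mode,
                                 n_classes=cfg.n_classes,
                                 gate_hidden=cfg.gate_hidden, seed=cfg.seed)
        return _finish(model, ctx, X, y, splits, cfg)


def _finish(model, ctx, X, y, splits, cfg):
    history = _fit(model, ctx, X, y, splits, cfg)
    test_idx = splits["test"] if len(splits["test"]) else splits["val"]
    report = compute_metrics(y[test_idx], _scores(model, ctx, X[test_idx]))
    val_idx = splits["val"] if len(splits["val"]) else splits["train"]
    val_report = compute_metrics(y[val_idx], _scores(model, ctx, X[val_idx]))
    return TrainResult(model=model, report=report, val_report=val_report,
                       history=history, splits=splits, config_hash=config_hash(cfg))


def evaluate_model(model, bags) -> MetricReport:
    ctx, X, y = _stack_bags(bags)
    return compute_metrics(y, _scores(model, ctx, X))


def predict_bags(model, bags):
    """Per-slide probabilities and attention weights (if the model has
    attention), as (DataFrame, dict slide_id -> (a, rows, cols))."""
    ctx, X, y = _stack_bags(bags)
    sorted_bags = [b.sorted_by_grid() for b in bags]
    records, attn = [], {}
    for lo in range(0, len(X), 32):
        logits, a, _ = model.forward(Tensor(X[lo:lo + 32]), ctx)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        for j in range(len(p)):
            bag = sorted_bags[lo + j]
            records.append({"slide_id": bag.slide_id,
                            **{f"p_class{c}": p[j, c] for c in range(p.shape[1])},
                            "predicted_label": int(np.argmax(p[j])),
                            "label": bag.label})
            if a is not None:
                attn[bag.slide_id] = (a.data[j], bag.rows, bag.cols)
    return pd.DataFrame.from_records(records), attn


def k_sweep(bags, cfg: MilTrainConfig, k_values) -> pd.DataFrame:
    """One seeded run per k over shared splits; plot-ready table."""
    if not len(k_values):
        raise ValueError("k_values must be nonempty")
    ctx, X, y = _stack_bags(bags)
    splits = stratified_split(y, cfg.val_frac, cfg.test_frac,
                              np.random.default_rng(cfg.seed))
    rows = []
    for k in k_values:
        res = train_natmil(bags, replace(cfg, k=int(k)), splits=splits)
        rows.append({"k": int(k), "auc": res.report.auc, "acc": res.report.acc,
                     "macro_f1": res.report.macro_f1, "seed": cfg.seed,
                     "config_hash": res.config_hash})
    return pd.DataFrame(rows)


def ablation_attention_type(bags, cfg: MilTrainConfig, variants=MIXERS) -> pd.DataFrame:
    """Swap the stage token mixer under one config; metrics per variant."""
    for v in variants:
        if v not in MIXERS:
            raise ValueError(f"unknown variant {v!r}; valid: {MIXERS}")
    ctx, X, y = _stack_bags(bags)
    splits = stratified_split(y, cfg.val_frac, cfg.test_frac,
                              np.random.default_rng(cfg.seed))
    rows = []
    for v in variants:
        res = train_natmil(bags, replace(cfg, mixer=v), splits=splits)
        n_attn = sum(p.data.size for name, p in res.model.named_parameters()
                     if any(s in name for s in ("Wq", "Wk", "Wv", "bias_table")))
        rows.append({"variant": v, "auc": res.report.auc, "acc": res.report.acc,
                     "macro_f1": res.report.macro_f1,
                     "attention_params": n_attn, "seed": cfg.seed,
                     "config_hash": res.config_hash})
    return pd.DataFrame(rows)
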