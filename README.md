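# natmil

Neighborhood-attention transformer multiple-instance learning (MIL) for
tiled slide images, exercisable entirely on synthetic data.

Whole-slide images are processed as grids of tiles carrying only a
slide-level label. `natmil` re-scores tile-level attention with a
sliding-window **neighborhood attention** (NA) operator over the tile
grid — each tile attends to its k nearest valid grid neighbors with
learned relative-positional biases, windows shifting inward at edges so
every query keeps a full-size span — aggregates tiles with **gated
attention pooling**, and classifies at slide level. The package covers
the full pipeline:

- `natmil.synthetic` — seeded synthetic slides (random-walk tumor blobs,
  periodic texture motif, known tile labels) and feature bags with
  controllable tumor fraction, spatial clustering, and class separation.
- `natmil.preprocess` — Otsu-on-saturation tissue segmentation and
  non-overlapping fixed-size grid tiling into a CSV manifest.
- `natmil.contrastive` — SimCLR-style two-view contrastive training
  (NT-Xent loss, two-hidden-layer projection head) of a small residual
  conv encoder; per-tile feature export to HDF5 bags.
- `natmil.na` — the NA operator plus a dense masked-attention oracle
  used only for testing (the two agree to <1e-5 everywhere).
- `natmil.backbone` — hierarchical NAT: overlapping-conv tokenizer (or
  1×1 linear embedding for tile grids), four stages of pre-norm blocks
  with LayerScale, channel-doubling stride-2 conv downsamplers. Token
  mixers are swappable (neighborhood / window / global / conv) for
  ablations.
- `natmil.mil` — gated attention pooling, residual bag aggregation,
  linear slide classifier, and mean/max/gated-AB-MIL baselines.
- `natmil.pipeline` + `natmil.cli` — training loops (AdamW, cosine
  schedule, early stopping), rank-based AUC / ACC@0.5 / macro-F1
  metrics, the k-sweep and attention-type ablation harnesses.

Everything runs on CPU: models are built on a small numpy reverse-mode
autodiff core (`natmil._tensor`), so no deep-learning framework is
required.

## CLI

```bash
natmil simulate --kind bags  --n 200 --seed 0 --out bags.h5
natmil simulate --kind slides --n 4 --seed 0 --out slides/
natmil preprocess --image slides/slide_0000.png --tile-px 8 --out manifest.csv
natmil simclr-train --tiles tiles/ --out encoder.npz
natmil extract --checkpoint encoder.npz --image slides/slide_0000.png \
    --manifest manifest.csv --out bag.h5
natmil train  --bags bags.h5 --seed 0 --out run/
natmil eval   --bags bags.h5 --model-dir run/ --out eval/ --heatmaps
natmil k-sweep --bags bags.h5 --k-values 1,2,3,4,8 --out sweep.csv
natmil ablate  --bags bags.h5 --variants neighborhood,window,global,conv --out ablate.csv
```

All commands take `--config config.yaml` (sections `bags:`, `slides:`,
`mil:`, `simclr:` mirroring the config dataclasses) plus `--seed`;
artifacts embed the config hash and seed.

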