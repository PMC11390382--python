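"""Feature-bag container shared across modules, with HDF5 round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["FeatureBag", "save_bags", "load_bags"]


@dataclass
class FeatureBag:
    """One slide's tile embeddings H (n×d) with grid coordinates and label."""

    slide_id: str
    H: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    label: int
    tile_labels: np.ndarray | None = None  # optional instance ground truth

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        n = self.H.shape[0]
        if n < 1:
            raise ValueError("bag must contain at least one tile")
        if len(self.rows) != n or len(self.cols) != n:
            raise ValueError("coordinate lists must match H's row count")
        coords = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(coords) != n:
            raise ValueError("duplicate (row, col) tile coordinates")
        if self.tile_labels is not None:
            self.tile_labels = np.asarray(self.tile_labels, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def d(self) -> int:
        return self.H.shape[1]

    def grid_shape(self) -> tuple:
        return int(self.rows.max()) + 1, int(self.cols.max()) + 1

    def sorted_by_grid(self) -> "FeatureBag":
        order = np.lexsort((self.cols, self.rows))
        return FeatureBag(self.slide_id, self.H[order], self.rows[order],
                          self.cols[order], self.label,
                          None if self.tile_labels is None else self.tile_labels[order])


def save_bags(path, bags, seed: int | None = None, config_hash: str | None = None):
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        for i, bag in enumerate(bags):
            grp = f.create_group(f"bag_{i:05d}")
            grp.attrs["slide_id"] = bag.slide_id
            grp.attrs["bag_label"] = int(bag.label)
            grp.create_dataset("features", data=bag.H)
            grp.create_dataset("rows", data=bag.rows)
            grp.create_dataset("cols", data=bag.cols)
            if bag.tile_labels is not None:
                grp.create_dataset("tile_labels", data=bag.tile_labels)


def load_bags(path):
    bags = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            grp = f[key]
            bags.append(FeatureBag(
                slide_id=str(grp.attrs["slide_id"]),
                H=grp["features"][...],
                rows=grp["rows"][...],
                cols=grp["cols"][...],
                label=int(grp.attrs["bag_label"]),
                tile_labels=grp["tile_labels"][...] if "tile_labels" in grp else None,
            ))
    return bags
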