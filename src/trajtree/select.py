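"""Training-set assembly: selection window and featurization.

Neighbouring frames of one trajectory are nearly identical, and path
sampling produces trajectories that are themselves correlated.  To keep
the classifier from learning that correlation structure, a small number
of frames per path is drawn at random from a narrow order-parameter
window placed near the initial state (default 1.1 < s < 1.25 Å, one
frame per path).  Window location, window width and frames-per-path are
the three hyper-parameters of the whole approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .colvar import ColvarConfig, order_parameter
from .invrep import (
    FeatureLabel,
    distance_matrix,
    flatten,
    index_invariant_matrix,
    select_reference_atom,
)
from .trajio import Frame, PathRecord

__all__ = ["SelectionWindow", "Dataset", "window_select", "build_dataset"]

log = logging.getLogger(__name__)


@dataclass
class SelectionWindow:
    """The method's three hyper-parameters plus the sampling seed."""

    lower: float = 1.1
    upper: float = 1.25
    frames_per_path: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("window needs lower < upper")
        if self.frames_per_path < 1:
            raise ValueError("frames_per_path must be >= 1")


@dataclass
class Dataset:
    """Feature matrix with aligned labels, provenance and feature names.

    Rows are ordered by ``generation_orders`` so that contiguous blocks
    correspond to sampling time (required by the block-error estimate).
    ``source_frames`` keeps the selected frames for back-mapping and
    visualization.
    """

    features: np.ndarray  # (N, F)
    labels: np.ndarray  # (N,) int, reactive=1
    path_ids: list[str]
    generation_orders: np.ndarray  # (N,) int
    feature_labels: list[FeatureLabel]
    source_frames: list[Frame] | None = None

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.path_ids) == len(self.generation_orders) == n):
            raise ValueError("dataset fields are not aligned")
        if self.features.shape[1] != len(self.feature_labels):
            raise ValueError("feature_labels must match feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def window_select(
    paths: list[PathRecord], cfg: ColvarConfig, win: SelectionWindow
) -> list[tuple[PathRecord, Frame]]:
    """Draw up to ``frames_per_path`` in-window frames from each path.

    Window bounds are strict inequalities.  Paths with fewer candidates
    contribute what they have; paths with none contribute nothing (at
    debug log level).  Selection is deterministic given ``win.seed``.
    """
    rng = np.random.default_rng(win.seed)
    selected: list[tuple[PathRecord, Frame]] = []
    for rec in paths:
        candidates = [
            f for f in rec.frames
            if win.lower < order_parameter(f, cfg) < win.upper
        ]
        if not candidates:
            log.debug("path %s has no frames in (%g, %g)", rec.path_id, win.lower, win.upper)
            continue
        k = min(win.frames_per_path, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        selected.extend((rec, candidates[i]) for i in sorted(idx))
    if not selected:
        raise ValueError(
            f"no path has any frame with s in ({win.lower}, {win.upper}); "
            "widen or move the selection window"
        )
    return selected


def build_dataset(
    selected: list[tuple[PathRecord, Frame]],
    ref_rule="C",
    group_order: tuple[str, ...] | None = None,
) -> Dataset:
    """Featurize selected frames into the classifier's data matrix.

    Each frame becomes one row: the flattened index-invariant distance
    matrix (length M²).  Labels are 1 for frames from reactive paths, 0
    for unreactive.  Rows are sorted by the owning path's
    generation_order.
    """
    if not selected:
        raise ValueError("empty selection")
    selected = sorted(selected, key=lambda pair: pair[0].generation_order)
    rows, labels, pids, orders, frames = [], [], [], [], []
    flat_labels: list[FeatureLabel] | None = None
    n_atoms = selected[0][1].n_atoms
    for rec, frame in selected:
        if frame.n_atoms != n_atoms:
            raise ValueError(
                f"path {rec.path_id}: {frame.n_atoms} atoms, expected {n_atoms}"
            )
        ref = select_reference_atom(frame, ref_rule)
        inv = index_invariant_matrix(distance_matrix(frame), ref, group_order)
        vec, labs = flatten(inv)
        if flat_labels is None:
            flat_labels = labs
        rows.append(vec)
        labels.append(1 if rec.label == "reactive" else 0)
        pids.append(rec.path_id)
        orders.append(rec.generation_order)
        frames.append(frame)
    return Dataset(
        features=np.vstack(rows),
        labels=np.array(labels, dtype=int),
        path_ids=pids,
        generation_orders=np.array(orders, dtype=int),
        feature_labels=flat_labels,
        source_frames=frames,
    )
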