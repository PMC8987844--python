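"""Tile-level accuracy assessment and cross-source transferability.

Evaluation follows the pure-cover protocol: test photographs that are
nearly 100 % covered by the target (positives) or entirely free of it
(negatives) are chopped with 50 % overlap, a fixed number of test tiles
(default 500, balanced between classes) is sampled, and each model's calls
are tallied into a confusion table.  Reported metrics::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    kappa     = (p_o - p_e) / (1 - p_e)

with observed agreement ``p_o = accuracy`` and chance agreement
``p_e = [(TP+FN)(TP+FP) + (TN+FN)(TN+FP)] / n^2`` (Cohen's kappa for two
raters, two classes).  Metrics with a zero denominator are reported as
``None`` ("undefined") rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledTileSet, SourceImage
from .errors import SamplingError
from .tiling import ChopConfig, chop_image

__all__ = ["ConfusionCounts", "MetricsReport", "TransferMatrix",
           "build_test_set", "confusion", "metrics", "evaluate_model", "transferability"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; a ``None`` field means its denominator was zero."""

    counts: ConfusionCounts
    accuracy: float
    recall: float | None
    precision: float | None
    kappa: float | None

    def to_dict(self) -> dict:
        return {"tp": self.counts.tp, "fn": self.counts.fn, "fp": self.counts.fp,
                "tn": self.counts.tn, "accuracy": self.accuracy, "recall": self.recall,
                "precision": self.precision, "kappa": self.kappa}


def confusion(calls: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    """Four-way tally of binary calls against ground-truth labels."""
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape:
        raise ValueError(f"calls {calls.shape} and labels {labels.shape} differ in length")
    calls = calls.astype(bool)
    labels = labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & labels)),
        fn=int(np.sum(~calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        tn=int(np.sum(~calls & ~labels)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall, precision and Cohen's kappa from a confusion table."""
    n = counts.total
    if n == 0:
        raise ValueError("confusion table is empty")
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    accuracy = (tp + tn) / n
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    p_e = ((tp + fn) * (tp + fp) + (tn + fn) * (tn + fp)) / (n * n)
    if p_e == 1.0:
        kappa = 1.0 if accuracy == 1.0 else None
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)
    return MetricsReport(counts=counts, accuracy=accuracy, recall=recall,
                         precision=precision, kappa=kappa)


def build_test_set(
    pure_positive_images: Sequence[SourceImage],
    pure_negative_images: Sequence[SourceImage],
    chop: ChopConfig | None = None,
    n_tiles: int = 500,
    positive_fraction: float = 0.5,
    seed: int = 0,
) -> LabeledTileSet:
    """Sample a fixed-size, class-balanced test tile set (seeded).

    Positive images must be essentially fully covered by the target and
    negative images free of it, so every chopped tile inherits its image's
    label.  Raises :class:`SamplingError` when either class cannot supply
    its share of ``n_tiles``.
    """
    chop = chop or ChopConfig()
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_tiles * positive_fraction))
    n_neg = n_tiles - n_pos

    def _collect(sources: Sequence[SourceImage]) -> tuple[np.ndarray, list[str]]:
        pixels, ids = [], []
        for src in sources:
            _, tiles = chop_image(src.image, chop, source_id=src.source_id)
            for t in tiles:
                pixels.append(t.pixels)
                ids.append(t.source_id)
        return (np.stack(pixels) if pixels else
                np.empty((0, chop.tile_size_px, chop.tile_size_px, 3), np.uint8)), ids

    pos_px, pos_ids = _collect(pure_positive_images)
    neg_px, neg_ids = _collect(pure_negative_images)
    if len(pos_px) < n_pos:
        raise SamplingError(f"need {n_pos} positive test tiles, only {len(pos_px)} available")
    if len(neg_px) < n_neg:
        raise SamplingError(f"need {n_neg} negative test tiles, only {len(neg_px)} available")
    pi = rng.choice(len(pos_px), size=n_pos, replace=False)
    ni = rng.choice(len(neg_px), size=n_neg, replace=False)
    tiles = np.concatenate([pos_px[pi], neg_px[ni]])
    labels = np.concatenate([np.ones(n_pos, np.int8), np.zeros(n_neg, np.int8)])
    ids = [pos_ids[i] for i in pi] + [neg_ids[i] for i in ni]
    return LabeledTileSet(tiles=tiles, labels=labels,
                          size_classes=[None] * n_tiles, source_ids=ids,
                          split=np.array(["test"] * n_tiles, dtype="U10"))


def evaluate_model(model, test_set: LabeledTileSet) -> MetricsReport:
    """Run a classifier over a labeled test set and derive all metrics."""
    calls = model.predict(test_set.tiles)
    return metrics(confusion(calls, test_set.labels))


@dataclass
class TransferMatrix:
    """Model-source x test-source grid of metric reports."""

    model_ids: list[str]
    test_ids: list[str]
    cells: dict[tuple[str, str], MetricsReport]

    def kappa_frame(self) -> pd.DataFrame:
        data = [[self.cells[(m, t)].kappa for t in self.test_ids] for m in self.model_ids]
        frame = pd.DataFrame(data, index=self.model_ids, columns=self.test_ids)
        frame["Average"] = frame.mean(axis=1)
        return frame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.model_ids:
            for t in self.test_ids:
                row = {"model_source": m, "test_source": t}
                row.update(self.cells[(m, t)].to_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def transferability(models: Mapping[str, object],
                    test_sets: Mapping[str, LabeledTileSet]) -> TransferMatrix:
    """Evaluate every model on every test source independently."""
    if not models or not test_sets:
        raise ValueError("need at least one model and one test set")
    cells = {
        (m_id, t_id): evaluate_model(model, test_set)
        for m_id, model in models.items()
        for t_id, test_set in test_sets.items()
    }
    return TransferMatrix(model_ids=list(models), test_ids=list(test_sets), cells=cells)
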