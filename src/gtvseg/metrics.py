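"""Geometric segmentation metrics and multi-observer agreement analysis.

All metrics are volume-level: confusion counts are voxel counts over the
whole (shared) grid, so per-subject scores match the per-patient reporting
convention.  Degenerate cases follow a fixed documented convention:

* both masks empty  -> dsc = precision = recall = 1.0, flagged degenerate;
* prediction empty, reference non-empty -> dsc = 0, recall = 0, precision
  undefined (NaN, flagged) and excluded from aggregation;
* reference empty, prediction non-empty -> dsc = 0, precision = 0, recall
  undefined (NaN, flagged).

Consensus regions over K observers use cumulative agreement: level k is the
set of voxels marked by *at least* k observers, so the regions are nested
(level K inside level K-1 ... inside level 1 = the union).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRecord:
    """Per-subject, per-comparison geometric scores with provenance labels."""

    subject_id: str
    predictor: str
    reference: str
    dsc: float
    precision: float
    recall: float
    truth_volume_voxels: int
    degenerate: bool = False


@dataclass
class ConsensusRegions:
    """Agreement-level masks: ``region(k)`` = voxels marked by >= k observers."""

    K: int
    votes: np.ndarray

    def region(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.K:
            raise ValueError(f"level must be in 1..{self.K}")
        return self.votes >= k

    @property
    def regions(self) -> list[np.ndarray]:
        return [self.region(k) for k in range(1, self.K + 1)]


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")


def confusion(pred: np.ndarray, ref: np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion counts of a predicted mask against a reference."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    _check_grids(pred, ref)
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2tp / (2tp + fp + fn); 1.0 if both empty."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp); 1.0 if both masks empty, NaN if prediction empty only."""
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else float("nan")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn); 1.0 if both masks empty, NaN if reference empty only."""
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else float("nan")
    return c.tp / (c.tp + c.fn)


def metric_record(pred, ref, subject_id: str, predictor: str, reference: str) -> MetricRecord:
    c = confusion(pred, ref)
    degenerate = (c.tp + c.fn == 0) or (c.tp + c.fp == 0)
    return MetricRecord(
        subject_id=subject_id,
        predictor=predictor,
        reference=reference,
        dsc=dsc(c),
        precision=precision(c),
        recall=recall(c),
        truth_volume_voxels=c.tp + c.fn,
        degenerate=degenerate,
    )


def pairwise_observer_dsc(masks: list[np.ndarray], subject_id: str = "") -> list[MetricRecord]:
    """DSC for every unordered observer pair: K observers give K(K-1)/2 records."""
    K = len(masks)
    if K < 2:
        raise ValueError("need at least 2 observer masks")
    for m in masks[1:]:
        _check_grids(masks[0], m)
    records = []
    for i in range(K):
        for j in range(i + 1, K):
            records.append(metric_record(masks[i], masks[j], subject_id, f"RO{i + 1}", f"RO{j + 1}"))
    return records


def model_vs_observers(pred: np.ndarray, masks: list[np.ndarray], subject_id: str = "",
                       predictor: str = "model") -> list[MetricRecord]:
    """One record per observer, with the observer mask as the reference."""
    if not masks:
        raise ValueError("no observer masks given")
    for m in masks:
        _check_grids(np.asarray(pred), m)
    return [metric_record(pred, m, subject_id, predictor, f"RO{i + 1}") for i, m in enumerate(masks)]


def consensus_regions(masks: list[np.ndarray]) -> ConsensusRegions:
    """Vote-count the observer masks into nested agreement-level regions."""
    K = len(masks)
    if K < 2:
        raise ValueError("need at least 2 observer masks")
    for m in masks[1:]:
        _check_grids(masks[0], m)
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += np.asarray(m).astype(bool)
    return ConsensusRegions(K=K, votes=votes)


def consensus_recall(pred: np.ndarray, cr: ConsensusRegions) -> dict[int, float]:
    """Recall of the prediction against each agreement-level region.

    Level k uses region(k) as the reference: |pred & region(k)| / |region(k)|.
    Returns {level: recall} for k = K down to 1; an empty region gives NaN.
    """
    pred = np.asarray(pred).astype(bool)
    _check_grids(pred, cr.votes)
    out: dict[int, float] = {}
    for k in range(cr.K, 0, -1):
        region = cr.region(k)
        size = int(region.sum())
        out[k] = float("nan") if size == 0 else float(np.count_nonzero(pred & region) / size)
    return out
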