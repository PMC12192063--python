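"""Dice evaluation over the nested BraTS tumor regions.

Regions are composed from the label map: whole tumor WT = {1, 2, 4},
tumor core TC = {1, 4}, enhancing tumor ET = {4}; ET is a subset of TC is a
subset of WT by construction.  Dice = 2TP / (2TP + FP + FN); when both masks
are empty the score defaults to 1.0 (configurable to skip such slices).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import MultimodalSample
from .student import modality_batch

__all__ = [
    "RegionMasks",
    "region_masks",
    "dice",
    "RegionReport",
    "evaluate_segmenter",
    "evaluate_teacher",
    "write_report_csv",
]

REGION_LABELS = {"wt": (1, 2, 4), "tc": (1, 4), "et": (4,)}


@dataclass
class RegionMasks:
    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray


def region_masks(label: np.ndarray) -> RegionMasks:
    """Binary WT/TC/ET masks from one BraTS label map."""
    return RegionMasks(
        wt=np.isin(label, REGION_LABELS["wt"]),
        tc=np.isin(label, REGION_LABELS["tc"]),
        et=np.isin(label, REGION_LABELS["et"]),
    )


def dice(pred: np.ndarray, truth: np.ndarray, empty_value: float = 1.0) -> float:
    """Dice similarity 2TP / (2TP + FP + FN) for binary masks in [0, 1].

    `empty_value` is returned when both masks are empty; pass
    ``float('nan')`` to mark such slices for skipping.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    denom = 2 * tp + fp + fn
    if denom == 0:
        return empty_value
    return 2.0 * tp / denom


@dataclass
class RegionReport:
    modality: str
    wt: float
    tc: float
    et: float

    @property
    def avg(self) -> float:
        return (self.wt + self.tc + self.et) / 3.0

    def as_row(self) -> dict:
        return {
            "modality": self.modality,
            "WT": round(self.wt, 4),
            "TC": round(self.tc, 4),
            "ET": round(self.et, 4),
            "Avg": round(self.avg, 4),
        }


def evaluate_segmenter(
    model,
    samples: list[MultimodalSample],
    modality: str,
    empty_value: float = 1.0,
    batch_size: int = 8,
) -> RegionReport:
    """Per-region Dice of a single-modality segmenter, averaged over slices.

    `model` maps a (B, 1, H, W) tensor to a ``SegmentationOutput``.  Scores
    are computed per slice and averaged (NaN-skipping when `empty_value` is
    NaN); regions are composed from the argmax label map of each prediction.
    """
    if not samples:
        raise ValueError("empty evaluation dataset")
    model.eval()
    scores: dict[str, list[float]] = {"wt": [], "tc": [], "et": []}
    for start in range(0, len(samples), batch_size):
        batch = samples[start : start + batch_size]
        x = modality_batch(batch, modality)
        pred_labels = model(x).predicted_labels()
        for p, s in zip(pred_labels, batch):
            pm = region_masks(p)
            tm = region_masks(s.label)
            for r in scores:
                scores[r].append(dice(getattr(pm, r), getattr(tm, r), empty_value))
    means = {r: float(np.nanmean(v)) for r, v in scores.items()}
    return RegionReport(modality=modality, wt=means["wt"], tc=means["tc"], et=means["et"])


def evaluate_teacher(
    teacher,
    samples: list[MultimodalSample],
    empty_value: float = 1.0,
    batch_size: int = 8,
) -> RegionReport:
    """Per-region Dice of the full-modality teacher."""
    from .teacher import batch_from_samples

    if not samples:
        raise ValueError("empty evaluation dataset")
    teacher.eval()
    scores: dict[str, list[float]] = {"wt": [], "tc": [], "et": []}
    for start in range(0, len(samples), batch_size):
        batch = samples[start : start + batch_size]
        pa, pb, _ = batch_from_samples(batch)
        pred_labels = teacher.forward(pa, pb).predicted_labels()
        for p, s in zip(pred_labels, batch):
            pm = region_masks(p)
            tm = region_masks(s.label)
            for r in scores:
                scores[r].append(dice(getattr(pm, r), getattr(tm, r), empty_value))
    means = {r: float(np.nanmean(v)) for r, v in scores.items()}
    return RegionReport(modality="all", wt=means["wt"], tc=means["tc"], et=means["et"])


def write_report_csv(reports: list[RegionReport], path: str | Path) -> None:
    """Write reports in the modality / WT / TC / ET / Avg table layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["modality", "WT", "TC", "ET", "Avg"])
        writer.writeheader()
        for r in reports:
            writer.writerow(r.as_row())
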