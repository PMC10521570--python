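"""Dice evaluation: thresholding, per-slice scoring and report generation.

The Dice coefficient between two binary masks A and B is
``2|A ∩ B| / (|A| + |B|)``. Conventions where the formula is indeterminate:
two empty masks score 1.0 (nothing to find, nothing found), one empty mask
scores 0.0. Probability maps are binarised at a strict ``>`` threshold
(default 0.5, so a pixel at exactly the threshold is background).

Evaluation reports are produced twice: over the original slices and over
the flip-expanded evaluation set (each flipped copy scored as an
independent sample), plus per-subject aggregates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .augment import augment, eval_policy
from .errors import ShapeError
from .io import SlicePair, to_model_space
from .models import Network
from .phantom import SubjectVolume

__all__ = ["DiceReport", "EvaluationResult", "binarize", "dice_coefficient",
           "evaluate", "predict_volume", "write_prediction_nifti"]


def binarize(probability_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 where probability > threshold, else 0 (strict inequality)."""
    p = np.asarray(probability_map)
    if p.size and (float(p.min()) < 0.0 or float(p.max()) > 1.0):
        raise ValueError(
            f"probability map values outside [0, 1]: [{p.min()}, {p.max()}]")
    return (p > threshold).astype(np.uint8)


def dice_coefficient(y: np.ndarray, y_hat: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) for binary masks; both-empty scores 1.0."""
    a = np.asarray(y)
    b = np.asarray(y_hat)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for name, m in (("y", a), ("y_hat", b)):
        if m.size and not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"{name} is not binary")
    asum = int(a.sum())
    bsum = int(b.sum())
    if asum + bsum == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (asum + bsum)


@dataclass
class DiceReport:
    """Per-slice Dice scores and their aggregates for one evaluation variant."""

    records: pd.DataFrame       # subject_id, modality, slice_index, transform_id, dice
    threshold: float
    variant: str                # "original" or "flip_augmented"
    dataset: str = "synthetic"  # provenance tag carried into every report

    @property
    def mean_dice(self) -> float:
        return float(self.records.dice.mean())

    @property
    def count(self) -> int:
        return len(self.records)

    @property
    def per_subject(self) -> pd.Series:
        """Subject-level means — the alternative aggregation to slice-level."""
        return self.records.groupby("subject_id").dice.mean()

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "dataset": self.dataset,
            "threshold": self.threshold,
            "count": self.count,
            "mean_dice": self.mean_dice,
            "per_subject_mean_dice": self.per_subject.round(6).to_dict(),
            "slices": self.records.to_dict(orient="records"),
        }, indent=1)

    def write(self, path) -> None:
        """Delimited per-slice table plus a JSON summary next to it."""
        path = Path(path)
        self.records.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
        path.with_suffix(".json").write_text(self.to_json())


@dataclass
class EvaluationResult:
    original: DiceReport
    flip_augmented: DiceReport


def _score(model: Network, slices: list[SlicePair], threshold: float,
           batch_size: int, variant: str, dataset: str) -> DiceReport:
    x = np.stack([p.image for p in slices])[..., None].astype(np.float32)
    probs = model.predict(x, batch_size=batch_size)[..., 0]
    rows = []
    for i, p in enumerate(slices):
        pred = binarize(probs[i], threshold)
        rows.append({"subject_id": p.subject_id, "modality": p.modality,
                     "slice_index": p.slice_index, "transform_id": p.transform_id,
                     "dice": dice_coefficient(p.mask, pred)})
    return DiceReport(records=pd.DataFrame(rows), threshold=threshold,
                      variant=variant, dataset=dataset)


def evaluate(model: Network, slices: list[SlicePair], *, threshold: float = 0.5,
             batch_size: int = 8, dataset: str = "synthetic") -> EvaluationResult:
    """Predict, binarise and Dice-score every slice.

    Returns both the original-slice report and the flip-expanded report in
    which each flipped copy counts as an independent sample.
    """
    if not slices:
        raise ValueError("empty evaluation set")
    original = _score(model, slices, threshold, batch_size, "original", dataset)
    flipped = _score(model, augment(slices, eval_policy()), threshold, batch_size,
                     "flip_augmented", dataset)
    return EvaluationResult(original=original, flip_augmented=flipped)


def predict_volume(model: Network, volume: SubjectVolume, *,
                   batch_size: int = 8) -> np.ndarray:
    """Per-slice probability maps for a whole volume, stacked (H, W, D) in
    model space. Slices are mapped to the model grid exactly as in training
    (resample + min-max normalisation) but without lesion-slice selection."""
    pairs = [to_model_space(SlicePair(
        image=volume.image[:, :, s], mask=np.zeros_like(volume.mask[:, :, s]),
        subject_id=volume.subject_id, modality=volume.modality, slice_index=s),
        size=model.input_size) for s in range(volume.image.shape[2])]
    x = np.stack([p.image for p in pairs])[..., None].astype(np.float32)
    probs = model.predict(x, batch_size=batch_size)[..., 0]
    return np.transpose(probs, (1, 2, 0)).astype(np.float32)


def write_prediction_nifti(probabilities: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(probabilities.astype(np.float32), np.eye(4)), path)
    return path
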