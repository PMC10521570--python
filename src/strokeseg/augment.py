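"""Deterministic slice augmentation by the dihedral transforms of the square.

Training expands every slice into eight: the four quarter-turn rotations of
the original and of its horizontally flipped copy — the full symmetry group
of the square, applied as pure index permutations (no interpolation, the
pixel multiset is preserved). Validation and test slices are expanded only
into {identity, flip}, and the two are counted as independent evaluation
samples rather than averaged.

Per modality this reproduces the clinical cohort's sample ledger
(560 training slices -> 4480, 120 validation -> 240, 112 test -> 224).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ShapeError
from .io import SlicePair

__all__ = ["AugmentationPolicy", "train_policy", "eval_policy",
           "apply_transform", "augment", "transform_id"]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ordered list of (flip, quarter_turns) transforms."""

    mode: str  # "train" or "eval"
    transforms: tuple[tuple[bool, int], ...]

    def __post_init__(self):
        for flip, qt in self.transforms:
            if qt not in (0, 1, 2, 3):
                raise ValueError(f"quarter_turns must be 0-3, got {qt}")
        if self.mode == "train" and len(self.transforms) != 8:
            raise ValueError("train policy must have exactly 8 transforms")
        if self.mode == "eval" and len(self.transforms) != 2:
            raise ValueError("eval policy must have exactly 2 transforms")


def train_policy() -> AugmentationPolicy:
    """{no-flip, flip} x {0, 90, 180, 270} degrees — 8 transforms per slice."""
    return AugmentationPolicy("train", tuple(
        (flip, qt) for flip in (False, True) for qt in range(4)))


def eval_policy() -> AugmentationPolicy:
    """{identity, flip} — 2 transforms per slice."""
    return AugmentationPolicy("eval", ((False, 0), (True, 0)))


def transform_id(flip: bool, quarter_turns: int) -> str:
    return f"{'flip' if flip else 'orig'}-rot{90 * quarter_turns}"


def _apply(arr: np.ndarray, flip: bool, quarter_turns: int) -> np.ndarray:
    if flip:
        arr = np.flip(arr, axis=1)  # horizontal (left-right) mirror
    return np.rot90(arr, k=quarter_turns)  # counter-clockwise


def apply_transform(pair: SlicePair, flip: bool, quarter_turns: int) -> SlicePair:
    """Flip (optionally) then rotate CCW by quarter turns; image and mask in
    lock-step. Requires a square slice (rotation must preserve the shape)."""
    if pair.image.shape[0] != pair.image.shape[1]:
        raise ShapeError(f"transforms require square slices, got {pair.image.shape}")
    if quarter_turns not in (0, 1, 2, 3):
        raise ValueError(f"quarter_turns must be 0-3, got {quarter_turns}")
    return replace(pair,
                   image=np.ascontiguousarray(_apply(pair.image, flip, quarter_turns)),
                   mask=np.ascontiguousarray(_apply(pair.mask, flip, quarter_turns)),
                   transform_id=transform_id(flip, quarter_turns))


def augment(slices: list[SlicePair], policy: AugmentationPolicy) -> list[SlicePair]:
    """All transforms of slice 1, then slice 2, ... — length multiplies by
    the policy size; an empty input yields an empty output."""
    out = []
    for pair in slices:
        for flip, qt in policy.transforms:
            out.append(apply_transform(pair, flip, qt))
    return out
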