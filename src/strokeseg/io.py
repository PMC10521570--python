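"""Volume I/O and the two-stage slice preparation pipeline.

Stage one centres the brain in each slice (scans arrive with the head
anywhere in the field of view); stage two keeps only the slices whose mask
actually contains lesion, resamples them to the network's 160x160 input
grid and min-max normalises intensities to [0, 1]. Splitting into
train/validation/test is done at the *subject* level so no subject's slices
leak across partitions.

Volumes are read and written as NIfTI pairs — ``<subject>_<modality>.nii.gz``
plus ``<subject>_mask.nii.gz`` — with float32 images and uint8 masks so the
round trip is lossless. Prepared slices can be exported as a compressed
tensor container (``.npz``) with a JSON manifest of their provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .errors import FormatError, ShapeError
from .phantom import SubjectVolume

logger = logging.getLogger(__name__)

MODEL_SIZE = 160

__all__ = [
    "SlicePair", "DatasetSplit", "write_nifti", "read_nifti",
    "center_brain", "center_volume", "select_lesion_slices", "to_model_space",
    "split_by_subject", "prepare_volume", "save_slices", "load_slices",
    "MODEL_SIZE",
]


@dataclass
class SlicePair:
    """A 2-D image slice with its binary mask and provenance."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    modality: str
    slice_index: int
    transform_id: str = "identity"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ShapeError(f"image {self.image.shape} vs mask {self.mask.shape}")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split partitions overlap")


# ---------------------------------------------------------------- NIfTI I/O

def image_filename(subject_id: str, modality: str) -> str:
    return f"{subject_id}_{modality}.nii.gz"


def mask_filename(subject_id: str) -> str:
    return f"{subject_id}_mask.nii.gz"


def write_nifti(volume: SubjectVolume, directory) -> tuple[Path, Path]:
    """Write a volume as an image/mask NIfTI pair; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / image_filename(volume.subject_id, volume.modality)
    msk_path = directory / mask_filename(volume.subject_id)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(volume.image.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), affine), msk_path)
    return img_path, msk_path


def _load_nifti_array(path, dtype) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return np.asarray(nib.load(path).get_fdata(), dtype=dtype)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI volume: {exc}") from exc


def read_nifti(image_path, mask_path=None, *, subject_id: str | None = None,
               modality: str | None = None) -> SubjectVolume:
    """Read an image/mask pair back into a SubjectVolume.

    With only ``image_path`` given, the mask path and provenance are inferred
    from the ``<subject>_<modality>.nii.gz`` naming convention.
    """
    image_path = Path(image_path)
    stem = image_path.name.removesuffix(".nii.gz").removesuffix(".nii")
    if subject_id is None or modality is None:
        if "_" not in stem:
            raise FormatError(
                f"cannot infer subject/modality from {image_path.name!r}; "
                "pass subject_id and modality explicitly")
        inferred_subject, inferred_modality = stem.rsplit("_", 1)
        subject_id = subject_id or inferred_subject
        modality = modality or inferred_modality
    if mask_path is None:
        mask_path = image_path.with_name(mask_filename(subject_id))
    image = _load_nifti_array(image_path, np.float32)
    mask = _load_nifti_array(mask_path, np.uint8)
    return SubjectVolume(image=image, mask=mask, subject_id=subject_id, modality=modality)


# ------------------------------------------------------------ preprocessing

def center_brain(slice_image: np.ndarray, *, threshold_frac: float = 0.1) -> np.ndarray:
    """Translate the foreground centroid to the image centre (whole pixels).

    Foreground is everything above ``threshold_frac`` of the slice maximum.
    The shift uses zero fill; all-background slices are returned unchanged.
    """
    img = np.asarray(slice_image)
    if img.ndim != 2 or img.size == 0:
        raise ShapeError(f"expected a non-empty 2-D slice, got shape {img.shape}")
    peak = float(img.max())
    fg = img > threshold_frac * peak
    if peak <= 0 or not fg.any():
        logger.debug("all-background slice: centering is a no-op")
        return img.copy()
    rows, cols = np.nonzero(fg)
    dr = int(round((img.shape[0] - 1) / 2.0 - rows.mean()))
    dc = int(round((img.shape[1] - 1) / 2.0 - cols.mean()))
    out = np.zeros_like(img)
    h, w = img.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), max(0, dr) + (src_r.stop - src_r.start))
    dst_c = slice(max(0, dc), max(0, dc) + (src_c.stop - src_c.start))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def _shift2d(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), max(0, dr) + (src_r.stop - src_r.start))
    dst_c = slice(max(0, dc), max(0, dc) + (src_c.stop - src_c.start))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def center_volume(volume: SubjectVolume, *, threshold_frac: float = 0.1,
                  per_slice: bool = True) -> SubjectVolume:
    """Centre the brain in every slice, shifting the mask in lock-step.

    ``per_slice=False`` applies one whole-volume shift computed from the
    mean slice instead (useful when slice-wise centroids are noisy).
    """
    img = volume.image
    msk = volume.mask
    out_img = np.empty_like(img)
    out_msk = np.empty_like(msk)
    if per_slice:
        for s in range(img.shape[2]):
            sl = img[:, :, s]
            peak = float(sl.max())
            fg = sl > threshold_frac * peak if peak > 0 else np.zeros_like(sl, bool)
            if not fg.any():
                out_img[:, :, s] = sl
                out_msk[:, :, s] = msk[:, :, s]
                continue
            rows, cols = np.nonzero(fg)
            dr = int(round((sl.shape[0] - 1) / 2.0 - rows.mean()))
            dc = int(round((sl.shape[1] - 1) / 2.0 - cols.mean()))
            out_img[:, :, s] = _shift2d(sl, dr, dc)
            out_msk[:, :, s] = _shift2d(msk[:, :, s], dr, dc)
    else:
        mean_slice = img.mean(axis=2)
        centred = center_brain(mean_slice, threshold_frac=threshold_frac)
        # recover the integer shift applied to the mean slice
        peak = float(mean_slice.max())
        fg = mean_slice > threshold_frac * peak
        rows, cols = np.nonzero(fg)
        dr = int(round((mean_slice.shape[0] - 1) / 2.0 - rows.mean())) if fg.any() else 0
        dc = int(round((mean_slice.shape[1] - 1) / 2.0 - cols.mean())) if fg.any() else 0
        for s in range(img.shape[2]):
            out_img[:, :, s] = _shift2d(img[:, :, s], dr, dc)
            out_msk[:, :, s] = _shift2d(msk[:, :, s], dr, dc)
    return SubjectVolume(image=out_img, mask=out_msk, subject_id=volume.subject_id,
                         modality=volume.modality, lesion_slices=volume.lesion_slices)


def select_lesion_slices(volume: SubjectVolume) -> list[SlicePair]:
    """The slices whose mask contains at least one positive pixel, ascending."""
    if volume.image.shape != volume.mask.shape:
        raise ShapeError(f"image {volume.image.shape} vs mask {volume.mask.shape}")
    out = []
    for s in range(volume.mask.shape[2]):
        if volume.mask[:, :, s].any():
            out.append(SlicePair(image=volume.image[:, :, s], mask=volume.mask[:, :, s],
                                 subject_id=volume.subject_id, modality=volume.modality,
                                 slice_index=s))
    return out


def to_model_space(pair: SlicePair, *, size: int = MODEL_SIZE) -> SlicePair:
    """Resample to ``size`` x ``size`` and min-max normalise the image to [0, 1].

    Images are resampled with bilinear interpolation, masks with nearest
    neighbour so they stay binary. A constant-intensity slice normalises to
    all zeros (logged).
    """
    img = pair.image
    msk = pair.mask
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(np.float32)
        msk = resize(msk, (size, size), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(np.uint8)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        logger.debug("constant-intensity slice %s/%d normalised to zeros",
                     pair.subject_id, pair.slice_index)
        img = np.zeros_like(img, dtype=np.float32)
    else:
        img = ((img - lo) / (hi - lo)).astype(np.float32)
    return replace(pair, image=img, mask=msk)


def prepare_volume(volume: SubjectVolume, *, size: int = MODEL_SIZE,
                   center: bool = True, per_slice: bool = True) -> list[SlicePair]:
    """Full slice preparation: centre, select lesion slices, map to model space."""
    v = center_volume(volume, per_slice=per_slice) if center else volume
    return [to_model_space(p, size=size) for p in select_lesion_slices(v)]


def split_by_subject(subject_ids, counts: tuple[int, int, int],
                     seed: int) -> DatasetSplit:
    """Random subject-level partition into train/val/test of the given sizes."""
    ids = list(subject_ids)
    if sum(counts) != len(ids):
        raise ValueError(f"counts {counts} sum to {sum(counts)}, but there are "
                         f"{len(ids)} subjects")
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_tr, n_va, n_te = counts
    return DatasetSplit(train=tuple(shuffled[:n_tr]),
                        val=tuple(shuffled[n_tr:n_tr + n_va]),
                        test=tuple(shuffled[n_tr + n_va:]))


# ---------------------------------------------------------- slice container

def save_slices(pairs: list[SlicePair], path) -> Path:
    """Export prepared slices as .npz tensors plus a JSON provenance manifest."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    images = np.stack([p.image for p in pairs]) if pairs else np.zeros((0, 0, 0), np.float32)
    masks = np.stack([p.mask for p in pairs]) if pairs else np.zeros((0, 0, 0), np.uint8)
    np.savez_compressed(path, images=images, masks=masks)
    manifest = [{"subject_id": p.subject_id, "modality": p.modality,
                 "slice_index": p.slice_index, "transform_id": p.transform_id}
                for p in pairs]
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return path


def load_slices(path) -> list[SlicePair]:
    path = Path(path)
    try:
        with np.load(path) as data:
            images, masks = data["images"], data["masks"]
    except Exception as exc:
        raise FormatError(f"{path} is not a readable slice container: {exc}") from exc
    manifest = json.loads(path.with_suffix(".json").read_text())
    if len(manifest) != len(images):
        raise FormatError(f"manifest lists {len(manifest)} slices, container has {len(images)}")
    return [SlicePair(image=images[i], mask=masks[i], **manifest[i])
            for i in range(len(manifest))]
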