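"""MRI-like phantom cohorts with ground-truth lesion masks.

Real acute-stroke MRI is private; every downstream stage of this package is
therefore exercised on synthetic volumes that reproduce the *structure* the
pipeline depends on rather than MR physics: a bright elliptical "brain" on a
dark noisy background, one hyperintense ellipsoid-profile lesion spanning a
contiguous slice interval, a binary mask marking exactly the lesion voxels,
and two co-registered modalities that share lesion geometry but differ in
noise realisation and lesion conspicuity (the second modality's lesion
contrast is scaled by 0.6, emulating DWI being the more lesion-conspicuous
sequence than FLAIR).

Default geometry mirrors the clinical cohort the pipeline was designed
around: 60 slices per volume, 160x160 in-plane, and a lesion spanning 12-24
slices so that roughly 18 lesion-bearing slices per subject survive slice
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomParams", "SubjectVolume", "generate_cohort", "generate_subject"]

MODALITY_CONTRAST_SCALE = {0: 1.0, 1: 0.6}  # first listed modality shows the lesion strongest


@dataclass(frozen=True)
class PhantomParams:
    """Cohort geometry, intensity and noise settings.

    lesion_slice_range is inclusive; every generated mask has a positive
    pixel count in exactly that many contiguous slices.
    """

    n_subjects: int = 10
    slices_per_volume: int = 60
    height: int = 160
    width: int = 160
    lesion_slice_range: tuple[int, int] = (12, 24)
    lesion_radius_range: tuple[float, float] = (6.0, 16.0)
    lesion_contrast: float = 0.45
    noise_sd: float = 0.05
    brain_intensity: float = 0.55
    modalities: tuple[str, ...] = ("DWI", "FLAIR")
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "slices_per_volume", "height", "width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.lesion_slice_range
        if not (1 <= lo <= hi <= self.slices_per_volume):
            raise ValueError("lesion_slice_range must lie within [1, slices_per_volume]")
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("lesion_radius_range must be positive and ordered")
        # the brain ellipse semi-axes are ~0.35 * (H, W); a lesion must fit inside
        if rhi >= 0.35 * min(self.height, self.width):
            raise ValueError(
                f"max lesion radius {rhi} exceeds the brain radius "
                f"({0.35 * min(self.height, self.width):.0f} px)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.modalities:
            raise ValueError("at least one modality tag is required")


@dataclass
class SubjectVolume:
    """One modality's 3-D image with its binary lesion mask.

    Arrays are indexed (row, col, slice); the mask is {0,1} and identical
    across all modalities of one subject (co-registered lesion geometry).
    """

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    modality: str
    lesion_slices: tuple[int, int] | None = None  # inclusive ground-truth interval

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} dims differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {vals}")


def _brain_ellipse(h: int, w: int, center: tuple[float, float],
                   semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return (((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _lesion_mask(params: PhantomParams, rng: np.random.Generator,
                 brain_center: tuple[float, float],
                 brain_semi: tuple[float, float]) -> tuple[np.ndarray, tuple[int, int]]:
    """3-D mask with an elliptical-profile lesion over a contiguous slice run.

    The in-plane radius follows an ellipsoid profile along the slice axis but
    is floored at 1.2 px so every slice of the drawn interval contains lesion
    pixels — the slice count is exact by construction.
    """
    h, w, d = params.height, params.width, params.slices_per_volume
    lo, hi = params.lesion_slice_range
    n_slices = int(rng.integers(lo, hi + 1))
    s0 = int(rng.integers(0, d - n_slices + 1))
    rmax = float(rng.uniform(*params.lesion_radius_range))
    # lesion centre: inside the brain, away from the rim by the lesion radius
    margin = (max(brain_semi[0] - rmax, 1.0), max(brain_semi[1] - rmax, 1.0))
    u = rng.uniform(-0.8, 0.8, size=2)
    centre = (brain_center[0] + u[0] * margin[0] * 0.5,
              brain_center[1] + u[1] * margin[1] * 0.5)
    aspect = float(rng.uniform(0.7, 1.3))
    mask = np.zeros((h, w, d), dtype=np.uint8)
    half = (n_slices - 1) / 2.0 if n_slices > 1 else 0.5
    mid = s0 + (n_slices - 1) / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    for s in range(s0, s0 + n_slices):
        frac = 1.0 - ((s - mid) / (half + 0.5)) ** 2
        r = max(1.2, rmax * np.sqrt(max(frac, 0.0)))
        ell = (((rr - centre[0]) / r) ** 2 + ((cc - centre[1]) / (r * aspect)) ** 2) <= 1.0
        mask[:, :, s] = ell
    return mask, (s0, s0 + n_slices - 1)


def generate_subject(params: PhantomParams, subject_id: str,
                     rng: np.random.Generator) -> list[SubjectVolume]:
    """All modalities of one subject, sharing brain and lesion geometry."""
    h, w, d = params.height, params.width, params.slices_per_volume
    # brain ellipse: fixed shape, random off-centre placement (re-centred later
    # by the preprocessing stage, as with real scans)
    semi = (0.35 * h * float(rng.uniform(0.9, 1.0)), 0.35 * w * float(rng.uniform(0.8, 0.95)))
    offset = rng.uniform(-0.08, 0.08, size=2)
    center = (h / 2.0 + offset[0] * h, w / 2.0 + offset[1] * w)
    brain2d = _brain_ellipse(h, w, center, semi).astype(np.float32)
    mask, interval = _lesion_mask(params, rng, center, semi)

    volumes = []
    for m_idx, modality in enumerate(params.modalities):
        scale = MODALITY_CONTRAST_SCALE.get(m_idx, 0.6)
        noise = rng.uniform(0.0, 1.0, size=(h, w, d)).astype(np.float32)
        texture = gaussian_filter(noise, sigma=(2.0, 2.0, 0.0))
        img = 0.1 + 0.1 * texture
        img += params.brain_intensity * brain2d[:, :, None]
        img += params.lesion_contrast * scale * mask
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=(h, w, d)).astype(np.float32)
        volumes.append(SubjectVolume(image=img.astype(np.float32), mask=mask.copy(),
                                     subject_id=subject_id, modality=modality,
                                     lesion_slices=interval))
    return volumes


def generate_cohort(params: PhantomParams) -> list[SubjectVolume]:
    """Deterministic cohort: one SubjectVolume per subject per modality,
    ordered subject-major then in the order of ``params.modalities``."""
    rng = np.random.default_rng(params.seed)
    out: list[SubjectVolume] = []
    for i in range(params.n_subjects):
        out.extend(generate_subject(params, f"sub-{i + 1:03d}", rng))
    return out
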