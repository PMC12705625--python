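"""DiMANI (diffusion MRI anatomical image) computation and PICS contrast.

DiMANI is the voxelwise arithmetic mean of the diffusion-weighted volumes
with b above a threshold (default: keep b > 100 s/mm^2 only). The mean-b0
image is the complementary average over the low-b volumes. Adaptive
histogram equalization is provided strictly for display: every quantitative
operation in this package consumes the raw, unequalized image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

from .io_formats import Affine, DWIVolume, LabelVolume, ScalarVolume

__all__ = ["DimaniImage", "compute_dimani", "compute_b0_mean", "equalize_adaptive", "pics_contrast"]


@dataclass
class DimaniImage:
    """Mean diffusion-weighted image with provenance metadata."""

    data: np.ndarray
    affine: Affine
    b_threshold: float
    n_volumes_used: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.n_volumes_used < 1:
            raise ValueError("DiMANI must average at least one volume")

    def as_scalar(self) -> ScalarVolume:
        return ScalarVolume(self.data, self.affine)


def compute_dimani(dwi: DWIVolume, b_threshold: float = 100.0) -> DimaniImage:
    """Voxelwise mean over exactly the volumes with b > ``b_threshold``."""
    keep = dwi.gradients.bvals > b_threshold
    n = int(keep.sum())
    if n == 0:
        raise ValueError(f"no volumes with b > {b_threshold} s/mm^2")
    mean = dwi.data[..., keep].mean(axis=3)
    return DimaniImage(mean, dwi.affine, float(b_threshold), n)


def compute_b0_mean(dwi: DWIVolume, b_threshold: float = 100.0) -> ScalarVolume:
    """Voxelwise mean over the volumes with b <= ``b_threshold``."""
    keep = dwi.gradients.bvals <= b_threshold
    if not keep.any():
        raise ValueError(f"no volumes with b <= {b_threshold} s/mm^2")
    return ScalarVolume(dwi.data[..., keep].mean(axis=3), dwi.affine)


def equalize_adaptive(
    img: ScalarVolume,
    tiles: tuple[int, int, int] = (8, 8, 8),
    clip: float = 0.01,
) -> ScalarVolume:
    """Tiled (CLAHE-style) adaptive histogram equalization, display only.

    ``tiles`` is the tile count per axis; ``clip`` the clip limit as a
    fraction of the tile voxel count (``inf`` disables clipping). Output is
    rescaled to [0, 1]. ``tiles=(1,1,1)`` with ``clip=inf`` reduces to
    classic global histogram equalization.
    """
    if any(t <= 0 for t in tiles):
        raise ValueError("tile counts must be positive")
    data = img.data
    if not np.isfinite(data).all():
        raise ValueError("image must be finite")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:  # constant image: equalization is the identity up to scale
        return ScalarVolume(np.zeros_like(data), img.affine)
    norm = (data - lo) / (hi - lo)
    if all(t == 1 for t in tiles) and np.isinf(clip):
        out = exposure.equalize_hist(norm)
    else:
        kernel = tuple(max(1, s // t) for s, t in zip(data.shape, tiles))
        clip_limit = 1.0 if np.isinf(clip) else float(clip)
        out = exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip_limit)
    return ScalarVolume(np.clip(out, 0.0, 1.0), img.affine)


def pics_contrast(
    dimani: DimaniImage, pics_mask: LabelVolume, flank_mask: LabelVolume
) -> float:
    """Contrast ratio mean(DiMANI in PICS) / mean(DiMANI in flanking capsule).

    Uses raw (unequalized) intensities. Masks must be nonempty and disjoint.
    """
    p = pics_mask.mask()
    f = flank_mask.mask()
    if not p.any() or not f.any():
        raise ValueError("empty mask")
    if (p & f).any():
        raise ValueError("PICS and flank masks overlap")
    return float(dimani.data[p].mean() / dimani.data[f].mean())
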