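"""NIfTI / bval / bvec input-output and the coordinate conventions used package-wide.

Conventions (fixed once, relied upon everywhere):

* voxel indices are 0-based; slice ranges are half-open;
* world space is RAS (+x right/lateral, +y anterior, +z superior), in mm;
* an "axial slice" is a fixed ``k`` index along the third (superior) axis;
* "anterior-posterior" position means world ``y``;
* bvec sign conventions are taken verbatim from file — no flipping heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("picsparcel")

__all__ = [
    "Affine",
    "ScalarVolume",
    "LabelVolume",
    "GradientTable",
    "DWIVolume",
    "read_nifti",
    "write_nifti",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]


@dataclass(frozen=True)
class Affine:
    """4x4 homogeneous map from 0-based voxel indices (i,j,k,1) to world mm (x,y,z,1)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {m.shape}")
        if abs(np.linalg.det(m[:3, :3])) <= 0:
            raise ValueError("affine upper-left 3x3 block is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.matrix[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Column norms of the 3x3 block: voxel edge lengths in mm."""
        return np.linalg.norm(self.matrix[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel coordinates (may be fractional) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.matrix)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.isfinite(data).all():
        raise ValueError(f"{what} contains NaN or infinite voxels")


@dataclass
class ScalarVolume:
    """3-D real-valued image with its world affine."""

    data: np.ndarray
    affine: Affine

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got {self.data.ndim}-D")
        _check_finite(self.data, "ScalarVolume")


@dataclass
class LabelVolume:
    """3-D nonnegative integer label image; label 0 is background.

    ``names`` maps each nonzero label present in the data to a region name.
    """

    data: np.ndarray
    affine: Affine
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D data, got {data.ndim}-D")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label data is not integer-valued")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.data = data
        present = set(np.unique(data).tolist()) - {0}
        missing = present - set(self.names)
        if missing and self.names:
            raise ValueError(f"labels {sorted(missing)} missing from names map")
        if not self.names:
            self.names = {int(v): str(int(v)) for v in sorted(present)}

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label (or of all nonzero labels)."""
        if label is None:
            return self.data > 0
        return self.data == label


@dataclass
class GradientTable:
    """Diffusion gradient scheme: per-volume b-value (s/mm^2) and unit direction."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} != ({self.bvals.size}, 3)"
            )
        if (self.bvals < 0).any():
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if dw.any() and np.abs(norms[dw] - 1.0).max() > 1e-3:
            raise ValueError("non-unit gradient direction for b > 0 (tol 1e-3)")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass
class DWIVolume:
    """4-D diffusion-weighted series (x, y, z, volume) with its gradient table."""

    data: np.ndarray
    affine: Affine
    gradients: GradientTable

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.gradients):
            raise ValueError(
                f"{self.data.shape[3]} volumes but {len(self.gradients)} gradient entries"
            )
        _check_finite(self.data, "DWIVolume")
        if self.data.min() < 0:
            raise ValueError("DWI intensities must be nonnegative")


def _best_affine(img: nib.Nifti1Image) -> Affine:
    # sform preferred over qform, falling back to the header's composite affine
    sform, scode = img.get_sform(coded=True)
    if scode != 0:
        return Affine(sform)
    qform, qcode = img.get_qform(coded=True)
    if qcode != 0:
        return Affine(qform)
    return Affine(img.affine)


def read_nifti(
    path: str | Path,
    kind: str = "scalar",
    gradients: GradientTable | None = None,
    names: dict[int, str] | None = None,
) -> ScalarVolume | LabelVolume | DWIVolume:
    """Read a NIfTI-1/2 file as a typed volume.

    Parameters
    ----------
    kind : {"scalar", "label", "dwi"}
        The declared type the data is cast to. ``"dwi"`` requires `gradients`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = _best_affine(img)
    if kind == "dwi":
        if data.ndim != 4:
            raise ValueError(f"{path}: expected 4-D image for DWI, got {data.ndim}-D")
        if gradients is None:
            raise ValueError("reading a DWI volume requires a gradient table")
        if data.shape[3] != len(gradients):
            raise ValueError(
                f"{path}: {data.shape[3]} volumes but gradient table has "
                f"{len(gradients)} entries"
            )
        return DWIVolume(data, affine, gradients)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D image, got {data.ndim}-D")
    if kind == "label":
        return LabelVolume(data, affine, names or {})
    if kind == "scalar":
        return ScalarVolume(data, affine)
    raise ValueError(f"unknown kind {kind!r}")


def write_nifti(volume, path: str | Path) -> None:
    """Write a typed volume back to NIfTI; DWI volumes also get .bval/.bvec sidecars."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        data = volume.data.astype(np.int32)
    else:
        data = volume.data.astype(np.float64)
    img = nib.Nifti1Image(data, volume.affine.matrix)
    img.set_sform(volume.affine.matrix, code=1)
    img.set_qform(volume.affine.matrix, code=1)
    nib.save(img, str(path))
    if isinstance(volume, DWIVolume):
        stem = str(path)
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        write_bvals_bvecs(volume.gradients, stem + ".bval", stem + ".bvec")


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-dialect bval/bvec files (whitespace-separated; bvec as 3 rows).

    Directions with b > 0 are renormalized to unit length; renormalization of any
    vector off by more than 1e-6 is logged.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:  # single volume
        bvecs = bvecs.reshape(3, 1)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval has {bvals.size} entries but bvec has {bvecs.shape[0]} columns"
        )
    if (bvals < 0).any():
        raise ValueError("negative b-value in bval file")
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    if dw.any():
        if (norms[dw] == 0).any():
            raise ValueError("zero-length direction for a b > 0 volume")
        off = np.abs(norms[dw] - 1.0) > 1e-6
        if off.any():
            logger.warning(
                "renormalized %d bvec direction(s) to unit length", int(off.sum())
            )
        bvecs[dw] = bvecs[dw] / norms[dw, None]
    bvecs[~dw] = 0.0
    return GradientTable(bvals, bvecs)


def write_bvals_bvecs(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a gradient table in FSL dialect (bvec as 3 whitespace-separated rows)."""
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")
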