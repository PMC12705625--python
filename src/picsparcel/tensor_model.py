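"""Per-voxel diffusion tensor fitting, FA, principal directions, and the
Otsu threshold that scales the deterministic tracker's stopping rule.

The fit is weighted log-linear least squares: ln S = ln S0 - b g^T D g,
solved per voxel with weights S^2 (the standard first-order correction for
log-transformed noise). Nonpositive signals are excluded from the fit.
Negative eigenvalues are clamped to zero after fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Affine, DWIVolume, LabelVolume, ScalarVolume

__all__ = ["TensorVolume", "FAMap", "fit_tensor", "compute_fa", "principal_direction", "otsu_threshold"]

# lower-triangular component order used throughout
_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


@dataclass
class TensorVolume:
    """Grid of symmetric tensors, stored as 6 coefficients per voxel
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz; mm^2/s), plus the fitted S0 map."""

    coeffs: np.ndarray  # (nx, ny, nz, 6)
    s0_map: ScalarVolume
    affine: Affine

    def __post_init__(self):
        if self.coeffs.ndim != 4 or self.coeffs.shape[3] != 6:
            raise ValueError("coeffs must be (nx, ny, nz, 6)")

    def as_matrices(self) -> np.ndarray:
        """Expand to full (nx, ny, nz, 3, 3) symmetric matrices."""
        c = self.coeffs
        m = np.empty(c.shape[:3] + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending, clamped >= 0) and matching eigenvectors.

        Returns ``(vals, vecs)`` with vals (..., 3) sorted λ1 >= λ2 >= λ3 and
        vecs (..., 3, 3) whose column ``[..., :, i]`` pairs with ``vals[..., i]``.
        """
        vals, vecs = np.linalg.eigh(self.as_matrices())
        order = vals.argsort(axis=-1)[..., ::-1]
        vals = np.take_along_axis(vals, order, axis=-1)
        vecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
        return np.clip(vals, 0.0, None), vecs


@dataclass
class FAMap:
    """Fractional anisotropy in [0, 1]; 0 where the tensor is degenerate."""

    data: np.ndarray
    affine: Affine

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("FA out of [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)


def _design_matrix(gtab) -> np.ndarray:
    g = gtab.bvecs
    b = gtab.bvals
    cols = [
        g[:, 0] ** 2,
        2 * g[:, 0] * g[:, 1],
        2 * g[:, 0] * g[:, 2],
        g[:, 1] ** 2,
        2 * g[:, 1] * g[:, 2],
        g[:, 2] ** 2,
    ]
    X = np.empty((len(b), 7))
    X[:, 0] = 1.0
    X[:, 1:] = -b[:, None] * np.stack(cols, axis=1)
    return X


def fit_tensor(dwi: DWIVolume, mask: LabelVolume | None = None) -> TensorVolume:
    """Weighted log-linear LS tensor fit per (masked) voxel.

    Requires >= 6 distinct DW directions and at least one b0. Voxels with
    fewer than 7 usable (positive-signal) measurements, or an all-zero
    signal, get a zero (degenerate) tensor.
    """
    gtab = dwi.gradients
    if (gtab.bvals > 0).sum() < 6 or not (gtab.bvals == 0).any():
        raise ValueError("need >= 6 DW directions and >= 1 b0 volume")
    X = _design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient design matrix rank < 7")

    shape = dwi.data.shape[:3]
    sel = mask.mask() if mask is not None else np.ones(shape, dtype=bool)
    S = dwi.data[sel]  # (nvox, nvol)
    nvox = S.shape[0]
    coeffs = np.zeros((nvox, 7))
    ok = S > 0
    usable = ok.sum(axis=1) >= 7
    if usable.any():
        Su = S[usable]
        oku = ok[usable]
        y = np.where(oku, np.log(np.where(oku, Su, 1.0)), 0.0)
        w = np.where(oku, Su**2, 0.0)  # weights S^2; excluded points get 0
        # normal equations per voxel: (X^T W X) beta = X^T W y
        XtWX = np.einsum("vn,ni,nj->vij", w, X, X)
        XtWy = np.einsum("vn,ni,vn->vi", w, X, y)
        try:
            beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(XtWX, XtWy)]
            )
        coeffs[usable] = beta
    n_excluded = int((~ok).sum())
    if n_excluded:
        import logging

        logging.getLogger("picsparcel").info(
            "tensor fit: excluded %d nonpositive signal measurements", n_excluded
        )

    full = np.zeros(shape + (7,))
    full[sel] = coeffs
    s0 = np.exp(full[..., 0]) * (full[..., 1:] != 0).any(axis=-1)
    tv = TensorVolume(full[..., 1:], ScalarVolume(s0, dwi.affine), dwi.affine)
    # clamp negative eigenvalues to zero, re-assembling the coefficients
    vals, vecs = np.linalg.eigh(tv.as_matrices())
    if vals.min() < 0:
        vals = np.clip(vals, 0.0, None)
        m = np.einsum("...ij,...j,...kj->...ik", vecs, vals, vecs)
        c = np.stack(
            [m[..., 0, 0], m[..., 0, 1], m[..., 0, 2], m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]],
            axis=-1,
        )
        tv = TensorVolume(c, tv.s0_map, tv.affine)
    return tv


def compute_fa(tensors: TensorVolume) -> FAMap:
    """FA = sqrt(1/2) sqrt(sum of squared eigenvalue differences) / |lambda|;
    zero where the tensor is degenerate (all eigenvalues zero)."""
    vals, _ = tensors.eigensystem()
    l1, l2, l3 = vals[..., 0], vals[..., 1], vals[..., 2]
    num = np.sqrt(0.5) * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    fa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return FAMap(np.clip(fa, 0.0, 1.0), tensors.affine)


def principal_direction(tensors: TensorVolume) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue per voxel (sign-free:
    callers must treat v and -v as the same axis); zero where degenerate."""
    vals, vecs = tensors.eigensystem()
    v1 = vecs[..., :, 0]
    degenerate = vals[..., 0] <= 0
    v1 = np.where(degenerate[..., None], 0.0, v1)
    return v1


def otsu_threshold(fa: FAMap, mask: LabelVolume | None = None, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance over ``nbins``
    equal bins on [0, max]. Returns the bin-edge threshold value."""
    data = fa.data[mask.mask()] if mask is not None else fa.data.ravel()
    if np.unique(data).size < 2:
        raise ValueError("constant image has no Otsu threshold")
    top = float(data.max())
    counts, edges = np.histogram(data, bins=nbins, range=(0.0, top))
    counts = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    mu = np.cumsum(counts * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu / w0
        m1 = (mu_t - mu) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between = np.nan_to_num(between, nan=-1.0)
    # threshold sits at the upper edge of the best split's lower class
    k = int(np.argmax(between[:-1]))
    return float(edges[k + 1])
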