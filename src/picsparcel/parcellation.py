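"""Connectivity maps -> capsule parcels, center-of-mass skeletons, and
anterior-posterior somatotopic orderings.

Two renderings of the same connectivity data:

* *Parcels* keep every in-capsule voxel whose count is at least a fraction
  (default 80%) of that region's in-capsule maximum — deliberately not a
  winner-take-all rule, so parcels may overlap.
* *Skeletons* summarize the full (unthresholded) in-capsule distribution as
  one count-weighted centroid per axial slice, tracing the course of each
  territory's fibers through the capsule.

The anterior-posterior ordering ranks territories by the weighted mean world
y of their skeleton points (anteriormost first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LabelVolume
from .tractography import ConnectivityMap

__all__ = [
    "Parcel",
    "Skeleton",
    "APOrdering",
    "threshold_parcel",
    "skeletonize",
    "order_anterior_posterior",
    "parcel_overlap",
]


@dataclass
class Parcel:
    """Binary in-capsule territory mask thresholded at a fraction of the
    region's maximum connectivity."""

    mask: LabelVolume
    region_name: str
    threshold_value: float
    max_connectivity: float


@dataclass
class Skeleton:
    """Ordered per-axial-slice weighted centers of mass for one territory."""

    region_name: str
    points: list[tuple[int, float, float, float, float]]  # (k, x, y, z, weight)

    def __post_init__(self):
        ks = [p[0] for p in self.points]
        if len(ks) != len(set(ks)):
            raise ValueError("more than one skeleton point on an axial slice")
        if any(p[4] <= 0 for p in self.points):
            raise ValueError("skeleton weights must be positive")
        self.points = sorted(self.points, key=lambda p: p[0])

    @property
    def xyz(self) -> np.ndarray:
        return np.array([[p[1], p[2], p[3]] for p in self.points])

    @property
    def weights(self) -> np.ndarray:
        return np.array([p[4] for p in self.points])


@dataclass
class APOrdering:
    """Territories ranked anterior (max world y) to posterior."""

    ranking: list[str]
    scores: dict[str, float]
    ties: list[tuple[str, str]]


def threshold_parcel(
    conn: ConnectivityMap, capsule_mask: LabelVolume, frac: float = 0.8
) -> Parcel:
    """Keep in-capsule voxels with counts >= ``frac`` x the in-capsule
    maximum (strict >=; counts outside the capsule are ignored entirely).

    Note the ``frac = 0`` edge: the rule ``counts >= 0`` keeps the whole
    capsule, background zeros included.
    """
    cap = capsule_mask.mask()
    inside = np.where(cap, conn.counts, 0)
    peak = float(conn.counts[cap].max()) if cap.any() else 0.0
    if peak <= 0:
        raise ValueError("connectivity map is zero everywhere inside the capsule")
    thr = frac * peak
    keep = cap & (conn.counts >= thr)
    return Parcel(
        mask=LabelVolume(keep.astype(np.int32), conn.affine, {1: conn.seed_name} if keep.any() else {}),
        region_name=conn.seed_name,
        threshold_value=thr,
        max_connectivity=peak,
    )


def skeletonize(conn: ConnectivityMap, capsule_mask: LabelVolume) -> Skeleton:
    """Count-weighted centroid of the full in-capsule distribution on each
    axial slice with nonzero counts (zero-count slices are skipped)."""
    cap = capsule_mask.mask()
    counts = np.where(cap, conn.counts, 0).astype(float)
    if counts.sum() == 0:
        raise ValueError("connectivity map is zero everywhere inside the capsule")
    points = []
    for k in range(counts.shape[2]):
        sl = counts[:, :, k]
        w = sl.sum()
        if w == 0:
            continue
        ij = np.argwhere(sl > 0)
        wv = sl[ij[:, 0], ij[:, 1]]
        centroid_vox = (ij * wv[:, None]).sum(axis=0) / w
        world = conn.affine.voxel_to_world(
            np.array([centroid_vox[0], centroid_vox[1], float(k)])
        )
        points.append((k, float(world[0]), float(world[1]), float(world[2]), float(w)))
    return Skeleton(conn.seed_name, points)


def order_anterior_posterior(skeletons: list[Skeleton]) -> APOrdering:
    """Weighted mean world y per territory; rank anterior (max y) first.
    Exact ties are broken lexicographically and reported."""
    if len(skeletons) < 2:
        raise ValueError("need at least two skeletons to order")
    scores = {
        s.region_name: float(np.average(s.xyz[:, 1], weights=s.weights))
        for s in skeletons
    }
    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    ties = [
        (a, b)
        for i, a in enumerate(ranking)
        for b in ranking[i + 1 :]
        if scores[a] == scores[b]
    ]
    return APOrdering(ranking, scores, ties)


def parcel_overlap(parcels: list[Parcel]) -> np.ndarray:
    """Pairwise Dice coefficients 2|A∩B| / (|A|+|B|) between parcel masks."""
    if len(parcels) < 2:
        raise ValueError("need at least two parcels")
    n = len(parcels)
    masks = [p.mask.mask() for p in parcels]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = masks[i], masks[j]
            denom = a.sum() + b.sum()
            dice = 2.0 * (a & b).sum() / denom if denom else 0.0
            out[i, j] = out[j, i] = dice
    return out
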