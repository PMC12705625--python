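"""Deterministic and probabilistic streamline tractography.

Two trackers share one machinery: trilinear interpolation of a sign-free
(axial) principal-direction field, world-mm stepping, and seeded RNG draws
for every randomized quantity.

* The deterministic tracker follows the interpolated field exactly. Per
  streamline it draws an anisotropy stopping threshold uniformly from
  (0.5, 0.7) x Otsu(FA) and an angular threshold uniformly from
  (45, 90) degrees, steps at the voxel spacing, tracks both directions from
  a uniformly jittered sub-voxel seed position, and discards any pathway
  entering an exclusion region.

* The probabilistic tracker emulates a probtrackx-style run: per seed voxel
  it propagates ``n_samples`` samples whose step directions are drawn from a
  Watson-type axial distribution about the local principal direction with
  concentration kappa = kappa0 * FA / (1 - FA + 1e-6). A draw whose cosine
  with the previous direction falls below the curvature threshold terminates
  the sample; samples also stop on low anisotropy, on leaving the volume, at
  the step cap, or (loopcheck) on re-entering a voxel already visited. After
  both directions are concatenated, a sample touching any avoidance region
  is discarded and a sample is counted only if it intersects the waypoint;
  the connectivity map counts, per voxel, how many counted samples visited it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Affine, LabelVolume
from .tensor_model import FAMap, otsu_threshold

__all__ = [
    "DeterministicParams",
    "ProbabilisticParams",
    "StreamlineSet",
    "ConnectivityMap",
    "track_deterministic",
    "track_probabilistic",
    "endpoint_labels",
    "midline_exclusion_mask",
]


@dataclass(frozen=True)
class DeterministicParams:
    """Deterministic tracking settings (defaults follow DSI-Studio's)."""

    anisotropy_frac_range: tuple[float, float] = (0.5, 0.7)
    angle_range_deg: tuple[float, float] = (45.0, 90.0)
    step: float | None = None  # None -> voxel spacing
    n_tracts_target: int = 10_000
    max_steps: int = 500
    min_points: int = 3
    max_seed_attempts_factor: int = 50
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.anisotropy_frac_range
        if not (0 < lo <= hi):
            raise ValueError("bad anisotropy fraction range")
        alo, ahi = self.angle_range_deg
        if not (0 < alo <= ahi <= 180):
            raise ValueError("bad angle range")


@dataclass(frozen=True)
class ProbabilisticParams:
    """Probabilistic tracking settings (defaults follow the reference run:
    curvature 0.2, 2000 steps/sample, 5000 samples, 0.5 mm steps, subsidiary
    volume-fraction floor 0.01, loopcheck on)."""

    curvature_cos_threshold: float = 0.2
    max_steps_per_sample: int = 2000
    n_samples: int = 5000
    step: float = 0.5
    volume_fraction_threshold: float = 0.01
    loopcheck: bool = True
    dispersion_kappa0: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (-1.0 <= self.curvature_cos_threshold <= 1.0):
            raise ValueError("curvature cosine threshold must be in [-1, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class StreamlineSet:
    """Polylines in world mm with per-streamline status and threshold draws."""

    streamlines: list[np.ndarray]
    status: list[str]  # accepted | rejected_exclusion | rejected_no_waypoint | terminated_short
    step: float
    fa_thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    angle_thresholds_deg: np.ndarray = field(default_factory=lambda: np.empty(0))

    def accepted(self) -> list[np.ndarray]:
        return [s for s, st in zip(self.streamlines, self.status) if st == "accepted"]


@dataclass
class ConnectivityMap:
    """Per-voxel count of accepted (waypoint-passing) samples for one seed ROI."""

    counts: np.ndarray
    affine: Affine
    seed_name: str
    n_samples_total: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0:
            raise ValueError("negative counts")
        if self.counts.max() > self.n_samples_total:
            raise ValueError("counts exceed total sample count")


# ---------------------------------------------------------------- interpolation


def _trilinear_weights(pts: np.ndarray, shape: tuple[int, int, int]):
    """Corner indices and weights for trilinear interpolation at fractional
    voxel coordinates, clipped to the grid."""
    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    corners = []
    weights = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + np.array([dx, dy, dz])
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                np.clip(idx, 0, np.array(shape) - 1, out=idx)
                corners.append(idx)
                weights.append(w)
    return corners, weights


def interpolate_scalar(vol: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a scalar grid at (n, 3) voxel coordinates."""
    corners, weights = _trilinear_weights(pts_vox, vol.shape)
    out = np.zeros(pts_vox.shape[0])
    for idx, w in zip(corners, weights):
        out += w * vol[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def interpolate_axial_field(
    dirfield: np.ndarray, pts_vox: np.ndarray, ref: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of a sign-free direction field.

    Each corner vector is flipped to lie in the hemisphere of ``ref`` before
    weighting (axial data: v and -v are the same orientation). Returns unit
    vectors; rows with negligible norm come back as zero (degenerate).
    """
    corners, weights = _trilinear_weights(pts_vox, dirfield.shape[:3])
    out = np.zeros_like(ref)
    for idx, w in zip(corners, weights):
        v = dirfield[idx[:, 0], idx[:, 1], idx[:, 2]]
        sign = np.where(np.einsum("ij,ij->i", v, ref) < 0, -1.0, 1.0)
        out += w[:, None] * sign[:, None] * v
    norm = np.linalg.norm(out, axis=1)
    good = norm > 1e-8
    out[good] /= norm[good, None]
    out[~good] = 0.0
    return out


def _in_bounds(pts_vox: np.ndarray, shape) -> np.ndarray:
    return ((pts_vox >= 0) & (pts_vox <= np.array(shape) - 1)).all(axis=1)


# ---------------------------------------------------------------- deterministic


def _initial_directions(dirfield, seeds_vox):
    """Field orientation at seed points with an arbitrary (but fixed) sign."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (seeds_vox.shape[0], 1))
    d = interpolate_axial_field(dirfield, seeds_vox, ref)
    # where the field is near-perpendicular to z the +z reference is unstable;
    # retry those rows against +x
    weak = np.linalg.norm(d, axis=1) < 0.5
    if weak.any():
        ref2 = np.tile(np.array([1.0, 0.0, 0.0]), (int(weak.sum()), 1))
        d[weak] = interpolate_axial_field(dirfield, seeds_vox[weak], ref2)
    return d


def _propagate_deterministic(
    dirfield, fa_data, affine, start_world, start_dir, fa_thr, cos_thr, step, max_steps
):
    """March a batch of streamlines one direction; returns per-streamline
    point arrays (excluding the start point)."""
    n = start_world.shape[0]
    pos = start_world.copy()
    prev = start_dir.copy()
    active = np.linalg.norm(prev, axis=1) > 0.5
    paths: list[list[np.ndarray]] = [[] for _ in range(n)]
    for _ in range(max_steps):
        if not active.any():
            break
        ia = np.where(active)[0]
        nxt = pos[ia] + step * prev[ia]
        nxt_vox = affine.world_to_voxel(nxt)
        inb = _in_bounds(nxt_vox, fa_data.shape)
        ia = ia[inb]
        if ia.size == 0:
            active[:] = False
            break
        active[np.where(active)[0][~inb]] = False
        nxt = nxt[inb]
        nxt_vox = nxt_vox[inb]
        fa_here = interpolate_scalar(fa_data, nxt_vox)
        ok_fa = fa_here >= fa_thr[ia]
        active[ia[~ok_fa]] = False
        ia = ia[ok_fa]
        if ia.size == 0:
            continue
        nxt = nxt[ok_fa]
        nxt_vox = nxt_vox[ok_fa]
        newdir = interpolate_axial_field(dirfield, nxt_vox, prev[ia])
        norm_ok = np.linalg.norm(newdir, axis=1) > 0.5
        cosang = np.einsum("ij,ij->i", newdir, prev[ia])
        ok_ang = norm_ok & (cosang >= cos_thr[ia])
        active[ia[~ok_ang]] = False
        ia = ia[ok_ang]
        for row, p in zip(ia, nxt[ok_ang]):
            paths[row].append(p)
        pos[ia] = nxt[ok_ang]
        prev[ia] = newdir[ok_ang]
    return paths


def track_deterministic(
    dirfield: np.ndarray,
    fa: FAMap,
    seeds: LabelVolume,
    exclusion: LabelVolume | None = None,
    params: DeterministicParams = DeterministicParams(),
) -> StreamlineSet:
    """Deterministic fiber tracking from every seed voxel.

    Streamlines launch from uniform-random sub-voxel positions inside seed
    voxels and are tracked in both directions along the interpolated
    principal-direction field. Per-streamline FA and angle thresholds are
    drawn once from the seeded RNG. Whole pathways entering the exclusion
    region are discarded; generation stops once ``n_tracts_target``
    streamlines are accepted or the attempt budget is exhausted.
    """
    seed_idx = np.argwhere(seeds.mask())
    if seed_idx.size == 0:
        raise ValueError("empty seed mask")
    affine = fa.affine
    step = params.step if params.step is not None else float(np.mean(affine.voxel_sizes))
    try:
        otsu = otsu_threshold(fa)
    except ValueError:  # constant anisotropy: scale thresholds off the plateau
        otsu = float(fa.data.max())
    rng = np.random.default_rng(params.seed)
    excl = exclusion.mask() if exclusion is not None else None

    streamlines: list[np.ndarray] = []
    status: list[str] = []
    fa_draws: list[float] = []
    ang_draws: list[float] = []
    n_accepted = 0
    budget = params.max_seed_attempts_factor * params.n_tracts_target
    batch = min(2048, budget)
    attempts = 0
    while n_accepted < params.n_tracts_target and attempts < budget:
        m = min(batch, budget - attempts)
        attempts += m
        pick = rng.integers(0, seed_idx.shape[0], size=m)
        jitter = rng.uniform(-0.5, 0.5, size=(m, 3))
        seeds_vox = seed_idx[pick] + jitter
        start_world = affine.voxel_to_world(seeds_vox)
        flo, fhi = params.anisotropy_frac_range
        fa_thr = rng.uniform(flo, fhi, size=m) * otsu
        alo, ahi = params.angle_range_deg
        ang = rng.uniform(alo, ahi, size=m)
        cos_thr = np.cos(np.deg2rad(ang))
        d0 = _initial_directions(dirfield, seeds_vox)
        fa_seed = interpolate_scalar(fa.data, seeds_vox)
        viable = (np.linalg.norm(d0, axis=1) > 0.5) & (fa_seed >= fa_thr)
        fwd = _propagate_deterministic(
            dirfield, fa.data, affine, start_world, np.where(viable[:, None], d0, 0.0),
            fa_thr, cos_thr, step, params.max_steps,
        )
        bwd = _propagate_deterministic(
            dirfield, fa.data, affine, start_world, np.where(viable[:, None], -d0, 0.0),
            fa_thr, cos_thr, step, params.max_steps,
        )
        for i in range(m):
            if n_accepted >= params.n_tracts_target:
                break
            if not viable[i]:
                continue
            pts = bwd[i][::-1] + [start_world[i]] + fwd[i]
            line = np.asarray(pts)
            if line.shape[0] < params.min_points:
                st = "terminated_short"
            elif excl is not None and _touches_mask(line, affine, excl):
                st = "rejected_exclusion"
            else:
                st = "accepted"
                n_accepted += 1
            streamlines.append(line)
            status.append(st)
            fa_draws.append(float(fa_thr[i]))
            ang_draws.append(float(ang[i]))
    return StreamlineSet(
        streamlines, status, step, np.asarray(fa_draws), np.asarray(ang_draws)
    )


def _touches_mask(line: np.ndarray, affine: Affine, mask: np.ndarray) -> bool:
    vox = np.round(affine.world_to_voxel(line)).astype(int)
    inb = _in_bounds(vox.astype(float), mask.shape)
    vox = vox[inb]
    if vox.size == 0:
        return False
    return bool(mask[vox[:, 0], vox[:, 1], vox[:, 2]].any())


# ---------------------------------------------------------------- probabilistic


def _sample_watson(mu: np.ndarray, kappa: np.ndarray, rng) -> np.ndarray:
    """Watson-type axial draw about unit axes ``mu`` with concentration
    ``kappa``: a tangent-plane Gaussian with variance 1/(2 kappa), matching
    the Watson distribution's small-angle behavior. ``kappa = inf`` returns
    ``mu`` exactly."""
    n = mu.shape[0]
    out = mu.copy()
    finite = np.isfinite(kappa) & (np.linalg.norm(mu, axis=1) > 0)
    if finite.any():
        m = mu[finite]
        # orthonormal tangent basis per axis
        helper = np.where(np.abs(m[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(m, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(m, e1)
        sd = 1.0 / np.sqrt(2.0 * np.maximum(kappa[finite], 1e-12))
        g = rng.standard_normal((int(finite.sum()), 2)) * sd[:, None]
        v = m + g[:, 0:1] * e1 + g[:, 1:2] * e2
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        out[finite] = v
    return out


class _LoopLedger:
    """Per-sample history of distinct visited voxels for loop checking."""

    def __init__(self, n: int, cap: int = 64):
        self.hist = np.full((n, cap), -1, dtype=np.int64)
        self.h = np.zeros(n, dtype=np.int64)
        self.current = np.full(n, -1, dtype=np.int64)

    def _grow(self):
        extra = np.full((self.hist.shape[0], self.hist.shape[1]), -1, dtype=np.int64)
        self.hist = np.concatenate([self.hist, extra], axis=1)

    def visit(self, rows: np.ndarray, lin: np.ndarray) -> np.ndarray:
        """Record voxel entries; returns a bool array (per row) that is True
        where the sample just re-entered a previously visited voxel."""
        changed = lin != self.current[rows]
        looped = np.zeros(rows.size, dtype=bool)
        if changed.any():
            r = rows[changed]
            l = lin[changed]
            seen = (self.hist[r] == l[:, None]).any(axis=1)
            looped[changed] = seen
            newly = ~seen
            if newly.any():
                rn, ln = r[newly], l[newly]
                if self.h[rn].max(initial=0) >= self.hist.shape[1]:
                    self._grow()
                self.hist[rn, self.h[rn]] = ln
                self.h[rn] += 1
            self.current[rows] = lin
        return looped


def _propagate_probabilistic(
    dirfield, fa_data, affine, start_world, start_dir, params: ProbabilisticParams, rng
):
    """March a batch of probabilistic samples one direction; returns, per
    sample, the set of visited voxel linear indices (as index/sample-id pairs)."""
    shape = fa_data.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    n = start_world.shape[0]
    pos = start_world.copy()
    prev = start_dir.copy()
    active = np.linalg.norm(prev, axis=1) > 0.5
    ledger = _LoopLedger(n) if params.loopcheck else None
    current = np.full(n, -1, dtype=np.int64)  # voxel each sample is inside
    visited_pairs: list[np.ndarray] = []

    vox0 = np.round(affine.world_to_voxel(pos)).astype(np.int64)
    inb0 = _in_bounds(vox0.astype(float), shape)
    active &= inb0
    rows0 = np.where(active)[0]
    lin0 = vox0[rows0] @ strides
    current[rows0] = lin0
    visited_pairs.append(np.stack([rows0, lin0], axis=1))
    if ledger is not None and rows0.size:
        ledger.visit(rows0, lin0)

    for _ in range(params.max_steps_per_sample):
        rows = np.where(active)[0]
        if rows.size == 0:
            break
        pts_vox = affine.world_to_voxel(pos[rows])
        mu = interpolate_axial_field(dirfield, pts_vox, prev[rows])
        fa_here = interpolate_scalar(fa_data, pts_vox)
        ok = (np.linalg.norm(mu, axis=1) > 1e-6) & (
            fa_here >= params.volume_fraction_threshold
        )
        active[rows[~ok]] = False
        rows = rows[ok]
        if rows.size == 0:
            continue
        mu = mu[ok]
        kappa = params.dispersion_kappa0 * fa_here[ok] / (1.0 - fa_here[ok] + 1e-6)
        if np.isinf(params.dispersion_kappa0):
            kappa = np.full(rows.size, np.inf)
        d = _sample_watson(mu, kappa, rng)
        # axial: orient draw along the direction of travel
        flip = np.einsum("ij,ij->i", d, prev[rows]) < 0
        d[flip] *= -1.0
        cosang = np.einsum("ij,ij->i", d, prev[rows])
        ok_curv = cosang >= params.curvature_cos_threshold
        active[rows[~ok_curv]] = False
        rows = rows[ok_curv]
        if rows.size == 0:
            continue
        d = d[ok_curv]
        nxt = pos[rows] + params.step * d
        nxt_vox_f = affine.world_to_voxel(nxt)
        inb = _in_bounds(nxt_vox_f, shape)
        active[rows[~inb]] = False
        rows = rows[inb]
        if rows.size == 0:
            continue
        nxt = nxt[inb]
        d = d[inb]
        vox = np.round(nxt_vox_f[inb]).astype(np.int64)
        lin = vox @ strides
        if ledger is not None:
            looped = ledger.visit(rows, lin)
            if looped.any():
                active[rows[looped]] = False
                keep = ~looped
                rows, lin, nxt, d = rows[keep], lin[keep], nxt[keep], d[keep]
                if rows.size == 0:
                    continue
        changed = lin != current[rows]
        if changed.any():  # record voxel-entry events only
            visited_pairs.append(
                np.stack([rows[changed], lin[changed]], axis=1)
            )
            current[rows[changed]] = lin[changed]
        pos[rows] = nxt
        prev[rows] = d
    if visited_pairs:
        return np.concatenate(visited_pairs, axis=0)
    return np.empty((0, 2), dtype=np.int64)


def track_probabilistic(
    dirfield: np.ndarray,
    fa: FAMap,
    seed_roi: LabelVolume,
    waypoint: LabelVolume,
    avoid_list: Sequence[LabelVolume] = (),
    params: ProbabilisticParams = ProbabilisticParams(),
    seed_name: str = "seed",
) -> ConnectivityMap:
    """probtrackx-style run: seed ROI -> waypoint-filtered visit-count map.

    Per seed voxel, ``params.n_samples`` samples are propagated in both
    directions (paths concatenated before evaluation). Samples touching any
    avoidance mask are discarded; samples are counted only if they intersect
    the waypoint. Returns per-voxel counts of counted samples.
    """
    shape = fa.data.shape
    seed_idx = np.argwhere(seed_roi.mask())
    if seed_idx.size == 0:
        raise ValueError("empty seed mask")
    if not waypoint.mask().any():
        raise ValueError("empty waypoint mask")
    for av in avoid_list:
        if (seed_roi.mask() & av.mask()).any():
            raise ValueError("seed ROI overlaps an avoidance mask")
    affine = fa.affine
    rng = np.random.default_rng(params.seed)
    n_total = seed_idx.shape[0] * params.n_samples

    starts_vox = (
        np.repeat(seed_idx, params.n_samples, axis=0)
        + rng.uniform(-0.5, 0.5, size=(n_total, 3))
    )
    start_world = affine.voxel_to_world(starts_vox)
    d0 = _initial_directions(dirfield, starts_vox)

    pairs_f = _propagate_probabilistic(
        dirfield, fa.data, affine, start_world, d0, params, rng
    )
    pairs_b = _propagate_probabilistic(
        dirfield, fa.data, affine, start_world, -d0, params, rng
    )
    pairs = np.concatenate([pairs_f, pairs_b], axis=0)
    if pairs.size == 0:
        return ConnectivityMap(np.zeros(shape, dtype=np.int64), affine, seed_name, n_total)
    # unique (sample, voxel) pairs: each sample contributes each voxel once
    nvox = int(np.prod(shape))
    key = pairs[:, 0] * nvox + pairs[:, 1]
    key = np.unique(key)
    pairs = np.stack([key // nvox, key % nvox], axis=1)
    way_lin = np.flatnonzero(waypoint.mask().reshape(-1))
    avoid_lin = (
        np.unique(
            np.concatenate(
                [np.flatnonzero(av.mask().reshape(-1)) for av in avoid_list]
            )
        )
        if avoid_list
        else np.empty(0, dtype=np.int64)
    )
    hits_way = np.isin(pairs[:, 1], way_lin)
    hits_avoid = np.isin(pairs[:, 1], avoid_lin) if avoid_lin.size else np.zeros(
        pairs.shape[0], dtype=bool
    )
    bad = np.zeros(n_total, dtype=bool)
    np.logical_or.at(bad, pairs[hits_avoid, 0], True)
    good = np.zeros(n_total, dtype=bool)
    np.logical_or.at(good, pairs[hits_way, 0], True)
    counted = good & ~bad

    keep = counted[pairs[:, 0]]
    lin = pairs[keep, 1]
    counts = np.bincount(lin, minlength=int(np.prod(shape))).reshape(shape)
    return ConnectivityMap(counts.astype(np.int64), affine, seed_name, n_total)


# ------------------------------------------------------------------- utilities


def endpoint_labels(streams: StreamlineSet, labels: LabelVolume) -> dict[int, int]:
    """Count the label under each accepted streamline's two terminal points
    (label 0 = background is allowed)."""
    out: dict[int, int] = {}
    affine_inv_cache = labels.affine
    for line in streams.accepted():
        for pt in (line[0], line[-1]):
            vox = np.round(affine_inv_cache.world_to_voxel(pt)).astype(int)
            if ((vox >= 0) & (vox < np.array(labels.data.shape))).all():
                lab = int(labels.data[tuple(vox)])
            else:
                lab = 0
            out[lab] = out.get(lab, 0) + 1
    return out


def midline_exclusion_mask(
    grid_shape: tuple[int, int, int], affine: Affine, scp_z: float
) -> LabelVolume:
    """1-voxel-thick sagittal wall at world x ~ 0 extending from the top of
    the volume down to just above ``scp_z`` (open below, so pathways may
    cross the midline at and below that level)."""
    idx = np.indices(grid_shape, dtype=float)
    world = affine.voxel_to_world(np.stack(idx, axis=-1))
    x, z = world[..., 0], world[..., 2]
    vx = affine.voxel_sizes[0]
    wall = (np.abs(x) <= vx / 2.0) & (z > scp_z)
    names = {1: "midline"} if wall.any() else {}
    return LabelVolume(wall.astype(np.int32), affine, names)
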