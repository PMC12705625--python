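"""Ground-truthed diffusion phantom: somatotopically ordered fiber bundles
through a "capsule" slab, a PICS-analog high-mean-DWI subregion, cortical
target labels, a midline exclusion wall, and stimulation sites.

The phantom emulates, at desk scale, the geometry the parcellation pipeline
is built for: a set of tubes (one per body-part territory) runs
inferior-to-superior through a white-matter slab standing in for the
posterior limb of the internal capsule (pLIC), each tube crossing the slab
at a distinct anterior-posterior (world y) offset. The ground-truth
anterior-to-posterior order of those crossings is the quantity the
parcellation must recover.

Signal model: single diffusion tensor per voxel, axially symmetric about the
local bundle direction with eigenvalues (lambda_par, lambda_perp,
lambda_perp); isotropic lambda_iso outside bundles. Inside the PICS-analog
mask all diffusivities are scaled by ``pics_lambda_scale`` < 1, which raises
the mean diffusion-weighted signal there (the hyperintensity the landmark is
defined by). Optional Rician noise at a given b0 SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_formats import (
    Affine,
    DWIVolume,
    GradientTable,
    LabelVolume,
    write_nifti,
)

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "StimulationSite",
    "PhantomTruth",
    "make_gradient_table",
    "simulate_bundle_field",
    "simulate_dwi_signal",
    "make_phantom",
    "default_spec",
    "write_phantom",
]


@dataclass(frozen=True)
class BundleSpec:
    """One somatotopic bundle: a tube crossing the capsule slab.

    ``ap_offset``/``ml_offset`` place the tube's capsule crossing in world mm
    (y anterior, x lateral). ``somatotopic_rank`` is ground truth: 1 =
    anteriormost. ``cortical_xy`` optionally displaces the cortical end of
    the tube, bending it; by default the tube is vertical.
    """

    name: str
    ap_offset: float
    ml_offset: float
    radius: float
    cortical_target: int
    somatotopic_rank: int
    cortical_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("bundle radius must be positive")


@dataclass(frozen=True)
class StimulationSite:
    """A stimulation location in world mm, with optional stimulation settings."""

    name: str
    position: tuple[float, float, float]
    depth_note: str = ""
    stim_params: dict | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("site position must be finite")


def _default_bundles() -> tuple[BundleSpec, ...]:
    # Five M1-homunculus territories crossing the slab at distinct y offsets,
    # anterior (max y) to posterior: tongue/larynx, head/face, upper limb,
    # trunk, lower limb — rank 1 = anteriormost.
    names = ["tongue_larynx", "head_face", "upper_limb", "trunk", "lower_limb"]
    ys = [15.0, 7.5, 0.0, -7.5, -15.0]
    return tuple(
        BundleSpec(
            name=n,
            ap_offset=y,
            ml_offset=12.0,
            radius=2.5,
            cortical_target=i + 1,
            somatotopic_rank=i + 1,
        )
        for i, (n, y) in enumerate(zip(names, ys))
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; ``seed`` fixes every source of randomness."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.25
    bval: float = 1500.0
    n_directions: int = 50
    n_b0: int = 5
    s0: float = 1000.0
    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    lambda_iso: float = 0.8e-3
    pics_lambda_scale: float = 0.7
    pics_bundles: tuple[str, ...] = ("upper_limb", "trunk", "lower_limb")
    snr: float = np.inf
    bundles: tuple[BundleSpec, ...] = field(default_factory=_default_bundles)
    seed: int = 0
    capsule_z: tuple[float, float] = (-10.0, 10.0)
    capsule_x: tuple[float, float] = (8.0, 16.0)
    capsule_y_margin: float = 3.0
    cortex_thickness_mm: float = 1.0
    overlap_tolerance: int = 0

    def __post_init__(self):
        if not (self.lambda_par > self.lambda_perp > 0):
            raise ValueError("need lambda_par > lambda_perp > 0")
        ranks = [b.somatotopic_rank for b in self.bundles]
        if len(set(ranks)) != len(ranks):
            raise ValueError("somatotopic ranks must be unique")

    @property
    def affine(self) -> Affine:
        """RAS affine centering the grid on the world origin."""
        v = self.voxel_size
        shape = np.asarray(self.grid_shape, dtype=float)
        m = np.eye(4)
        m[0, 0] = m[1, 1] = m[2, 2] = v
        m[:3, 3] = -(shape - 1) / 2.0 * v
        return Affine(m)


@dataclass
class PhantomTruth:
    """Everything the phantom knows and the pipeline must recover."""

    bundle_labels: LabelVolume
    capsule_mask: LabelVolume
    pics_mask: LabelVolume
    cortical_labels: LabelVolume
    midline_exclusion: LabelVolume
    ap_rank: dict[str, int]
    sites: list[StimulationSite]
    bundle_names: dict[int, str] = field(default_factory=dict)


def make_gradient_table(
    n_directions: int, bval: float, n_b0: int, seed: int = 0
) -> GradientTable:
    """Build an acquisition scheme: ``n_b0`` b=0 volumes then ``n_directions``
    unit directions at ``bval``, spread on the sphere by electrostatic
    repulsion of antipodal point pairs (deterministic for a given seed)."""
    if n_directions < 6:
        raise ValueError("need >= 6 directions to determine a tensor")
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_directions, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # Repulsion between all antipodal pairs; small damped steps.
    step = 0.05
    for _ in range(300):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            if sign < 0:
                d2[d2 < 1e-12] = np.inf  # a point and its own antipode
            force += (diff / (d2[..., None] ** 1.5 + 1e-12)).sum(axis=1)
        # project onto tangent plane
        force -= np.einsum("ij,ij->i", force, pts)[:, None] * pts
        pts += step * force / np.maximum(np.linalg.norm(force, axis=1, keepdims=True), 1.0)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), pts])
    return GradientTable(bvals, bvecs)


def _world_grids(spec: PhantomSpec):
    aff = spec.affine
    idx = np.indices(spec.grid_shape, dtype=float)
    ijk = np.stack(idx, axis=-1)
    return aff.voxel_to_world(ijk)  # (nx, ny, nz, 3)


def simulate_bundle_field(spec: PhantomSpec):
    """Rasterize the bundles into a unit direction field plus ground truth.

    Each bundle is a tube of voxels running inferior-to-superior; the
    centerline is vertical below the cortex band and, when ``cortical_xy``
    differs from the capsule crossing, bends linearly toward it over the top
    third of the grid. Raises if two bundles claim the same voxel (beyond
    ``overlap_tolerance`` voxels).
    """
    shape = spec.grid_shape
    aff = spec.affine
    world = _world_grids(spec)
    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    z_top = z.max()
    z_cortex_lo = z_top - spec.cortex_thickness_mm
    z_bend_lo = z_top - (z_top - z.min()) / 3.0

    labels = np.zeros(shape, dtype=np.int32)
    field3 = np.zeros(shape + (3,), dtype=float)
    cortical = np.zeros(shape, dtype=np.int32)
    collisions: list[tuple[str, str]] = []
    owner: dict[int, str] = {}

    for b in spec.bundles:
        cx = np.array([b.ml_offset, b.ap_offset])
        top = np.array(b.cortical_xy) if b.cortical_xy is not None else cx
        # fraction of the bend completed at height z (0 below z_bend_lo)
        t = np.clip((z - z_bend_lo) / max(z_top - z_bend_lo, 1e-9), 0.0, 1.0)
        cxz = cx[0] + t * (top[0] - cx[0])
        cyz = cx[1] + t * (top[1] - cx[1])
        r2 = (x - cxz) ** 2 + (y - cyz) ** 2
        inside = r2 <= b.radius**2
        hit = inside & (labels > 0)
        if hit.any():
            for lab in np.unique(labels[hit]):
                collisions.append((owner[int(lab)], b.name))
        if int(hit.sum()) > spec.overlap_tolerance and collisions:
            raise ValueError(f"overlapping bundles: {sorted(set(collisions))}")
        labels[inside] = b.cortical_target
        owner[b.cortical_target] = b.name
        # tangent of the centerline: d/dz of (cxz, cyz, z)
        dz = max(z_top - z_bend_lo, 1e-9)
        tan = np.zeros(shape + (3,))
        bend = (z > z_bend_lo)[..., None]
        tan[..., 0] = np.where(bend[..., 0], (top[0] - cx[0]) / dz, 0.0)
        tan[..., 1] = np.where(bend[..., 0], (top[1] - cx[1]) / dz, 0.0)
        tan[..., 2] = 1.0
        tan /= np.linalg.norm(tan, axis=-1, keepdims=True)
        field3[inside] = tan[inside]
        cortical[inside & (z >= z_cortex_lo)] = b.cortical_target

    names = {b.cortical_target: b.name for b in spec.bundles}
    name_map = {k: v for k, v in names.items()}

    capsule = (
        (z >= spec.capsule_z[0])
        & (z <= spec.capsule_z[1])
        & (x >= spec.capsule_x[0])
        & (x <= spec.capsule_x[1])
    )
    ys = [b.ap_offset for b in spec.bundles]
    rmax = max(b.radius for b in spec.bundles)
    capsule &= (y >= min(ys) - rmax - spec.capsule_y_margin) & (
        y <= max(ys) + rmax + spec.capsule_y_margin
    )

    pics = np.zeros(shape, dtype=bool)
    for b in spec.bundles:
        if b.name in spec.pics_bundles:
            pics |= (labels == b.cortical_target) & capsule

    # 1-voxel-thick midline wall open below the "SCP" level (bottom of slab)
    from .tractography import midline_exclusion_mask

    midline = midline_exclusion_mask(shape, aff, scp_z=spec.capsule_z[0])

    sites = _default_sites(spec)
    truth = PhantomTruth(
        bundle_labels=LabelVolume(labels, aff, dict(name_map)),
        capsule_mask=LabelVolume(capsule.astype(np.int32), aff, {1: "capsule"}),
        pics_mask=LabelVolume(pics.astype(np.int32), aff, {1: "pics"}),
        cortical_labels=LabelVolume(cortical, aff, dict(name_map)),
        midline_exclusion=midline,
        ap_rank={b.name: b.somatotopic_rank for b in spec.bundles},
        sites=sites,
        bundle_names=dict(name_map),
    )
    return field3, truth


def _default_sites(spec: PhantomSpec) -> list[StimulationSite]:
    """Two sites medial to the capsule slab, 3.7 mm and 2.3 mm above the
    target-depth plane (z = 0), at the anterior ("head/face") end."""
    by_name = {b.name: b for b in spec.bundles}
    ref = by_name.get("head_face", spec.bundles[0])
    x_site = spec.capsule_x[0] - 4.0  # medial to the slab
    return [
        StimulationSite(
            "site_3.7mm",
            (x_site, ref.ap_offset, 3.7),
            depth_note="3.7 mm above target",
            stim_params={"freq_hz": 130.0, "pw_us": 90.0, "amp_ma": 4.0},
        ),
        StimulationSite(
            "site_2.3mm",
            (x_site, ref.ap_offset, 2.3),
            depth_note="2.3 mm above target",
            stim_params={"freq_hz": 130.0, "pw_us": 90.0, "amp_ma": 4.5},
        ),
    ]


def simulate_dwi_signal(
    direction_field: np.ndarray, truth: PhantomTruth, spec: PhantomSpec
) -> DWIVolume:
    """Forward-model the DWI signal from the direction field.

    S(b, g) = S0 exp(-b g^T D g) with an axially symmetric tensor about the
    local direction inside bundles and an isotropic tensor outside; inside
    the PICS-analog mask all eigenvalues are scaled by ``pics_lambda_scale``.
    Rician noise (scale S0/snr) is added when ``snr`` is finite.
    """
    if direction_field.shape[:3] != spec.grid_shape:
        raise ValueError("direction field grid does not match spec")
    gtab = make_gradient_table(spec.n_directions, spec.bval, spec.n_b0, seed=spec.seed)
    bundle = truth.bundle_labels.data > 0
    pics = truth.pics_mask.data > 0

    lam_par = np.where(bundle, spec.lambda_par, spec.lambda_iso)
    lam_perp = np.where(bundle, spec.lambda_perp, spec.lambda_iso)
    scale = np.where(pics, spec.pics_lambda_scale, 1.0)
    lam_par = lam_par * scale
    lam_perp = lam_perp * scale

    # g^T D g = lam_perp + (lam_par - lam_perp) (g . v)^2
    g = gtab.bvecs  # (n, 3)
    dot = np.einsum("xyzc,nc->xyzn", direction_field, g)
    adc = lam_perp[..., None] + (lam_par - lam_perp)[..., None] * dot**2
    signal = spec.s0 * np.exp(-gtab.bvals[None, None, None, :] * adc)

    if np.isfinite(spec.snr):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5161]))
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    return DWIVolume(signal, spec.affine, gtab)


def make_phantom(spec: PhantomSpec) -> tuple[DWIVolume, PhantomTruth]:
    """Compose field rasterization and signal simulation; deterministic for a
    fixed ``spec.seed``. Returns the DWI series and the ground truth."""
    field3, truth = simulate_bundle_field(spec)
    dwi = simulate_dwi_signal(field3, truth, spec)
    return dwi, truth


def default_spec(**overrides) -> PhantomSpec:
    """The standard 5-bundle phantom used throughout tests and analyses."""
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write dwi.nii.gz (+ .bval/.bvec), truth masks, and sites.csv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dwi, truth = make_phantom(spec)
    paths = {"dwi": out / "dwi.nii.gz"}
    write_nifti(dwi, paths["dwi"])
    for key in ("bundle_labels", "capsule_mask", "pics_mask", "cortical_labels", "midline_exclusion"):
        paths[key] = out / f"{key}.nii.gz"
        write_nifti(getattr(truth, key), paths[key])
    import csv

    paths["sites"] = out / "sites.csv"
    with open(paths["sites"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x_mm", "y_mm", "z_mm", "freq_hz", "pw_us", "amp_ma"])
        for s in truth.sites:
            p = s.stim_params or {}
            w.writerow(
                [s.name, *s.position, p.get("freq_hz", ""), p.get("pw_us", ""), p.get("amp_ma", "")]
            )
    return paths
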