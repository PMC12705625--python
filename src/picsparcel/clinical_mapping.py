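"""Capsule-volume statistics and stimulation-site-to-skeleton distance
ranking — the clinical-facing summaries of the parcellation.

The packaged fixture ``data/plic_volumes.csv`` transcribes the study
cohort's manually segmented pLIC volumes (15 essential-tremor patients,
left/right, mm^3) together with demographics; disease durations are kept as
free text because two rows carry range values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import LabelVolume
from .parcellation import Skeleton
from .synthetic_phantom import StimulationSite

__all__ = [
    "VolumeRecord",
    "DistanceReport",
    "mask_volume",
    "summarize_volumes",
    "site_skeleton_distances",
    "load_sites",
    "load_cohort_volumes",
]


@dataclass(frozen=True)
class VolumeRecord:
    """Left/right capsule volume for one subject, in mm^3."""

    subject_id: str
    left_volume_mm3: float
    right_volume_mm3: float

    def __post_init__(self):
        if self.left_volume_mm3 <= 0 or self.right_volume_mm3 <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class DistanceReport:
    """Per-region minimum distance (mm) from one site to skeleton points,
    plus the ascending-distance ranking."""

    site_name: str
    distances: dict[str, float]
    ranking: list[str]
    ties: list[tuple[str, str]]


def mask_volume(mask: LabelVolume, label: int) -> float:
    """Volume of one label in mm^3: voxel count x |det| of the affine's 3x3
    block. An absent label yields 0 with a warning."""
    n = int((mask.data == label).sum())
    if n == 0:
        import logging

        logging.getLogger("picsparcel").warning("label %d not present in mask", label)
    return n * mask.affine.voxel_volume


def summarize_volumes(records: list[VolumeRecord]) -> dict[str, float]:
    """Per-side mean and sample SD (n-1), plus the paired mean difference
    (left - right), reported descriptively."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    left = np.array([r.left_volume_mm3 for r in records], dtype=float)
    right = np.array([r.right_volume_mm3 for r in records], dtype=float)
    return {
        "n": len(records),
        "left_mean_mm3": float(left.mean()),
        "left_sd_mm3": float(left.std(ddof=1)),
        "right_mean_mm3": float(right.mean()),
        "right_sd_mm3": float(right.std(ddof=1)),
        "paired_mean_difference_mm3": float((left - right).mean()),
        "paired_sd_difference_mm3": float((left - right).std(ddof=1)),
    }


def load_cohort_volumes(path: str | Path | None = None) -> list[VolumeRecord]:
    """Load the packaged (or a user-supplied) cohort volume table."""
    if path is None:
        source = resources.files("picsparcel.data").joinpath("plic_volumes.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        VolumeRecord(
            str(row["subject"]),
            float(row["left_plic_volume_mm3"]),
            float(row["right_plic_volume_mm3"]),
        )
        for _, row in df.iterrows()
    ]


def site_skeleton_distances(
    site: StimulationSite, skeletons: list[Skeleton]
) -> DistanceReport:
    """Minimum Euclidean distance from the site to each territory's skeleton
    point set; territories ranked by ascending distance, exact ties flagged."""
    if not skeletons:
        raise ValueError("no skeletons supplied")
    p = np.asarray(site.position, dtype=float)
    distances = {
        s.region_name: float(np.min(np.linalg.norm(s.xyz - p, axis=1)))
        for s in skeletons
    }
    ranking = sorted(distances, key=lambda n: (distances[n], n))
    ties = [
        (a, b)
        for i, a in enumerate(ranking)
        for b in ranking[i + 1 :]
        if distances[a] == distances[b]
    ]
    return DistanceReport(site.name, distances, ranking, ties)


def load_sites(csv_path: str | Path) -> list[StimulationSite]:
    """Read stimulation sites from CSV (header: name,x_mm,y_mm,z_mm with
    optional freq_hz,pw_us,amp_ma columns)."""
    sites = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "x_mm", "y_mm", "z_mm"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"sites CSV must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                pos = (float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"]))
            except (TypeError, ValueError) as err:
                raise ValueError(f"row {i}: bad or missing coordinate") from err
            stim = None
            if row.get("freq_hz") not in (None, ""):
                stim = {
                    "freq_hz": float(row["freq_hz"]),
                    "pw_us": float(row.get("pw_us") or "nan"),
                    "amp_ma": float(row.get("amp_ma") or "nan"),
                }
            sites.append(StimulationSite(row["name"], pos, stim_params=stim))
    return sites
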