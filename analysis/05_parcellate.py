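"""Probabilistic parcellation of the capsule slab.

One probtrackx-style run per cortical territory (territory ROI as seed, the
capsule slab as waypoint, every other territory plus the midline wall as
avoidance) yields a connectivity map; each map becomes an 80%-of-max parcel
and a per-slice center-of-mass skeleton; skeleton mean-y positions give the
anterior-posterior ordering, which is compared against the phantom's
ground-truth somatotopic ranks.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from picsparcel import parcellation as pc
from picsparcel import synthetic_phantom as sp
from picsparcel.io_formats import LabelVolume, write_nifti
from picsparcel.pipeline import parcellate_phantom

OUT = Path("results/parcellation")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sp.default_spec(n_directions=30, seed=0)
    truth, conn_maps, parcels, skeletons, ordering, _ = parcellate_phantom(
        spec, n_samples=500, track_seed=0
    )

    for name, conn in conn_maps.items():
        write_nifti(
            LabelVolume(conn.counts.astype(np.int64), conn.affine),
            OUT / f"conn_{name}.nii.gz",
        )
    for name, parcel in parcels.items():
        write_nifti(parcel.mask, OUT / f"parcel_{name}.nii.gz")
    rows = [
        {"region": s.region_name, "k": p[0], "x": p[1], "y": p[2], "z": p[3], "weight": p[4]}
        for s in skeletons.values()
        for p in s.points
    ]
    pd.DataFrame(rows).to_csv(OUT / "skeletons.csv", index=False)

    names = list(parcels)
    dice = pc.parcel_overlap([parcels[n] for n in names])
    truth_order = sorted(truth.ap_rank, key=truth.ap_rank.get)
    payload = {
        "ranking_anterior_to_posterior": ordering.ranking,
        "scores_mean_y_mm": ordering.scores,
        "ground_truth_order": truth_order,
        "exact_recovery": ordering.ranking == truth_order,
        "dice": {"regions": names, "matrix": dice.tolist()},
    }
    with open(OUT / "ordering.json", "w") as fh:
        json.dump(payload, fh, indent=2)

    print("recovered ordering (anterior -> posterior):", ordering.ranking)
    print("ground truth:                              ", truth_order)
    print("exact recovery:", payload["exact_recovery"])
    off = dice[~np.eye(len(names), dtype=bool)]
    print(f"parcel overlap (Dice, off-diagonal): max {off.max():.3f} "
          f"— parcels are near-disjoint on this phantom")


if __name__ == "__main__":
    main()
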