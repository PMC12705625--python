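"""Somatotopic ordering recovery across seeded phantoms.

Twenty independently seeded 5-bundle phantoms (30 directions, 500 samples
per seed voxel) are parcellated end to end, noiseless and at Rician SNR 20.
Reported: the fraction of runs recovering the exact ground-truth
anterior-posterior ordering, and the mean Spearman rank correlation.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from picsparcel.pipeline import somatotopic_recovery_experiment

OUT = Path("results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-phantoms", type=int, default=20)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = {}
    for label, snr in (("noiseless", np.inf), ("snr20", 20.0)):
        res = somatotopic_recovery_experiment(
            n_phantoms=args.n_phantoms, snr=snr, seed=args.seed
        )
        results[label] = {
            "exact_recovery_fraction": res["exact_recovery_fraction"],
            "mean_spearman": res["mean_spearman"],
        }
        print(f"{label}: exact recovery {100*res['exact_recovery_fraction']:.0f}% "
              f"of {args.n_phantoms} runs, mean Spearman {res['mean_spearman']:.3f}")
    with open(OUT / "recovery_experiment.json", "w") as fh:
        json.dump(results, fh, indent=2)


if __name__ == "__main__":
    main()
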