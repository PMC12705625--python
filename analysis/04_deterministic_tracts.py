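"""Deterministic tractography seeded in the PICS-analog slab.

Replicates the exploratory experiment asking which cortex the PICS fibers
reach: streamlines launch from the PICS-analog mask (with the midline
exclusion wall active), and their endpoints are tallied against the
cortical territory labels. The expectation is that PICS fibers terminate
in the limb/trunk ("corticospinal") territories and nowhere else.
"""

import json
from collections import Counter
from pathlib import Path

from picsparcel import synthetic_phantom as sp
from picsparcel import tensor_model as tm
from picsparcel import tractography as trk

OUT = Path("results/deterministic")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sp.default_spec(n_directions=30, seed=0)
    dwi, truth = sp.make_phantom(spec)
    tensors = tm.fit_tensor(dwi)
    fa = tm.compute_fa(tensors)
    dirfield = tm.principal_direction(tensors)

    params = trk.DeterministicParams(n_tracts_target=500, seed=1)
    streams = trk.track_deterministic(
        dirfield, fa, truth.pics_mask, truth.midline_exclusion, params
    )
    endpoints = trk.endpoint_labels(streams, truth.cortical_labels)
    named = {
        truth.bundle_names.get(k, "outside_cortex"): v
        for k, v in sorted(endpoints.items())
    }
    status = Counter(streams.status)
    with open(OUT / "endpoints.json", "w") as fh:
        json.dump({"endpoints": named, "status": dict(status)}, fh, indent=2)

    print(f"accepted streamlines: {status['accepted']}")
    print("endpoint territories:", named)
    pics_set = set(spec.pics_bundles)
    stray = {k: v for k, v in named.items() if k not in pics_set | {"outside_cortex"}}
    if stray:
        print("WARNING: endpoints outside the PICS territories:", stray)
    else:
        print("all cortical endpoints fall in the PICS (corticospinal) territories")


if __name__ == "__main__":
    main()
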