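"""Build the default somatotopic fiber phantom and write it to disk.

The phantom stands in for a patient diffusion scan: five bundles (one per
M1-homunculus territory) cross a capsule slab at distinct anterior-posterior
offsets, with a reduced-diffusivity PICS-analog subregion and two
stimulation sites medial to the slab. Outputs land in results/phantom/.
"""

import json
from pathlib import Path

from picsparcel import synthetic_phantom as sp
from picsparcel.clinical_mapping import mask_volume

OUT = Path("results/phantom")


def main():
    spec = sp.default_spec(n_directions=30, seed=0)
    paths = sp.write_phantom(spec, OUT)
    _, truth = sp.make_phantom(spec)
    summary = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": spec.voxel_size,
        "n_volumes": spec.n_b0 + spec.n_directions,
        "capsule_volume_mm3": mask_volume(truth.capsule_mask, 1),
        "pics_volume_mm3": mask_volume(truth.pics_mask, 1),
        "bundles": {
            name: {"rank": truth.ap_rank[name]} for name in truth.ap_rank
        },
        "sites": [
            {"name": s.name, "position_mm": list(s.position)} for s in truth.sites
        ],
    }
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote {len(paths)} phantom files to {OUT}/")
    print(f"capsule slab volume: {summary['capsule_volume_mm3']:.0f} mm^3 "
          f"(same scale as a human pLIC)")
    print(f"PICS-analog volume:  {summary['pics_volume_mm3']:.0f} mm^3")


if __name__ == "__main__":
    main()
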