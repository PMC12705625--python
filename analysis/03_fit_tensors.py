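"""Fit diffusion tensors to the phantom and check recovery of the forward
model: bundle FA, principal directions, and the Otsu anisotropy threshold
the deterministic tracker scales its stopping rule from.
"""

import json
from pathlib import Path

import numpy as np

from picsparcel import synthetic_phantom as sp
from picsparcel import tensor_model as tm
from picsparcel.io_formats import ScalarVolume, write_nifti

OUT = Path("results/tensor")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = sp.default_spec(n_directions=30, seed=0)
    dwi, truth = sp.make_phantom(spec)
    tensors = tm.fit_tensor(dwi)
    fa = tm.compute_fa(tensors)
    write_nifti(ScalarVolume(fa.data, fa.affine), OUT / "fa.nii.gz")

    bundle = truth.bundle_labels.mask() & ~truth.pics_mask.mask()
    vals, _ = tensors.eigensystem()
    lam = vals[bundle]
    otsu = tm.otsu_threshold(fa)
    summary = {
        "bundle_fa_median": float(np.median(fa.data[bundle])),
        "background_fa_max": float(fa.data[~truth.bundle_labels.mask()].max()),
        "recovered_lambda_par": float(np.median(lam[:, 0])),
        "recovered_lambda_perp": float(np.median(lam[:, 1:])),
        "otsu_threshold": otsu,
    }
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"bundle FA (median): {summary['bundle_fa_median']:.4f} "
          f"(closed-form value for lambda=(1.7,0.3,0.3)e-3 is 0.7990)")
    print(f"recovered diffusivities: lambda_par={summary['recovered_lambda_par']:.2e}, "
          f"lambda_perp={summary['recovered_lambda_perp']:.2e} mm^2/s")
    print(f"Otsu FA threshold: {otsu:.4f} (separates bundle from background)")


if __name__ == "__main__":
    main()
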