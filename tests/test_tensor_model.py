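"""Tensor fit recovery, FA, principal directions, and the Otsu threshold."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picsparcel import synthetic_phantom as sp
from picsparcel import tensor_model as tm
from picsparcel.io_formats import Affine, DWIVolume

AFF = Affine(np.eye(4))


def _single_voxel_dwi(D, s0=1000.0, n_dirs=30, bval=1500.0, snr=np.inf, seed=0):
    """Forward-simulate one voxel under tensor D (3x3, mm^2/s)."""
    gtab = sp.make_gradient_table(n_dirs, bval, 3, seed=seed)
    adc = np.einsum("ni,ij,nj->n", gtab.bvecs, D, gtab.bvecs)
    S = s0 * np.exp(-gtab.bvals * adc)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        S = np.sqrt((S + rng.normal(0, sigma, S.shape)) ** 2 + rng.normal(0, sigma, S.shape) ** 2)
    return DWIVolume(S[None, None, None, :], AFF, gtab)


def _diag(l1, l2, l3):
    return np.diag([l1, l2, l3])


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestFitTensor:
    def test_isotropic_recovery(self):
        dwi = _single_voxel_dwi(_diag(1e-3, 1e-3, 1e-3))
        tv = tm.fit_tensor(dwi)
        D = tv.as_matrices()[0, 0, 0]
        assert np.abs(D - 1e-3 * np.eye(3)).max() < 1e-9
        assert tm.compute_fa(tv).data[0, 0, 0] < 1e-6

    def test_single_fiber_recovery_noiseless(self):
        dwi = _single_voxel_dwi(_diag(0.3e-3, 0.3e-3, 1.7e-3))
        tv = tm.fit_tensor(dwi)
        vals, _ = tv.eigensystem()
        lam = vals[0, 0, 0]
        assert np.abs(lam - [1.7e-3, 0.3e-3, 0.3e-3]).max() / 1.7e-3 < 1e-6
        v1 = tm.principal_direction(tv)[0, 0, 0]
        assert abs(abs(v1[2]) - 1.0) < 1e-6  # +/- z

    def test_all_zero_signal_degenerate(self):
        gtab = sp.make_gradient_table(30, 1500, 3, seed=0)
        dwi = DWIVolume(np.zeros((1, 1, 1, 33)), AFF, gtab)
        tv = tm.fit_tensor(dwi)
        assert tm.compute_fa(tv).data[0, 0, 0] == 0.0
        assert np.allclose(tm.principal_direction(tv)[0, 0, 0], 0.0)

    def test_too_few_directions_rejected(self):
        gtab = sp.make_gradient_table(6, 1500, 1, seed=0)
        few = DWIVolume(
            np.ones((1, 1, 1, 5)),
            AFF,
            type(gtab)(gtab.bvals[:5], gtab.bvecs[:5]),
        )
        with pytest.raises(ValueError):
            tm.fit_tensor(few)

    def test_noisy_recovery_within_10pct_at_snr20(self):
        """Median relative eigenvalue error < 10% over repeated noisy voxels."""
        errs = []
        for seed in range(40):
            dwi = _single_voxel_dwi(
                _diag(0.3e-3, 0.3e-3, 1.7e-3), snr=20.0, seed=seed
            )
            vals, _ = tm.fit_tensor(dwi).eigensystem()
            errs.append(abs(vals[0, 0, 0, 0] - 1.7e-3) / 1.7e-3)
        assert np.median(errs) < 0.10


class TestFA:
    @pytest.mark.parametrize(
        "lams,expected",
        [((1.0, 1.0, 1.0), 0.0), ((1.0, 1e-12, 1e-12), 1.0)],
    )
    def test_limits(self, lams, expected):
        c = np.array([lams[0], 0, 0, lams[1], 0, lams[2]])[None, None, None, :]
        tv = tm.TensorVolume(c, None, AFF)
        assert tm.compute_fa(tv).data[0, 0, 0] == pytest.approx(expected, abs=1e-6)

    def test_single_fiber_spot_value(self):
        """lambda = (1.7, 0.3, 0.3) x 1e-3 gives FA 0.7990 by the closed formula."""
        l1, l2, l3 = 1.7e-3, 0.3e-3, 0.3e-3
        hand = (
            np.sqrt(0.5)
            * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
            / np.sqrt(l1**2 + l2**2 + l3**2)
        )
        c = np.array([l1, 0, 0, l2, 0, l3])[None, None, None, :]
        tv = tm.TensorVolume(c, None, AFF)
        fa = tm.compute_fa(tv).data[0, 0, 0]
        assert fa == pytest.approx(hand, abs=1e-12)
        assert fa == pytest.approx(0.7990, abs=5e-4)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        R = _random_rotation(seed)
        D = _diag(1.7e-3, 0.5e-3, 0.2e-3)
        Dr = R @ D @ R.T
        def fa_of(M):
            c = np.array(
                [M[0, 0], M[0, 1], M[0, 2], M[1, 1], M[1, 2], M[2, 2]]
            )[None, None, None, :]
            return tm.compute_fa(tm.TensorVolume(c, None, AFF)).data[0, 0, 0]
        assert abs(fa_of(D) - fa_of(Dr)) < 1e-9


class TestPrincipalDirection:
    def test_rotation_equivariance(self):
        D = _diag(1.7e-3, 0.3e-3, 0.3e-3)
        for seed in range(5):
            R = _random_rotation(seed)
            Dr = R @ D @ R.T
            c = np.array(
                [Dr[0, 0], Dr[0, 1], Dr[0, 2], Dr[1, 1], Dr[1, 2], Dr[2, 2]]
            )[None, None, None, :]
            v = tm.principal_direction(tm.TensorVolume(c, None, AFF))[0, 0, 0]
            expected = R @ np.array([1.0, 0, 0])
            assert min(
                np.abs(v - expected).max(), np.abs(v + expected).max()
            ) < 1e-9


def _brute_force_otsu(data, nbins=256):
    """Independent oracle: exhaustive search over the histogram's bin edges,
    in exact rational arithmetic (empty bins between the classes make the
    between-class variance exactly flat, so ties must be exact to resolve
    to the first maximizing edge)."""
    from fractions import Fraction

    counts, edges = np.histogram(data, bins=nbins, range=(0.0, float(data.max())))
    centers = [
        Fraction(float(edges[i])) + (Fraction(float(edges[i + 1])) - Fraction(float(edges[i]))) / 2
        for i in range(nbins)
    ]
    counts = [int(c) for c in counts]
    best, best_t = Fraction(-1), edges[1]
    for k in range(nbins - 1):
        w0 = sum(counts[: k + 1])
        w1 = sum(counts[k + 1 :])
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(c * x for c, x in zip(counts[: k + 1], centers[: k + 1])) / w0
        m1 = sum(c * x for c, x in zip(counts[k + 1 :], centers[k + 1 :])) / w1
        between = w0 * w1 * (m0 - m1) ** 2
        if between > best:
            best, best_t = between, edges[k + 1]
    return best_t


class TestOtsu:
    def _fa_map(self, values):
        return tm.FAMap(np.asarray(values, float).reshape(-1, 1, 1), AFF)

    def test_bimodal_threshold_between_modes(self):
        fa = self._fa_map([0.1] * 50 + [0.8] * 50)
        t = tm.otsu_threshold(fa)
        assert 0.1 < t < 0.8

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate(
            [rng.beta(2, 8, 300), rng.beta(8, 2, 120)]
        )
        fa = self._fa_map(vals)
        assert tm.otsu_threshold(fa) == pytest.approx(
            _brute_force_otsu(vals), abs=1e-12
        )

    def test_close_to_skimage(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.beta(2, 8, 300), rng.beta(8, 2, 120)])
        mine = tm.otsu_threshold(self._fa_map(vals))
        ref = threshold_otsu(vals, nbins=256)
        bin_width = vals.max() / 256
        assert abs(mine - ref) <= 2 * bin_width

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            tm.otsu_threshold(self._fa_map([0.5] * 10))

    def test_separates_phantom_bundle_from_background(self, phantom_fit, default_phantom):
        _, fa, _ = phantom_fit
        _, _, truth = default_phantom
        t = tm.otsu_threshold(fa)
        inside = truth.bundle_labels.mask()
        assert (fa.data[inside] > t).mean() > 0.99
        assert (fa.data[~inside] < t).mean() > 0.99


class TestOnPhantom:
    def test_forward_fit_recovery_noiseless(self, phantom_fit, default_phantom):
        tensors, _, _ = phantom_fit
        _, _, truth = default_phantom
        sel = truth.bundle_labels.mask() & ~truth.pics_mask.mask()
        vals, _ = tensors.eigensystem()
        lam = vals[sel]
        assert np.abs(lam[:, 0] - 1.7e-3).max() / 1.7e-3 < 1e-6
        assert np.abs(lam[:, 1:] - 0.3e-3).max() / 0.3e-3 < 1e-6
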