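"""Tracker oracles: straight-field exactness, bend termination, waypoint and
avoidance logic, loop checking, determinism, and convergence."""

import numpy as np
import pytest

from picsparcel import tractography as trk
from picsparcel.io_formats import Affine, LabelVolume
from picsparcel.tensor_model import FAMap

AFF = Affine(np.eye(4))


def _label(mask, affine=AFF, name="roi"):
    return LabelVolume(mask.astype(np.int32), affine, {1: name} if mask.any() else {})


def _fa(shape, value=0.8, affine=AFF):
    return FAMap(np.full(shape, float(value)), affine)


def _zfield(shape):
    f = np.zeros(shape + (3,))
    f[..., 2] = 1.0
    return f


class TestDeterministic:
    def test_straight_line_in_constant_field(self, uniform_z_setup):
        field, fa, seeds = uniform_z_setup
        params = trk.DeterministicParams(n_tracts_target=5, step=1.0, seed=1)
        streams = trk.track_deterministic(field, fa, seeds, None, params)
        acc = streams.accepted()
        assert len(acc) == 5
        for line in acc:
            # x, y frozen; z spans the volume
            assert np.ptp(line[:, 0]) < 1e-9 and np.ptp(line[:, 1]) < 1e-9
            assert line[:, 2].min() < 1.0 and line[:, 2].max() > 9.0
            spacing = np.linalg.norm(np.diff(line, axis=0), axis=1)
            assert np.abs(spacing - 1.0).max() < 1e-6

    def test_bend_beyond_angle_threshold_terminates(self):
        """A 95-degree bend stops tracking when the angular threshold is 45."""
        shape = (5, 5, 21)
        field = _zfield(shape)
        # beyond z=10 the field turns 95 degrees away from +z (toward -x)
        turned = np.array([-np.sin(np.deg2rad(95.0)), 0.0, np.cos(np.deg2rad(95.0))])
        field[:, :, 11:, :] = turned
        fa = _fa(shape)
        seeds = np.zeros(shape, dtype=np.int32)
        seeds[2, 2, 2] = 1
        params = trk.DeterministicParams(
            angle_range_deg=(45.0, 45.0), n_tracts_target=3, step=1.0, seed=0
        )
        streams = trk.track_deterministic(field, fa, _label(seeds), None, params)
        for line in streams.streamlines:
            assert line[:, 2].max() < 12.5  # stopped at the bend, not the face

    def test_zero_fa_seed_yields_no_tracts(self, uniform_z_setup):
        field, _, seeds = uniform_z_setup
        fa = _fa((11, 11, 11), value=0.0)
        fa.data[0, 0, 0] = 0.5  # keep Otsu defined
        params = trk.DeterministicParams(
            n_tracts_target=5, step=1.0, seed=0, max_seed_attempts_factor=3
        )
        streams = trk.track_deterministic(field, fa, seeds, None, params)
        assert len(streams.accepted()) == 0

    def test_fixed_seed_reproducible(self, uniform_z_setup):
        field, fa, seeds = uniform_z_setup
        params = trk.DeterministicParams(n_tracts_target=10, step=1.0, seed=7)
        a = trk.track_deterministic(field, fa, seeds, None, params)
        b = trk.track_deterministic(field, fa, seeds, None, params)
        assert len(a.streamlines) == len(b.streamlines)
        for la, lb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(la, lb)
        assert np.array_equal(a.fa_thresholds, b.fa_thresholds)

    def test_exclusion_discards_whole_pathway(self, uniform_z_setup):
        field, fa, seeds = uniform_z_setup
        wall = np.zeros((11, 11, 11), dtype=np.int32)
        wall[5, 5, 9] = 1  # on the path, above the seed
        params = trk.DeterministicParams(n_tracts_target=5, step=1.0, seed=1,
                                         max_seed_attempts_factor=2)
        streams = trk.track_deterministic(field, fa, seeds, _label(wall), params)
        assert len(streams.accepted()) == 0
        assert all(s == "rejected_exclusion" for s in streams.status)


class TestProbabilistic:
    def _setup(self, shape=(7, 7, 15)):
        field = _zfield(shape)
        fa = _fa(shape)
        seeds = np.zeros(shape, dtype=np.int32)
        seeds[3, 3, 2] = 1
        way = np.zeros(shape, dtype=np.int32)
        way[3, 3, 10] = 1
        return field, fa, _label(seeds), _label(way)

    def test_zero_dispersion_counts_exactly_on_path(self):
        field, fa, seeds, way = self._setup()
        params = trk.ProbabilisticParams(
            n_samples=20, dispersion_kappa0=np.inf, seed=0, max_steps_per_sample=100
        )
        conn = trk.track_probabilistic(field, fa, seeds, way, (), params)
        col = conn.counts[3, 3, :]
        assert conn.counts.sum() == col.sum()  # nothing off the seed column
        assert col.max() == 20  # n_samples x 1 seed voxel
        assert (col[1:14] == 20).all()

    def test_waypoint_off_path_zeroes_map(self):
        field, fa, seeds, _ = self._setup()
        way = np.zeros((7, 7, 15), dtype=np.int32)
        way[0, 0, 7] = 1
        params = trk.ProbabilisticParams(
            n_samples=10, dispersion_kappa0=np.inf, seed=0, max_steps_per_sample=100
        )
        conn = trk.track_probabilistic(field, fa, seeds, _label(way), (), params)
        assert conn.counts.sum() == 0

    def test_counts_bounded_by_total_samples(self):
        field, fa, seeds, way = self._setup()
        for kappa0 in (2.0, 30.0, np.inf):
            params = trk.ProbabilisticParams(
                n_samples=10, dispersion_kappa0=kappa0, seed=3, max_steps_per_sample=60
            )
            conn = trk.track_probabilistic(field, fa, seeds, way, (), params)
            assert conn.counts.max() <= conn.n_samples_total

    def test_avoid_mask_discards_samples_exhaustively(self):
        """With the avoidance mask covering the only path, every sample dies."""
        field, fa, seeds, way = self._setup()
        avoid = np.zeros((7, 7, 15), dtype=np.int32)
        avoid[3, 3, 6] = 1  # between seed and waypoint
        params = trk.ProbabilisticParams(
            n_samples=10, dispersion_kappa0=np.inf, seed=0, max_steps_per_sample=100
        )
        conn = trk.track_probabilistic(
            field, fa, seeds, way, (_label(avoid),), params
        )
        assert conn.counts.sum() == 0

    def test_seed_overlapping_avoid_rejected(self):
        field, fa, seeds, way = self._setup()
        with pytest.raises(ValueError, match="overlap"):
            trk.track_probabilistic(
                field, fa, seeds, way, (seeds,), trk.ProbabilisticParams(n_samples=1)
            )

    def test_empty_waypoint_rejected(self):
        field, fa, seeds, _ = self._setup()
        empty = _label(np.zeros((7, 7, 15)))
        with pytest.raises(ValueError, match="waypoint"):
            trk.track_probabilistic(field, fa, seeds, empty, (),
                                    trk.ProbabilisticParams(n_samples=1))

    def test_fixed_seed_reproducible(self):
        field, fa, seeds, way = self._setup()
        params = trk.ProbabilisticParams(n_samples=25, seed=11, max_steps_per_sample=60)
        a = trk.track_probabilistic(field, fa, seeds, way, (), params)
        b = trk.track_probabilistic(field, fa, seeds, way, (), params)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_dispersion_matches_deterministic_path(self, uniform_z_setup):
        """From the same launch point, kappa0 = inf probabilistic stepping
        traces the deterministic path to within half a step on a smooth field."""
        field, fa, _ = uniform_z_setup
        rng = np.random.default_rng(0)
        start = np.array([[5.0, 5.0, 5.0]])
        d0 = np.array([[0.0, 0.0, 1.0]])
        det_pts = trk._propagate_deterministic(
            field, fa.data, AFF, start, d0,
            np.array([0.1]), np.array([0.0]), 1.0, 50,
        )[0]
        det_line = np.vstack([start, det_pts])
        params = trk.ProbabilisticParams(
            n_samples=1, dispersion_kappa0=np.inf, step=0.5, max_steps_per_sample=50
        )
        pairs = trk._propagate_probabilistic(
            field, fa.data, AFF, start, d0, params, rng
        )
        shape = (11, 11, 11)
        for lin in pairs[:, 1]:
            v = np.array(np.unravel_index(int(lin), shape), dtype=float)
            d = np.linalg.norm(det_line - v, axis=1).min()
            assert d <= 0.5 + 1e-9

    def test_loop_ledger_flags_revisits_only(self):
        """Loop checking fires on re-entering a previously *left* voxel, not
        on consecutive steps inside the same voxel."""
        ledger = trk._LoopLedger(2, cap=2)  # tiny cap exercises growth
        rows = np.array([0, 1])
        assert not ledger.visit(rows, np.array([5, 7])).any()
        # sample 0 moves on, sample 1 stays put
        assert not ledger.visit(rows, np.array([6, 7])).any()
        # sample 0 returns to voxel 5 -> loop; sample 1 moves to a new voxel
        looped = ledger.visit(rows, np.array([5, 8]))
        assert looped.tolist() == [True, False]
        # growth beyond the initial cap keeps history intact
        assert not ledger.visit(np.array([1]), np.array([9])).any()
        assert ledger.visit(np.array([1]), np.array([7])).tolist() == [True]


class TestEndpointLabels:
    def test_counts_terminal_labels(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[4, 4, 4] = 3
        lv = LabelVolume(labels, AFF, {3: "target"})
        line = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0], [4.0, 4.0, 4.0]])
        streams = trk.StreamlineSet([line], ["accepted"], 1.0)
        assert trk.endpoint_labels(streams, lv) == {0: 1, 3: 1}

    def test_empty_set(self):
        lv = LabelVolume(np.zeros((2, 2, 2), dtype=np.int32), AFF)
        streams = trk.StreamlineSet([], [], 1.0)
        assert trk.endpoint_labels(streams, lv) == {}

    def test_phantom_pics_fibers_reach_motor_cortex(
        self, default_phantom, phantom_fit
    ):
        """Tracts seeded in the PICS-analog slab end in the limb/trunk
        ("corticospinal") cortical territories, not the oral ones."""
        spec, _, truth = default_phantom
        _, fa, dirfield = phantom_fit
        params = trk.DeterministicParams(n_tracts_target=100, seed=4)
        streams = trk.track_deterministic(
            dirfield, fa, truth.pics_mask, truth.midline_exclusion, params
        )
        counts = trk.endpoint_labels(streams, truth.cortical_labels)
        motor = {
            lab
            for lab, name in truth.bundle_names.items()
            if name in spec.pics_bundles
        }
        hit = sum(v for k, v in counts.items() if k in motor)
        nonmotor = sum(v for k, v in counts.items() if k not in motor and k != 0)
        assert hit > 0
        assert nonmotor == 0


class TestMidlineExclusion:
    def test_full_height_wall_when_scp_at_bottom(self):
        aff = Affine(np.diag([1.0, 1.0, 1.0, 1.0]))
        m = aff.matrix.copy()
        m[:3, 3] = [-5.0, -5.0, -5.0]
        aff = Affine(m)
        wall = trk.midline_exclusion_mask((11, 11, 11), aff, scp_z=-5.5)
        assert wall.data[5].sum() == 11 * 11
        assert wall.data.sum() == 11 * 11

    def test_empty_when_scp_at_top(self):
        m = np.eye(4)
        m[:3, 3] = [-5.0, -5.0, -5.0]
        wall = trk.midline_exclusion_mask((11, 11, 11), Affine(m), scp_z=5.5)
        assert wall.data.sum() == 0

    def test_streamline_crossing_above_scp_rejected_below_accepted(self):
        m = np.eye(4)
        m[:3, 3] = [-5.0, -5.0, -5.0]
        aff = Affine(m)
        wall = trk.midline_exclusion_mask((11, 11, 11), aff, scp_z=0.0)
        shape = (11, 11, 11)
        field = np.zeros(shape + (3,))
        field[..., 0] = 1.0  # tracks run along x, crossing the midline
        fa = FAMap(np.full(shape, 0.8), aff)
        high = np.zeros(shape, dtype=np.int32)
        high[2, 5, 9] = 1  # z = +4: wall present
        low = np.zeros(shape, dtype=np.int32)
        low[2, 5, 1] = 1  # z = -4: below the wall opening
        params = trk.DeterministicParams(n_tracts_target=5, step=1.0, seed=0,
                                         max_seed_attempts_factor=2)
        blocked = trk.track_deterministic(
            field, fa, LabelVolume(high, aff, {1: "s"}), wall, params
        )
        passed = trk.track_deterministic(
            field, fa, LabelVolume(low, aff, {1: "s"}), wall, params
        )
        assert len(blocked.accepted()) == 0
        assert len(passed.accepted()) > 0


def test_connectivity_converges_across_seeds(default_phantom, phantom_fit):
    """Two independent-seed probabilistic maps of the same territory agree
    (in-capsule voxelwise correlation > 0.95 at 500 samples/voxel)."""
    spec, _, truth = default_phantom
    _, fa, dirfield = phantom_fit
    lab = 3  # upper limb
    seed_roi = LabelVolume(
        (truth.cortical_labels.data == lab).astype(np.int32),
        truth.cortical_labels.affine, {1: "roi"},
    )
    maps = []
    for s in (101, 202):
        params = trk.ProbabilisticParams(n_samples=500, seed=s, max_steps_per_sample=400)
        maps.append(
            trk.track_probabilistic(
                dirfield, fa, seed_roi, truth.capsule_mask, (), params
            )
        )
    cap = truth.capsule_mask.mask()
    a, b = maps[0].counts[cap].astype(float), maps[1].counts[cap].astype(float)
    r = np.corrcoef(a, b)[0, 1]
    assert r > 0.95
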