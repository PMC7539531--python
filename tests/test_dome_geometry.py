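import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezokit import (
    FittingError,
    MembraneSpec,
    Trajectory,
    assign_leaflets,
    dome_depth,
    dome_depth_series,
    fit_to_reference,
    generate_dome_bilayer,
    height_map,
)
from piezokit.leaflet_assign import LeafletPartition
from scipy.spatial.transform import Rotation

from conftest import make_frame


# ---------------------------------------------------------------------------
# dome_depth
# ---------------------------------------------------------------------------

class TestDomeDepth:
    def test_constant_leaflet_has_zero_depth(self):
        r = dome_depth(np.full(20, 5.0))
        assert r.surface_level == 5.0
        assert r.bottom_z == 5.0
        assert r.depth == 0.0

    def test_tied_top_values_inclusive_percentile(self):
        zs = np.array([10.0] * 9 + [4.0])
        r = dome_depth(zs)
        assert r.surface_level == 10.0
        assert r.bottom_z == 4.0
        assert r.depth == 6.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            dome_depth([1.0])

    def test_synthetic_dome_recovers_amplitude(self):
        spec = MembraneSpec(particles_per_leaflet=2000, box_xy=(40.0, 40.0),
                            dome_amplitude=6.0, dome_sigma=5.0, noise_sd=0.1,
                            seed=17)
        traj, truth = generate_dome_bilayer(spec)
        fr = traj.frames[0]
        for ids in (truth.upper_ids, truth.lower_ids):
            r = dome_depth(fr.positions[ids, 2])
            assert r.depth == pytest.approx(6.0, abs=0.3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(0)
        zs = rng.normal(0, 2, size=50)
        base = dome_depth(zs).depth
        assert dome_depth(zs + shift).depth == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert dome_depth(zs * scale).depth == pytest.approx(base * scale, rel=1e-9)


# ---------------------------------------------------------------------------
# fit_to_reference
# ---------------------------------------------------------------------------

def _traj_with_reference(positions, frame_positions, names):
    ref = make_frame(positions, names=names)
    frames = [make_frame(fp, names=names, frame_index=i)
              for i, fp in enumerate(frame_positions)]
    return Trajectory(frames=frames, reference=ref)


class TestFitToReference:
    @pytest.fixture
    def ref_positions(self):
        rng = np.random.default_rng(2)
        return rng.uniform(0, 5, size=(12, 3))

    def test_identity_when_already_aligned(self, ref_positions):
        names = ["BB"] * 6 + ["PO4"] * 6
        traj = _traj_with_reference(ref_positions, [ref_positions.copy()], names)
        fitted = fit_to_reference(traj, "BB")
        np.testing.assert_allclose(fitted.frames[0].positions, ref_positions,
                                   atol=1e-9)

    def test_recovers_known_rigid_transform(self, ref_positions):
        names = ["BB"] * 6 + ["PO4"] * 6
        rot = Rotation.from_euler("xyz", [0.4, -0.2, 1.1])
        moved = rot.apply(ref_positions) + np.array([3.0, -1.0, 2.0])
        traj = _traj_with_reference(ref_positions, [moved], names)
        fitted = fit_to_reference(traj, "BB")
        rmsd = np.sqrt(((fitted.frames[0].positions - ref_positions) ** 2)
                       .sum(axis=1).mean())
        assert rmsd < 1e-6

    def test_noise_fit_never_increases_selected_rmsd(self, ref_positions):
        names = ["BB"] * 12
        rng = np.random.default_rng(9)
        noisy = ref_positions + rng.normal(0, 0.3, ref_positions.shape) \
            + np.array([1.0, 0.5, -0.7])
        traj = _traj_with_reference(ref_positions, [noisy], names)
        fitted = fit_to_reference(traj, "BB")
        pre = np.sqrt(((noisy - ref_positions) ** 2).sum(axis=1).mean())
        post = np.sqrt(((fitted.frames[0].positions - ref_positions) ** 2)
                       .sum(axis=1).mean())
        assert post <= pre + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        names = ["BB"] * 5
        traj = _traj_with_reference(line, [line.copy()], names)
        with pytest.raises(FittingError):
            fit_to_reference(traj, "BB")

    def test_too_few_selected_rejected(self):
        pos = np.random.default_rng(1).uniform(size=(5, 3))
        names = ["BB", "BB", "PO4", "PO4", "PO4"]
        traj = _traj_with_reference(pos, [pos.copy()], names)
        with pytest.raises(FittingError):
            fit_to_reference(traj, "BB")


# ---------------------------------------------------------------------------
# dome_depth_series
# ---------------------------------------------------------------------------

def _valid_partition(frame, upper_ids, lower_ids):
    return LeafletPartition(
        upper=frozenset(int(i) for i in upper_ids),
        lower=frozenset(int(i) for i in lower_ids),
        cutoff=2.0, seed_particle=int(upper_ids[0]), validated=True,
    )


def _depth_frame(depth, frame_index, n=40):
    """Constructed noise-free leaflet pair with exact per-leaflet depth."""
    xs = np.linspace(0.5, 19.5, n)
    z_up = np.full(n, 10.0)
    z_up[0] = 10.0 - depth
    z_lo = np.full(n, 2.0)
    z_lo[0] = 2.0 - depth
    pos = np.column_stack([
        np.concatenate([xs, xs]),
        np.full(2 * n, 1.0),
        np.concatenate([z_up, z_lo]),
    ])
    return make_frame(pos, frame_index=frame_index)


class TestDepthSeries:
    def test_flat_frames_zero_depth_zero_sd(self, flat_bilayer):
        traj, _ = flat_bilayer
        frames = [traj.frames[0]] * 5
        frames = [make_frame(f.positions, box=f.box, frame_index=i)
                  for i, f in enumerate(frames)]
        traj5 = Trajectory(frames=frames)
        parts = [assign_leaflets(f) for f in traj5.frames]
        results, summaries, skipped = dome_depth_series(traj5, parts)
        assert skipped == 0
        assert all(r.depth == pytest.approx(0.0, abs=1e-9) for r in results)
        for s in summaries.values():
            assert s.mean == pytest.approx(0.0, abs=1e-9)
            assert s.sd == pytest.approx(0.0, abs=1e-9)

    def test_alternating_depths_mean_and_sd(self):
        frames = [_depth_frame(d, i) for i, d in enumerate([5.0, 7.0] * 2)]
        traj = Trajectory(frames=frames)
        n = 40
        parts = [_valid_partition(f, np.arange(n), np.arange(n, 2 * n))
                 for f in frames]
        results, summaries, _ = dome_depth_series(traj, parts)
        for s in summaries.values():
            assert s.mean == pytest.approx(6.0)
            assert s.sd == pytest.approx(np.std([5, 7, 5, 7], ddof=1))

    def test_degenerate_frames_skipped(self):
        frames = [_depth_frame(5.0, i) for i in range(5)]
        traj = Trajectory(frames=frames)
        n = 40
        parts = [_valid_partition(f, np.arange(n), np.arange(n, 2 * n))
                 for f in frames]
        parts[2] = LeafletPartition(
            upper=parts[2].upper | parts[2].lower, lower=frozenset(),
            cutoff=2.0, seed_particle=0, validated=False,
            degenerate_reason="merged",
        )
        results, summaries, skipped = dome_depth_series(traj, parts)
        assert skipped == 1
        assert all(s.n_frames == 4 for s in summaries.values())

    def test_all_degenerate_is_error(self):
        frame = _depth_frame(5.0, 0)
        traj = Trajectory(frames=[frame])
        bad = LeafletPartition(upper=frozenset(range(80)), lower=frozenset(),
                               cutoff=2.0, seed_particle=0, validated=False,
                               degenerate_reason="merged")
        with pytest.raises(ValueError):
            dome_depth_series(traj, [bad])


# ---------------------------------------------------------------------------
# height_map
# ---------------------------------------------------------------------------

class TestHeightMap:
    def test_flat_leaflet_constant_map(self, flat_bilayer):
        traj, truth = flat_bilayer
        hm = height_map(traj, truth.upper_ids, n_bins=10)
        occupied = hm.mean_z[~hm.missing]
        assert occupied.size > 0
        assert np.allclose(occupied, occupied[0])

    def test_two_particles_two_bins_others_missing(self):
        pos = np.array([[0.5, 0.5, 1.0], [9.5, 9.5, 3.0]])
        frame = make_frame(pos, box=np.array([10.0, 10.0, 10.0]))
        hm = height_map(Trajectory(frames=[frame]), [0, 1], n_bins=5)
        assert hm.mean_z[0, 0] == 1.0
        assert hm.mean_z[4, 4] == 3.0
        assert hm.missing.sum() == 23

    def test_bin_averaged_across_contributing_frames(self):
        f0 = make_frame([[0.5, 0.5, 2.0]], box=np.array([10.0, 10.0, 10.0]))
        f1 = make_frame([[0.5, 0.5, 4.0]], box=np.array([10.0, 10.0, 10.0]),
                        frame_index=1)
        hm = height_map(Trajectory(frames=[f0, f1]), [0], n_bins=5)
        assert hm.mean_z[0, 0] == 3.0
        assert hm.frames_counted[0, 0] == 2

    def test_invalid_bins(self, flat_bilayer):
        traj, truth = flat_bilayer
        with pytest.raises(ValueError):
            height_map(traj, truth.upper_ids, n_bins=0)

    def test_dome_fixture_minimum_at_center_and_relief(self, dome_bilayer):
        traj, truth = dome_bilayer
        hm = height_map(traj, truth.upper_ids, n_bins=75)
        i, j = hm.argmin_bin()
        cx, cy = truth.dome_center
        x_center = 0.5 * (hm.bin_edges_x[i] + hm.bin_edges_x[i + 1])
        y_center = 0.5 * (hm.bin_edges_y[j] + hm.bin_edges_y[j + 1])
        bin_w = hm.bin_edges_x[1] - hm.bin_edges_x[0]
        assert abs(x_center - cx) <= bin_w
        assert abs(y_center - cy) <= bin_w
        assert hm.relief() == pytest.approx(truth.true_depth, rel=0.10)
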