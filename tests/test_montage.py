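"""Trial trimming, windowing, grid projection, interpolation and stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegcube as ec
from eegcube.datatypes import FrameMap
from eegcube.montage import bicubic_weight_matrix, get_renderer, _keys_kernel


def make_trial(seconds=63.0, fs=128.0, n_channels=32, seed=0, **kw):
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_channels, int(seconds * fs)))
    return ec.RawTrial(samples=samples, sampling_rate=fs,
                       valence_rating=6.0, arousal_rating=3.0, **kw)


class TestMontageGrid:
    def test_deap_layout_is_valid(self, deap_montage):
        assert deap_montage.grid_shape == (9, 9)
        assert deap_montage.n_channels == 32
        cells = {tuple(c) for c in deap_montage.cells}
        assert len(cells) == 32  # all distinct
        assert all(0 <= r < 9 and 0 <= c < 9 for r, c in cells)

    def test_midline_channels_sit_in_center_column(self, deap_montage):
        for ch in ("Fz", "Cz", "Pz", "Oz"):
            assert deap_montage.assignments[ch][1] == 4

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="same cell"):
            ec.MontageGrid(grid_shape=(9, 9),
                           assignments={"A": (0, 0), "B": (0, 0)},
                           channel_order=["A", "B"])


class TestTrimAndSegment:
    def test_deap_trim_keeps_last_60_seconds(self):
        trial = make_trial(63.0)
        trimmed = ec.trim_trial(trial, 3.0)
        assert trimmed.n_samples == 7680  # 60 s x 128 Hz
        np.testing.assert_array_equal(trimmed.samples, trial.samples[:, 384:])
        assert trimmed.valence_rating == trial.valence_rating

    def test_zero_trim_is_identity(self):
        trial = make_trial(2.0)
        out = ec.trim_trial(trial, 0.0)
        np.testing.assert_array_equal(out.samples, trial.samples)

    def test_trim_longer_than_trial_errors_with_lengths(self):
        trial = make_trial(2.0)
        with pytest.raises(ValueError, match="256"):
            ec.trim_trial(trial, 4.0)

    @pytest.mark.parametrize("n_samples,expected", [(7680, 60), (128, 1), (200, 1), (100, 0)])
    def test_window_counts_follow_floor_rule(self, n_samples, expected):
        trial = make_trial(n_samples / 128.0)
        segments = ec.segment_windows(trial, 1.0)
        assert len(segments) == expected
        for seg in segments:
            assert seg.shape == (32, 128)

    def test_segments_are_contiguous_and_ordered(self):
        trial = make_trial(3.0)
        segments = ec.segment_windows(trial, 1.0)
        np.testing.assert_array_equal(np.hstack(segments), trial.samples)

    @given(n_windows=st.integers(0, 5), extra=st.integers(0, 127))
    @settings(max_examples=20, deadline=None)
    def test_floor_rule_property(self, n_windows, extra):
        n = n_windows * 128 + extra
        if n == 0:
            return
        trial = make_trial(n / 128.0)
        assert len(ec.segment_windows(trial, 1.0)) == n_windows


class TestProjectToGrid:
    def test_occupancy_is_32_of_81(self, deap_montage):
        frame = ec.project_to_grid(np.arange(32.0), deap_montage)
        assert frame.occupancy.sum() == 32
        assert np.isnan(frame.values[~frame.occupancy]).all()
        assert (~frame.occupancy).sum() == 49

    def test_one_hot_lands_on_assigned_cell(self, deap_montage):
        v = np.zeros(32)
        v[0] = 1.0
        frame = ec.project_to_grid(v, deap_montage)
        r, c = deap_montage.assignments[deap_montage.channel_order[0]]
        assert frame.values[r, c] == 1.0
        occupied = frame.values[frame.occupancy]
        assert occupied.sum() == 1.0

    def test_all_zero_input_gives_zero_occupied_cells(self, deap_montage):
        frame = ec.project_to_grid(np.zeros(32), deap_montage)
        assert (frame.values[frame.occupancy] == 0).all()

    def test_length_mismatch_names_counts(self, deap_montage):
        with pytest.raises(ValueError, match="32.*31"):
            ec.project_to_grid(np.zeros(31), deap_montage)


class TestRbfFill:
    def test_constant_field_reproduced(self, deap_montage):
        frame = ec.project_to_grid(np.full(32, 4.2), deap_montage)
        filled = ec.rbf_fill(frame, deap_montage)
        np.testing.assert_allclose(filled.values, 4.2, atol=1e-6)

    def test_planar_ramp_reproduced(self, deap_montage):
        cells = deap_montage.cells
        ramp = 1.5 * cells[:, 0] - 0.7 * cells[:, 1] + 2.0
        filled = ec.rbf_fill(ec.project_to_grid(ramp, deap_montage), deap_montage)
        rows, cols = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
        np.testing.assert_allclose(filled.values, 1.5 * rows - 0.7 * cols + 2.0, atol=1e-6)

    def test_electrode_values_unchanged(self, deap_montage):
        v = np.random.default_rng(1).standard_normal(32)
        frame = ec.project_to_grid(v, deap_montage)
        filled = ec.rbf_fill(frame, deap_montage)
        cells = deap_montage.cells
        np.testing.assert_allclose(filled.values[cells[:, 0], cells[:, 1]], v,
                                   rtol=0, atol=1e-9)
        assert filled.is_complete

    def test_collinear_nodes_rejected(self):
        values = np.full((9, 9), np.nan)
        occ = np.zeros((9, 9), dtype=bool)
        values[4, 1:4] = 1.0
        occ[4, 1:4] = True
        with pytest.raises(ValueError, match="collinear"):
            ec.rbf_fill(FrameMap(values=values, occupancy=occ))


class TestBicubicUpsample:
    def test_constant_grid_maps_to_constant(self):
        out = ec.upsample_bicubic(np.full((9, 9), 2.5), 64)
        assert out.shape == (64, 64)
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            ec.upsample_bicubic(np.zeros((9, 9)), 8)

    def test_incomplete_frame_rejected(self):
        values = np.full((9, 9), np.nan)
        values[0, 0] = 1.0
        with pytest.raises(ValueError, match="populated"):
            ec.upsample_bicubic(values, 64)

    def test_matches_direct_keys_convolution(self):
        """Oracle: evaluate the Keys kernel sum directly at each target point."""
        rng = np.random.default_rng(5)
        grid = rng.standard_normal((9, 9))
        n_src, n_dst = 9, 64

        def reflect(i):
            period = 2 * n_src - 2
            i = i % period
            return period - i if i >= n_src else i

        def interp_1d(row, s):
            base = int(np.floor(s))
            return sum(
                _keys_kernel(np.array([s - i]))[0] * row[reflect(i)]
                for i in range(base - 1, base + 3)
            )

        # separable: interpolate rows then columns
        expected = np.empty((n_dst, n_dst))
        tmp = np.empty((n_src, n_dst))
        for r in range(n_src):
            for tj in range(n_dst):
                tmp[r, tj] = interp_1d(grid[r], tj * (n_src - 1) / (n_dst - 1))
        for ti in range(n_dst):
            for tj in range(n_dst):
                expected[ti, tj] = interp_1d(tmp[:, tj], ti * (n_src - 1) / (n_dst - 1))

        out = ec.upsample_bicubic(grid, n_dst)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_weight_rows_sum_to_one(self):
        W = bicubic_weight_matrix(9, 64)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)


class TestWindowTensor:
    def test_full_size_window_shape(self, deap_montage):
        seg = np.random.default_rng(0).standard_normal((32, 128))
        wt = ec.build_window_tensor(seg, deap_montage, 64)
        assert wt.shape == (128, 64, 64)
        assert np.isfinite(wt.data).all()

    def test_time_constant_segment_gives_identical_slices(self, deap_montage):
        v = np.random.default_rng(1).standard_normal(32)
        seg = np.tile(v[:, None], (1, 8))
        wt = ec.build_window_tensor(seg, deap_montage, 16)
        for t in range(1, 8):
            np.testing.assert_array_equal(wt.data[t], wt.data[0])

    def test_permuting_time_samples_permutes_depth_slices(self, deap_montage):
        seg = np.random.default_rng(2).standard_normal((32, 8))
        wt = ec.build_window_tensor(seg, deap_montage, 16)
        perm = seg[:, ::-1].copy()
        wt2 = ec.build_window_tensor(perm, deap_montage, 16)
        np.testing.assert_array_equal(wt2.data, wt.data[::-1])

    def test_fused_renderer_matches_staged_pipeline(self, deap_montage):
        v = np.random.default_rng(3).standard_normal(32)
        staged = ec.upsample_bicubic(
            ec.rbf_fill(ec.project_to_grid(v, deap_montage), deap_montage), 16
        )
        fused = get_renderer(deap_montage, 16).render(v[:, None])[0]
        np.testing.assert_allclose(fused, staged, atol=1e-8)

    def test_pre_upsample_grid_preserves_channel_values(self, deap_montage):
        seg = np.random.default_rng(4).standard_normal((32, 4))
        grids = get_renderer(deap_montage, 16).render_grids(seg)
        cells = deap_montage.cells
        for t in range(4):
            np.testing.assert_allclose(
                grids[t, cells[:, 0], cells[:, 1]], seg[:, t], atol=1e-9
            )

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=10, deadline=None)
    def test_amplitude_scaling_equivariance(self, scale, deap_montage):
        seg = np.random.default_rng(6).standard_normal((32, 4))
        base = ec.build_window_tensor(seg, deap_montage, 16).data
        scaled = ec.build_window_tensor(scale * seg, deap_montage, 16).data
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-9)

    def test_rendering_is_bit_deterministic(self, deap_montage):
        seg = np.random.default_rng(7).standard_normal((32, 8))
        a = ec.build_window_tensor(seg, deap_montage, 16).data
        b = ec.build_window_tensor(seg.copy(), deap_montage, 16).data
        assert np.array_equal(a, b)


class TestBuildDataset:
    def test_two_deap_length_trials_yield_120_windows(self, deap_montage):
        trials = [make_trial(63.0, seed=i, trial_id=i) for i in range(2)]
        ds = ec.build_dataset(trials, deap_montage, window_seconds=1.0,
                              target_side=9, pre_stimulus_seconds=3.0)
        assert len(ds) == 120
        assert ds.tensors.shape == (120, 128, 9, 9)

    def test_empty_input_gives_empty_collection(self, deap_montage):
        ds = ec.build_dataset([], deap_montage, target_side=9)
        assert len(ds) == 0

    def test_provenance_round_trip_is_unique(self, deap_montage):
        trials = [make_trial(5.0, seed=i, trial_id=i, subject_id=1) for i in range(3)]
        ds = ec.build_dataset(trials, deap_montage, window_seconds=1.0,
                              target_side=9, pre_stimulus_seconds=3.0)
        keys = list(zip(ds.provenance.trial_id, ds.provenance.window_index))
        assert len(set(keys)) == len(ds) == 6

    def test_inconsistent_channel_counts_rejected(self, deap_montage):
        t1 = make_trial(4.0, n_channels=32)
        t2 = make_trial(4.0, n_channels=16)
        with pytest.raises(ValueError, match="channel counts"):
            ec.build_dataset([t1, t2], deap_montage, target_side=9)

    def test_labels_follow_threshold_rule(self, deap_montage):
        trial = make_trial(4.0)  # valence 6.0 (high), arousal 3.0 (low)
        ds = ec.build_dataset([trial], deap_montage, target_side=9)
        assert (ds.labels_valence == 1).all()
        assert (ds.labels_arousal == 0).all()

    def test_hdf5_round_trip(self, deap_montage, tmp_path):
        trials = [make_trial(4.0, seed=9, trial_id=0)]
        ds = ec.build_dataset([trials[0]], deap_montage, target_side=9)
        path = tmp_path / "windows.h5"
        ds.to_hdf5(path)
        back = ec.WindowDataset.from_hdf5(path)
        np.testing.assert_array_equal(back.tensors, ds.tensors)
        np.testing.assert_array_equal(back.labels_valence, ds.labels_valence)
        assert back.provenance.equals(ds.provenance)
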