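"""Trial sequences, ground-truth networks and cohort assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from durnet import design as dg
from durnet import space as sp


class TestTimingConfig:
    def test_defaults_match_protocol(self, default_timing):
        t = default_timing
        assert t.n_trial_types == 16
        assert t.n_runs * t.volumes_per_run == 3042
        assert t.run_length == pytest.approx(169 * 1.368)
        assert len(t.isi_grid) == 16
        assert t.isi_grid[0] == 4.0 and t.isi_grid[-1] == pytest.approx(5.2)

    @pytest.mark.parametrize("kwargs", [
        {"isi_min": 5.2, "isi_max": 4.0},
        {"isi_step": 0.07},
        {"s1_durations": (0.2, -0.1)},
        {"weber_fraction": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dg.TimingConfig(**kwargs)


class TestS2Assignment:
    @pytest.mark.parametrize("s1,direction,expected", [
        (0.2, "shorter", 0.1), (0.2, "longer", 0.3), (1.0, "longer", 1.5)])
    def test_weber_scaling(self, s1, direction, expected):
        assert dg.assign_s2_duration(s1, 0.5, direction) == pytest.approx(expected)

    def test_degenerate_weber_rejected(self):
        with pytest.raises(ValueError):
            dg.assign_s2_duration(0.4, 0.0, "shorter")

    @given(s1=st.floats(0.05, 2.0), weber=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shorter_longer_bracket_s1(self, s1, weber):
        lo = dg.assign_s2_duration(s1, weber, "shorter")
        hi = dg.assign_s2_duration(s1, weber, "longer")
        assert lo < s1 < hi


class TestTrialSequence:
    def test_sixteen_trials_once_each(self, default_timing):
        ev = dg.generate_trial_sequence(default_timing, run=0, seed=3)
        s1 = ev[ev.trial_type.str.startswith("s1_offset")]
        assert len(s1) == 16
        # each duration regressor has one event per orientation
        for j in range(1, 5):
            sub = s1[s1.trial_type == f"s1_offset_d{j}"]
            assert len(sub) == 4
            assert sorted(sub.orientation) == [36.0, 72.0, 108.0, 144.0]

    def test_every_trial_complete(self, default_timing):
        ev = dg.generate_trial_sequence(default_timing, run=0, seed=5)
        assert (ev.trial_type == "s2_onset").sum() == 16
        assert (ev.trial_type == "response_onset").sum() == 16
        assert (ev.duration == 0).all()

    def test_isi_on_grid(self, default_timing):
        for seed in range(5):
            ev = dg.generate_trial_sequence(default_timing, run=0, seed=seed)
            s1 = ev[ev.trial_type.str.startswith("s1_offset")].onset.to_numpy()
            s2 = ev[ev.trial_type == "s2_onset"].onset.to_numpy()
            isi = np.sort(s2) - np.sort(s1)
            assert np.all(isi >= 4.0 - 1e-9) and np.all(isi <= 5.2 + 1e-9)
            steps = (isi - 4.0) / 0.08
            assert np.allclose(steps, np.round(steps), atol=1e-6)

    def test_onsets_increasing_and_within_run(self, default_timing):
        ev = dg.generate_trial_sequence(default_timing, run=0, seed=11)
        assert (ev.onset.diff().dropna() > 0).all()
        assert ev.onset.max() + default_timing.response_period <= default_timing.run_length

    def test_deterministic_given_seed(self, default_timing):
        a = dg.generate_trial_sequence(default_timing, run=2, seed=9)
        b = dg.generate_trial_sequence(default_timing, run=2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_overflow_raises_structured_error(self):
        tiny = dg.TimingConfig(volumes_per_run=40)
        with pytest.raises(dg.RunOverflowError) as exc:
            dg.generate_trial_sequence(tiny, run=0, seed=0)
        assert exc.value.needed > exc.value.available


class TestGroundTruth:
    def test_masks_respected(self):
        gt = dg.make_ground_truth_network(hypothesis_b=("dependent", "dependent"),
                                          n_clusters=4, seed=1)
        spec = sp.make_model_spec("independent", "independent", "dependent",
                                  "dependent", "dependent")
        assert not np.any((gt.params.A != 0) & ~spec.a_mask.allowed)
        assert not np.any((gt.params.B != 0) & ~spec.b_masks)
        # dependent modulation only links clusters sharing the input's duration
        for j in range(4):
            t, s_ = np.nonzero(gt.params.B[j])
            assert np.all(t % 4 == j) and np.all(s_ % 4 == j)

    def test_stability_invariant(self):
        for seed in range(3):
            gt = dg.make_ground_truth_network(seed=seed)
            assert gt.params.max_real_eigenvalue() < 0

    def test_deterministic(self):
        a = dg.make_ground_truth_network(seed=7)
        b = dg.make_ground_truth_network(seed=7)
        assert np.array_equal(a.params.A, b.params.A)
        assert np.array_equal(a.params.C, b.params.C)

    def test_unstable_request_raises(self):
        with pytest.raises(ValueError):
            dg.make_ground_truth_network(between_strength=3.0, seed=0)

    def test_cluster_amplitudes_peak_at_preferred(self):
        gt = dg.make_ground_truth_network(seed=0)
        amp = gt.cluster_amplitudes
        assert np.all(np.argmax(amp, axis=1) == np.arange(amp.shape[0]))


class TestCohort:
    def test_unit_and_volume_counts(self, small_timing):
        truth = dg.region_level_ground_truth(
            region_graph=sp.induced_subgraph(sp.region_graph_peblike(),
                                             ["CRB", "V1", "IPS"]),
            seed=0, drive_pattern=np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.0]]))
        ds = dg.build_cohort(2, small_timing, truth, seed=0)
        assert ds.n_first_level_units() == 2 * small_timing.n_runs
        assert ds.volumes_per_subject() == small_timing.n_runs * small_timing.volumes_per_run
        for s in ds.subjects:
            for ts in s.timeseries:
                assert ts.shape == (small_timing.volumes_per_run, 3)
                assert np.all(np.isfinite(ts))

    def test_default_geometry_counts(self, default_timing):
        """11 subjects x 18 runs -> 198 units; 18 x 169 -> 3,042 volumes."""
        assert 11 * default_timing.n_runs == 198
        assert default_timing.n_runs * default_timing.volumes_per_run == 3042

    def test_zero_variability_gives_identical_subjects(self, small_timing):
        truth = dg.region_level_ground_truth(
            region_graph=sp.induced_subgraph(sp.region_graph_peblike(),
                                             ["CRB", "V1", "IPS"]),
            seed=0, drive_pattern=np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.0]]))
        truth.between_subject_sd = 0.0
        ds = dg.build_cohort(2, small_timing, truth, seed=1, noise_sd=0.0)
        assert np.array_equal(ds.subjects[0].params.A, ds.subjects[1].params.A)

    def test_bit_identical_regeneration(self, small_timing):
        truth = dg.region_level_ground_truth(
            region_graph=sp.induced_subgraph(sp.region_graph_peblike(),
                                             ["CRB", "V1", "IPS"]),
            seed=0, drive_pattern=np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.0]]))
        a = dg.build_cohort(2, small_timing, truth, seed=5)
        b = dg.build_cohort(2, small_timing, truth, seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            for ta, tb in zip(sa.timeseries, sb.timeseries):
                assert np.array_equal(ta, tb)

    def test_jitter_keeps_stability_margin(self):
        truth = dg.region_level_ground_truth(seed=2)
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = dg.jitter_params(truth.params, 0.1, rng)
            assert p.max_real_eigenvalue() < -0.08


class TestVoxelExpansion:
    def test_shapes_and_ownership(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((40, 3))
        vox, owner = dg.expand_to_voxels(ts, 10, 0.5, rng)
        assert vox.shape == (40, 30)
        assert np.array_equal(owner, np.repeat([0, 1, 2], 10))

    def test_noiseless_voxels_correlate_with_node(self):
        rng = np.random.default_rng(0)
        ts = np.sin(np.linspace(0, 10, 100))[:, None]
        vox, _ = dg.expand_to_voxels(ts, 5, 0.0, rng)
        for v in range(5):
            r = np.corrcoef(ts[:, 0], vox[:, v])[0, 1]
            assert r > 0.999


class TestEventIO:
    def test_tsv_roundtrip(self, default_timing, tmp_path):
        ev = dg.generate_trial_sequence(default_timing, run=0, seed=0)
        path = tmp_path / "events.tsv"
        dg.write_events_tsv(ev, str(path))
        back = dg.read_events_tsv(str(path))
        pd.testing.assert_frame_equal(ev, back, check_dtype=False)

    def test_timeseries_roundtrip(self, tmp_path):
        ts = np.random.default_rng(0).standard_normal((20, 3)).round(6)
        path = tmp_path / "ts.tsv"
        dg.write_timeseries_tsv(ts, ["a", "b", "c"], str(path))
        back, labels = dg.read_timeseries_tsv(str(path))
        assert labels == ["a", "b", "c"]
        assert np.allclose(back, ts)

    def test_channel_selection(self, default_timing):
        ev = dg.generate_trial_sequence(default_timing, run=0, seed=0)
        s1_all, s2 = dg.onsets_for_channels(ev, ("s1_all", "s2"))
        assert len(s1_all) == 16 and len(s2) == 16
        with pytest.raises(ValueError):
            dg.onsets_for_channels(ev, ("nope",))
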