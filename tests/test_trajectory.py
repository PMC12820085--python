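import io as _io
import math
import textwrap

import numpy as np
import pytest

from flagwrap import trajectory as tj
from flagwrap import synthetic as sy


def make_track(x, dt=0.1, tid="t"):
    x = np.asarray(x, float)
    return tj.Track(tid, np.arange(len(x)) * dt, x)


class TestReadTracks:
    def test_well_formed_two_tracks(self, tmp_path):
        csv = textwrap.dedent("""\
            track_id,frame,time_s,x_um
            a,0,0.0,0.0
            a,1,0.1,0.5
            a,2,0.2,1.0
            b,0,0.0,2.0
            b,1,0.1,2.5
        """)
        path = tmp_path / "tracks.csv"
        path.write_text(csv)
        tracks = tj.read_tracks(path)
        assert [t.track_id for t in tracks] == ["a", "b"]

    def test_duplicated_frame_rejects_track(self, tmp_path):
        csv = "track_id,frame,time_s,x_um\na,0,0.0,0.0\na,0,0.1,0.5\n"
        path = tmp_path / "dup.csv"
        path.write_text(csv)
        with pytest.warns(UserWarning, match="duplicated"):
            assert tj.read_tracks(path) == []

    def test_nonmonotone_time_rejects_track(self, tmp_path):
        csv = ("track_id,frame,time_s,x_um\n"
               "a,0,0.2,0.0\na,1,0.1,0.5\na,2,0.3,0.9\n")
        path = tmp_path / "bad.csv"
        path.write_text(csv)
        with pytest.warns(UserWarning):
            assert tj.read_tracks(path) == []

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("track_id,frame,time_s,x_um\n")
        with pytest.warns(UserWarning, match="no tracks"):
            assert tj.read_tracks(path) == []


class TestSegmentRuns:
    def test_monotone_track_is_single_run(self):
        track = make_track(np.linspace(0, 10, 101))
        segs = tj.segment_runs(track, 0.2)
        assert len(segs) == 1
        assert segs[0].direction == "forward"
        assert segs[0].duration_s == pytest.approx(track.duration)

    def test_triangle_wave_alternating_unit_runs(self):
        dt = 0.01
        t = np.arange(0, 10, dt)
        x = 2.0 * np.abs((t / 2) % 1 - 0.5) * 2  # period 2 s, amplitude 2
        segs = tj.segment_runs(tj.Track("tri", t, x), 0.2)
        interior = [s for s in segs if not s.censored]
        assert len(interior) >= 7
        for s in interior:
            assert s.duration_s == pytest.approx(1.0, abs=2 * dt)
        dirs = [s.direction for s in segs]
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_subthreshold_jitter_keeps_single_run(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 201) + rng.uniform(-0.05, 0.05, 201)
        segs = tj.segment_runs(make_track(x, dt=0.05), 0.2)
        assert len(segs) == 1

    def test_segments_tile_track(self):
        track, _ = sy.gen_run_reverse_track(sy.RunReverseParams(), seed=4)
        segs = tj.segment_runs(track, 0.2)
        total = sum(s.duration_s for s in segs)
        assert total == pytest.approx(track.duration, abs=track.dt)

    def test_short_track_empty(self):
        assert tj.segment_runs(make_track([0.0, 1.0]), 0.2) == []

    def test_time_origin_shift_invariance(self):
        track, _ = sy.gen_run_reverse_track(sy.RunReverseParams(), seed=5)
        shifted = tj.Track("s", track.time_s + 13.0, track.x_um + 7.0)
        a = tj.segment_runs(track, 0.2)
        b = tj.segment_runs(shifted, 0.2)
        assert np.allclose([s.duration_s for s in a],
                           [s.duration_s for s in b])
        assert [s.direction for s in a] == [s.direction for s in b]


class TestRunTimeConstant:
    def test_single_duration_with_warning(self):
        fit = tj.fit_run_time_constant([0.7])
        assert fit["tau_s"] == pytest.approx(0.7)
        assert fit["warning"]

    def test_exponential_draws_recovered(self):
        rng = np.random.default_rng(42)
        d = rng.exponential(0.5, 1000)
        fit = tj.fit_run_time_constant(d)
        assert 0.45 < fit["tau_s"] < 0.55
        assert fit["ci_95"][0] < fit["tau_s"] < fit["ci_95"][1]

    def test_estimator_bias_small_at_1e4(self):
        rng = np.random.default_rng(7)
        fit = tj.fit_run_time_constant(rng.exponential(0.5, 10_000))
        assert abs(fit["tau_s"] / 0.5 - 1) < 0.02

    def test_identical_durations_zero_width_ci(self):
        fit = tj.fit_run_time_constant([0.3] * 20)
        assert fit["tau_s"] == pytest.approx(0.3)
        assert fit["zero_width_ci"]

    def test_merge_corrected_pipeline_recovery(self):
        """Full segmentation round trip recovers both time constants
        within 10% once the detection floor is modelled."""
        p = sy.RunReverseParams(tau_forward=0.9, tau_backward=0.45,
                                duration=60.0)
        dur_f, dur_b, segs_all = [], [], []
        for s in range(40):
            trk, _ = sy.gen_run_reverse_track(p, seed=s)
            segs = tj.segment_runs(trk, 0.2)
            segs_all.extend(segs)
            dur_f += [x.duration_s for x in segs
                      if not x.censored and x.direction == "forward"]
            dur_b += [x.duration_s for x in segs
                      if not x.censored and x.direction == "backward"]
        assert len(dur_f) + len(dur_b) > 1000
        v = tj.run_speed(segs_all)
        floor = 0.2 / v + 0.1 / 4
        fit = tj.fit_alternating_time_constants(dur_f, dur_b, floor)
        assert fit["converged"]
        assert abs(fit["tau_forward_s"] / 0.9 - 1) < 0.10
        assert abs(fit["tau_backward_s"] / 0.45 - 1) < 0.10


class TestForwardBias:
    def test_all_forward_bins_at_one(self):
        segs = [tj.RunSegment("forward", 0.0, d, d) for d in
                (0.2, 0.7, 1.3, 1.8)]
        table = tj.forward_bias_by_duration(segs)
        assert (table["forward_fraction"] == 1.0).all()

    def test_symmetric_cohort_near_half(self):
        segs = []
        for s in range(30):
            trk, _ = sy.gen_run_reverse_track(
                sy.RunReverseParams(tau_forward=0.6, tau_backward=0.6),
                seed=s)
            segs += tj.segment_runs(trk, 0.2)
        table = tj.forward_bias_by_duration(segs)
        big = table[table["n"] >= 50]
        assert ((big["forward_fraction"] - 0.5).abs()
                < 3 * np.sqrt(0.25 / big["n"]) + 0.05).all()

    def test_rising_bias_reproduced(self):
        """A generator whose forward persistence grows with run duration
        produces a rising forward fraction across duration bins."""
        segs = []
        for s in range(60):
            trk, truth = sy.gen_run_reverse_track(
                sy.RunReverseParams(tau_forward=1.2, tau_backward=0.5,
                                    bias_logistic=(0.5, 0.95, 0.8)),
                seed=s)
            segs += [t for t in truth if not t.censored]
        table = tj.forward_bias_by_duration(segs)
        occupied = table[table["n"] >= 30]
        first, last = occupied.iloc[0], occupied.iloc[-1]
        assert last["forward_fraction"] > first["forward_fraction"]

    def test_empty_bins_absent(self):
        segs = [tj.RunSegment("forward", 0.0, 0.2, 0.2),
                tj.RunSegment("backward", 0.2, 3.3, -3.3)]
        table = tj.forward_bias_by_duration(segs)
        assert set(table["bin_left_s"]) == {0.0, 3.0}


class TestDisplacementMeasures:
    def test_constant_velocity_gives_eighty(self):
        t = np.arange(0, 120.0001, 0.1)
        track = tj.Track("v", t, (4.0 / 3.0) * t)
        assert tj.net_displacement_per_minute(track) == pytest.approx(80.0)

    def test_stationary_track_zero(self):
        assert tj.net_displacement_per_minute(
            make_track(np.zeros(1300))) == 0.0

    def test_mirror_invariance(self):
        track, _ = sy.gen_run_reverse_track(
            sy.RunReverseParams(duration=120.0), seed=9)
        mirrored = tj.Track("m", track.time_s, -track.x_um)
        assert tj.net_displacement_per_minute(track) == pytest.approx(
            tj.net_displacement_per_minute(mirrored))

    def test_short_track_scaled_with_warning(self):
        t = np.arange(0, 30, 0.1)
        with pytest.warns(UserWarning, match="shorter"):
            nd = tj.net_displacement_per_minute(tj.Track("s", t, 1.0 * t))
        assert nd == pytest.approx(60.0, rel=0.01)

    def test_mirror_paired_cohort_symmetric(self):
        base = [sy.gen_run_reverse_track(
            sy.RunReverseParams(duration=70.0), seed=s)[0]
            for s in range(6)]
        mirrored = [tj.Track(t.track_id + "m", t.time_s, -t.x_um)
                    for t in base]
        out = tj.signed_mean_displacement(base + mirrored)
        assert out["mean_um"] == pytest.approx(0.0, abs=1e-9)

    def test_all_forward_cohort_positive(self):
        tracks = [make_track(np.linspace(0, 50, 700) + i) for i in range(4)]
        out = tj.signed_mean_displacement(tracks)
        assert out["mean_um"] > 0
        assert out["fraction_positive"] == 1.0


class TestMsd:
    def test_ballistic_msd_exact(self):
        t = np.arange(0, 30, 0.1)
        v = 1.7
        msd = tj.compute_msd([tj.Track("b", t, v * t)])
        assert np.allclose(msd["msd_um2"], v**2 * msd["lag_s"] ** 2)
        fit = tj.fit_msd(msd, 1)
        assert fit["v_um_per_s"] == pytest.approx(v, rel=1e-6)
        assert abs(fit["D_um2_per_s"]) < 1e-9

    def test_brownian_diffusion_recovered(self):
        tracks = [sy.gen_brownian_track(0.1, 2, 0.1, 300, seed=s)
                  for s in range(200)]
        fit = tj.fit_msd(tj.compute_msd(tracks), 2)
        assert abs(fit["D_um2_per_s"] / 0.1 - 1) < 0.10

    def test_msd_zero_at_zero_lag(self):
        msd = tj.compute_msd([sy.gen_brownian_track(0.1, 1, 0.1, 100,
                                                    seed=0)])
        assert msd["msd_um2"].iloc[0] == 0.0

    def test_ballistic_plus_brownian_additivity(self):
        """MSD of summed independent components equals sum of MSDs."""
        v, D, n = 0.8, 0.05, 400
        t = np.arange(n) * 0.1
        rng_tracks, sum_tracks, bal_tracks = [], [], []
        for s in range(150):
            b = sy.gen_brownian_track(D, 1, 0.1, n, seed=s)
            rng_tracks.append(b)
            sum_tracks.append(tj.Track("s", t, b.x_um + v * t))
            bal_tracks.append(tj.Track("v", t, v * t))
        m_sum = tj.compute_msd(sum_tracks)["msd_um2"]
        m_parts = (tj.compute_msd(rng_tracks)["msd_um2"]
                   + tj.compute_msd(bal_tracks)["msd_um2"])
        assert np.allclose(m_sum[1:], m_parts[1:], rtol=0.15)


class TestDiffusionRatio:
    def test_identical_cohorts_unit_ratio(self):
        tracks = [sy.gen_brownian_track(0.2, 2, 0.1, 200, seed=s)
                  for s in range(50)]
        out = tj.diffusion_confinement_ratio(tracks, tracks, 2, 2, n_boot=5)
        assert out["ratio"] == pytest.approx(1.0)

    def test_sixty_fold_reduction_recovered(self):
        free = [sy.gen_brownian_track(0.6, 2, 0.1, 300, seed=s)
                for s in range(120)]
        conf = [sy.gen_brownian_track(0.01, 2, 0.1, 300, seed=5000 + s)
                for s in range(120)]
        out = tj.diffusion_confinement_ratio(free, conf, 2, 2, n_boot=30)
        assert abs(out["ratio"] / 60.0 - 1) < 0.15
        assert out["ratio_ci_95"][0] < out["ratio"] < out["ratio_ci_95"][1]

    def test_swapped_arguments_reciprocal(self):
        a = [sy.gen_brownian_track(0.4, 2, 0.1, 200, seed=s)
             for s in range(40)]
        b = [sy.gen_brownian_track(0.1, 2, 0.1, 200, seed=100 + s)
             for s in range(40)]
        r1 = tj.diffusion_confinement_ratio(a, b, 2, 2, n_boot=0)["ratio"]
        r2 = tj.diffusion_confinement_ratio(b, a, 2, 2, n_boot=0)["ratio"]
        assert r1 == pytest.approx(1.0 / r2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            tj.diffusion_confinement_ratio([], [], 2, 2)


class TestCompetitiveIndex:
    def test_equal_proportions_unity(self):
        assert tj.competitive_index(5000, 5000, 120, 120) == 1.0

    def test_zero_swapped_output(self):
        assert tj.competitive_index(5000, 5000, 0, 100) == 0.0

    def test_worked_example(self):
        assert tj.competitive_index(5000, 5000, 10, 100) == pytest.approx(0.1)

    def test_zero_native_output_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            tj.competitive_index(5000, 5000, 10, 0)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            tj.competitive_index(0, 5000, 10, 100)


class TestInvarianceProperties:
    """Property checks of the statistics' invariances."""

    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale_in=st.floats(0.1, 50.0), scale_out=st.floats(0.1, 50.0))
    def test_competitive_index_scale_invariant(self, scale_in, scale_out):
        """CI is a ratio of ratios: rescaling all input counts or all
        output counts leaves it unchanged."""
        base = tj.competitive_index(5000, 4000, 30, 90)
        scaled = tj.competitive_index(5000 * scale_in, 4000 * scale_in,
                                      30 * scale_out, 90 * scale_out)
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(shift=st.floats(-100.0, 100.0), seed=st.integers(0, 50))
    def test_net_displacement_translation_invariant(self, shift, seed):
        track, _ = sy.gen_run_reverse_track(
            sy.RunReverseParams(duration=70.0), seed=seed)
        shifted = tj.Track("s", track.time_s, track.x_um + shift)
        assert tj.net_displacement_per_minute(shifted) == pytest.approx(
            tj.net_displacement_per_minute(track))
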