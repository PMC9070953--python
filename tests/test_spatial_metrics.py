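import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrierassay import (
    Arena,
    EmptyProfileError,
    SimulationConfig,
    UnitError,
    calibrate,
    default_bin_edges,
    instantaneous_velocity,
    residence_probability,
    signed_distance,
    simulate_experiment,
    velocity_profile,
)

from conftest import make_set, make_track


class TestSignedDistance:
    def test_point_at_barrier(self, arena):
        ts = make_set([make_track("a", [arena.barrier_x], units="mm")], arena)
        assert signed_distance(ts)["a"][0] == 0.0

    def test_origin_side_is_negative(self, arena):
        ts = make_set([make_track("a", [arena.barrier_x - 22.0], units="mm")], arena)
        assert signed_distance(ts)["a"][0] == pytest.approx(-22.0)

    def test_reflection_for_decreasing_x(self):
        arena = Arena(odor_direction="decreasing_x")
        # odor toward decreasing x: a point left of the barrier is odor-side
        ts = make_set([make_track("a", [arena.barrier_x - 5.0], units="mm")], arena)
        assert signed_distance(ts)["a"][0] == pytest.approx(5.0)

    def test_pixel_units_rejected(self, arena):
        ts = make_set([make_track("a", [1.0], units="pixel")], arena)
        with pytest.raises(UnitError):
            signed_distance(ts)

    @given(st.lists(st.floats(0.1, 46.9), min_size=1, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_brute_force_subtraction(self, xs):
        for direction in ("increasing_x", "decreasing_x"):
            arena = Arena(odor_direction=direction)
            ts = make_set([make_track("a", xs, units="mm")], arena)
            got = signed_distance(ts)["a"]
            sign = 1.0 if direction == "increasing_x" else -1.0
            for g, x in zip(got, xs):
                assert g == pytest.approx((x - arena.barrier_x) * sign)


class TestResidenceProbability:
    def test_worked_example_139_of_345(self, arena):
        bx = arena.barrier_x
        xs = np.concatenate(
            [
                np.full(139, bx + 0.5),  # bin [0, 1)
                np.full(103, bx - 0.5),  # bin [-1, 0)
                np.full(103, bx + 1.5),  # bin [1, 2)
            ]
        )
        ts = make_set([make_track("a", xs, units="mm")], arena)
        prof = residence_probability(ts, bin_edges=np.arange(-2.0, 3.0))
        bin_idx = np.where(prof.bin_edges[:-1] == 0.0)[0][0]
        assert round(prof.probabilities[bin_idx], 4) == 0.4029
        assert prof.counts.sum() == 345

    def test_all_in_one_bin(self, arena):
        ts = make_set(
            [make_track("a", np.full(10, arena.barrier_x + 0.2), units="mm")], arena
        )
        prof = residence_probability(ts, bin_edges=np.arange(-3.0, 4.0))
        assert prof.probabilities.max() == 1.0
        assert prof.probabilities.sum() == pytest.approx(1.0)

    def test_uniform_45_bins_mean_is_one_45th(self, arena):
        rng = np.random.default_rng(0)
        edges = np.arange(-22.0, 24.0)  # 45 bins
        xs = arena.barrier_x + rng.uniform(-22.0, 23.0, size=500)
        ts = make_set([make_track("a", np.sort(xs), units="mm")], arena)
        prof = residence_probability(ts, bin_edges=edges)
        assert prof.n_bins == 45
        assert round(float(prof.probabilities.mean()), 4) == 0.0222

    def test_normalization(self, arena):
        rng = np.random.default_rng(1)
        tracks = [
            make_track(f"t{i}", rng.uniform(1, 46, 50), units="mm") for i in range(4)
        ]
        prof = residence_probability(make_set(tracks, arena))
        assert prof.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (prof.probabilities >= 0).all()

    def test_empty_range_errors(self, arena):
        ts = make_set([make_track("a", [arena.barrier_x + 30.0], units="mm")], arena)
        with pytest.raises(EmptyProfileError):
            residence_probability(ts, bin_edges=np.array([-2.0, -1.0, 0.0]))

    def test_half_open_bins(self, arena):
        # a point exactly on an interior edge belongs to the right-hand bin
        ts = make_set([make_track("a", [arena.barrier_x + 1.0], units="mm")], arena)
        prof = residence_probability(ts, bin_edges=np.arange(0.0, 3.0))
        assert prof.counts.tolist() == [0, 1]

    def test_resampling_density_invariance(self, arena):
        # doubling midpoint sampling of the same geometric path keeps
        # probabilities within one count quantum
        n = 120
        xs = np.linspace(5.0, 40.0, n)
        xs2 = np.linspace(5.0, 40.0, 2 * n)
        p1 = residence_probability(
            make_set([make_track("a", xs, units="mm")], arena)
        ).probabilities
        p2 = residence_probability(
            make_set([make_track("a", xs2, units="mm")], arena)
        ).probabilities
        assert np.abs(p1 - p2).max() <= 1.0 / n


class TestInstantaneousVelocity:
    def test_worked_example_2s_window(self):
        # positions 1 s before and after are 425.7 um apart
        x = np.array([0.0, 0.1, 0.2, 0.21285, 0.3257, 0.4, 0.4257])
        t = make_track("a", x, np.zeros(7), units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        assert v[3] == pytest.approx(212.85, abs=1e-9)
        assert np.isnan(v[[0, 1, 2, 4, 5, 6]]).all()

    def test_stationary_track(self):
        t = make_track("a", np.full(30, 5.0), np.full(30, 5.0), units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        defined = v[np.isfinite(v)]
        assert defined.size == 30 - 6
        assert (defined == 0).all()

    def test_constant_speed_line(self):
        # 0.1 mm per frame at 3 fps -> 300 um/s
        x = np.arange(40) * 0.1
        t = make_track("a", x, np.zeros(40), units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        np.testing.assert_allclose(v[np.isfinite(v)], 300.0)

    def test_track_shorter_than_window_all_nan(self):
        t = make_track("a", [0.0, 0.1, 0.2], units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        assert np.isnan(v).all()

    def test_frame_gap_leaves_sample_undefined(self):
        frames = np.array([0, 1, 2, 3, 4, 6, 7, 8, 9])  # frame 5 missing
        from barrierassay import Track

        t = Track("a", frames, frames / 3.0, frames * 0.1, np.zeros(9), units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        # sample centred on frame 2 needs frame 5: undefined
        assert np.isnan(v[frames.tolist().index(2)])
        # sample centred on frame 3 needs frames 0 and 6: defined
        assert np.isfinite(v[frames.tolist().index(3)])

    def test_chord_never_exceeds_arc(self):
        rng = np.random.default_rng(4)
        steps = rng.normal(0, 0.05, size=(60, 2))
        xy = np.cumsum(steps, axis=0)
        t = make_track("a", xy[:, 0], xy[:, 1], units="mm")
        v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        seg = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
        for i in np.flatnonzero(np.isfinite(v)):
            arc = seg[i - 3 : i + 3].sum()  # path length over the window
            assert v[i] <= arc * 1000.0 / 2.0 + 1e-9

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(7)
        xy = np.cumsum(rng.normal(0, 0.05, size=(40, 2)), axis=0) + 10
        t = make_track("a", xy[:, 0], xy[:, 1], units="mm")
        v0 = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = xy @ R.T + np.array([3.0, -2.0])
        t2 = make_track("a", rot[:, 0], rot[:, 1], units="mm")
        v1 = instantaneous_velocity(t2, window=2.0, frame_rate=3.0)
        np.testing.assert_allclose(v0, v1, rtol=1e-9)


class TestVelocityProfile:
    def test_constant_speed_every_bin(self, arena):
        x = np.arange(5.0, 40.0, 0.05)
        ts = make_set([make_track("a", x, units="mm")], arena)
        prof = velocity_profile(ts, window=2.0)
        occupied = prof.n_samples > 0
        np.testing.assert_allclose(
            prof.mean_velocity[occupied], 0.05 * 3.0 * 1000.0, rtol=1e-9
        )

    def test_two_speeds_average(self, arena):
        # two tracks at fixed x in one bin, moving in y at 100 and 300 um/s:
        # equal sample counts, so the bin mean is the arithmetic mean, 200
        bx = arena.barrier_x
        n = 31
        slow_y = 10.0 + np.arange(n) * (100.0 / 3.0 / 1000.0)
        fast_y = 10.0 + np.arange(n) * (300.0 / 3.0 / 1000.0)
        ts = make_set(
            [
                make_track("slow", np.full(n, bx - 3.5), slow_y, units="mm"),
                make_track("fast", np.full(n, bx - 3.5), fast_y, units="mm"),
            ],
            arena,
        )
        edges = np.array([-4.0, -3.0])
        prof = velocity_profile(ts, window=2.0, bin_edges=edges)
        assert prof.n_samples[0] == 2 * (n - 6)
        assert prof.mean_velocity[0] == pytest.approx(200.0, rel=1e-9)
        # arithmetic oracle over the pooled per-sample velocities
        pooled = []
        for t in ts:
            v = instantaneous_velocity(t, window=2.0, frame_rate=3.0)
            pooled.extend(v[np.isfinite(v)])
        assert prof.mean_velocity[0] == pytest.approx(np.mean(pooled), rel=1e-12)

    def test_empty_bins_flagged(self, arena):
        ts = make_set([make_track("a", np.linspace(5, 8, 60), units="mm")], arena)
        prof = velocity_profile(ts)
        assert (prof.n_samples == 0).any()
        assert np.isnan(prof.mean_velocity[prof.n_samples == 0]).all()

    def test_speed_law_recovery_within_3_sem(self):
        law = ((-24.0, 150.0), (-10.0, 220.0), (0.0, 120.0), (24.0, 180.0))
        cfg = SimulationConfig(
            n_animals=20,
            duration=600.0,
            seed=13,
            speed_vs_distance=law,
            heading_persistence=0.9999,
            step_noise_sd=0.0,
            odor_bias=0.0,
            crossing_propensity=0.0,
        )
        ts, _ = simulate_experiment(cfg)
        mm = calibrate(ts)
        prof = velocity_profile(mm)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        law_x = np.array([k[0] for k in law])
        law_y = np.array([k[1] for k in law])
        # wall reflections fold paths within the window (chord < arc), so
        # bins within 2 mm of the x walls are excluded from the check
        walls = np.array([-cfg.arena.barrier_x, cfg.arena.fov_width - cfg.arena.barrier_x])
        checked = 0
        for c, m, s, n in zip(
            centers, prof.mean_velocity, prof.sem, prof.n_samples
        ):
            if n < 50 or not np.isfinite(s) or s == 0:
                continue
            if np.abs(c - walls).min() < 2.0 or abs(c) < 4.0:
                continue
            expected = np.interp(c, law_x, law_y)
            assert abs(m - expected) <= 3 * s + 0.01 * expected, (c, m, expected, s)
            checked += 1
        assert checked >= 10
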