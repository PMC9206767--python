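import numpy as np
import pytest

from codmotion.simulate import (C11_HALF_LIFE_MIN, MotionSchedule, PhantomSpec,
                                GaussianBlob, brain_like_phantom,
                                exponential_drift, fdg_like_study,
                                location_series, simulate_events,
                                simulate_trace, tof_fwhm_mm)
from codmotion.trace import compute_cod


class TestMotionSchedule:
    def test_translation_amplitudes_equal_step_norms(self):
        sched = MotionSchedule.from_translations(
            [100.0, 200.0], [[3.0, 0, 0], [0, 4.0, 0]])
        np.testing.assert_allclose(sched.step_amplitudes(), [3.0, 4.0])

    def test_rotation_amplitude_uses_cube_vertices(self):
        th = np.deg2rad(5)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        sched = MotionSchedule([60.0], [rot], [np.zeros(3)])
        amp = sched.step_amplitudes()[0]
        # 5 deg about z at ~70.7 mm transaxial vertex radius -> ~6 mm
        assert 4.0 < amp < 8.0

    def test_identity_before_first_breakpoint(self):
        sched = MotionSchedule.from_translations([10.0], [[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(sched.offsets([5.0])[0], [0, 0, 0])
        np.testing.assert_array_equal(sched.offsets([10.0])[0], [1, 2, 3])

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            MotionSchedule([1.0], [np.eye(3) * 2.0], [np.zeros(3)])

    def test_tof_fwhm_conversion(self):
        assert tof_fwhm_mm(580.0) == pytest.approx(86.9, abs=0.1)


class TestSimulateEvents:
    def test_seeded_reproducibility(self):
        ph = brain_like_phantom(rate0=2000.0)
        sched = MotionSchedule.from_translations([5.0], [[2.0, 0, 0]])
        a = simulate_events(ph, sched, 10.0, seed=42)
        b = simulate_events(ph, sched, 10.0, seed=42)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.x, b.x)

    def test_decay_halves_event_rate(self):
        ph = PhantomSpec(half_life_min=C11_HALF_LIFE_MIN, rate0=3000.0)
        ev = simulate_events(ph, MotionSchedule.identity(), 2 * 20.36 * 60,
                             seed=0)
        hl = 20.36 * 60
        early = np.sum(ev.t < 60)
        late = np.sum((ev.t >= hl) & (ev.t < hl + 60))
        assert late / early == pytest.approx(0.5, rel=0.1)

    def test_symmetric_phantom_cod_centered(self):
        ph = PhantomSpec(blobs=[GaussianBlob(center=(0, 0, 0), sd=(30, 30, 30))],
                         rate0=40_000.0)
        ev = simulate_events(ph, MotionSchedule.identity(), 30.0, seed=1)
        se = 30.0 / np.sqrt(len(ev))  # per-event SD ~ blob SD
        for coord in (ev.x.mean(), ev.y.mean()):
            assert abs(coord) < 4 * se

    def test_step_translation_recovered_in_cod(self):
        ph = brain_like_phantom(rate0=30_000.0)
        sched = MotionSchedule.from_translations([300.0], [[2.0, 0.0, 0.0]])
        ev = simulate_events(ph, sched, 600.0, seed=3, mode="tof")
        tr = compute_cod(ev, 1.0)
        delta = np.nanmean(tr.cx[300:]) - np.nanmean(tr.cx[:300])
        assert delta == pytest.approx(2.0, abs=0.15)

    def test_nontof_midpoints_attenuate_the_step(self):
        ph = brain_like_phantom(rate0=30_000.0)
        sched = MotionSchedule.from_translations([300.0], [[4.0, 0.0, 0.0]])
        deltas = {}
        for mode in ("tof", "nontof"):
            ev = simulate_events(ph, sched, 600.0, seed=7, mode=mode)
            tr = compute_cod(ev, 1.0)
            deltas[mode] = np.nanmean(tr.cx[300:]) - np.nanmean(tr.cx[:300])
        assert 0.2 < deltas["nontof"] < deltas["tof"]
        assert deltas["tof"] == pytest.approx(4.0, abs=0.3)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(blobs=[GaussianBlob(activity=0.0)])


class TestSimulateTrace:
    def test_noise_free_step_is_exact(self):
        sched = MotionSchedule.from_translations([40.0], [[0, 0, 1.5]])
        sim = simulate_trace(0.0, 109.77, None, sched, 100.0, seed=0)
        assert sim.true_mtp_bins.tolist() == [40]
        np.testing.assert_array_equal(sim.trace.cz[:40], 0.0)
        np.testing.assert_array_equal(sim.trace.cz[40:], 1.5)

    def test_noise_sd_doubles_after_two_half_lives(self):
        sim = simulate_trace(0.5, 1.0, None, MotionSchedule.identity(),
                             121.0, seed=0)   # half-life 60 s
        assert sim.sigma[120] / sim.sigma[0] == pytest.approx(2.0, rel=1e-9)

    def test_empirical_sd_matches_model(self):
        reps, T = 400, 120
        vals = np.empty((reps, 2))
        sigma = None
        for r in range(reps):
            sim = simulate_trace(0.5, 1.0, None, MotionSchedule.identity(),
                                 float(T), seed=1000 + r)
            vals[r] = sim.trace.cx[0], sim.trace.cx[T - 1]
            sigma = sim.sigma
        assert vals[:, 0].std() == pytest.approx(sigma[0], rel=0.12)
        assert vals[:, 1].std() == pytest.approx(sigma[T - 1], rel=0.12)

    def test_drift_bounded_and_smooth(self):
        drift = exponential_drift([1.0, -0.5, 0.2], tau=1200.0)
        t = np.arange(5400.0)
        d = drift(t)
        assert np.all(np.abs(d) <= 1.0)
        assert np.all(np.abs(np.diff(d, axis=0)) < 1e-2)

    def test_study_generator_properties(self):
        sim = fdg_like_study(seed=9)
        assert sim.trace.n_bins == 5400
        assert sim.true_mtp_bins.size == 10
        amps = sim.schedule.step_amplitudes()
        assert np.all((amps >= 2.0) & (amps <= 8.0))
        assert np.all(np.diff(sim.schedule.breakpoints) >= 30.0)

    def test_location_series_tracks_translations(self):
        sched = MotionSchedule.from_translations([3.0], [[1.0, 1.0, 0.0]])
        series = location_series(sched, 6.0, rate=20.0)
        np.testing.assert_allclose(series[:60], 0.0)
        np.testing.assert_allclose(series[60:, 0], 1.0)
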