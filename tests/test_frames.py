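import numpy as np
import pytest

from codmotion.detection import DetectionConfig, detect_3d
from codmotion.frames import (DISCARDED_INTRA, DISCARDED_LOW, KEPT,
                              discarded_summary, prune_intra_motion,
                              prune_low_count, read_gating, write_gating)

from conftest import axis_trace

CFG = DetectionConfig(alpha=1.0, n_max=15, partition_duration=300.0)


def detect(trace):
    return detect_3d(trace, CFG)


def noisy_step_trace(rng, sd=0.4, n=1200, wobble=None):
    """Step at 600; optionally a fast oscillation no step model can track."""
    v = np.concatenate([rng.normal(0, sd, 600), rng.normal(6, sd, 600)])
    if wobble is not None:
        # period 4 bins: far above the changepoint budget, so it must show
        # up as intra-frame variation rather than extra MTPs
        amp, a, b = wobble
        v[a:b] += amp * np.sin(np.arange(b - a) * (np.pi / 2))
    return axis_trace(v)


class TestIntraMotionRule:
    def test_clean_frames_kept(self, rng):
        tr = noisy_step_trace(rng)
        decisions = prune_intra_motion(detect(tr), tr)
        assert all(d.status == KEPT for d in decisions)

    def test_oscillating_frame_discarded(self, rng):
        # oscillation with SD ~ 3x the noise inside one detected MFF
        tr = noisy_step_trace(rng, wobble=(1.6, 100, 220))
        res = detect(tr)
        decisions = prune_intra_motion(res, tr)
        bad = [d for d in decisions if d.status == DISCARDED_INTRA]
        assert bad, "oscillating frame should be discarded"
        assert any(d.start <= 100 < d.end or d.start < 220 <= d.end or
                   (100 <= d.start and d.end <= 220) for d in bad)

    def test_boundary_exactly_twice_predicted_is_kept(self, rng):
        tr = noisy_step_trace(rng)
        res = detect(tr)
        decisions = prune_intra_motion(res, tr)
        d = decisions[0]
        # rebuild the gate by hand: strict inequality at exactly 2x
        for ax in "xyz":
            assert not (d.sd[ax] == 2.0 * d.predicted_sd[ax] and d.status != KEPT)

    def test_noise_free_discards_nothing(self):
        v = np.concatenate([np.zeros(400), np.full(400, 5.0), np.full(400, 1.0)])
        tr = axis_trace(v)
        decisions = prune_intra_motion(detect(tr), tr)
        assert all(d.status == KEPT for d in decisions)

    def test_kept_and_discarded_tile_the_mffs(self, rng):
        tr = noisy_step_trace(rng, wobble=(2.0, 650, 780))
        res = detect(tr)
        decisions = prune_intra_motion(res, tr)
        spans = [(d.start, d.end) for d in decisions]
        assert spans == res.mff_intervals
        assert sum(b - a for a, b in spans) == pytest.approx(tr.duration)

    def test_larger_noise_prediction_never_adds_discards(self, rng):
        # the 2xSD gate is monotone: inflating the predicted no-motion RSS
        # can only keep more frames
        tr = noisy_step_trace(rng, wobble=(1.2, 100, 260))
        res = detect(tr)
        counts = []
        for factor in (1.0, 1.6, 2.5):
            for ax in "xyz":
                res.per_axis[ax].enm.rss_nm = res.per_axis[ax].enm.rss_nm * factor
            dec = prune_intra_motion(res, tr)
            counts.append(sum(d.status == DISCARDED_INTRA for d in dec))
            for ax in "xyz":
                res.per_axis[ax].enm.rss_nm = res.per_axis[ax].enm.rss_nm / factor
        assert counts == sorted(counts, reverse=True)


class TestLowCountRule:
    def test_zero_threshold_discards_nothing(self, rng):
        tr = noisy_step_trace(rng)
        dec = prune_low_count(prune_intra_motion(detect(tr), tr), tr, 0)
        assert all(d.status == KEPT for d in dec)

    def test_low_count_frame_reflagged(self, rng):
        tr = noisy_step_trace(rng)  # 600 bins x 1000 counts per MFF
        dec = prune_low_count(prune_intra_motion(detect(tr), tr), tr,
                              min_counts=700_000)
        assert all(d.status == DISCARDED_LOW for d in dec)
        assert all(d.counts < 700_000 for d in dec)

    def test_intra_motion_status_is_final(self, rng):
        tr = noisy_step_trace(rng, wobble=(2.0, 100, 250))
        dec = prune_intra_motion(detect(tr), tr)
        dec2 = prune_low_count(dec, tr, min_counts=10 ** 9)
        for before, after in zip(dec, dec2):
            if before.status == DISCARDED_INTRA:
                assert after.status == DISCARDED_INTRA

    def test_negative_threshold_rejected(self, rng):
        tr = noisy_step_trace(rng)
        with pytest.raises(ValueError):
            prune_low_count(prune_intra_motion(detect(tr), tr), tr, -1)


class TestBookkeeping:
    def test_discard_summary_seconds_and_percent(self, rng):
        tr = noisy_step_trace(rng, wobble=(2.5, 650, 780))
        dec = prune_intra_motion(detect(tr), tr)
        s = discarded_summary(dec)
        assert s["total_seconds"] == pytest.approx(1200.0)
        assert s["discarded_percent"] == pytest.approx(
            100 * s["discarded_seconds"] / 1200.0)

    def test_gating_roundtrip(self, tmp_path, rng):
        tr = noisy_step_trace(rng)
        dec = prune_intra_motion(detect(tr), tr)
        p = tmp_path / "gating.csv"
        write_gating(dec, p)
        rows = read_gating(p)
        assert [(r[0], r[1]) for r in rows] == [(d.start, d.end) for d in dec]
        assert all(r[2] in (KEPT, DISCARDED_INTRA, DISCARDED_LOW) for r in rows)
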