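import numpy as np
import pytest

from codmotion.detection import (DetectionConfig, detect_3d, estimate_enm,
                                 scout_emin, select_ntar)
from codmotion.trace import CODTrace, make_partitions

from conftest import axis_trace


def _segment_at(values, n, n_max=None):
    curve = scout_emin(values, n_max or max(n, 1), engine="dp")
    return curve.segmentation(n)


class TestEstimateEnm:
    def test_noise_free_piecewise_constant_gives_zero(self, fixtures):
        v = fixtures["threelevel"]
        tr = axis_trace(v)
        seg = _segment_at(v, 5)
        enm = estimate_enm(v, seg, make_partitions(tr, 20.0), 2)
        assert enm.e_nm == 0.0

    def test_partition_covered_by_single_mff_recovers_its_rss(self, rng):
        v = rng.normal(size=60)
        tr = axis_trace(v)
        seg = _segment_at(v, 0)  # one MFF spanning everything
        parts = make_partitions(tr, 60.0)
        enm = estimate_enm(v, seg, parts, 2)
        assert enm.rss_nm[0] == pytest.approx(seg.mff_rss[0])

    def test_spanning_mff_portion_scaling(self, rng):
        # one MFF over two partitions: each partition gets
        # N_PART * RSS(portion) / N(portion)
        v = rng.normal(size=100)
        tr = axis_trace(v)
        seg = _segment_at(v, 0)
        parts = make_partitions(tr, 50.0)
        enm = estimate_enm(v, seg, parts, 2)
        for p, (a, b) in zip(parts, [(0, 50), (50, 100)]):
            seg_v = v[a:b]
            rss = ((seg_v - seg_v.mean()) ** 2).sum()
            assert enm.rss_nm[p.index] == pytest.approx(50 * rss / 50)

    def test_gaussian_noise_recovers_variance_in_long_mff_regime(self):
        # low changepoint density (long MFFs): E_NM tracks T * sigma^2
        rng = np.random.default_rng(5)
        sigma, T = 0.7, 600
        ratios = []
        for _ in range(30):
            v = rng.normal(0, sigma, T)
            tr = axis_trace(v)
            seg = _segment_at(v, 8)
            enm = estimate_enm(v, seg, make_partitions(tr, 300.0), 2)
            ratios.append(enm.e_nm / (T * sigma ** 2))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.12)

    def test_empty_partition_flagged(self):
        v = np.concatenate([np.zeros(10), np.full(10, np.nan), np.ones(10)])
        tr = axis_trace(v)
        seg = _segment_at(v, 1)
        enm = estimate_enm(v, seg, make_partitions(tr, 10.0), 2)
        assert enm.empty_partitions == [1]
        assert enm.rss_nm[1] == 0.0


class TestSelectNtar:
    def test_generous_target_detects_nothing(self, rng):
        v = rng.normal(size=30)
        curve = scout_emin(v, 10, engine="dp")
        n, seg, warn = select_ntar(curve, curve.e[0] + 1.0)
        assert n == 0 and not warn

    def test_unreachable_target_flags_warning(self, rng):
        v = rng.normal(size=30)
        curve = scout_emin(v, 10, engine="dp")
        n, seg, warn = select_ntar(curve, 0.0)
        assert n == 10
        assert "target_unreachable" in warn

    def test_noise_free_three_level_crosses_at_two(self, fixtures):
        curve = scout_emin(fixtures["threelevel"], 5, engine="dp")
        n, seg, warn = select_ntar(curve, 0.0)
        assert n == 2
        assert seg.mtps.tolist() == [20, 40]


class TestDetect3d:
    CFG = DetectionConfig(alpha=1.0, n_max=20, partition_duration=300.0)

    def test_identical_step_on_all_axes_merges_to_one_mtp(self):
        v = np.concatenate([np.zeros(600), np.full(600, 5.0)])
        res = detect_3d(axis_trace(v), self.CFG)
        assert res.mtp_bins.tolist() == [600]
        assert res.mff_intervals == [(0.0, 600.0), (600.0, 1200.0)]

    def test_axis_specific_steps_union(self):
        n = 1200
        x = np.concatenate([np.zeros(300), np.full(n - 300, 4.0)])
        z = np.concatenate([np.zeros(900), np.full(n - 900, -3.0)])
        tr = CODTrace(1.0, x, np.zeros(n), z, np.full(n, 100))
        res = detect_3d(tr, self.CFG)
        assert res.mtp_bins.tolist() == [300, 900]
        assert res.per_axis["y"].n_tar == 0

    @pytest.mark.parametrize("alpha", [1.0, 1.6, 3.0])
    def test_noise_free_steps_recovered_for_any_alpha(self, alpha):
        v = np.concatenate([np.zeros(400), np.full(300, 3.0), np.full(500, -2.0)])
        cfg = DetectionConfig(alpha=alpha, n_max=20, partition_duration=300.0)
        res = detect_3d(axis_trace(v), cfg)
        assert res.mtp_bins.tolist() == [400, 700]

    def test_engines_agree_on_strong_steps(self, rng):
        v = np.concatenate([rng.normal(s, 0.2, 250) for s in (0, 5, -4, 3)])
        tr = axis_trace(v)
        dp = detect_3d(tr, DetectionConfig(alpha=1.6, n_max=15, engine="dp"))
        sweep = detect_3d(tr, DetectionConfig(alpha=1.6, n_max=15, engine="pelt"))
        assert dp.mtp_bins.tolist() == sweep.mtp_bins.tolist() == [250, 500, 750]

    def test_too_few_unmasked_bins_rejected(self):
        v = np.array([1.0, np.nan, np.nan])
        with pytest.raises(ValueError):
            detect_3d(axis_trace(v), self.CFG)

    def test_translation_invariance_of_detection(self, rng):
        v = np.concatenate([rng.normal(0, 0.3, 300), rng.normal(4, 0.3, 300)])
        tr1 = axis_trace(v)
        tr2 = axis_trace(v + 50.0)
        cfg = DetectionConfig(n_max=10)
        r1, r2 = detect_3d(tr1, cfg), detect_3d(tr2, cfg)
        assert r1.mtp_bins.tolist() == r2.mtp_bins.tolist()
        for ax in "xyz":
            assert r1.per_axis[ax].n_tar == r2.per_axis[ax].n_tar
            assert r1.per_axis[ax].enm.e_nm == pytest.approx(
                r2.per_axis[ax].enm.e_nm, rel=1e-6, abs=1e-9)
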