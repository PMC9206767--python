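"""Detection and motion-estimation accuracy metrics.

Ground-truth motion time points are derived from a high-rate head-location
series (the average coordinate of a set of ROI centers-of-mass, natively
20 Hz) resampled to 1 Hz: any second whose Euclidean displacement to the
next exceeds a mm threshold is a ground-truth MTP.  A detection counts as
correct when it falls within 1 s before or after a ground-truth MTP
(one-to-one greedy nearest matching).  Detectability is the pooled fraction
of ground-truth MTPs matched; the false-positive rate is the fraction of
detections left unmatched.

The mean distance error (MDE, mm) compares two rigid-motion trajectories by
moving each ROI center with both and averaging the Euclidean distance first
across ROIs, then across sampling times.
"""

from __future__ import annotations

import numpy as np

from .simulate import MotionSchedule, location_series

__all__ = [
    "resample_1hz",
    "ground_truth_mtps",
    "match_mtps",
    "detectability",
    "false_positive_rate",
    "mde",
]

DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def resample_1hz(series: np.ndarray, rate: float) -> np.ndarray:
    """Average a (n, 3) location series down to 1 Hz.

    Each output sample is the mean of one second's worth of native samples;
    a trailing partial second is dropped.
    """
    series = np.asarray(series, dtype=float)
    per = int(round(rate))
    n = series.shape[0] // per
    if n < 2:
        raise ValueError("series must cover at least 2 s")
    return series[:n * per].reshape(n, per, 3).mean(axis=1)


def ground_truth_mtps(motion, threshold: float, rate: float = 20.0,
                      duration: float | None = None,
                      points: np.ndarray | None = None) -> np.ndarray:
    """Ground-truth MTP times (seconds) at a displacement threshold.

    ``motion`` is either an (n, 3) location series at ``rate`` Hz or a
    :class:`MotionSchedule` (then ``duration`` is required and the series is
    synthesized from the reference ``points``).  After 1-Hz resampling, the
    per-second displacement ``dl[t] = |l[t+1] - l[t]|`` is computed and an
    MTP is registered at second t+1 (where the new position first holds)
    whenever ``dl[t]`` exceeds the threshold.
    """
    if isinstance(motion, MotionSchedule):
        if duration is None:
            raise ValueError("duration required with a MotionSchedule")
        series = location_series(motion, duration, rate=rate, points=points)
    else:
        series = np.asarray(motion, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("location series must be (n, 3)")
    l1 = resample_1hz(series, rate)
    dl = np.linalg.norm(np.diff(l1, axis=0), axis=1)
    return np.flatnonzero(dl > threshold).astype(float) + 1.0


def match_mtps(detected, truth, window: float = 1.0) -> list[tuple[float, float]]:
    """One-to-one greedy nearest matching of detected to truth MTPs.

    Candidate pairs within ``window`` seconds are accepted in order of
    increasing |time difference| (ties toward earlier truth time); each
    detected MTP validates at most one ground-truth MTP.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    pairs = []
    for ti, tv in enumerate(truth):
        for di, dv in enumerate(detected):
            if abs(dv - tv) <= window + 1e-9:
                pairs.append((abs(dv - tv), tv, ti, di))
    pairs.sort(key=lambda p: (p[0], p[1]))
    used_t, used_d = set(), set()
    matches = []
    for _, _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append((float(truth[ti]), float(detected[di])))
    return matches


def detectability(detected, truth, window: float = 1.0) -> float:
    """Fraction of ground-truth MTPs matched by a detection within +-window s."""
    truth = np.asarray(truth, dtype=float)
    if truth.size == 0:
        raise ValueError("detectability undefined for empty ground truth")
    return len(match_mtps(detected, truth, window)) / truth.size


def false_positive_rate(detected, truth, window: float = 1.0) -> float:
    """Fraction of detected MTPs with no ground-truth MTP within +-window s."""
    detected = np.asarray(detected, dtype=float)
    if detected.size == 0:
        return 0.0
    return 1.0 - len(match_mtps(detected, truth, window)) / detected.size


def mde(roi_centers: np.ndarray, gt: MotionSchedule, est: MotionSchedule,
        sample_times) -> float:
    """Mean distance error between two rigid-motion trajectories, mm.

    Each ROI center is moved by both schedules at each sampling time; the
    Euclidean distances are averaged over ROIs first, then over time.
    """
    roi_centers = np.atleast_2d(np.asarray(roi_centers, dtype=float))
    if roi_centers.shape[0] < 1:
        raise ValueError("at least one ROI required")
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise ValueError("sample_times is empty")
    per_time = np.empty(sample_times.size)
    for k, t in enumerate(sample_times):
        d = np.linalg.norm(gt.apply(roi_centers, t) - est.apply(roi_centers, t),
                           axis=1)
        per_time[k] = d.mean()
    return float(per_time.mean())
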