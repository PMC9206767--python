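"""Adaptive changepoint-based motion detection on COD traces.

The detector models each COD axis as piecewise constant between motion time
points (MTPs) plus Gaussian noise.  For a given number of changepoints *n*
the optimal MTP placement minimizes the total within-segment residual sum of
squares E; the curve of minima E_min(n) is non-increasing in n.  The number
of MTPs is chosen adaptively: the no-motion error of the scan, E_NM, is
predicted from the longest motion-free frames (MFFs) inside equal-duration
partitions of the scan (which adapts the prediction to isotope decay and
tracer clearance), inflated by a tracer-dependent factor alpha >= 1 into a
target error E_tar = alpha * E_NM, and n_tar is the smallest n whose E_min
does not exceed E_tar.  Detection runs independently per axis; the final
MTP set is the union over the three axes.

Two engines provide E_min:

``dp``
    exact segment-neighborhood dynamic programming, O(n_max * T^2) — every
    n in 0..n_max is solved to global optimality;
``pelt``
    a CROPS-style penalty sweep of PELT runs, which attains exactly the n
    on the lower convex hull of the E_min curve (off-hull n are filled by
    linear interpolation and flagged; they are never selected as n_tar).

``auto`` picks ``dp`` for traces up to 2000 unmasked bins and the penalty
sweep above that.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .trace import AXES, CODTrace, Partition, make_partitions

__all__ = [
    "DetectionConfig",
    "Segmentation",
    "EminCurve",
    "NoMotionErrorEstimate",
    "AxisDetection",
    "DetectionResult",
    "segment_rss",
    "optimal_segmentation_exact",
    "pelt_penalized",
    "scout_emin",
    "estimate_enm",
    "select_ntar",
    "detect_3d",
]

_DP_MAX_BINS = 2000  # "auto" engine switch-over


@dataclass
class DetectionConfig:
    """Detector parameters.

    alpha : float
        Inflation factor on the predicted no-motion error (>= 1).  1.0 suits
        tracers with broad uptake (FDG-like); 1.6 suits focal distributions
        (raclopride-like) and is an acceptable single choice for both.
    n_max : int
        Upper end of the E_min scouting range (300 for a 90-min scan,
        200 for 60 min).
    partition_duration : float
        Seconds per no-motion-prediction partition (default 300 s).
    p_longest : int
        Number of longest MFFs per partition used for the prediction.
    bin_duration : float
        COD sampling interval, seconds.
    engine : {"auto", "dp", "pelt"}
    """

    alpha: float = 1.0
    n_max: int = 300
    partition_duration: float = 300.0
    p_longest: int = 2
    bin_duration: float = 1.0
    engine: str = "auto"

    def __post_init__(self) -> None:
        if self.alpha < 1.0:
            raise ValueError("alpha must be >= 1")
        if self.n_max < 1 or self.p_longest < 1:
            raise ValueError("n_max and p_longest must be positive")
        if self.partition_duration <= 0 or self.bin_duration <= 0:
            raise ValueError("durations must be positive")
        if self.engine not in ("auto", "dp", "pelt"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @classmethod
    def fdg(cls, **kw) -> "DetectionConfig":
        """Preset for broad-uptake tracers, 90-min scans."""
        return cls(**{"alpha": 1.0, "n_max": 300, **kw})

    @classmethod
    def raclopride(cls, **kw) -> "DetectionConfig":
        """Preset for focal tracers, 60-min scans."""
        return cls(**{"alpha": 1.6, "n_max": 200, **kw})


# ---------------------------------------------------------------------------
# axis handling: masked bins are compressed out before the DP runs

class _AxisData:
    """One COD axis with its mask compressed away.

    ``orig[c]`` maps compressed index c back to the original bin index; a
    changepoint between compressed bins c-1 and c lives at original bin
    ``orig[c]`` (the first bin of the right-hand segment).
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        self.n_bins = values.size
        self.orig = np.flatnonzero(np.isfinite(values))
        if self.orig.size == 0:
            raise ValueError("axis has no unmasked bins")
        self.values = values[self.orig]
        self.T = self.orig.size
        self.s1, self.s2, self.floor = K.prepare_prefix(self.values)

    def map_cps(self, cps: np.ndarray) -> np.ndarray:
        return self.orig[np.asarray(cps, dtype=np.int64)]


def segment_rss(values: np.ndarray, start: int = 0, stop: int | None = None):
    """Mean, RSS and unmasked count of ``values[start:stop]`` (NaN = masked).

    Two-pass mean-then-deviations evaluation.
    """
    v = np.asarray(values, dtype=np.float64)[start:stop]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("segment contains no unmasked bins")
    mean = float(v.mean())
    d = v - mean
    return {"mean": mean, "rss": float(d @ d), "n": int(v.size)}


@dataclass
class Segmentation:
    """An ordered MTP set with its MFFs and total error E.

    MTP indices are on the original bin grid: an MTP at index k separates
    bin k-1 from bin k.  MFF ranges are half-open ``[start, stop)`` bin
    ranges tiling the whole trace; per-MFF statistics are computed over
    unmasked bins only.
    """

    n: int
    mtps: np.ndarray
    mff_bounds: np.ndarray       # length n+2, includes 0 and n_bins
    mff_n: np.ndarray            # unmasked bins per MFF
    mff_mean: np.ndarray
    mff_rss: np.ndarray
    E: float

    @property
    def mffs(self) -> list[tuple[int, int]]:
        return list(zip(self.mff_bounds[:-1].tolist(), self.mff_bounds[1:].tolist()))


def _build_segmentation(values: np.ndarray, mtps_orig: np.ndarray) -> Segmentation:
    values = np.asarray(values, dtype=np.float64)
    mtps_orig = np.asarray(mtps_orig, dtype=np.int64)
    bounds = np.concatenate(([0], mtps_orig, [values.size]))
    means, rss, ns = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        st = segment_rss(values, int(a), int(b))
        means.append(st["mean"])
        rss.append(st["rss"])
        ns.append(st["n"])
    return Segmentation(n=mtps_orig.size, mtps=mtps_orig, mff_bounds=bounds,
                        mff_n=np.array(ns), mff_mean=np.array(means),
                        mff_rss=np.array(rss), E=float(sum(rss)))


def optimal_segmentation_exact(values: np.ndarray, n: int) -> Segmentation:
    """Globally optimal segmentation with exactly ``n`` changepoints.

    Segment-neighborhood dynamic programming; ties broken toward the
    earlier changepoint index.
    """
    ax = _AxisData(values)
    if not 0 <= n < ax.T:
        raise ValueError(f"n={n} out of range for {ax.T} unmasked bins")
    E, B = K.segment_neighborhood(ax.s1, ax.s2, ax.floor, n)
    cps = K.backtrack_segneigh(B, n, ax.T)
    return _build_segmentation(values, ax.map_cps(cps))


def pelt_penalized(values: np.ndarray, penalty: float) -> Segmentation:
    """Minimize E + penalty * n over all segmentations (PELT pruning).

    Identical to un-pruned optimal partitioning.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    ax = _AxisData(values)
    prev = K.pelt(ax.s1, ax.s2, ax.floor, float(penalty))
    cps = K.backtrack_pelt(prev)
    return _build_segmentation(values, ax.map_cps(cps))


@dataclass
class EminCurve:
    """E_min as a function of changepoint count n for one axis.

    ``provenance[n]`` is one of ``exact_dp``, ``penalty_sweep`` or
    ``interpolated-not-attained``; only attained n carry a segmentation.
    """

    n_max: int
    e: np.ndarray
    provenance: list[str]
    _axis: _AxisData = field(repr=False)
    _cps: dict = field(repr=False)       # attained n -> compressed cps
    _extra: dict = field(repr=False, default_factory=dict)  # attained n > n_max

    @property
    def attained(self) -> list[int]:
        return sorted(self._cps)

    def segmentation(self, n: int) -> Segmentation:
        store = self._cps if n in self._cps else self._extra
        if n not in store:
            raise KeyError(f"n={n} was not attained by the scouting engine")
        return _build_segmentation_from_axis(self._axis, store[n])

    def segmentation_at_least(self, n: int) -> Segmentation:
        """Attained segmentation with the smallest n >= requested n."""
        cand = [m for m in list(self._cps) + list(self._extra) if m >= n]
        if not cand:
            return self.segmentation(max(self.attained))
        return self.segmentation(min(cand))


def _build_segmentation_from_axis(ax: _AxisData, cps: np.ndarray) -> Segmentation:
    full = np.full(ax.n_bins, np.nan)
    full[ax.orig] = ax.values
    return _build_segmentation(full, ax.map_cps(cps))


def _scout_dp(ax: _AxisData, n_max: int) -> EminCurve:
    E, B = K.segment_neighborhood(ax.s1, ax.s2, ax.floor, n_max)
    e = E[:, ax.T].copy()
    cps = {n: K.backtrack_segneigh(B, n, ax.T) for n in range(n_max + 1)}
    return EminCurve(n_max=n_max, e=e, provenance=["exact_dp"] * (n_max + 1),
                     _axis=ax, _cps=cps)


def _crops_sweep(ax: _AxisData, n_max: int):
    """Penalty sweep collecting all convex-hull points of E_min up to n_max."""
    sols: dict[int, tuple[float, np.ndarray]] = {}

    def run(beta: float):
        prev = K.pelt(ax.s1, ax.s2, ax.floor, float(beta))
        cps = K.backtrack_pelt(prev)
        e = K.total_rss(ax.s1, ax.s2, ax.floor, cps)
        n = cps.size
        if n not in sols or e < sols[n][0]:
            sols[n] = (e, cps)
        return n, e

    beta_hi = K.total_rss(ax.s1, ax.s2, ax.floor, np.array([], dtype=np.int64))
    beta_hi = max(beta_hi * 1.001, ax.floor, 1e-300)
    n_hi, e_hi = run(beta_hi)
    target = min(n_max, ax.T - 1)
    beta = beta_hi
    n_lo, e_lo = n_hi, e_hi
    while n_lo < target and beta > 1e-14 * beta_hi:
        beta /= 8.0
        n_lo, e_lo = run(beta)
    if n_lo < target:
        n_lo, e_lo = run(0.0)
    stack = [((n_lo, e_lo), (n_hi, e_hi))]
    while stack:
        (na, ea), (nb, eb) = stack.pop()   # na > nb
        if na <= nb + 1:
            continue
        beta_int = (eb - ea) / (na - nb)
        ni, ei = run(beta_int)
        if ni >= na or ni <= nb:
            continue
        stack.append(((na, ea), (ni, ei)))
        stack.append(((ni, ei), (nb, eb)))
    return sols


def _scout_pelt(ax: _AxisData, n_max: int) -> EminCurve:
    sols = _crops_sweep(ax, n_max)
    e = np.full(n_max + 1, np.nan)
    provenance = ["interpolated-not-attained"] * (n_max + 1)
    cps = {}
    extra = {}
    for n, (en, c) in sols.items():
        if n <= n_max:
            e[n] = en
            provenance[n] = "penalty_sweep"
            cps[n] = c
        else:
            extra[n] = c
    # fill off-hull n by linear interpolation between attained neighbours
    att = sorted(cps)
    for lo, hi in zip(att[:-1], att[1:]):
        for n in range(lo + 1, hi):
            w = (n - lo) / (hi - lo)
            e[n] = (1 - w) * e[lo] + w * e[hi]
    if att and att[-1] < n_max:
        e[att[-1] + 1:] = e[att[-1]]
    return EminCurve(n_max=n_max, e=e, provenance=provenance, _axis=ax,
                     _cps=cps, _extra=extra)


def scout_emin(values: np.ndarray, n_max: int, engine: str = "dp") -> EminCurve:
    """E_min(n) for n = 0..n_max on one axis (E_min scouting).

    The curve is non-increasing; at n = unmasked bins - 1 it reaches
    exactly zero (every segment a single sample).
    """
    ax = _AxisData(values)
    if not 0 < n_max < ax.T:
        raise ValueError(f"n_max={n_max} out of range for {ax.T} unmasked bins")
    if engine == "auto":
        engine = "dp" if ax.T <= _DP_MAX_BINS else "pelt"
    if engine == "dp":
        return _scout_dp(ax, n_max)
    if engine == "pelt":
        return _scout_pelt(ax, n_max)
    raise ValueError(f"unknown engine {engine!r}")


@dataclass
class NoMotionErrorEstimate:
    """Predicted no-motion RSS per partition and for the whole scan."""

    rss_nm: np.ndarray          # per partition
    n_part: np.ndarray          # sampling intervals per partition
    empty_partitions: list[int]
    e_nm: float
    alpha: float | None = None
    e_tar: float | None = None

    def predicted_sd(self, s: int) -> float:
        """sqrt(RSS_NM,s / N_PART,s) — per-bin no-motion SD of partition s."""
        if self.n_part[s] == 0:
            return 0.0
        return float(np.sqrt(self.rss_nm[s] / self.n_part[s]))


def estimate_enm(values: np.ndarray, segmentation_at_nmax: Segmentation,
                 partitions: list[Partition], p_longest: int = 2) -> NoMotionErrorEstimate:
    """Predict the no-motion error E_NM from the longest MFFs per partition.

    For partition s the no-motion RSS is
    ``RSS_NM,s = N_PART,s * sum_p RSS_LONG,p / sum_p N_LONG,p`` over the
    ``p_longest`` longest MFFs inside the partition (all of them if fewer).
    An MFF extending beyond the partition contributes the RSS and count of
    its within-partition portion, refit with the portion's own mean.
    """
    if p_longest < 1:
        raise ValueError("p_longest must be >= 1")
    values = np.asarray(values, dtype=np.float64)
    seg = segmentation_at_nmax
    rss_nm = np.zeros(len(partitions))
    n_part = np.array([p.n_part for p in partitions], dtype=np.int64)
    empty = []
    for p in partitions:
        cand = []  # (N, start, rss)
        for (a, b), rm, nm in zip(seg.mffs, seg.mff_rss, seg.mff_n):
            oa, ob = max(a, p.start_bin), min(b, p.end_bin)
            if ob <= oa:
                continue
            if a >= p.start_bin and b <= p.end_bin:
                if nm > 0:
                    cand.append((int(nm), a, float(rm)))
            else:
                seg_vals = values[oa:ob]
                if np.any(np.isfinite(seg_vals)):
                    st = segment_rss(values, oa, ob)
                    cand.append((st["n"], oa, st["rss"]))
        if not cand:
            empty.append(p.index)
            continue
        cand.sort(key=lambda c: (-c[0], c[1]))
        top = cand[:p_longest]
        num = sum(c[2] for c in top)
        den = sum(c[0] for c in top)
        rss_nm[p.index] = p.n_part * num / den if den > 0 else 0.0
    return NoMotionErrorEstimate(rss_nm=rss_nm, n_part=n_part,
                                 empty_partitions=empty, e_nm=float(rss_nm.sum()))


def select_ntar(curve: EminCurve, e_tar: float):
    """Smallest n with E_min(n) <= E_tar, with its optimizing segmentation.

    With a penalty-sweep curve only attained n are eligible (interpolated
    values have no realizable segmentation).  If even n_max misses the
    target the result is n_max with ``target_unreachable`` flagged.
    """
    if e_tar < 0:
        raise ValueError("e_tar must be >= 0")
    warnings: list[str] = []
    for n in curve.attained:
        if curve.e[n] <= e_tar:
            return n, curve.segmentation(n), warnings
    warnings.append("target_unreachable")
    n = max(curve.attained)
    return n, curve.segmentation(n), warnings


@dataclass
class AxisDetection:
    axis: str
    curve: EminCurve
    enm: NoMotionErrorEstimate
    n_tar: int
    segmentation: Segmentation
    warnings: list[str]


@dataclass
class DetectionResult:
    """Merged three-axis detection with per-axis diagnostics."""

    per_axis: dict[str, AxisDetection]
    mtp_bins: np.ndarray
    mtp_times: np.ndarray
    mff_bounds: np.ndarray       # merged, bin indices, includes 0 and n_bins
    config: DetectionConfig
    bin_duration: float

    @property
    def mffs(self) -> list[tuple[int, int]]:
        return list(zip(self.mff_bounds[:-1].tolist(), self.mff_bounds[1:].tolist()))

    @property
    def mff_intervals(self) -> list[tuple[float, float]]:
        """Merged MFFs as half-open [start, end) intervals in seconds."""
        return [(a * self.bin_duration, b * self.bin_duration) for a, b in self.mffs]


def detect_3d(trace: CODTrace, config: DetectionConfig | None = None) -> DetectionResult:
    """Run adaptive motion detection on all three COD axes and merge.

    Per axis: E_min scouting up to n_max, E_NM prediction from the n_max
    segmentation, E_tar = alpha * E_NM, first-crossing selection of n_tar.
    The merged MTP list is the sorted deduplicated union over axes; merged
    MFFs are rebuilt from it.
    """
    if config is None:
        config = DetectionConfig()
    if abs(config.bin_duration - trace.bin_duration) > 1e-9:
        config = replace(config, bin_duration=trace.bin_duration)
    partitions = make_partitions(trace, config.partition_duration)
    per_axis: dict[str, AxisDetection] = {}
    for axname in AXES:
        values = trace.axis(axname)
        n_unmasked = int(np.isfinite(values).sum())
        if n_unmasked < 2:
            raise ValueError(f"axis {axname} has fewer than 2 unmasked bins")
        warn: list[str] = []
        n_max = config.n_max
        if n_max >= n_unmasked:
            n_max = n_unmasked - 1
            warn.append(f"n_max clamped to {n_max}")
        engine = config.engine
        if engine == "auto":
            engine = "dp" if n_unmasked <= _DP_MAX_BINS else "pelt"
        curve = scout_emin(values, n_max, engine=engine)
        seg_nmax = curve.segmentation_at_least(n_max)
        enm = estimate_enm(values, seg_nmax, partitions, config.p_longest)
        enm.alpha = config.alpha
        enm.e_tar = config.alpha * enm.e_nm
        n_tar, seg, w2 = select_ntar(curve, enm.e_tar)
        if w2:
            _warnings.warn(f"axis {axname}: E_tar unreachable within n_max", stacklevel=2)
        per_axis[axname] = AxisDetection(axis=axname, curve=curve, enm=enm,
                                         n_tar=n_tar, segmentation=seg,
                                         warnings=warn + w2)
    merged = np.unique(np.concatenate(
        [per_axis[a].segmentation.mtps for a in AXES]).astype(np.int64))
    bounds = np.concatenate(([0], merged, [trace.n_bins]))
    return DetectionResult(per_axis=per_axis, mtp_bins=merged,
                           mtp_times=merged * trace.bin_duration,
                           mff_bounds=bounds, config=config,
                           bin_duration=trace.bin_duration)


def detection_report(result: DetectionResult) -> dict:
    """JSON-serializable detection report with per-axis diagnostics."""
    out = {
        "config": {
            "alpha": result.config.alpha,
            "n_max": result.config.n_max,
            "partition_duration": result.config.partition_duration,
            "p_longest": result.config.p_longest,
            "bin_duration": result.config.bin_duration,
            "engine": result.config.engine,
        },
        "mtp_times": result.mtp_times.tolist(),
        "mff_intervals": result.mff_intervals,
        "axes": {},
    }
    for axname, det in result.per_axis.items():
        out["axes"][axname] = {
            "n_tar": det.n_tar,
            "e_nm": det.enm.e_nm,
            "e_tar": det.enm.e_tar,
            "rss_nm_per_partition": det.enm.rss_nm.tolist(),
            "emin": [None if not np.isfinite(v) else float(v) for v in det.curve.e],
            "emin_provenance": det.curve.provenance,
            "mtp_times": (det.segmentation.mtps * result.bin_duration).tolist(),
            "warnings": det.warnings,
        }
    return out
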