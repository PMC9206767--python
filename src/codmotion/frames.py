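"""Final motion-free-frame (MFF) determination.

After detection, some MFFs still contain residual intra-frame motion (the
changepoint model only captures instantaneous steps) and some hold too few
counts for reliable downstream registration.  Both kinds are discarded:

* intra-frame motion: an MFF is discarded when, on any axis, the standard
  deviation of the COD within the MFF exceeds twice the predicted no-motion
  SD ``sqrt(RSS_NM,s / N_PART,s)`` of the partition(s) hosting the MFF
  (strictly greater; an MFF spanning partitions uses the unmasked-bin-count
  weighted average of the per-partition predictions);
* low counts: a kept MFF whose summed true-coincidence counts fall below a
  threshold (2 million for real scanner data; scaled down for synthetic
  work) cannot be registered robustly and is discarded.

Statuses are final and the intra-motion rule is applied first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .detection import DetectionResult
from .trace import AXES, CODTrace, make_partitions

__all__ = [
    "FrameDecision",
    "prune_intra_motion",
    "prune_low_count",
    "discarded_summary",
    "write_gating",
    "read_gating",
]

KEPT = "kept"
DISCARDED_INTRA = "discarded_intra_motion"
DISCARDED_LOW = "discarded_low_count"

# COD variation below this (mm) is numerically indistinguishable from zero
# and never counts as intra-frame motion.
SD_FLOOR_MM = 1e-9


@dataclass
class FrameDecision:
    start: float                 # seconds, half-open [start, end)
    end: float
    status: str
    sd: dict                     # per-axis SD of COD within the MFF (NaN if <2 bins)
    predicted_sd: dict           # per-axis prediction from host partition(s)
    counts: int


def _mff_sd(values: np.ndarray, a: int, b: int) -> float:
    v = values[a:b]
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def prune_intra_motion(result: DetectionResult, trace: CODTrace) -> list[FrameDecision]:
    """Flag merged MFFs whose within-frame COD SD betrays residual motion.

    Discards an MFF iff on *any* axis SD > 2 x predicted partition SD
    (strict inequality; SD undefined for MFFs with < 2 unmasked bins, which
    are kept by this rule).
    """
    partitions = make_partitions(trace, result.config.partition_duration)
    mask = trace.mask
    decisions: list[FrameDecision] = []
    dt = trace.bin_duration
    for a, b in result.mffs:
        sds = {}
        preds = {}
        discard = False
        for axname in AXES:
            det = result.per_axis[axname]
            sds[axname] = _mff_sd(trace.axis(axname), a, b)
            # weight each spanned partition by the MFF's unmasked bins inside it
            wsum = 0.0
            acc = 0.0
            for p in partitions:
                oa, ob = max(a, p.start_bin), min(b, p.end_bin)
                if ob <= oa:
                    continue
                w = int(mask[oa:ob].sum())
                if w == 0:
                    continue
                acc += w * det.enm.predicted_sd(p.index)
                wsum += w
            preds[axname] = acc / wsum if wsum > 0 else 0.0
            if np.isfinite(sds[axname]) and sds[axname] > max(2.0 * preds[axname],
                                                              SD_FLOOR_MM):
                discard = True
        counts = int(trace.counts[a:b].sum())
        decisions.append(FrameDecision(start=a * dt, end=b * dt,
                                       status=DISCARDED_INTRA if discard else KEPT,
                                       sd=sds, predicted_sd=preds, counts=counts))
    return decisions


def prune_low_count(decisions: list[FrameDecision], trace: CODTrace,
                    min_counts: int = 2_000_000) -> list[FrameDecision]:
    """Re-flag kept MFFs with fewer than ``min_counts`` summed counts.

    Earlier statuses are final: a frame already discarded for intra-frame
    motion keeps that status.
    """
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    out = []
    for d in decisions:
        if d.status == KEPT and d.counts < min_counts:
            d = FrameDecision(start=d.start, end=d.end, status=DISCARDED_LOW,
                              sd=d.sd, predicted_sd=d.predicted_sd, counts=d.counts)
        out.append(d)
    return out


def discarded_summary(decisions: list[FrameDecision]) -> dict:
    """Discarded time in seconds and as percent of the scan, per Fig.-caption style."""
    total = sum(d.end - d.start for d in decisions)
    disc = sum(d.end - d.start for d in decisions if d.status != KEPT)
    return {"discarded_seconds": disc, "total_seconds": total,
            "discarded_percent": 100.0 * disc / total if total > 0 else 0.0}


def write_gating(decisions: list[FrameDecision], path) -> None:
    """Gating CSV ``start,end,status`` — which frames feed reconstruction."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start", "end", "status"])
        for d in decisions:
            w.writerow([f"{d.start:.6g}", f"{d.end:.6g}", d.status])


def read_gating(path) -> list[tuple[float, float, str]]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    return [(float(r["start"]), float(r["end"]), r["status"]) for r in rows]
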