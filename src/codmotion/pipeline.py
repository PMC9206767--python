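"""End-to-end pipeline: simulate/load -> COD -> detect -> prune -> reports.

All randomness flows from one top-level seed, split deterministically per
stage, so a run with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .detection import DetectionConfig, DetectionResult, detect_3d, detection_report
from .frames import FrameDecision, discarded_summary, prune_intra_motion, \
    prune_low_count, write_gating
from .simulate import MotionSchedule, fdg_like_study
from .trace import CODTrace, compute_cod, read_events, read_trace, write_trace

__all__ = [
    "RunConfig",
    "run_pipeline",
    "make_fixtures",
    "write_schedule",
    "read_schedule",
]


def write_schedule(schedule: MotionSchedule, path) -> None:
    """Motion-schedule CSV ``t,r11..r33,tx,ty,tz`` (one row per breakpoint)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t"] + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
                   + ["tx", "ty", "tz"])
        for k in range(schedule.breakpoints.size):
            w.writerow([f"{schedule.breakpoints[k]:.6g}"]
                       + [repr(float(v)) for v in schedule.rotations[k].ravel()]
                       + [repr(float(v)) for v in schedule.translations[k]])


def read_schedule(path) -> MotionSchedule:
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    t = np.array([float(r["t"]) for r in rows])
    rot = np.array([[float(r[f"r{i}{j}"]) for i in (1, 2, 3) for j in (1, 2, 3)]
                    for r in rows]).reshape(-1, 3, 3)
    tr = np.array([[float(r["tx"]), float(r["ty"]), float(r["tz"])] for r in rows])
    return MotionSchedule(t, rot, tr)


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    seed: int = 0
    out_dir: str = "codmotion_run"
    trace: str | None = None             # path to a COD trace CSV
    events: str | None = None            # path to an event CSV
    simulate: dict | None = None         # kwargs for fdg_like_study
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    min_counts: int = 0
    bin_duration: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        det = raw.pop("detection", {})
        if isinstance(det, dict):
            dknown = {f.name for f in fields(DetectionConfig)}
            dunknown = set(det) - dknown
            if dunknown:
                raise ValueError(f"unknown detection keys: {sorted(dunknown)}")
            det = DetectionConfig(**det)
        return cls(detection=det, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and persist every stage's artifact.

    Resolution order for the input trace: ``simulate`` spec, then
    ``events`` file (binned to COD), then ``trace`` file.  Returns the
    in-memory objects alongside the written report paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.simulate is not None:
        sim = fdg_like_study(seed=config.seed, **config.simulate)
        trace = sim.trace
        truth = sim.schedule
        write_trace(trace, out / "trace.csv")
        write_schedule(truth, out / "truth_schedule.csv")
    elif config.events is not None:
        events = read_events(config.events)
        trace = compute_cod(events, bin_duration=config.bin_duration)
        write_trace(trace, out / "trace.csv")
    elif config.trace is not None:
        trace = read_trace(config.trace)
    else:
        raise ValueError("pipeline: config must provide simulate, events or trace")

    try:
        result = detect_3d(trace, config.detection)
    except Exception as exc:  # pragma: no cover - stage labeling only
        raise RuntimeError(f"detect stage failed: {exc}") from exc
    decisions = prune_intra_motion(result, trace)
    decisions = prune_low_count(decisions, trace, config.min_counts)

    report = detection_report(result)
    report["provenance"] = {"seed": config.seed, "config": config.to_dict()}
    report["discarded"] = discarded_summary(decisions)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    write_gating(decisions, out / "gating.csv")
    return {"trace": trace, "result": result, "decisions": decisions,
            "truth": truth, "report": report, "out_dir": str(out)}


# ---------------------------------------------------------------------------
# canonical miniature fixtures

def _enumerate_emin(values: np.ndarray, n: int) -> float:
    """Exhaustive minimum total RSS with exactly n changepoints (tiny traces)."""
    values = np.asarray(values, dtype=float)
    T = values.size
    best = np.inf
    for cps in itertools.combinations(range(1, T), n):
        bounds = (0,) + cps + (T,)
        e = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = values[a:b]
            e += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, e)
    return best


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the small canonical test inputs used across the test suite.

    * ``step50``  — 100-bin noise-free unit step at bin 50 + expected MTP;
    * ``threelevel`` — noise-free three-level trace (two true steps);
    * ``rand20`` — seeded 20-bin Gaussian trace + brute-force E_min table
      for n = 0..4 computed by exhaustive enumeration at build time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    step = np.concatenate([np.zeros(50), np.full(50, 10.0)])
    _write_axis_trace(step, out / "step50.csv")
    (out / "step50.expected.json").write_text(json.dumps({"mtps": [50]}))

    tl = np.concatenate([np.zeros(20), np.full(20, 5.0), np.full(20, -3.0)])
    _write_axis_trace(tl, out / "threelevel.csv")
    (out / "threelevel.expected.json").write_text(
        json.dumps({"mtps": [20, 40], "emin2": 0.0}))

    rand20 = rng.standard_normal(20)
    _write_axis_trace(rand20, out / "rand20.csv")
    table = {str(n): _enumerate_emin(rand20, n) for n in range(5)}
    (out / "rand20.emin.json").write_text(json.dumps(table))
    return {"step50": step, "threelevel": tl, "rand20": rand20,
            "rand20_emin": {int(k): v for k, v in table.items()}}


def _write_axis_trace(values: np.ndarray, path) -> None:
    trace = CODTrace(bin_duration=1.0, cx=values, cy=values.copy(),
                     cz=values.copy(), counts=np.full(values.size, 1000))
    write_trace(trace, path)
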