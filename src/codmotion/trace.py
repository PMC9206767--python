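"""Center-of-tracer-distribution (COD) traces from PET list-mode events.

A COD trace is the per-time-bin mean 3D localization coordinate of PET
coincidence events, in mm from the scanner field-of-view center.  With
time-of-flight (TOF) data the per-event coordinate is the TOF-bin center;
without TOF it is the midpoint of the line of response (LOR).  Step changes
in the trace indicate head motion; the per-bin random component is Gaussian
by the central limit theorem, with SD shrinking as 1/sqrt(counts per bin).

Coordinate convention: x = lateral, y = anterior-posterior,
z = superior-inferior, origin at FOV center, units mm.  Time bins are
half-open ``[t, t + bin_duration)`` on a grid anchored at scan start; an
event exactly on a boundary belongs to the later bin.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXES = ("x", "y", "z")

__all__ = [
    "AXES",
    "EventStream",
    "CODTrace",
    "Partition",
    "compute_cod",
    "make_partitions",
    "read_events",
    "write_events",
    "read_trace",
    "write_trace",
]


@dataclass
class EventStream:
    """Per-event timestamps and 3D localization coordinates.

    Parameters
    ----------
    t : array of float
        Seconds from scan start, nonnegative and nondecreasing.
    x, y, z : array of float
        Event localization in mm from the scanner FOV center.
    mode : {"tof", "nontof"}
        Whether (x, y, z) is a TOF-bin center or an LOR midpoint.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    mode: str = "tof"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.mode not in ("tof", "nontof"):
            raise ValueError(f"mode must be 'tof' or 'nontof', got {self.mode!r}")
        n = self.t.size
        if n == 0:
            raise ValueError("event stream is empty")
        for name in ("x", "y", "z"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError("t, x, y, z must have equal length")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name} coordinate in event stream")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite event time")
        if self.t[0] < 0:
            raise ValueError("negative event time")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("event times must be nondecreasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CODTrace:
    """Time-binned three-axis COD trace with per-bin counts.

    ``cx``, ``cy``, ``cz`` hold NaN where ``counts`` is zero (masked bins);
    a bin with no events has no centroid, so masked bins carry no value and
    are skipped by all downstream residual computations.
    """

    bin_duration: float
    cx: np.ndarray
    cy: np.ndarray
    cz: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cx = np.asarray(self.cx, dtype=np.float64)
        self.cy = np.asarray(self.cy, dtype=np.float64)
        self.cz = np.asarray(self.cz, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_duration <= 0:
            raise ValueError("bin_duration must be positive")
        n = self.counts.size
        if not (self.cx.size == self.cy.size == self.cz.size == n):
            raise ValueError("cx, cy, cz, counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        empty = self.counts == 0
        for arr in (self.cx, self.cy, self.cz):
            arr[empty] = np.nan

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_duration

    @property
    def t_start(self) -> np.ndarray:
        """Left edge of each bin, seconds."""
        return np.arange(self.n_bins) * self.bin_duration

    @property
    def mask(self) -> np.ndarray:
        """True for bins that hold a value (counts > 0)."""
        return self.counts > 0

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.cx, "y": self.cy, "z": self.cz}[name]


@dataclass
class Partition:
    """One equal-duration chunk of the scan used for no-motion RSS prediction.

    ``n_part`` is the number of sampling intervals (bins) inside the span,
    i.e. span / bin_duration rounded down.
    """

    index: int
    start: float
    end: float
    start_bin: int
    end_bin: int
    n_part: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_part = self.end_bin - self.start_bin


def compute_cod(events: EventStream, bin_duration: float = 1.0,
                scan_span: float | None = None) -> CODTrace:
    """Bin an event stream into a three-axis COD trace.

    Each bin's value is the arithmetic mean of the event coordinates falling
    in the half-open interval ``[k*bin_duration, (k+1)*bin_duration)``.
    Bins with no events are masked.

    Parameters
    ----------
    events : EventStream
    bin_duration : float
        Sampling interval in seconds (default 1 s).
    scan_span : float, optional
        Total scan duration; must cover all event times.  Defaults to the
        smallest whole number of bins covering the last event.
    """
    if bin_duration <= 0:
        raise ValueError("bin_duration must be positive")
    t_last = float(events.t[-1])
    if scan_span is None:
        n_bins = int(np.floor(t_last / bin_duration)) + 1
    else:
        if scan_span <= t_last:
            raise ValueError("scan_span must cover all event times")
        n_bins = int(np.ceil(scan_span / bin_duration - 1e-12))
    idx = np.floor(events.t / bin_duration).astype(np.int64)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.empty((3, n_bins))
    for i, coord in enumerate((events.x, events.y, events.z)):
        sums[i] = np.bincount(idx, weights=coord, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return CODTrace(bin_duration=bin_duration, cx=means[0], cy=means[1],
                    cz=means[2], counts=counts)


def make_partitions(trace: CODTrace, partition_duration: float = 300.0) -> list[Partition]:
    """Tile the scan into equal-duration partitions.

    A trailing remainder shorter than ``partition_duration`` is kept as its
    own partition with its true bin count: the no-motion RSS prediction
    scales by the per-partition bin count, so unequal final partitions are
    handled naturally.
    """
    if partition_duration < trace.bin_duration:
        raise ValueError("partition_duration must be at least one bin")
    bins_per = int(np.floor(partition_duration / trace.bin_duration + 1e-9))
    out: list[Partition] = []
    b = 0
    k = 0
    while b < trace.n_bins:
        e = min(b + bins_per, trace.n_bins)
        out.append(Partition(index=k, start=b * trace.bin_duration,
                             end=e * trace.bin_duration, start_bin=b, end_bin=e))
        b = e
        k += 1
    return out


# ---------------------------------------------------------------------------
# I/O: columnar text formats (gzip tolerated by extension)

def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"))
    return open(path, mode)


def write_events(events: EventStream, path) -> None:
    """Write events as CSV with header ``t,x,y,z`` and a mode comment line."""
    with _open_text(path, "w") as fh:
        fh.write(f"# mode={events.mode}\n")
        pd.DataFrame({"t": events.t, "x": events.x, "y": events.y,
                      "z": events.z}).to_csv(fh, index=False)


def read_events(path) -> EventStream:
    with _open_text(path, "r") as fh:
        first = fh.readline().strip()
        mode = "tof"
        if first.startswith("#"):
            if "mode=" in first:
                mode = first.split("mode=")[1].strip()
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(io.StringIO(first + "\n" + fh.read()))
    return EventStream(t=df["t"].to_numpy(), x=df["x"].to_numpy(),
                       y=df["y"].to_numpy(), z=df["z"].to_numpy(), mode=mode)


def write_trace(trace: CODTrace, path) -> None:
    """CSV with header ``t_start,cx,cy,cz,counts``; masked bins have empty fields."""
    df = pd.DataFrame({"t_start": trace.t_start, "cx": trace.cx,
                       "cy": trace.cy, "cz": trace.cz, "counts": trace.counts})
    df.to_csv(path, index=False, na_rep="")


def read_trace(path) -> CODTrace:
    df = pd.read_csv(path)
    t = df["t_start"].to_numpy(dtype=float)
    if t.size < 2:
        bin_duration = 1.0 if t.size == 0 else max(t[0], 1.0)
    else:
        bin_duration = float(np.median(np.diff(t)))
    return CODTrace(bin_duration=bin_duration,
                    cx=df["cx"].to_numpy(dtype=float),
                    cy=df["cy"].to_numpy(dtype=float),
                    cz=df["cz"].to_numpy(dtype=float),
                    counts=df["counts"].fillna(0).to_numpy(dtype=np.int64))
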