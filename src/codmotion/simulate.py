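"""Synthetic PET event streams and COD traces with known ground-truth motion.

Two levels of simulation are provided:

* :func:`simulate_events` draws annihilation events directly from a phantom
  of 3D Gaussian activity blobs under an inhomogeneous Poisson process whose
  rate decays with the isotope half-life, moves them with a piecewise-
  constant rigid-motion schedule, and localizes each event either at a
  TOF-blurred point (TOF mode) or at the midpoint of a chord through the
  scanner bore (non-TOF mode).  Attenuation, scatter and randoms are not
  modeled.
* :func:`simulate_trace` is a direct statistical model of the COD trace
  itself: per-bin value = slow tracer drift + rigid-motion offset +
  Gaussian noise whose SD grows as counts decay,
  ``sigma(t) = sigma0 * 2**(t / (2 * half_life))`` (SD ∝ 1/sqrt(counts)).

Motion step amplitudes are quoted in the 10-cm-cube metric: the mean
displacement of the eight vertices of a 10-cm side-length cube centered in
the FOV, which for a pure translation equals the translation norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import CODTrace, EventStream

__all__ = [
    "F18_HALF_LIFE_MIN",
    "C11_HALF_LIFE_MIN",
    "MotionSchedule",
    "GaussianBlob",
    "PhantomSpec",
    "brain_like_phantom",
    "tof_fwhm_mm",
    "simulate_events",
    "SimulatedTrace",
    "simulate_trace",
    "exponential_drift",
    "fdg_like_study",
    "location_series",
]

F18_HALF_LIFE_MIN = 109.77
C11_HALF_LIFE_MIN = 20.36

_LIGHT_SPEED_MM_PER_PS = 0.299792458

CUBE_VERTICES = np.array([[sx * 50.0, sy * 50.0, sz * 50.0]
                          for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])


def tof_fwhm_mm(fwhm_ps: float) -> float:
    """Localization FWHM along the LOR for a given timing resolution.

    Half the light-travel distance of the timing uncertainty:
    580 ps -> ~87 mm.
    """
    return _LIGHT_SPEED_MM_PER_PS * fwhm_ps / 2.0


@dataclass
class MotionSchedule:
    """Piecewise-constant rigid head motion.

    ``transforms[i]`` (a 3x3 rotation and a translation in mm) is active on
    ``[breakpoints[i], breakpoints[i+1])``; the identity holds before the
    first breakpoint.
    """

    breakpoints: np.ndarray                  # seconds, strictly increasing
    rotations: np.ndarray                    # (k, 3, 3)
    translations: np.ndarray                 # (k, 3) mm

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.float64)
        self.rotations = np.asarray(self.rotations, dtype=np.float64).reshape(-1, 3, 3)
        self.translations = np.asarray(self.translations, dtype=np.float64).reshape(-1, 3)
        k = self.breakpoints.size
        if self.rotations.shape[0] != k or self.translations.shape[0] != k:
            raise ValueError("one transform per breakpoint required")
        if k and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        for r in self.rotations:
            if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
                raise ValueError("rotation matrices must be orthonormal")

    @classmethod
    def identity(cls) -> "MotionSchedule":
        return cls(np.empty(0), np.empty((0, 3, 3)), np.empty((0, 3)))

    @classmethod
    def from_translations(cls, times, displacements) -> "MotionSchedule":
        """Cumulative translations: each step adds ``displacements[i]``."""
        times = np.asarray(times, dtype=np.float64)
        disp = np.cumsum(np.asarray(displacements, dtype=np.float64).reshape(-1, 3),
                         axis=0)
        rots = np.broadcast_to(np.eye(3), (times.size, 3, 3)).copy()
        return cls(times, rots, disp)

    def interval_index(self, t) -> np.ndarray:
        """-1 before the first breakpoint, else index of the active transform."""
        return np.searchsorted(self.breakpoints, np.asarray(t, dtype=float),
                               side="right") - 1

    def apply(self, points: np.ndarray, t) -> np.ndarray:
        """Transform ``points`` (n, 3) by the transform active at scalar time t."""
        i = int(self.interval_index(t))
        points = np.atleast_2d(points)
        if i < 0:
            return points.copy()
        return points @ self.rotations[i].T + self.translations[i]

    def offsets(self, times, reference=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Displacement of a reference point at each time, (n, 3) mm."""
        ref = np.asarray(reference, dtype=float)
        idx = self.interval_index(times)
        out = np.zeros((np.size(times), 3))
        for i in np.unique(idx):
            sel = idx == i
            if i < 0:
                continue
            out[sel] = self.rotations[i] @ ref + self.translations[i] - ref
        return out

    def step_amplitudes(self) -> np.ndarray:
        """Per-breakpoint amplitude: mean 10-cm-cube vertex displacement."""
        amps = np.empty(self.breakpoints.size)
        prev_r, prev_t = np.eye(3), np.zeros(3)
        for i in range(self.breakpoints.size):
            before = CUBE_VERTICES @ prev_r.T + prev_t
            after = CUBE_VERTICES @ self.rotations[i].T + self.translations[i]
            amps[i] = np.linalg.norm(after - before, axis=1).mean()
            prev_r, prev_t = self.rotations[i], self.translations[i]
        return amps


def location_series(schedule: MotionSchedule, duration: float, rate: float = 20.0,
                    points: np.ndarray | None = None) -> np.ndarray:
    """Head location over time: mean of transformed reference points.

    Emulates the average of ROI centers-of-mass sampled at ``rate`` Hz
    (default 20 Hz, the optical-tracker rate); the default point set is the
    10-cm cube.  Returns an (n, 3) array.
    """
    if points is None:
        points = CUBE_VERTICES
    n = int(round(duration * rate))
    if n < 2:
        raise ValueError("series must span at least 2 samples")
    times = np.arange(n) / rate
    com = points.mean(axis=0)
    idx = schedule.interval_index(times)
    out = np.empty((n, 3))
    for i in np.unique(idx):
        sel = idx == i
        if i < 0:
            out[sel] = com
        else:
            moved = (points @ schedule.rotations[i].T + schedule.translations[i])
            out[sel] = moved.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# event-level simulator

@dataclass
class GaussianBlob:
    """One 3D Gaussian activity component."""

    center: tuple = (0.0, 0.0, 0.0)      # mm
    sd: tuple = (30.0, 30.0, 30.0)       # mm, per axis
    activity: float = 1.0                # relative
    washout_per_min: float = 0.0         # mono-exponential decay of relative activity


@dataclass
class PhantomSpec:
    """Activity distribution and acquisition parameters for event simulation."""

    blobs: list = field(default_factory=lambda: [GaussianBlob()])
    half_life_min: float = F18_HALF_LIFE_MIN
    rate0: float = 20_000.0              # events/s at t = 0
    bore_radius_mm: float = 420.0
    tof_fwhm_ps: float = 580.0
    axial_sin_limit: float = 0.3         # LOR axial acceptance, |sin(polar)| bound

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")
        if any(b.activity < 0 for b in self.blobs):
            raise ValueError("activities must be nonnegative")
        if sum(b.activity for b in self.blobs) <= 0:
            raise ValueError("total activity is zero")
        extent = max(np.abs(np.asarray(b.center)).max() + 3 * max(b.sd)
                     for b in self.blobs)
        if self.bore_radius_mm <= extent:
            raise ValueError("bore radius must exceed the phantom extent")


def brain_like_phantom(**kw) -> PhantomSpec:
    """Asymmetric multi-blob phantom roughly the size of a head."""
    blobs = [
        GaussianBlob(center=(0.0, 5.0, 10.0), sd=(45.0, 55.0, 45.0), activity=1.0),
        GaussianBlob(center=(20.0, -25.0, -10.0), sd=(12.0, 12.0, 12.0), activity=0.25),
        GaussianBlob(center=(-15.0, 30.0, 25.0), sd=(10.0, 10.0, 10.0), activity=0.15),
    ]
    return PhantomSpec(blobs=blobs, **kw)


def simulate_events(phantom: PhantomSpec, motion: MotionSchedule, duration: float,
                    seed, mode: str = "tof") -> EventStream:
    """Draw a list-mode-like event stream from a moving phantom.

    Event times follow an inhomogeneous Poisson process with rate
    ``rate0 * 2**(-t / half_life)``; each annihilation point is sampled from
    the moved activity distribution at its time.  TOF mode blurs the point
    along a random LOR direction by the TOF localization FWHM; non-TOF mode
    records the midpoint of the chord through the bore along that direction.
    """
    rng = np.random.default_rng(seed)
    hl = phantom.half_life_min * 60.0
    lam = phantom.rate0 * hl / np.log(2) * (1 - 2 ** (-duration / hl))
    n = int(rng.poisson(lam))
    if n == 0:
        raise ValueError("no events generated; raise rate0 or duration")
    u = rng.random(n)
    t = -hl / np.log(2) * np.log1p(-u * (1 - 2 ** (-duration / hl)))
    t.sort()

    acts = np.array([b.activity for b in phantom.blobs])
    wash = np.array([b.washout_per_min for b in phantom.blobs])
    if np.any(wash > 0):
        w = acts[None, :] * np.exp(-wash[None, :] * t[:, None] / 60.0)
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        blob_idx = (rng.random(n)[:, None] > cum).sum(axis=1)
    else:
        blob_idx = rng.choice(len(acts), size=n, p=acts / acts.sum())

    pts = np.empty((n, 3))
    for bi, blob in enumerate(phantom.blobs):
        sel = blob_idx == bi
        k = int(sel.sum())
        pts[sel] = (np.asarray(blob.center) +
                    rng.standard_normal((k, 3)) * np.asarray(blob.sd))

    # rigid motion, grouped by schedule interval
    idx = motion.interval_index(t)
    for i in np.unique(idx):
        if i < 0:
            continue
        sel = idx == i
        pts[sel] = pts[sel] @ motion.rotations[i].T + motion.translations[i]

    # random LOR direction with limited axial acceptance
    phi = rng.uniform(0, 2 * np.pi, n)
    sz = rng.uniform(-phantom.axial_sin_limit, phantom.axial_sin_limit, n)
    cz = np.sqrt(1 - sz ** 2)
    u_dir = np.column_stack([np.cos(phi) * cz, np.sin(phi) * cz, sz])

    if mode == "tof":
        sigma = tof_fwhm_mm(phantom.tof_fwhm_ps) / 2.3548200450309493
        loc = pts + rng.standard_normal(n)[:, None] * sigma * u_dir
    elif mode == "nontof":
        # chord midpoint within the (infinite) cylinder of the bore radius
        a = u_dir[:, 0] ** 2 + u_dir[:, 1] ** 2
        b = 2 * (pts[:, 0] * u_dir[:, 0] + pts[:, 1] * u_dir[:, 1])
        m = -b / (2 * a)
        loc = pts + m[:, None] * u_dir
    else:
        raise ValueError(f"mode must be 'tof' or 'nontof', got {mode!r}")

    return EventStream(t=t, x=loc[:, 0], y=loc[:, 1], z=loc[:, 2], mode=mode)


# ---------------------------------------------------------------------------
# trace-level simulator

def exponential_drift(amplitudes, tau: float = 1200.0):
    """Smooth settling drift ``a * (1 - exp(-t / tau))`` per axis (mm)."""
    amp = np.asarray(amplitudes, dtype=float).reshape(3)

    def drift(t):
        t = np.asarray(t, dtype=float)
        return amp[None, :] * (1.0 - np.exp(-t / tau))[:, None]

    return drift


@dataclass
class SimulatedTrace:
    """A simulated COD trace bundled with its ground truth."""

    trace: CODTrace
    schedule: MotionSchedule
    true_mtp_bins: np.ndarray
    true_mtp_times: np.ndarray
    offsets: np.ndarray          # (n_bins, 3) motion contribution, mm
    sigma: np.ndarray            # per-bin noise SD, mm


def simulate_trace(noise_sd0: float, half_life_min: float, drift,
                   motion: MotionSchedule, duration: float,
                   bin_duration: float = 1.0, seed=0,
                   rate0: float = 20_000.0) -> SimulatedTrace:
    """Direct statistical model of a three-axis COD trace.

    Per-bin value = drift(t) + motion offset(t) + N(0, sigma(t)^2) with
    ``sigma(t) = noise_sd0 * 2**(t / (2 * half_life))`` — the per-bin SD
    grows as 1/sqrt(counts) while counts decay.  Counts per bin are emitted
    consistently as Poisson draws of the decaying rate.
    """
    if noise_sd0 < 0:
        raise ValueError("noise_sd0 must be nonnegative")
    if half_life_min <= 0 or duration <= 0 or bin_duration <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / bin_duration))
    t = np.arange(n_bins) * bin_duration
    hl = half_life_min * 60.0
    sigma = noise_sd0 * 2.0 ** (t / (2.0 * hl))
    base = np.zeros((n_bins, 3)) if drift is None else np.asarray(drift(t), dtype=float)
    offsets = motion.offsets(t)
    vals = base + offsets
    if noise_sd0 > 0:
        vals = vals + rng.standard_normal((n_bins, 3)) * sigma[:, None]
    counts = rng.poisson(rate0 * bin_duration * 2.0 ** (-t / hl))
    counts = np.maximum(counts, 1)   # the statistical model never yields empty bins
    trace = CODTrace(bin_duration=bin_duration, cx=vals[:, 0], cy=vals[:, 1],
                     cz=vals[:, 2], counts=counts)
    mtp_bins = np.round(motion.breakpoints / bin_duration).astype(np.int64)
    keep = (mtp_bins > 0) & (mtp_bins < n_bins)
    return SimulatedTrace(trace=trace, schedule=motion,
                          true_mtp_bins=mtp_bins[keep],
                          true_mtp_times=mtp_bins[keep] * bin_duration,
                          offsets=offsets, sigma=sigma)


def fdg_like_study(seed, duration: float = 5400.0, n_steps: int = 10,
                   amp_range: tuple = (2.0, 8.0), noise_sd0: float = 0.5,
                   drift_max: float = 1.0, half_life_min: float = F18_HALF_LIFE_MIN,
                   bin_duration: float = 1.0, min_separation: float = 30.0,
                   edge_margin: float = 60.0) -> SimulatedTrace:
    """One FDG-like 90-min study with planted instantaneous steps.

    Steps occur at random integer seconds (at least ``min_separation`` s
    apart and ``edge_margin`` s from the scan edges) along random isotropic
    3D directions with amplitudes uniform over ``amp_range`` mm in the
    10-cm-cube metric; per-axis noise starts at ``noise_sd0`` mm and grows
    with F-18 decay; the baseline drifts smoothly by at most ``drift_max``
    mm over the scan.
    """
    rng = np.random.default_rng(seed)
    # rejection-sample step times on the 1-s grid with minimum separation
    while True:
        times = np.sort(rng.integers(int(edge_margin),
                                     int(duration - edge_margin), n_steps))
        if n_steps < 2 or np.all(np.diff(times) >= min_separation):
            break
    times = times.astype(float)
    amps = rng.uniform(*amp_range, n_steps)
    dirs = rng.standard_normal((n_steps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    schedule = MotionSchedule.from_translations(times, dirs * amps[:, None])
    drift_amp = rng.uniform(-drift_max, drift_max, 3)
    drift = exponential_drift(drift_amp, tau=duration / 4.5)
    return simulate_trace(noise_sd0=noise_sd0, half_life_min=half_life_min,
                          drift=drift, motion=schedule, duration=duration,
                          bin_duration=bin_duration,
                          seed=rng.integers(2 ** 31))
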