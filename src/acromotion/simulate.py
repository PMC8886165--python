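"""Synthetic landmark recordings with known kinematic ground truth.

The generator emulates the geometry of repeated arm abduction/adduction as
seen by a transducer held over the lateral shoulder: the greater tuberosity
travels a circular arc of radius ``true_radius`` about a fixed rotation
centre, sweeping from rest (trough) up to ``true_sweep`` degrees (peak) and
back each cycle, with a sinusoidal-in-time angular profile (smooth start and
stop, as arms are raised and lowered naturally).  The arc is oriented so the
vertical separation below the acromial reference attains exactly
``min_separation`` at peak abduction — the moment the tuberosity rotates
underneath the acromion — while the horizontal coordinate is then maximal,
giving the sine-wave-like X signal used for phase segmentation.

Both landmarks ride a slow common transducer drift (so per-frame referencing
is consequential: a fixed first-frame reference would absorb the drift into
the trajectory) and receive independent isotropic Gaussian annotation
jitter.  A single integer seed fans out to independent substreams for drift
and noise, so changing the noise level never changes the noiseless path or
the drift realisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import Calibration, LandmarkFrame
from .reliability import RatingsTable

__all__ = ["MotionConfig", "GroundTruth", "simulate_recording", "simulate_ratings"]


@dataclass(frozen=True)
class MotionConfig:
    """Kinematic and acquisition parameters of a simulated recording.

    Defaults reflect the study conditions the generator emulates: five
    repetitions sampled at 4 frames/s with a 4 s cycle, a humeral rotation
    radius of 4.86 cm sweeping 36 degrees, and a minimal vertical
    acromiohumeral distance of 0.29 cm at peak abduction.
    """

    true_radius: float = 4.86        # cm, humeral rotation radius
    true_sweep: float = 36.0         # degrees swept per half-cycle
    min_separation: float = 0.29     # cm, vertical AHD at peak abduction
    n_cycles: int = 5
    fps: float = 4.0                 # frames per second
    cycle_period: float = 4.0        # seconds per full abduction+adduction cycle
    noise_sd: float = 0.02           # cm, per-landmark annotation jitter
    abduction_fraction: float = 0.5  # fraction of the cycle spent abducting
    drift_amplitude: float = 0.05    # cm, max common transducer drift
    cm_per_pixel: float = 0.01       # scan calibration used to emit pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_radius <= 0:
            raise ValueError("true_radius must be > 0")
        if not 0 < self.true_sweep < 180:
            raise ValueError("true_sweep must be in (0, 180) degrees")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.fps <= 0 or self.cycle_period <= 0:
            raise ValueError("fps and cycle_period must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 < self.abduction_fraction < 1:
            raise ValueError("abduction_fraction must be in (0, 1)")
        t_ab = self.abduction_fraction * self.cycle_period
        t_ad = self.cycle_period - t_ab
        if min(t_ab, t_ad) * self.fps < 2:
            raise ValueError(
                "configuration yields < 3 samples per phase; raise fps or "
                "cycle_period"
            )

    @property
    def calibration(self) -> Calibration:
        return Calibration.isotropic(self.cm_per_pixel)


@dataclass(frozen=True)
class GroundTruth:
    """Programmed truth of one simulated recording.

    Boundary indices are the samples nearest the true quarter-period
    boundaries; exact times are also kept.  The centre is expressed in the
    relative (GT minus acromion) frame, cm, image-y-down convention.
    """

    trough_indices: np.ndarray
    peak_indices: np.ndarray
    trough_times: np.ndarray
    peak_times: np.ndarray
    center: tuple[float, float]
    true_radius: float
    true_sweep: float
    min_separation: float
    config: MotionConfig


def _phase_fraction(t: np.ndarray, cfg: MotionConfig) -> np.ndarray:
    """Elevation fraction s(t) in [0, 1]: 0 at rest, 1 at peak abduction,
    cosine-smoothed within each half-cycle."""
    tau = np.mod(t, cfg.cycle_period)
    t_ab = cfg.abduction_fraction * cfg.cycle_period
    t_ad = cfg.cycle_period - t_ab
    s = np.where(
        tau <= t_ab,
        0.5 * (1 - np.cos(np.pi * tau / t_ab)),
        0.5 * (1 + np.cos(np.pi * (tau - t_ab) / t_ad)),
    )
    return s


def relative_path(t: np.ndarray, cfg: MotionConfig) -> np.ndarray:
    """Noiseless relative trajectory (cm): (n, 2) array, image-y-down.

    The greater tuberosity sits at angle ``beta = -sweep * (1 - s(t))``
    from the top of its circle about the centre ``(0, min_separation +
    radius)``, so x and the vertical separation both reach their extremes
    exactly at peak abduction.
    """
    sweep = np.radians(cfg.true_sweep)
    beta = -sweep * (1.0 - _phase_fraction(t, cfg))
    r = cfg.true_radius
    yc = cfg.min_separation + r
    return np.column_stack([r * np.sin(beta), yc - r * np.cos(beta)])


def simulate_recording(cfg: MotionConfig) -> tuple[list[LandmarkFrame], GroundTruth]:
    """Generate one landmark recording plus its ground truth.

    Deterministic for a given config (including seed).
    """
    total = cfg.n_cycles * cfg.cycle_period
    n = int(round(total * cfg.fps)) + 1
    t = np.arange(n) / cfg.fps

    rel = relative_path(t, cfg)

    ss = np.random.SeedSequence(cfg.seed)
    ss_drift, ss_noise = ss.spawn(2)
    rng_drift = np.random.default_rng(ss_drift)
    rng_noise = np.random.default_rng(ss_noise)

    # slow common transducer drift, one full wander over the recording
    phases = rng_drift.uniform(0, 2 * np.pi, size=2)
    drift = cfg.drift_amplitude * np.column_stack(
        [np.sin(2 * np.pi * t / total + phases[0]),
         np.sin(2 * np.pi * t / total + phases[1])]
    )

    noise_acr = rng_noise.normal(0.0, cfg.noise_sd, size=(n, 2))
    noise_gt = rng_noise.normal(0.0, cfg.noise_sd, size=(n, 2))

    acr_cm = np.array([3.0, 1.0]) + drift + noise_acr
    gt_cm = np.array([3.0, 1.0]) + drift + rel + noise_gt
    acr_px = acr_cm / cfg.cm_per_pixel
    gt_px = gt_cm / cfg.cm_per_pixel

    frames = [
        LandmarkFrame(
            frame_index=i,
            time=float(t[i]),
            acr=(float(acr_px[i, 0]), float(acr_px[i, 1])),
            gt=(float(gt_px[i, 0]), float(gt_px[i, 1])),
        )
        for i in range(n)
    ]

    t_ab = cfg.abduction_fraction * cfg.cycle_period
    trough_times = np.arange(cfg.n_cycles + 1) * cfg.cycle_period
    peak_times = np.arange(cfg.n_cycles) * cfg.cycle_period + t_ab
    truth = GroundTruth(
        trough_indices=np.round(trough_times * cfg.fps).astype(int),
        peak_indices=np.round(peak_times * cfg.fps).astype(int),
        trough_times=trough_times,
        peak_times=peak_times,
        center=(0.0, cfg.min_separation + cfg.true_radius),
        true_radius=cfg.true_radius,
        true_sweep=cfg.true_sweep,
        min_separation=cfg.min_separation,
        config=cfg,
    )
    return frames, truth


def simulate_ratings(
    truth: np.ndarray, rater_sd: float, k: int = 2, seed: int = 0
) -> RatingsTable:
    """Simulate a complete m x k ratings table around per-target true values.

    Each cell is ``truth[row] + Normal(0, rater_sd^2)``, independent across
    cells — the idealised design of the same clips measured repeatedly by
    one or more raters.
    """
    if rater_sd < 0:
        raise ValueError("rater_sd must be >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    values = truth[:, None] + rng.normal(0.0, rater_sd, size=(truth.size, k))
    return RatingsTable(values)
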