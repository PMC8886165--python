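"""End-to-end analysis: landmark CSV -> per-phase metrics -> report.

The stages run in a fixed order — read, calibrate to the relative
trajectory, detect extrema on the X signal, segment phases, keep the middle
cycles, then compute per-phase minimal vertical AHD, circle fit and rotation
angle, and per-direction averages.  Every warning emitted along the way
(gap interpolation, cycle-trim fallback, clipped separations, angles >= 90
degrees) is captured into the report: the pipeline never modifies data
silently.  Reports are deterministic for fixed input and options, except
for the provenance timestamp.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .landmarks import Calibration, read_landmark_csv, to_relative_trajectory
from .metrics import PhaseMetrics, average_by_direction, compute_phase_metrics
from .phases import detect_extrema, segment_phases, trim_middle_cycles
from .reliability import BlandAltmanResult, bland_altman
from .exceptions import AcromotionError, PairingError

__all__ = [
    "AnalysisOptions",
    "AnalysisReport",
    "analyze",
    "analyze_frames",
    "compare_angles",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable parameters of the analysis pipeline."""

    prominence: float = 0.2        # min extremum prominence, fraction of range
    min_separation: int | None = None  # min extremum spacing, samples
    keep_cycles: int = 3           # middle cycles retained


@dataclass
class AnalysisReport:
    """Full result of one recording's analysis, with provenance."""

    phases: list[PhaseMetrics]
    averages: dict[str, dict[str, float]]
    warnings: list[str]
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-phase table."""
        rows = []
        for m in self.phases:
            rows.append(
                {
                    "direction": m.direction,
                    "cycle": m.cycle,
                    "min_vertical_ahd_cm": m.min_vertical_ahd,
                    "radius_cm": m.fit.rc,
                    "theta_deg": m.rotation.theta,
                    "center_x_cm": m.fit.xc,
                    "center_y_cm": m.fit.yc,
                    "fit_cost_cm2": m.fit.cost,
                    "n_points": m.fit.n_points,
                    "fit_converged": m.fit.converged,
                    "theta_exceeds_90": m.rotation.exceeds_90,
                    "ahd_clipped": m.ahd_clipped,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "phases": [
                {
                    "direction": m.direction,
                    "cycle": m.cycle,
                    "min_vertical_ahd_cm": m.min_vertical_ahd,
                    "radius_cm": m.fit.rc,
                    "theta_deg": m.rotation.theta,
                    "fit": asdict(m.fit),
                    "rotation": asdict(m.rotation),
                    "ahd_clipped": m.ahd_clipped,
                }
                for m in self.phases
            ],
            "averages": self.averages,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def write(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")

    @property
    def abduction_thetas(self) -> list[float]:
        return [m.rotation.theta for m in self.phases if m.direction == "abduction"]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise package errors with the stage name."""

    class _Ctx:
        def __init__(self, n): self.n = n
        def __enter__(self): return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, AcromotionError):
                exc.args = (f"[{self.n}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx(name)


def analyze_frames(
    frames,
    calibration: Calibration,
    options: AnalysisOptions | None = None,
    source: str = "<in-memory>",
) -> AnalysisReport:
    """Run the pipeline from already-loaded landmark frames.

    Errors from any stage propagate as :class:`AcromotionError` subclasses
    with a stage-tagged message.
    """
    options = options or AnalysisOptions()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        with _stage("calibrate"):
            traj = to_relative_trajectory(frames, calibration)
        with _stage("extrema"):
            peaks = detect_extrema(
                traj.x,
                min_prominence_fraction=options.prominence,
                min_separation=options.min_separation,
            )
        with _stage("segment"):
            segments = segment_phases(traj, peaks)
        with _stage("trim"):
            retained = trim_middle_cycles(segments, keep=options.keep_cycles)
        with _stage("metrics"):
            phase_metrics = compute_phase_metrics(traj, retained)
            averages = average_by_direction(phase_metrics)
        caught = [str(w.message) for w in wrec]

    provenance = {
        "input": source,
        "calibration": {
            "cm_per_pixel_x": calibration.cm_per_pixel_x,
            "cm_per_pixel_y": calibration.cm_per_pixel_y,
            "y_axis_down": calibration.y_axis_down,
        },
        "options": asdict(options),
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return AnalysisReport(
        phases=phase_metrics,
        averages=averages,
        warnings=caught,
        provenance=provenance,
    )


def analyze(
    recording_csv,
    calibration: Calibration,
    options: AnalysisOptions | None = None,
) -> AnalysisReport:
    """Run the full pipeline on one landmark CSV (see :func:`analyze_frames`)."""
    with _stage("read"):
        frames = read_landmark_csv(recording_csv)
    return analyze_frames(
        frames, calibration, options=options, source=str(recording_csv)
    )


def compare_angles(
    report: AnalysisReport, external_angles: np.ndarray
) -> BlandAltmanResult:
    """Bland-Altman agreement between an external per-repetition abduction
    angle channel (e.g. an inclinometer) and the humeral-head rotation angle
    of each retained abduction phase, paired in time order.

    The difference is external minus rotation angle; a positive bias means
    whole-arm elevation exceeds the humeral-head rotation, the signature of
    scapular contribution to arm elevation.
    """
    ext = np.asarray(external_angles, dtype=float)
    thetas = np.asarray(report.abduction_thetas, dtype=float)
    if ext.shape != thetas.shape:
        raise PairingError(
            f"{ext.size} external angle(s) vs {thetas.size} retained "
            "abduction phase(s)"
        )
    return bland_altman(ext, thetas)
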