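"""End-to-end orchestration: streams in, averaged cycle curves and
cohort agreement statistics out.

Single-trial flow: read -> gap fill -> zero-lag low-pass -> (hip-centre
regression + sagittal projection for the marker path) -> joint angles ->
trigger detection -> foot-strike segmentation -> 20-cycle selection ->
time normalization -> averaging.  Cohort flow: assemble per-participant
averaged curves into 2x2 panels per joint and run the agreement statistics.
Cohort statistics never re-run per-participant processing; the averaged
curves are the interchange artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    CurvePanel,
    SPMResult,
    mae_curve,
    rmse_per_participant,
    sidak_alpha,
    spm_rm_anova_2way,
)
from .cycles import PERCENT_GRID, build_cycle_set, detect_trigger, segment_cycles
from .kinematics import (
    HipCentreParams,
    StaticCalibration,
    estimate_hip_centre,
    joint_angles,
    project_sagittal,
    static_calibration,
)
from .trajectories import (
    FilterSpec,
    KeypointSeries,
    MarkerSeries,
    fill_gaps,
    lowpass,
    read_keypoints,
    read_markers_csv,
)

__all__ = [
    "RunConfig",
    "TrialResult",
    "preprocess_keypoints",
    "preprocess_markers",
    "sagittal_points_from_markers",
    "process_trial",
    "run_participant",
    "run_cohort_comparison",
]

logger = logging.getLogger(__name__)

#: marker-name -> landmark-name map for the sagittal marker path
DEFAULT_MARKER_MAP = {
    "LACR": "shoulder",
    "LKNE": "knee",
    "LANK": "ankle",
    "LTOE": "big_toe",
}

GAP_WARN_FRACTION = 0.10


class PipelineError(RuntimeError):
    pass


@dataclass
class TrialResult:
    """Per-joint cycle sets plus the events that produced them."""

    cycle_sets: dict
    trigger_frame: int | None
    boundaries: list
    frame_rate: float

    def curves_frame(self) -> pd.DataFrame:
        """Tidy per-cycle curves: columns cycle, percent, joint, angle."""
        rows = []
        for joint, cs in self.cycle_sets.items():
            for c, row in enumerate(cs.normalized):
                rows.append(
                    pd.DataFrame(
                        {"cycle": c, "percent": PERCENT_GRID, "joint": joint, "angle": row}
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def mean_frame(self) -> pd.DataFrame:
        rows = []
        for joint, cs in self.cycle_sets.items():
            rows.append(
                pd.DataFrame(
                    {
                        "percent": PERCENT_GRID,
                        "joint": joint,
                        "mean_deg": cs.mean_curve,
                        "sd_deg": cs.sd_curve,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def preprocess_keypoints(
    series: KeypointSeries, spec: FilterSpec | None = None
) -> KeypointSeries:
    """Gap-fill and zero-lag low-pass every landmark track."""
    spec = spec or FilterSpec()
    points = {}
    for name, track in series.points.items():
        gap_fraction = float(np.isnan(track[:, 0]).mean())
        if gap_fraction > GAP_WARN_FRACTION:
            logger.warning(
                "landmark %s has %.0f%% missing frames", name, 100 * gap_fraction
            )
        points[name] = lowpass(fill_gaps(track), series.frame_rate, spec)
    return KeypointSeries(series.frame_rate, points, side=series.side)


def preprocess_markers(series: MarkerSeries, spec: FilterSpec | None = None) -> MarkerSeries:
    spec = spec or FilterSpec()
    markers = {}
    for name, track in series.markers.items():
        gap_fraction = float(np.isnan(track[:, 0]).mean())
        if gap_fraction > GAP_WARN_FRACTION:
            logger.warning("marker %s has %.0f%% missing frames", name, 100 * gap_fraction)
        markers[name] = lowpass(fill_gaps(track), series.frame_rate, spec)
    return MarkerSeries(series.frame_rate, markers, series.lab_axes)


def sagittal_points_from_markers(
    series: MarkerSeries,
    hip_params: HipCentreParams,
    marker_map: dict | None = None,
    side: str = "left",
) -> dict:
    """2D landmark dict (anterior, vertical; mm) from a filtered marker series.

    The hip landmark is the regressed hip joint centre; the other landmarks
    come from ``marker_map`` (defaults: acromion, lateral epicondyle,
    lateral malleolus, second metatarsal/toe marker).
    """
    marker_map = marker_map or DEFAULT_MARKER_MAP
    hip3d = estimate_hip_centre(series.markers, hip_params, side=side)
    points = {"hip": project_sagittal(hip3d, series.lab_axes)}
    for marker, landmark in marker_map.items():
        if marker not in series.markers:
            raise PipelineError(f"marker {marker!r} absent from the series")
        points[landmark] = project_sagittal(series.markers[marker], series.lab_axes)
    return points


def process_trial(
    series: KeypointSeries | MarkerSeries,
    calib: StaticCalibration,
    *,
    filter_spec: FilterSpec | None = None,
    hip_params: HipCentreParams | None = None,
    trigger_mode: str = "auto",
    n_cycles: int = 20,
    skip: int = 2,
    min_period_s: float = 0.5,
    search_window_s: float = 5.0,
) -> TrialResult:
    """Run the full single-trial pipeline on an in-memory stream."""
    if trigger_mode not in ("auto", "none"):
        raise PipelineError(f"trigger_mode must be auto or none, got {trigger_mode!r}")
    if isinstance(series, MarkerSeries):
        if hip_params is None:
            raise PipelineError("hip_params are required for the marker path")
        filtered = preprocess_markers(series, filter_spec)
        points = sagittal_points_from_markers(filtered, hip_params)
        fs = series.frame_rate
    else:
        filtered = preprocess_keypoints(series, filter_spec)
        points = filtered.points
        fs = series.frame_rate

    angles = joint_angles(points, calib, frame_rate=fs)
    trigger = (
        detect_trigger(points["ankle"][:, 1], fs, search_window_s=search_window_s)
        if trigger_mode == "auto"
        else None
    )
    boundaries = segment_cycles(points["ankle"][:, 0], fs, min_period_s=min_period_s)
    cycle_sets = {
        joint: build_cycle_set(angles[joint], boundaries, trigger, n_cycles=n_cycles, skip=skip)
        for joint in angles
    }
    return TrialResult(cycle_sets, trigger, boundaries, fs)


# ---------------------------------------------------------------------------
# File-level single-participant runner


@dataclass
class RunConfig:
    """Configuration for one participant trial, file-based."""

    input_path: str
    dialect: str = "csv"  # csv | openpifpaf_json | markers_csv
    static_path: str | None = None
    static_dialect: str | None = None  # defaults to the trial dialect
    output_dir: str = "."
    participant: str = "P01"
    frame_rate: float = 60.0
    image_height: float | None = None
    cutoff_hz: float = 6.0
    filter_order: int = 4
    leg_length_mm: float | None = None
    marker_diameter_mm: float = 14.0
    trigger_mode: str = "auto"
    n_cycles: int = 20
    skip: int = 2
    min_period_s: float = 0.5
    search_window_s: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise PipelineError(f"input path does not exist: {self.input_path}")
        if self.static_path is not None and not Path(self.static_path).exists():
            raise PipelineError(f"static calibration path does not exist: {self.static_path}")
        if self.n_cycles < 1:
            raise PipelineError("n_cycles must be >= 1")
        if self.dialect == "markers_csv" and self.leg_length_mm is None:
            raise PipelineError("leg_length_mm is required for the marker path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


def _load_series(config: RunConfig, path: str, dialect: str | None = None):
    dialect = dialect or config.dialect
    if dialect == "markers_csv":
        return read_markers_csv(path, frame_rate=config.frame_rate)
    return read_keypoints(
        path,
        dialect=dialect,
        frame_rate=config.frame_rate,
        image_height=config.image_height if dialect == "openpifpaf_json" else None,
    )


def run_participant(config: RunConfig) -> TrialResult:
    """File-in, file-out single-participant run with provenance."""
    config.validate()
    try:
        series = _load_series(config, config.input_path)
        if config.static_path is None:
            raise PipelineError("a static calibration recording is required")
        static = _load_series(config, config.static_path, config.static_dialect)
        spec = FilterSpec(cutoff_hz=config.cutoff_hz, order=config.filter_order)
        hip_params = (
            HipCentreParams(
                leg_length=config.leg_length_mm, marker_diameter=config.marker_diameter_mm
            )
            if config.leg_length_mm is not None
            else None
        )
        if isinstance(static, MarkerSeries):
            static_points = sagittal_points_from_markers(
                preprocess_markers(static, spec), hip_params
            )
        else:
            static_points = {
                name: fill_gaps(track) for name, track in static.points.items()
            }
        calib = static_calibration(static_points)
        result = process_trial(
            series,
            calib,
            filter_spec=spec,
            hip_params=hip_params,
            trigger_mode=config.trigger_mode,
            n_cycles=config.n_cycles,
            skip=config.skip,
            min_period_s=config.min_period_s,
            search_window_s=config.search_window_s,
        )
    except Exception as exc:
        raise PipelineError(f"participant {config.participant}: {exc}") from exc

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.curves_frame().to_csv(out / f"{config.participant}_cycles.csv", index=False)
    result.mean_frame().to_csv(out / f"{config.participant}_curves.csv", index=False)
    provenance = {
        "software_version": __version__,
        "config": dataclasses.asdict(config),
        "trigger_frame": result.trigger_frame,
        "cycle_boundaries": [list(b) for b in result.boundaries],
        "selected_cycles": {j: cs.selected for j, cs in result.cycle_sets.items()},
    }
    with open(out / f"{config.participant}_provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    return result


# ---------------------------------------------------------------------------
# Cohort comparison


def run_cohort_comparison(
    panels: dict,
    alpha: float = 0.05,
    n_joints: int | None = None,
    method: str = "permutation",
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Agreement statistics for per-joint 2x2 curve panels.

    ``panels`` maps joint name -> :class:`CurvePanel` (participants x
    factor A x factor B x 101).  The family-wise alpha is Šidák-adjusted
    for the number of joints tested.  Returns per joint: the per-percent
    MAE curve per level of factor B, the per-participant RMSE table, and
    the :class:`SPMResult`; plus a tidy mean±SD RMSE summary table.
    """
    n_joints = n_joints if n_joints is not None else len(panels)
    adj_alpha = sidak_alpha(alpha, n_joints)
    results: dict = {"alpha": alpha, "adjusted_alpha": adj_alpha, "joints": {}}
    summary_rows = []
    for j, (joint, panel) in enumerate(panels.items()):
        if not isinstance(panel, CurvePanel):
            panel = CurvePanel(np.asarray(panel), joint=joint)
        spm = spm_rm_anova_2way(
            panel,
            alpha=adj_alpha,
            method=method,
            n_permutations=n_permutations,
            seed=seed + j,
        )
        mae = {}
        rmse = {}
        for ib, level_b in enumerate(panel.factor_b):
            a0 = panel.data[:, 0, ib]
            a1 = panel.data[:, 1, ib]
            mae[level_b] = mae_curve(a0, a1)
            rmse[level_b] = rmse_per_participant(a0, a1)
            summary_rows.append(
                {
                    "joint": joint,
                    "speed": level_b,
                    "comparison": f"{panel.factor_a[0]} vs {panel.factor_a[1]}",
                    "rmse_mean_deg": float(np.mean(rmse[level_b])),
                    "rmse_sd_deg": float(np.std(rmse[level_b], ddof=1)),
                }
            )
        results["joints"][joint] = {"mae": mae, "rmse": rmse, "spm": spm}
    results["summary"] = pd.DataFrame(summary_rows)
    return results


def cohort_results_json(results: dict) -> dict:
    """JSON-serializable digest of :func:`run_cohort_comparison` output."""
    out = {
        "alpha": results["alpha"],
        "adjusted_alpha": results["adjusted_alpha"],
        "joints": {},
        "summary": results["summary"].to_dict(orient="records"),
    }
    for joint, res in results["joints"].items():
        spm: SPMResult = res["spm"]
        out["joints"][joint] = {
            "mae": {k: np.asarray(v).tolist() for k, v in res["mae"].items()},
            "rmse": {k: np.asarray(v).tolist() for k, v in res["rmse"].items()},
            "spm": {
                "threshold_main": spm.threshold_main,
                "threshold_interaction": spm.threshold_interaction,
                "clusters_main": spm.clusters_main,
                "clusters_interaction": spm.clusters_interaction,
                "p_main": spm.p_main,
                "p_interaction": spm.p_interaction,
                "method": spm.method,
                "seed": spm.seed,
            },
        }
    return out
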