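"""Synthetic planar treadmill-running streams with known ground truth.

A planar four-segment runner (trunk line, thigh, shank, foot) is driven by
periodic joint-angle templates (truncated Fourier series over cycle phase)
whose conventions are the exact inverse of :mod:`run2d.kinematics`: feeding
noise-free generated frames through the analysis pipeline must reproduce
the templates.  The generator emulates a typical validation protocol: 30 s
trials at 2.5 and 3.6 m/s, a "butt-kick" synchronization movement about one
second after the start, a 100 Hz 3D marker stream (with a rigid pelvis
cluster placed so the hip-centre regression recovers the true hip point)
and a 60 Hz pixel-space key-point stream with Gaussian noise, dropouts and
optional per-landmark bias (mimicking e.g. the acromion-vs-shoulder
localisation mismatch).

What it does **not** emulate: out-of-plane motion, soft-tissue artefact,
correlated detector errors, or appearance effects of clothing beyond a
constant key-point bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .agreement import CurvePanel
from .kinematics import HipCentreParams
from .trajectories import (
    KeypointSeries,
    LabAxes,
    MarkerSeries,
    write_keypoints_csv,
    write_markers_csv,
)

__all__ = [
    "FourierTemplate",
    "RunnerModel",
    "NoiseSpec",
    "GroundTruth",
    "default_model",
    "forward_kinematics",
    "render_streams",
    "render_static",
    "write_streams",
    "curve_panel",
]


@dataclass(frozen=True)
class FourierTemplate:
    """Periodic angle template: ``a0 + sum_k a_k cos(2 pi k phi) + b_k sin(...)``.

    Being a finite Fourier series it is automatically periodic in value and
    all derivatives at phase 0/1.
    """

    a0: float
    a: tuple = ()
    b: tuple = ()

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full_like(phase, self.a0, dtype=float)
        for k, (ak, bk) in enumerate(zip(self.a, self.b), start=1):
            out += ak * np.cos(2 * np.pi * k * phase) + bk * np.sin(2 * np.pi * k * phase)
        return out


@dataclass
class RunnerModel:
    """Segment lengths (mm), angle templates, cadence and hip excursion."""

    segment_lengths: dict = field(
        default_factory=lambda: {"trunk": 500.0, "thigh": 440.0, "shank": 430.0, "foot": 150.0}
    )
    templates: dict = field(default_factory=dict)
    trunk_lean: FourierTemplate = FourierTemplate(6.0, (1.5,), (1.0,))
    cadence_hz: float = 80.0 / 60.0
    hip_base: tuple = (0.0, 900.0)
    hip_excursion: tuple = (25.0, 45.0)  # horizontal @ 1x, vertical @ 2x cadence
    speed: float = 2.5

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise ValueError("segment lengths must be positive")

    @property
    def leg_length(self) -> float:
        # greater trochanter to medial malleolus, plus malleolus height
        return self.segment_lengths["thigh"] + self.segment_lengths["shank"] + 40.0


def default_model(speed: float = 2.5) -> RunnerModel:
    """Study-condition runner for one of the two treadmill speeds.

    Template shapes are smooth three-harmonic fits resembling published
    sagittal running curves: hip roughly +40 deg flexion to -10 deg
    extension, knee ~10-90 deg flexion, ankle ~ -20..+20 deg.  The faster
    speed has a higher cadence and slightly larger excursions.
    """
    if speed not in (2.5, 3.6):
        raise ValueError("speed must be 2.5 or 3.6 m/s")
    fast = speed == 3.6
    amp = 1.12 if fast else 1.0
    templates = {
        "hip": FourierTemplate(14.0, (22.0 * amp, 4.0 * amp, 1.2), (6.0 * amp, -2.0, 0.8)),
        "knee": FourierTemplate(46.0, (-16.0 * amp, -9.0 * amp, 1.5), (-24.0 * amp, 7.0, -2.0)),
        "ankle": FourierTemplate(-1.0, (7.0 * amp, -4.5, 1.0), (-9.0 * amp, 2.5, 0.8)),
    }
    return RunnerModel(
        templates=templates,
        cadence_hz=(88.0 if fast else 80.0) / 60.0,
        hip_excursion=(25.0 * amp, 45.0 * amp),
        speed=speed,
    )


@dataclass
class NoiseSpec:
    """Measurement-noise model for the rendered streams."""

    pixel_noise_sd: float = 0.0
    gap_probability: float = 0.0
    keypoint_bias: dict = field(default_factory=dict)  # landmark -> (dx, dy) px, image coords
    marker_noise_mm_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap_probability must lie in [0, 1)")
        if self.pixel_noise_sd < 0 or self.marker_noise_mm_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GroundTruth:
    """Exact event times and templates behind a rendered trial."""

    model: RunnerModel
    foot_strike_times: np.ndarray  # seconds
    trigger_time: float | None
    trigger_window: tuple | None
    duration_s: float
    foot_strike_phase: float = 0.0

    def foot_strike_frames(self, fs: float) -> np.ndarray:
        return np.round(self.foot_strike_times * fs).astype(int)

    def trigger_frame(self, fs: float) -> int | None:
        return None if self.trigger_time is None else int(round(self.trigger_time * fs))

    def template_curves(self, n_points: int = 101) -> dict:
        """Prescribed angle curves over one gait cycle (0-100 %).

        The cycle origin is the foot strike (the ankle's most-anterior
        phase), matching how the analysis pipeline segments cycles.
        """
        phase = self.foot_strike_phase + np.linspace(0.0, 1.0, n_points)
        return {j: tpl(phase) for j, tpl in self.model.templates.items()}


def _rot(deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rad = np.radians(deg)
    return np.cos(rad), np.sin(rad)


def _rotate(cos: np.ndarray, sin: np.ndarray, vec: np.ndarray) -> np.ndarray:
    x, y = vec[..., 0], vec[..., 1]
    return np.stack([cos * x - sin * y, sin * x + cos * y], axis=-1)


# Butt-kick transient: heel pulled to the buttock (deep knee flexion plus
# extra hip flexion) over one cycle, lifting the ankle well above any
# steady-running swing peak.
_TRIGGER_KNEE_PEAK = 172.0
_TRIGGER_HIP_BOOST = 35.0


def _trigger_weight(model: RunnerModel, t: np.ndarray, trigger_at_s: float | None) -> np.ndarray:
    if trigger_at_s is None:
        return np.zeros_like(t)
    s = (t - trigger_at_s) * model.cadence_hz
    return np.where((s >= 0) & (s <= 1), np.sin(np.pi * np.clip(s, 0, 1)) ** 2, 0.0)


def _trial_angles(model: RunnerModel, t: np.ndarray, trigger_at_s: float | None) -> dict:
    phase = model.cadence_hz * t
    ang = {j: tpl(phase) for j, tpl in model.templates.items()}
    ang["trunk"] = model.trunk_lean(phase)
    if trigger_at_s is not None:
        w = _trigger_weight(model, t, trigger_at_s)
        ang["knee"] = ang["knee"] + w * (_TRIGGER_KNEE_PEAK - ang["knee"])
        ang["hip"] = ang["hip"] + w * _TRIGGER_HIP_BOOST
    return ang


def forward_kinematics(
    model: RunnerModel, t: np.ndarray, trigger_at_s: float | None = None
) -> dict:
    """2D landmark positions (mm, anterior = +x, up = +y) at times ``t``.

    The chain inverts the analysis conventions exactly: the hip template is
    the signed thigh angle from the extended trunk line, the knee template
    rotates the shank posteriorly from the thigh line, and the ankle
    template is the dorsiflexion excess over the neutral 90-degree
    shank-foot angle.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ang = _trial_angles(model, t, trigger_at_s)
    phase = model.cadence_hz * t
    seg = model.segment_lengths

    # the butt-kick interrupts the stride: its weight also damps the hip's
    # running oscillation so the heel-to-buttock pose dominates ankle height
    damp = 1.0 - _trigger_weight(model, t, trigger_at_s)
    hx = model.hip_base[0] + damp * model.hip_excursion[0] * np.sin(2 * np.pi * phase)
    hy = model.hip_base[1] + damp * model.hip_excursion[1] * np.sin(4 * np.pi * phase)
    hip = np.stack([hx, hy], axis=-1)

    c, s = _rot(ang["trunk"])
    up_lean = np.stack([s, c], axis=-1)  # lean tilts the shoulder anteriorly
    shoulder = hip + seg["trunk"] * up_lean
    trunk_ext = -up_lean  # shoulder -> hip direction, extended below the hip

    c, s = _rot(ang["hip"])
    thigh_dir = _rotate(c, s, trunk_ext)
    knee = hip + seg["thigh"] * thigh_dir

    c, s = _rot(-ang["knee"])
    shank_dir = _rotate(c, s, thigh_dir)
    ankle = knee + seg["shank"] * shank_dir

    c, s = _rot(90.0 + ang["ankle"])
    foot_dir = _rotate(c, s, shank_dir)
    big_toe = ankle + seg["foot"] * foot_dir

    return {"shoulder": shoulder, "hip": hip, "knee": knee, "ankle": ankle, "big_toe": big_toe}


def _foot_strike_phase(model: RunnerModel) -> float:
    """Cycle phase of the ankle's maximum anterior position (fine-grid search)."""
    phase = np.linspace(0.0, 1.0, 4001, endpoint=False)
    pos = forward_kinematics(model, phase / model.cadence_hz)
    return float(phase[np.argmax(pos["ankle"][:, 0])])


def render_static(model: RunnerModel, n_frames: int = 60) -> dict:
    """Neutral standing pose (all joint templates zero), tiled over frames."""
    neutral = RunnerModel(
        segment_lengths=dict(model.segment_lengths),
        templates={j: FourierTemplate(0.0) for j in ("hip", "knee", "ankle")},
        trunk_lean=FourierTemplate(0.0),
        cadence_hz=model.cadence_hz,
        hip_base=model.hip_base,
        hip_excursion=(0.0, 0.0),
        speed=model.speed,
    )
    pose = forward_kinematics(neutral, np.zeros(n_frames))
    return pose


# pelvis cluster geometry (mm): rigid, no tilt, mediolateral axis = lab y
_INTER_ASIS = 240.0
_SACRAL_DEPTH = 130.0
_PSIS_HALF = 50.0
_MEDIOLAT_LEG = 150.0
_MEDIOLAT_ACR = 190.0


def hip_params(model: RunnerModel) -> HipCentreParams:
    return HipCentreParams(leg_length=model.leg_length, inter_asis_distance=_INTER_ASIS)


def _marker_frames(model: RunnerModel, pos2d: dict) -> dict:
    """Lift the planar pose to 3D markers (x anterior, y mediolateral-left, z up)."""
    n = len(pos2d["hip"])

    def lift(p2, y):
        return np.column_stack([p2[:, 0], np.full(n, y), p2[:, 1]])

    params = hip_params(model)
    ant, lat, vert = params.offsets(_INTER_ASIS, "left")
    # place the rigid pelvis so the regression recovers the true hip point
    origin = lift(pos2d["hip"], 0.0) - np.array([ant, lat, vert])
    markers = {
        "LASI": origin + np.array([0.0, _INTER_ASIS / 2, 0.0]),
        "RASI": origin + np.array([0.0, -_INTER_ASIS / 2, 0.0]),
        "LPSI": origin + np.array([-_SACRAL_DEPTH, _PSIS_HALF, 0.0]),
        "RPSI": origin + np.array([-_SACRAL_DEPTH, -_PSIS_HALF, 0.0]),
        "LACR": lift(pos2d["shoulder"], _MEDIOLAT_ACR),
        "LKNE": lift(pos2d["knee"], _MEDIOLAT_LEG),
        "LANK": lift(pos2d["ankle"], _MEDIOLAT_LEG),
        "LTOE": lift(pos2d["big_toe"], _MEDIOLAT_LEG),
    }
    return markers


def render_streams(
    model: RunnerModel,
    noise: NoiseSpec,
    duration_s: float,
    trigger_at_s: float | None = None,
    marker_fs: float = 100.0,
    keypoint_fs: float = 60.0,
    px_per_mm: float = 0.3,
    image_height: int = 720,
    camera_offset_px: tuple = (500.0, 30.0),
) -> tuple[MarkerSeries, KeypointSeries, GroundTruth]:
    """Render one trial as a 3D marker stream and a pixel key-point stream.

    The marker stream is low-noise mm at ``marker_fs``; the key-point
    stream is scaled to pixels, y-flipped to image convention before noise,
    bias and dropouts are applied, then returned as a y-up
    :class:`~run2d.trajectories.KeypointSeries` at ``keypoint_fs``.  When
    20-cycle selection will be exercised the duration must cover at least
    25 cycles.
    """
    min_dur = 25.0 / model.cadence_hz
    n_cycles = duration_s * model.cadence_hz
    if n_cycles < 4:
        raise ValueError(f"duration too short: need >= {4 / model.cadence_hz:.1f} s")
    rng = np.random.default_rng(noise.seed)

    # ground-truth events
    phi_star = _foot_strike_phase(model)
    k = np.arange(0, int(np.floor(duration_s * model.cadence_hz - phi_star)) + 1)
    strike_times = (phi_star + k) / model.cadence_hz
    strike_times = strike_times[strike_times < duration_s]
    trigger_time = trigger_window = None
    if trigger_at_s is not None:
        period = 1.0 / model.cadence_hz
        tt = np.linspace(trigger_at_s, trigger_at_s + period, 2001)
        pos = forward_kinematics(model, tt, trigger_at_s)
        trigger_time = float(tt[np.argmax(pos["ankle"][:, 1])])
        trigger_window = (trigger_at_s, trigger_at_s + period)

    # marker stream (100 Hz, mm)
    t_m = np.arange(int(round(duration_s * marker_fs))) / marker_fs
    pos_m = forward_kinematics(model, t_m, trigger_at_s)
    markers = _marker_frames(model, pos_m)
    if noise.marker_noise_mm_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, noise.marker_noise_mm_sd, markers[name].shape
            )
    marker_series = MarkerSeries(
        marker_fs, markers, LabAxes(anterior="x", vertical="z")
    )

    # key-point stream (60 Hz, px, image convention during corruption)
    t_k = np.arange(int(round(duration_s * keypoint_fs))) / keypoint_fs
    pos_k = forward_kinematics(model, t_k, trigger_at_s)
    points: dict[str, np.ndarray] = {}
    confidence: dict[str, np.ndarray] = {}
    n = len(t_k)
    for name, p2 in pos_k.items():
        x_px = p2[:, 0] * px_per_mm + camera_offset_px[0]
        y_img = image_height - (p2[:, 1] * px_per_mm + camera_offset_px[1])
        if name in noise.keypoint_bias:
            bx, by = noise.keypoint_bias[name]
            x_px = x_px + bx
            y_img = y_img + by
        if noise.pixel_noise_sd > 0:
            x_px = x_px + rng.normal(0.0, noise.pixel_noise_sd, n)
            y_img = y_img + rng.normal(0.0, noise.pixel_noise_sd, n)
        conf = np.clip(rng.normal(0.85, 0.05, n), 0.3, 1.0)
        if noise.gap_probability > 0:
            drop = rng.random(n) < noise.gap_probability
            drop[0] = drop[-1] = False  # keep endpoints for spline filling
            x_px[drop] = np.nan
            y_img[drop] = np.nan
            conf[drop] = np.nan
        points[name] = np.column_stack([x_px, image_height - y_img])
        confidence[name] = conf
    keypoint_series = KeypointSeries(keypoint_fs, points, confidence, side="left")

    truth = GroundTruth(
        model=model,
        foot_strike_times=strike_times,
        trigger_time=trigger_time,
        trigger_window=trigger_window,
        duration_s=duration_s,
        foot_strike_phase=phi_star,
    )
    return marker_series, keypoint_series, truth


def write_streams(
    out_dir: str | Path,
    marker_series: MarkerSeries,
    keypoint_series: KeypointSeries,
    truth: GroundTruth,
    image_height: int = 720,
) -> dict:
    """Write marker CSV, key-point CSV + prediction-style JSON, ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_markers_csv(marker_series, out / "markers.csv")
    write_keypoints_csv(keypoint_series, out / "keypoints.csv")

    from .trajectories import COCO_WHOLEBODY_INDICES

    idx = COCO_WHOLEBODY_INDICES[keypoint_series.side]
    n = keypoint_series.n_frames
    frames = []
    for i in range(n):
        kps = [0.0] * (21 * 3)
        any_present = False
        for name, j in idx.items():
            x, y = keypoint_series.points[name][i]
            c = keypoint_series.confidence[name][i]
            if np.isnan(x):
                continue
            kps[3 * j : 3 * j + 3] = [float(x), float(image_height - y), float(c)]
            any_present = True
        frames.append({"predictions": [{"keypoints": kps}] if any_present else []})
    with open(out / "keypoints_openpifpaf.json", "w") as fh:
        json.dump(frames, fh)

    gt = {
        "cadence_hz": truth.model.cadence_hz,
        "speed": truth.model.speed,
        "duration_s": truth.duration_s,
        "foot_strike_times": truth.foot_strike_times.tolist(),
        "trigger_time": truth.trigger_time,
        "leg_length_mm": truth.model.leg_length,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    return {
        "markers": out / "markers.csv",
        "keypoints": out / "keypoints.csv",
        "keypoints_json": out / "keypoints_openpifpaf.json",
        "ground_truth": out / "ground_truth.json",
    }


# ---------------------------------------------------------------------------
# Curve-level cohort generator for the agreement statistics


def curve_panel(
    n_participants: int = 30,
    noise_sd: float = 2.0,
    seed: int = 0,
    joint: str = "hip",
    effect_deg: float = 0.0,
    effect_window: tuple = (40.0, 60.0),
    subject_sd: float = 3.0,
    n_points: int = 101,
) -> CurvePanel:
    """Synthetic 2x2 within-participant panel of averaged joint curves.

    Each participant's underlying curve is the joint template plus a random
    constant offset and amplitude scaling (between-subject variability);
    each of the four cells adds independent Gaussian measurement noise of
    ``noise_sd`` degrees.  ``effect_deg`` injects a constant system offset
    into the second level of factor A restricted to ``effect_window``
    percent of the cycle (zero gives an exchangeable null panel).
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, n_points)
    base = {s: default_model(s).templates[joint](grid) for s in (2.5, 3.6)}
    data = np.empty((n_participants, 2, 2, n_points))
    window = (grid * 100 >= effect_window[0]) & (grid * 100 <= effect_window[1])
    for s in range(n_participants):
        offset = rng.normal(0.0, subject_sd)
        scale = rng.normal(1.0, 0.05)
        for ib, speed in enumerate((2.5, 3.6)):
            subject_curve = scale * base[speed] + offset
            for ia in range(2):
                cell = subject_curve + rng.normal(0.0, noise_sd, n_points)
                if ia == 1 and effect_deg:
                    cell = cell + effect_deg * window
                data[s, ia, ib] = cell
    return CurvePanel(data=data, joint=joint)
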