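"""Sagittal joint angles and hip-joint-centre estimation.

Angle conventions (recorded on every :class:`JointAngleSeries`):

* internal 2D frame: anterior = +x, up = +y;
* **ankle** — signed angle from the shank direction (knee→ankle) to the foot
  direction (ankle→big toe), minus the same raw angle averaged over a static
  neutral trial; dorsiflexion positive, neutral standing = 0°;
* **knee** — 180° minus the included angle at the knee between thigh and
  shank; flexion positive, full extension = 0°;
* **hip** — signed angle of the thigh (hip→knee) relative to the extended
  trunk line (shoulder→hip); flexion (thigh anterior to the trunk line)
  positive, neutral = 0°.  The trunk line is a surrogate for the pelvis,
  which a single side-view camera cannot resolve.

The hip joint centre for the marker-based path is regressed from the four
iliac-spine markers and leg length with the Newington–Gage (Davis) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectories import KeypointSeries, LabAxes

__all__ = [
    "StaticCalibration",
    "JointAngleSeries",
    "HipCentreParams",
    "estimate_hip_centre",
    "project_sagittal",
    "included_angle",
    "signed_angle",
    "joint_angles",
    "static_calibration",
]

JOINTS = ("ankle", "knee", "hip")

CONVENTIONS = {
    "ankle": "dorsiflexion positive, neutral standing 0 deg (static correction)",
    "knee": "flexion positive, full extension 0 deg",
    "hip": "flexion positive (thigh anterior to trunk line), neutral 0 deg",
}


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class StaticCalibration:
    """Mean raw joint angles over a neutral static trial, in degrees."""

    neutral_angle: dict
    n_frames: int = 10

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise KinematicsError("static calibration needs >= 10 frames")
        for joint, val in self.neutral_angle.items():
            if not math.isfinite(val):
                raise KinematicsError(f"non-finite neutral angle for {joint}")


@dataclass
class JointAngleSeries:
    """Per-frame sagittal angle (degrees) for one joint."""

    joint: str
    values: np.ndarray
    frame_rate: float
    convention: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.joint not in JOINTS:
            raise KinematicsError(f"unknown joint {self.joint!r}")
        if not self.convention:
            self.convention = CONVENTIONS[self.joint]


@dataclass
class HipCentreParams:
    """Inputs to the Newington–Gage (Davis) hip-centre regression.

    The regression offsets, in the pelvis anatomical frame, are::

        C      = 0.115 * leg_length - 15.3            (mm)
        x_dis  = 0.1288 * leg_length - 48.56          (mm, ASIS-trochanter)
        ant    = C * cos(theta) * sin(beta) - (x_dis + r) * cos(beta)
        lat    = inter_asis / 2 - C * sin(theta)      (toward the side)
        vert   = -C * cos(theta) * cos(beta) - (x_dis + r) * sin(beta)

    with theta = 28.4 deg, beta = 18 deg and r the marker radius.  The
    constants are exposed so other published variants can be substituted.
    """

    leg_length: float
    marker_diameter: float = 14.0
    inter_asis_distance: float | None = None
    theta_deg: float = 28.4
    beta_deg: float = 18.0
    c_slope: float = 0.115
    c_offset: float = -15.3
    x_slope: float = 0.1288
    x_offset: float = -48.56

    def __post_init__(self) -> None:
        if self.leg_length <= 0:
            raise KinematicsError("leg_length must be positive")
        if self.inter_asis_distance is not None and self.inter_asis_distance <= 0:
            raise KinematicsError("inter_asis_distance must be positive")

    def offsets(self, inter_asis: float, side: str) -> np.ndarray:
        """(anterior, lateral-toward-side, vertical) offsets in mm."""
        if side not in ("left", "right"):
            raise KinematicsError(f"side must be left or right, got {side!r}")
        theta = math.radians(self.theta_deg)
        beta = math.radians(self.beta_deg)
        c = self.c_slope * self.leg_length + self.c_offset
        x_dis = self.x_slope * self.leg_length + self.x_offset
        r = self.marker_diameter / 2.0
        ant = c * math.cos(theta) * math.sin(beta) - (x_dis + r) * math.cos(beta)
        lat = inter_asis / 2.0 - c * math.sin(theta)
        vert = -c * math.cos(theta) * math.cos(beta) - (x_dis + r) * math.sin(beta)
        return np.array([ant, lat, vert])


PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")


def estimate_hip_centre(
    pelvis_markers: dict,
    params: HipCentreParams,
    side: str = "left",
) -> np.ndarray:
    """Regress the hip joint centre from the four iliac-spine markers.

    Per frame the pelvis anatomical frame is built with origin at the
    mid-ASIS point, lateral axis along the ASIS line, anterior axis toward
    the mid-ASIS point from the mid-PSIS point (orthogonalised), vertical
    axis by the right-hand rule; the Davis regression offsets are then
    applied in that frame.  Returns an ``(n, 3)`` track in mm.
    """
    missing = [m for m in PELVIS_MARKERS if m not in pelvis_markers]
    if missing:
        raise KinematicsError(f"missing pelvis markers: {missing}")
    lasi = np.asarray(pelvis_markers["LASI"], dtype=float)
    rasi = np.asarray(pelvis_markers["RASI"], dtype=float)
    lpsi = np.asarray(pelvis_markers["LPSI"], dtype=float)
    rpsi = np.asarray(pelvis_markers["RPSI"], dtype=float)
    if any(np.isnan(m).any() for m in (lasi, rasi, lpsi, rpsi)):
        raise KinematicsError("pelvis markers contain gaps; fill gaps first")

    origin = 0.5 * (lasi + rasi)
    sacrum = 0.5 * (lpsi + rpsi)
    left_axis = lasi - rasi
    left_norm = np.linalg.norm(left_axis, axis=1, keepdims=True)
    forward = origin - sacrum
    # orthogonalise forward against the lateral axis
    y_hat = left_axis / left_norm
    proj = np.sum(forward * y_hat, axis=1, keepdims=True)
    x_axis = forward - proj * y_hat
    x_norm = np.linalg.norm(x_axis, axis=1, keepdims=True)
    bad = np.nonzero((left_norm[:, 0] < 1e-9) | (x_norm[:, 0] < 1e-9))[0]
    if bad.size:
        raise KinematicsError(
            f"degenerate pelvis frame (collinear markers) at frame {int(bad[0])}"
        )
    x_hat = x_axis / x_norm
    z_hat = np.cross(x_hat, y_hat)  # up for a right-handed (anterior, left) pair

    inter_asis = (
        params.inter_asis_distance
        if params.inter_asis_distance is not None
        else float(np.mean(np.linalg.norm(lasi - rasi, axis=1)))
    )
    ant, lat, vert = params.offsets(inter_asis, side)
    lat_signed = lat if side == "left" else -lat
    return origin + ant * x_hat + lat_signed * y_hat + vert * z_hat


def project_sagittal(track3d: np.ndarray, lab_axes: LabAxes) -> np.ndarray:
    """Drop the mediolateral coordinate: return (anterior, vertical) in mm."""
    arr = np.asarray(track3d, dtype=float)
    return arr[..., [lab_axes.index("anterior"), lab_axes.index("vertical")]]


def included_angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Included angle at ``vertex`` between rays to ``a`` and ``c``, degrees in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(vertex, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu < 1e-12) | (nv < 1e-12)
    if np.any(bad):
        frame = int(np.atleast_1d(bad).nonzero()[0][0])
        raise KinematicsError(f"zero-length limb vector at frame {frame}")
    cosang = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from ``u`` to ``v`` (degrees, counter-clockwise positive)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = np.sum(u * v, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def _raw_ankle(points: dict) -> np.ndarray:
    shank = points["ankle"] - points["knee"]
    foot = points["big_toe"] - points["ankle"]
    _check_nonzero(shank, "shank")
    _check_nonzero(foot, "foot")
    return signed_angle(shank, foot)


def _check_nonzero(seg: np.ndarray, name: str) -> None:
    norms = np.linalg.norm(seg, axis=-1)
    bad = np.nonzero(np.atleast_1d(norms) < 1e-12)[0]
    if bad.size:
        raise KinematicsError(f"zero-length {name} vector at frame {int(bad[0])}")


def _points_2d(series) -> tuple[dict, float]:
    if isinstance(series, KeypointSeries):
        return series.points, series.frame_rate
    if isinstance(series, dict):
        return series, float("nan")
    raise KinematicsError(
        "expected a KeypointSeries or a dict of named 2D tracks; project "
        "MarkerSeries to the sagittal plane first"
    )


def static_calibration(series, joints=("ankle",), min_frames: int = 10) -> StaticCalibration:
    """Mean raw angles over a neutral static trial (>= ``min_frames`` frames)."""
    points, _ = _points_2d(series)
    n = len(next(iter(points.values())))
    if n < min_frames:
        raise KinematicsError(f"static trial has {n} frames; need >= {min_frames}")
    neutral = {}
    for joint in joints:
        if joint == "ankle":
            raw = _raw_ankle(points)
        elif joint == "knee":
            raw = 180.0 - included_angle(points["hip"], points["knee"], points["ankle"])
        elif joint == "hip":
            raw = signed_angle(points["hip"] - points["shoulder"], points["knee"] - points["hip"])
        else:
            raise KinematicsError(f"unknown joint {joint!r}")
        neutral[joint] = float(np.nanmean(raw))
    return StaticCalibration(neutral_angle=neutral, n_frames=n)


def joint_angles(
    series,
    calib: StaticCalibration | None = None,
    *,
    frame_rate: float | None = None,
    neutral_correction_joints=("ankle",),
) -> dict:
    """Compute ankle, knee and hip sagittal angle series from 2D landmarks.

    ``series`` is a :class:`KeypointSeries` or a plain dict of ``(n, 2)``
    y-up tracks named ``shoulder, hip, knee, ankle, big_toe`` (the marker
    path projects its markers to this same dict, so both measurement
    systems share one code path).  The static correction is applied to the
    joints in ``neutral_correction_joints`` (default: ankle only).
    """
    points, fs = _points_2d(series)
    if frame_rate is not None:
        fs = frame_rate
    required = {"shoulder", "hip", "knee", "ankle", "big_toe"}
    missing = sorted(required - set(points))
    if missing:
        raise KinematicsError(f"missing landmarks: {missing}")
    for name, track in points.items():
        if np.isnan(np.asarray(track)).any():
            raise KinematicsError(f"landmark {name!r} has gaps; fill gaps first")

    raw = {
        "ankle": _raw_ankle(points),
        "knee": 180.0 - included_angle(points["hip"], points["knee"], points["ankle"]),
        "hip": signed_angle(points["hip"] - points["shoulder"], points["knee"] - points["hip"]),
    }
    out = {}
    for joint in JOINTS:
        values = raw[joint]
        if joint in neutral_correction_joints:
            if calib is None or joint not in calib.neutral_angle:
                raise KinematicsError(
                    f"static calibration required for the {joint} neutral correction"
                )
            values = values - calib.neutral_angle[joint]
        out[joint] = JointAngleSeries(joint, values, fs)
    return out
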