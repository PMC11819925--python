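"""Trajectory containers, file I/O, gap filling and zero-lag low-pass filtering.

Two kinds of time series enter the pipeline: 2D anatomical key points with
per-frame confidences (typically a pose-estimation network run on side-view
video at 60 Hz) and 3D reflective-marker trajectories from an optoelectronic
system (typically 100 Hz).  Internally the vertical axis always points *up*;
image-convention sources (y grows downward) are flipped at read time.

Missing samples are represented as NaN.  A key-point detection with
confidence below :data:`CONFIDENCE_FLOOR` is treated as missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter

__all__ = [
    "LANDMARKS",
    "CONFIDENCE_FLOOR",
    "COCO_WHOLEBODY_INDICES",
    "KeypointSeries",
    "MarkerSeries",
    "FilterSpec",
    "read_keypoints",
    "write_keypoints_csv",
    "read_markers_csv",
    "write_markers_csv",
    "read_markers_trc",
    "fill_gaps",
    "lowpass",
]

#: Anatomical landmarks used for sagittal ankle/knee/hip kinematics.
LANDMARKS = ("shoulder", "hip", "knee", "ankle", "big_toe")

#: Detections below this confidence are junk and treated as missing.
CONFIDENCE_FLOOR = 0.05

#: COCO WholeBody keypoint indices for the five landmarks, per body side.
COCO_WHOLEBODY_INDICES = {
    "left": {"shoulder": 5, "hip": 11, "knee": 13, "ankle": 15, "big_toe": 17},
    "right": {"shoulder": 6, "hip": 12, "knee": 14, "ankle": 16, "big_toe": 20},
}


class TrajectoryError(ValueError):
    """Raised for malformed or unusable trajectory data."""


@dataclass
class KeypointSeries:
    """Named 2D landmark tracks with confidences, one body side, y-up.

    Parameters
    ----------
    frame_rate : float
        Sampling rate in Hz (60 for typical smartphone video).
    points : dict
        Landmark name -> ``(n, 2)`` float array of (x, y) positions.
        Missing frames are NaN in both coordinates.
    confidence : dict
        Landmark name -> ``(n,)`` confidence in [0, 1]; NaN where missing.
    side : str
        ``"left"`` or ``"right"``.
    """

    frame_rate: float
    points: dict[str, np.ndarray]
    confidence: dict[str, np.ndarray] = field(default_factory=dict)
    side: str = "left"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise TrajectoryError("frame_rate must be positive")
        if self.side not in ("left", "right"):
            raise TrajectoryError(f"side must be left or right, got {self.side!r}")
        unknown = set(self.points) - set(LANDMARKS)
        if unknown:
            raise TrajectoryError(f"unknown landmark names: {sorted(unknown)}")
        lengths = {k: len(v) for k, v in self.points.items()}
        if not lengths:
            raise TrajectoryError("points must contain at least one landmark")
        n = next(iter(lengths.values()))
        if n < 2:
            raise TrajectoryError("landmark tracks must have length >= 2")
        if any(m != n for m in lengths.values()):
            raise TrajectoryError(f"landmark tracks have unequal lengths: {lengths}")
        for k, v in self.points.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise TrajectoryError(f"track {k!r} must have shape (n, 2)")
            self.points[k] = arr
        if not self.confidence:
            self.confidence = {
                k: np.where(np.isnan(v[:, 0]), np.nan, 1.0)
                for k, v in self.points.items()
            }

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.points.values())))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LabAxes:
    """Which lab axis is anterior and which is vertical ('x', 'y' or 'z')."""

    anterior: str = "x"
    vertical: str = "z"

    def __post_init__(self) -> None:
        axes = ("x", "y", "z")
        if self.anterior not in axes or self.vertical not in axes:
            raise TrajectoryError("axes must be one of 'x', 'y', 'z'")
        if self.anterior == self.vertical:
            raise TrajectoryError("anterior and vertical axes must be distinct")

    def index(self, which: str) -> int:
        return "xyz".index(getattr(self, which))


@dataclass
class MarkerSeries:
    """Named 3D marker tracks in mm, missing allowed as NaN."""

    frame_rate: float
    markers: dict[str, np.ndarray]
    lab_axes: LabAxes = field(default_factory=LabAxes)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise TrajectoryError("frame_rate must be positive")
        lengths = {k: len(v) for k, v in self.markers.items()}
        if not lengths:
            raise TrajectoryError("markers must contain at least one track")
        n = next(iter(lengths.values()))
        if n < 2:
            raise TrajectoryError("marker tracks must have length >= 2")
        if any(m != n for m in lengths.values()):
            raise TrajectoryError(f"marker tracks have unequal lengths: {lengths}")
        for k, v in self.markers.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise TrajectoryError(f"marker {k!r} must have shape (n, 3)")
            self.markers[k] = arr

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag low-pass Butterworth filter parameters.

    ``order`` is the order of each pass; the forward-backward application
    squares the magnitude response, so the effective gain at frequency f is
    ``1 / (1 + (f / cutoff_hz)**(2 * order))``.  No cutoff compensation is
    applied for the double pass: the nominal cutoff is handed to each pass
    directly, the prevailing convention in gait labs.
    """

    cutoff_hz: float = 6.0
    order: int = 4
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise TrajectoryError("cutoff_hz must be positive")
        if self.order < 2 or self.order % 2:
            raise TrajectoryError("order must be even and >= 2")


# ---------------------------------------------------------------------------
# Readers / writers


def _flip_y(y: np.ndarray, image_height: float) -> np.ndarray:
    return image_height - y


def read_keypoints(
    path: str | Path,
    dialect: str = "csv",
    *,
    frame_rate: float = 60.0,
    side: str = "left",
    image_height: float | None = None,
) -> KeypointSeries:
    """Read landmark tracks from CSV or pose-estimation prediction JSON.

    The CSV dialect has columns ``frame,landmark,x,y,confidence`` with a
    0-based frame index.  The JSON dialect is the OpenPifPaf prediction
    format: a list with one entry per frame, each holding a list of pose
    objects with a flat ``keypoints`` array in COCO WholeBody indexing
    (x, y, confidence triplets); the first pose is used (single runner).

    If ``image_height`` is given the source is taken to be in image
    convention (y grows downward) and is flipped to y-up.  JSON predictions
    are always in image convention, so ``image_height`` is required there.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_keypoints_csv(path, frame_rate, side, image_height)
    if dialect == "openpifpaf_json":
        if image_height is None:
            raise TrajectoryError("image_height is required for openpifpaf_json")
        return _read_keypoints_json(path, frame_rate, side, image_height)
    raise TrajectoryError(f"unknown dialect {dialect!r}")


def _read_keypoints_csv(
    path: Path, frame_rate: float, side: str, image_height: float | None
) -> KeypointSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "landmark", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise TrajectoryError(f"keypoint CSV must have columns {sorted(required)}")
    unknown = sorted(set(df["landmark"]) - set(LANDMARKS))
    if unknown:
        raise TrajectoryError(f"unknown landmark names: {unknown}")
    n = int(df["frame"].max()) + 1
    if df["frame"].min() < 0:
        raise TrajectoryError("negative frame indices")
    points: dict[str, np.ndarray] = {}
    confidence: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("landmark", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryError(f"non-monotone frame indices for landmark {name!r}")
        xy = np.full((n, 2), np.nan)
        conf = np.full(n, np.nan)
        xy[frames, 0] = grp["x"].to_numpy(dtype=float)
        xy[frames, 1] = grp["y"].to_numpy(dtype=float)
        conf[frames] = grp["confidence"].to_numpy(dtype=float)
        low = conf < CONFIDENCE_FLOOR
        xy[low] = np.nan
        conf[low] = np.nan
        if image_height is not None:
            xy[:, 1] = _flip_y(xy[:, 1], image_height)
        points[str(name)] = xy
        confidence[str(name)] = conf
    return KeypointSeries(frame_rate, points, confidence, side=side)


def _read_keypoints_json(
    path: Path, frame_rate: float, side: str, image_height: float
) -> KeypointSeries:
    with open(path) as fh:
        frames = json.load(fh)
    idx = COCO_WHOLEBODY_INDICES[side]
    n = len(frames)
    points = {name: np.full((n, 2), np.nan) for name in LANDMARKS}
    confidence = {name: np.full(n, np.nan) for name in LANDMARKS}
    for i, record in enumerate(frames):
        preds = record.get("predictions", record) if isinstance(record, dict) else record
        if not preds:
            continue
        kps = np.asarray(preds[0]["keypoints"], dtype=float).reshape(-1, 3)
        for name, j in idx.items():
            if j >= len(kps):
                continue
            x, y, c = kps[j]
            if c >= CONFIDENCE_FLOOR:
                points[name][i] = (x, _flip_y(y, image_height))
                confidence[name][i] = c
    return KeypointSeries(frame_rate, points, confidence, side=side)


def write_keypoints_csv(series: KeypointSeries, path: str | Path) -> None:
    """Write the CSV dialect (y-up values as stored; bit-exact round trip)."""
    rows = []
    for name in series.points:
        xy = series.points[name]
        conf = series.confidence[name]
        present = ~np.isnan(xy[:, 0])
        for i in np.nonzero(present)[0]:
            rows.append((int(i), name, xy[i, 0], xy[i, 1], conf[i]))
    df = pd.DataFrame(rows, columns=["frame", "landmark", "x", "y", "confidence"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_markers_csv(
    path: str | Path, *, frame_rate: float = 100.0, lab_axes: LabAxes | None = None
) -> MarkerSeries:
    """Read a marker CSV with columns ``frame,marker,x,y,z`` (mm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryError(f"marker CSV must have columns {sorted(required)}")
    n = int(df["frame"].max()) + 1
    markers: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("marker", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryError(f"non-monotone frame indices for marker {name!r}")
        xyz = np.full((n, 3), np.nan)
        xyz[frames] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        markers[str(name)] = xyz
    return MarkerSeries(frame_rate, markers, lab_axes or LabAxes())


def write_markers_csv(series: MarkerSeries, path: str | Path) -> None:
    rows = []
    for name, xyz in series.markers.items():
        present = ~np.isnan(xyz[:, 0])
        for i in np.nonzero(present)[0]:
            rows.append((int(i), name, xyz[i, 0], xyz[i, 1], xyz[i, 2]))
    df = pd.DataFrame(rows, columns=["frame", "marker", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_markers_trc(path: str | Path, *, lab_axes: LabAxes | None = None) -> MarkerSeries:
    """Read a TRC 3 motion-capture text file (tab-separated)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise TrajectoryError("TRC file too short")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    frame_rate = float(meta.get("DataRate", meta.get("CameraRate", 100.0)))
    header = lines[3].split("\t")
    names = [h for h in header[2:] if h.strip()]
    data = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        vals = [float(p) if p.strip() else np.nan for p in parts[2:]]
        data.append(vals)
    arr = np.asarray(data, dtype=float)
    if arr.shape[1] < 3 * len(names):
        raise TrajectoryError("TRC data columns do not match marker count")
    markers = {
        name: arr[:, 3 * i : 3 * i + 3] for i, name in enumerate(names)
    }
    return MarkerSeries(frame_rate, markers, lab_axes or LabAxes())


# ---------------------------------------------------------------------------
# Gap filling and filtering


def fill_gaps(track: np.ndarray) -> np.ndarray:
    """Fill missing (NaN) interior samples with a cubic spline.

    Works on a 1D sequence or an ``(n, k)`` array of coordinate columns
    (each column splined independently through its present frames).
    The first and last frames must be present; at least 3 present frames
    are required.  Present samples are returned unchanged.
    """
    arr = np.asarray(track, dtype=float)
    if arr.ndim == 1:
        return _fill_gaps_1d(arr)
    return np.column_stack([_fill_gaps_1d(arr[:, j]) for j in range(arr.shape[1])])


def _fill_gaps_1d(x: np.ndarray) -> np.ndarray:
    present = ~np.isnan(x)
    if present.all():
        return x.copy()
    if not present[0] or not present[-1]:
        raise TrajectoryError(
            "missing samples at the track endpoints; trim the recording to the "
            "first and last detected frames before gap filling"
        )
    n_present = int(present.sum())
    if n_present < 3:
        raise TrajectoryError(
            f"cubic spline gap filling needs >= 3 present samples, got {n_present}"
        )
    idx = np.arange(len(x))
    spline = CubicSpline(idx[present], x[present])
    out = x.copy()
    out[~present] = spline(idx[~present])
    return out


def lowpass(track: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-lag Butterworth low-pass filter.

    The zero-lag (forward-backward) Butterworth is defined by its zero
    phase and squared magnitude response, gain ``1 / (1 + (f/fc)**(2n))``
    at frequency ``f``.  That exact response is applied spectrally after
    odd-reflection padding, so the gain follows the analog Butterworth
    curve at every frequency instead of warping toward Nyquist as a
    bilinear-transform recursive implementation would; for gait signals
    (content well below Nyquist) the two are indistinguishable.  Requires
    a complete (gap-filled) track longer than ``3 * order`` samples and
    ``fs > 2 * cutoff``.
    """
    spec = spec or FilterSpec()
    arr = np.asarray(track, dtype=float)
    if np.isnan(arr).any():
        raise TrajectoryError("track contains missing samples; run fill_gaps first")
    if spec.cutoff_hz >= fs / 2:
        raise TrajectoryError(
            f"cutoff {spec.cutoff_hz} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    minlen = 3 * spec.order
    n = arr.shape[0]
    if n <= minlen:
        raise TrajectoryError(
            f"track too short for stable zero-lag filtering: need > {minlen} samples"
        )
    if not spec.zero_lag:
        from scipy.signal import lfilter

        b, a = butter(spec.order, spec.cutoff_hz, btype="low", fs=fs)
        return lfilter(b, a, arr, axis=0)

    # odd-reflection padding long enough for the ~fs/fc-sample edge transient
    pad = min(n - 1, max(minlen, int(round(3.0 * fs / spec.cutoff_hz))))
    first, last = arr[:1], arr[-1:]
    head = 2.0 * first - arr[1 : pad + 1][::-1]
    tail = 2.0 * last - arr[-pad - 1 : -1][::-1]
    ext = np.concatenate([head, arr, tail], axis=0)
    freqs = np.fft.rfftfreq(ext.shape[0], d=1.0 / fs)
    gain = 1.0 / (1.0 + (freqs / spec.cutoff_hz) ** (2 * spec.order))
    spectrum = np.fft.rfft(ext, axis=0)
    shaped = gain.reshape((-1,) + (1,) * (ext.ndim - 1))
    out = np.fft.irfft(spectrum * shaped, n=ext.shape[0], axis=0)
    return out[pad : pad + n]
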