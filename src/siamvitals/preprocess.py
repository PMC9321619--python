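"""Turn a facial video plus landmarks into the two fixed ROI streams.

The network consumes two region-of-interest streams cut from a facial video:
the forehead (top of the face region down to the eyebrows) and the cheek
(nose tip down to the chin, across the face width). Both boxes are chosen
once, on the first frame's 68-point landmark set, and held fixed for the
whole clip — no tracking. The middle ``n_frames`` of the video are selected,
each crop is resized to 40 (h) x 140 (w) x 3 and intensities are scaled to
[0, 1].

Landmark detection itself is out of scope: landmarks arrive from a file or
any callable producing 68 (x, y) points per frame, so the package carries no
trained-detector dependency. Coordinates are 0-based and boxes are half-open
``(x0, y0, x1, y1)``; tensors are ordered frames x height x width x channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .rates import VitalTrace

__all__ = [
    "ROIStream",
    "LandmarkFrame",
    "Box",
    "select_rois",
    "extract_stream",
    "align_reference",
    "read_landmarks_csv",
    "load_cohface_reference",
    "TARGET_ROI_SHAPE",
]

#: Standardized per-frame ROI shape: (height, width, channels).
TARGET_ROI_SHAPE = (40, 140, 3)

# 68-point landmark index groups (iBUG annotation scheme)
_JAW = slice(0, 17)
_BROWS = slice(17, 27)
_NOSE_TIP = 33
_CHIN = 8

Box = tuple[int, int, int, int]


@dataclass
class ROIStream:
    """A frames x height x width x channels clip for one facial region.

    ``pixels`` are floats in [0, 1]; ``source_box`` is the 0-based half-open
    pixel box the stream was cropped from in the original video (the same box
    for every frame — the fixed-box contract).
    """

    pixels: np.ndarray
    fps: float
    region_label: str
    source_box: Box | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be frames x height x width x channels")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class LandmarkFrame:
    """68 (x, y) pixel coordinates for one frame, 0-based."""

    points: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) points, got shape {pts.shape}")


def _clip_box(x0: float, y0: float, x1: float, y1: float,
              frame_shape: tuple[int, int], region: str) -> Box:
    h, w = frame_shape
    x0i = int(np.clip(round(x0), 0, w))
    x1i = int(np.clip(round(x1), 0, w))
    y0i = int(np.clip(round(y0), 0, h))
    y1i = int(np.clip(round(y1), 0, h))
    if x1i <= x0i or y1i <= y0i:
        raise ValueError(
            f"{region} box degenerates to zero area after clipping to "
            f"frame {frame_shape}: ({x0i}, {y0i}, {x1i}, {y1i})"
        )
    return (x0i, y0i, x1i, y1i)


def select_rois(
    landmarks_first_frame: LandmarkFrame,
    frame_shape: tuple[int, int],
    top_extension: float = 0.4,
) -> tuple[Box, Box]:
    """Forehead and cheek boxes from first-frame landmarks.

    The forehead spans the eyebrow extent horizontally and runs from the top
    of the face region down to the eyebrow line. 68-point sets contain no
    hairline point, so "top of the face" is the landmark hull's top edge
    extended upward by ``top_extension`` times the eyebrow-to-chin distance.
    The cheek spans the jaw-contour width and runs from the nose-tip line to
    the chin line. Both boxes are clipped to the frame; a zero-area result
    raises an error naming the region.
    """
    pts = landmarks_first_frame.points
    brows = pts[_BROWS]
    eyebrow_y = float(brows[:, 1].mean())
    chin_y = float(pts[_CHIN, 1])
    nose_tip_y = float(pts[_NOSE_TIP, 1])
    hull_top = float(pts[:, 1].min())
    top_y = hull_top - top_extension * (chin_y - eyebrow_y)

    forehead = _clip_box(
        brows[:, 0].min(), top_y, brows[:, 0].max(), eyebrow_y, frame_shape, "forehead"
    )
    jaw = pts[_JAW]
    cheek = _clip_box(
        jaw[:, 0].min(), nose_tip_y, jaw[:, 0].max(), chin_y, frame_shape, "cheek"
    )
    return forehead, cheek


def _middle_window(n_available: int, n_frames: int) -> int:
    if n_available < n_frames:
        raise ValueError(
            f"video has {n_available} frames but {n_frames} are required"
        )
    return (n_available - n_frames) // 2


def extract_stream(
    video_frames: np.ndarray,
    box: Box,
    *,
    target: tuple[int, int] = (40, 140),
    n_frames: int = 600,
    anchor: str = "middle",
    fps: float = 20.0,
    region_label: str = "roi",
) -> ROIStream:
    """Crop one fixed box from the centered frame window and standardize it.

    The same box is cropped in every selected frame (no tracking); the
    contiguous ``n_frames`` window is centered in the video (``anchor=
    "middle"``) or taken from the start (``"start"``). Each crop is resized
    to ``target`` (height, width) with bilinear interpolation and
    intensities are mapped to [0, 1] (integer input is divided by its dtype
    maximum; float input is assumed already scaled).
    """
    video_frames = np.asarray(video_frames)
    if video_frames.ndim != 4:
        raise ValueError("video_frames must be frames x height x width x channels")
    if anchor == "middle":
        start = _middle_window(video_frames.shape[0], n_frames)
    elif anchor == "start":
        _middle_window(video_frames.shape[0], n_frames)
        start = 0
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    x0, y0, x1, y1 = box
    crop = video_frames[start : start + n_frames, y0:y1, x0:x1, :]
    if crop.shape[1] == 0 or crop.shape[2] == 0:
        raise ValueError(f"box {box} crops to zero area")
    if np.issubdtype(crop.dtype, np.integer):
        crop = crop.astype(np.float64) / np.iinfo(video_frames.dtype).max
    else:
        crop = crop.astype(np.float64)
    th, tw = target
    out = _sk_resize(
        crop,
        (n_frames, th, tw, crop.shape[3]),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return ROIStream(
        pixels=out.astype(np.float32),
        fps=fps,
        region_label=region_label,
        source_box=box,
    )


def align_reference(
    trace: np.ndarray,
    source_rate: float,
    *,
    fps: float = 20.0,
    n_frames: int = 600,
    anchor: str = "middle",
    kind: str = "ppg",
) -> VitalTrace:
    """Resample a reference signal to one sample per selected video frame.

    The selected window is the same centered ``n_frames / fps`` seconds the
    video frames come from; within it the trace is linearly interpolated at
    frame times, giving exactly ``n_frames`` samples at ``fps``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("reference trace must be 1-D")
    trace_duration = trace.size / source_rate
    window_duration = n_frames / fps
    if anchor == "middle":
        offset = (trace_duration - window_duration) / 2.0
    elif anchor == "start":
        offset = 0.0
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if offset < -1e-9:
        raise ValueError(
            f"reference trace covers {trace_duration:.2f} s but the selected "
            f"window needs {window_duration:.2f} s"
        )
    sample_times = offset + np.arange(n_frames) / fps
    source_times = np.arange(trace.size) / source_rate
    resampled = np.interp(sample_times, source_times, trace)
    return VitalTrace(samples=resampled, fs=fps, kind=kind)


def read_video(path: str | Path) -> np.ndarray:
    """Read a video file into a frames x height x width x channels array.

    Multi-page TIFF stacks (the synthetic clip format) are read with
    tifffile; AVI/MP4 and other containers are delegated to imageio, which
    requires a suitable backend plugin for the format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v2 as imageio

        frames = np.stack(list(imageio.get_reader(path)))
    if frames.ndim == 3:  # grayscale -> replicate to three channels
        frames = np.repeat(frames[..., None], 3, axis=3)
    if frames.ndim != 4:
        raise ValueError(f"unsupported video array shape {frames.shape}")
    return frames


def read_landmarks_csv(path: str | Path, frame_index: int = 0) -> LandmarkFrame:
    """Read one frame's landmarks from a CSV of (frame_index, point_index, x, y)."""
    df = pd.read_csv(path)
    sub = df[df["frame_index"] == frame_index].sort_values("point_index")
    if len(sub) != 68:
        raise ValueError(
            f"frame {frame_index}: expected 68 landmark rows, found {len(sub)}"
        )
    return LandmarkFrame(points=sub[["x", "y"]].to_numpy(), frame_index=frame_index)


def load_cohface_reference(path: str | Path) -> dict[str, np.ndarray]:
    """Load a COHFACE-style HDF5 sidecar with pulse/respiration/time datasets."""
    import h5py

    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        for key in ("pulse", "respiration", "time"):
            if key in f:
                out[key] = np.asarray(f[key])
    if not out:
        raise ValueError(f"{path} contains none of pulse/respiration/time")
    return out
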