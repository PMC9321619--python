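"""Synthetic forehead/cheek ROI clips with known cardiac and respiratory truth.

The generator emulates the data contract of a webcam vitals recording: two
140 (w) x 40 (h) x 3 ROI streams at 20 FPS, 600 frames (30 s), with paired
ground-truth PPG and respiration traces sampled once per frame. It embeds

* a cardiac color modulation — a pulse-like periodic waveform (fundamental
  plus a weaker second harmonic) added predominantly to the green channel,
  the channel that carries most of the blood-volume signal in real video;
* a respiratory modulation — a sinusoid applied both as a global intensity
  change and as a sub-pixel vertical translation of the underlying intensity
  gradient (each mechanism independently switchable);
* nuisance terms — per-pixel Gaussian noise, a slow (0.03 Hz) illumination
  drift, and 8-bit quantization with clipping, matching consumer-camera
  output.

Identical ``(config, seed)`` produce bit-identical clips. The cardiac and
respiratory random phases are drawn from independent seed streams, so
changing ``rr_hz`` never perturbs the PPG truth.

The generator stands in for a recorded dataset: clips are plumbing for
training and evaluation, not photorealistic faces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ROIStream
from .rates import HR_BAND, RR_BAND, VitalTrace

__all__ = [
    "SimConfig",
    "SyntheticClip",
    "generate_clip",
    "ppg_waveform",
    "save_clip",
    "load_clip",
]

# second-harmonic weight of the pulse waveform; gives an asymmetric,
# pulse-like shape so peak detection is exercised beyond a pure sine
_HARMONIC = 0.3
_DRIFT_HZ = 0.03  # slow illumination drift, below both analysis bands
# RGB base colors (skin-like, green strongest after red) per region
_BASE_COLORS = {"forehead": (185.0, 144.0, 122.0), "cheek": (178.0, 136.0, 118.0)}
# relative channel weights of the cardiac modulation (green-dominant)
_PPG_CHANNEL_WEIGHTS = (0.4, 1.0, 0.5)
_GRADIENT_UNITS = 6.0  # peak-to-mid vertical intensity gradient, in 8-bit units


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a 30 s webcam ROI recording.

    ``hr_hz`` must lie inside the cardiac analysis band (0.66-3.3 Hz) and
    ``rr_hz`` inside the respiratory band (0.1-0.4 Hz) — outside them the
    generated truth is unrecoverable by design. At least two full
    respiration cycles must fit in the clip.
    """

    fps: float = 20.0
    n_frames: int = 600
    roi_width: int = 140
    roi_height: int = 40
    hr_hz: float = 1.2
    rr_hz: float = 0.25
    ppg_amplitude: float = 0.02
    resp_amplitude: float = 0.04
    resp_shift_px: float = 1.0
    pixel_noise_sd: float = 2.0
    drift_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0 or self.n_frames <= 0:
            raise ValueError("frame dimensions and count must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (HR_BAND.low_hz <= self.hr_hz <= HR_BAND.high_hz):
            raise ValueError(
                f"hr_hz={self.hr_hz} outside the cardiac band "
                f"[{HR_BAND.low_hz}, {HR_BAND.high_hz}] Hz"
            )
        if not (RR_BAND.low_hz <= self.rr_hz <= RR_BAND.high_hz):
            raise ValueError(
                f"rr_hz={self.rr_hz} outside the respiratory band "
                f"[{RR_BAND.low_hz}, {RR_BAND.high_hz}] Hz"
            )
        if self.n_frames < 2 * self.fps / self.rr_hz:
            raise ValueError(
                "clip too short: need at least two respiration cycles "
                f"({2 * self.fps / self.rr_hz:.0f} frames at rr_hz={self.rr_hz})"
            )
        for name in ("ppg_amplitude", "resp_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be nonnegative")


@dataclass
class SyntheticClip:
    """Paired ROI streams with their per-frame ground-truth traces."""

    forehead: ROIStream
    cheek: ROIStream
    ppg_truth: VitalTrace
    resp_truth: VitalTrace
    config: SimConfig

    def __post_init__(self) -> None:
        counts = {
            self.forehead.n_frames,
            self.cheek.n_frames,
            self.ppg_truth.samples.size,
            self.resp_truth.samples.size,
        }
        if len(counts) != 1:
            raise ValueError(f"member frame counts disagree: {counts}")


def ppg_waveform(t: np.ndarray, hr_hz: float, phase: float = 0.0) -> np.ndarray:
    """Pulse-like waveform: fundamental + 0.3 x second harmonic, scaled to [-1, 1]."""
    theta = 2 * np.pi * hr_hz * np.asarray(t, dtype=float) + phase
    w = np.sin(theta) + _HARMONIC * np.sin(2 * theta)
    return w / _AMP


def _waveform_amplitude() -> float:
    # max |sin(x) + h sin(2x)| evaluated once on a dense grid (deterministic)
    x = np.linspace(0.0, 2 * np.pi, 100_001)
    return float(np.max(np.abs(np.sin(x) + _HARMONIC * np.sin(2 * x))))


_AMP = _waveform_amplitude()


def generate_clip(config: SimConfig) -> SyntheticClip:
    """Generate one paired forehead/cheek clip with ground-truth traces.

    Frame construction, per region: a skin-like base color with a vertical
    intensity gradient; the cardiac waveform added with green-dominant
    channel weights at depth ``ppg_amplitude`` (relative to each base
    channel value); the respiration sinusoid added as a global intensity
    change at depth ``resp_amplitude`` and as a vertical translation of the
    gradient of at most ``resp_shift_px`` pixels; plus Gaussian pixel noise,
    slow drift and 8-bit quantization with clipping.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    ppg_ss, resp_ss, nuisance_ss = ss.spawn(3)
    ppg_phase = np.random.default_rng(ppg_ss).uniform(0.0, 2 * np.pi)
    resp_phase = np.random.default_rng(resp_ss).uniform(0.0, 2 * np.pi)
    nuisance_rng = np.random.default_rng(nuisance_ss)
    drift_phase = nuisance_rng.uniform(0.0, 2 * np.pi)

    t = np.arange(cfg.n_frames) / cfg.fps
    ppg = ppg_waveform(t, cfg.hr_hz, ppg_phase)
    resp = np.sin(2 * np.pi * cfg.rr_hz * t + resp_phase)
    drift = cfg.drift_amplitude * np.sin(2 * np.pi * _DRIFT_HZ * t + drift_phase)

    h, w = cfg.roi_height, cfg.roi_width
    rows = np.arange(h, dtype=float)
    row_center = (h - 1) / 2.0 if h > 1 else 0.0
    row_scale = _GRADIENT_UNITS / max(row_center, 1.0)

    streams = {}
    for region, base in _BASE_COLORS.items():
        base = np.asarray(base)
        # vertical translation of the (linear) gradient: exact sub-pixel shift
        shift = cfg.resp_shift_px * resp  # (T,)
        grad = (rows[None, :] + shift[:, None] - row_center) * row_scale  # (T, h)
        ppg_term = (  # green-dominant cardiac modulation, depth relative to base
            (cfg.ppg_amplitude * ppg)[:, None]
            * base[None, :]
            * np.asarray(_PPG_CHANNEL_WEIGHTS)[None, :]
        )  # (T, 3)
        resp_term = (  # global intensity change, depth relative to mean base
            cfg.resp_amplitude * float(base.mean()) * resp + drift
        )  # (T,)
        frames = (
            base[None, None, None, :]
            + grad[:, :, None, None]
            + ppg_term[:, None, None, :]
            + resp_term[:, None, None, None]
        )
        frames = np.broadcast_to(frames, (cfg.n_frames, h, w, 3)).copy()
        if cfg.pixel_noise_sd > 0:
            frames += nuisance_rng.normal(
                0.0, cfg.pixel_noise_sd, size=(cfg.n_frames, h, w, 3)
            )
        quantized = np.clip(np.round(frames), 0, 255).astype(np.uint8)
        streams[region] = ROIStream(
            pixels=(quantized.astype(np.float32) / 255.0),
            fps=cfg.fps,
            region_label=region,
            source_box=(0, 0, w, h),
        )

    return SyntheticClip(
        forehead=streams["forehead"],
        cheek=streams["cheek"],
        ppg_truth=VitalTrace(samples=ppg, fs=cfg.fps, kind="ppg"),
        resp_truth=VitalTrace(samples=resp, fs=cfg.fps, kind="respiration"),
        config=cfg,
    )


# ---- disk layout: TIFF stacks + COHFACE-style HDF5 sidecar + manifest ------


def save_clip(clip: SyntheticClip, directory: str | Path) -> Path:
    """Write a clip as lossless TIFF stacks plus an HDF5 trace sidecar.

    Layout: ``forehead.tif`` and ``cheek.tif`` (uint8, frames x h x w x 3),
    ``traces.h5`` with ``pulse``, ``respiration`` and ``time`` datasets, and
    ``config.json`` recording the generator parameters.
    """
    import h5py
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for region in ("forehead", "cheek"):
        stream: ROIStream = getattr(clip, region)
        pix = np.clip(np.round(stream.pixels * 255.0), 0, 255).astype(np.uint8)
        tifffile.imwrite(directory / f"{region}.tif", pix)
    with h5py.File(directory / "traces.h5", "w") as f:
        f.create_dataset("pulse", data=clip.ppg_truth.samples)
        f.create_dataset("respiration", data=clip.resp_truth.samples)
        f.create_dataset("time", data=clip.ppg_truth.times)
    (directory / "config.json").write_text(
        json.dumps(dataclasses.asdict(clip.config), indent=2)
    )
    return directory


def load_clip(directory: str | Path) -> SyntheticClip:
    """Load a clip written by :func:`save_clip`."""
    import h5py
    import tifffile

    directory = Path(directory)
    cfg = SimConfig(**json.loads((directory / "config.json").read_text()))
    streams = {}
    for region in ("forehead", "cheek"):
        pix = tifffile.imread(directory / f"{region}.tif")
        streams[region] = ROIStream(
            pixels=pix.astype(np.float32) / 255.0,
            fps=cfg.fps,
            region_label=region,
            source_box=(0, 0, cfg.roi_width, cfg.roi_height),
        )
    with h5py.File(directory / "traces.h5", "r") as f:
        ppg = np.asarray(f["pulse"])
        resp = np.asarray(f["respiration"])
    return SyntheticClip(
        forehead=streams["forehead"],
        cheek=streams["cheek"],
        ppg_truth=VitalTrace(samples=ppg, fs=cfg.fps, kind="ppg"),
        resp_truth=VitalTrace(samples=resp, fs=cfg.fps, kind="respiration"),
        config=cfg,
    )
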