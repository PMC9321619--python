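"""Rate extraction and evaluation metrics for predicted vital-sign traces.

A predicted (or reference) photoplethysmogram or respiration trace is turned
into a scalar rate in three deterministic steps: zero-phase Butterworth
bandpass filtering, peak detection, and the mean inter-peak interval rule

    rate = 60 / mean(p_i - p_{i-1})  [beats or breaths per minute]

Cardiac traces use a fourth-order filter over 0.66-3.3 Hz (40-198 BPM);
respiratory traces use a second-order filter over 0.1-0.4 Hz (6-24 RPM).
Paired predicted/reference rates are summarised by Pearson R, MAE and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "VitalTrace",
    "PeakSeries",
    "BandSpec",
    "MetricsReport",
    "HR_BAND",
    "RR_BAND",
    "band_for_kind",
    "bandpass",
    "detect_peaks",
    "rate_from_peaks",
    "estimate_rate",
    "compute_metrics",
]


@dataclass(frozen=True)
class BandSpec:
    """Butterworth bandpass design: filter order and cutoff frequencies in Hz."""

    order: int
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )


#: Cardiac analysis band, order 4 over 0.66-3.3 Hz.
HR_BAND = BandSpec(order=4, low_hz=0.66, high_hz=3.3)
#: Respiratory analysis band, order 2 over 0.1-0.4 Hz.
RR_BAND = BandSpec(order=2, low_hz=0.1, high_hz=0.4)


@dataclass
class VitalTrace:
    """A per-frame 1-D physiological signal with its sampling rate.

    Parameters
    ----------
    samples
        Real-valued signal, one value per video frame.
    fs
        Sampling rate in Hz (the video frame rate for network outputs).
    kind
        ``"ppg"`` or ``"respiration"``; selects the analysis band.
    """

    samples: np.ndarray
    fs: float
    kind: str = "ppg"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in ("ppg", "respiration"):
            raise ValueError(f"kind must be 'ppg' or 'respiration', got {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PeakSeries:
    """Strictly increasing peak time instants, in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("peak times must be 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MetricsReport:
    """Pearson R, MAE and RMSE over paired predicted vs. reference rates."""

    r: float
    mae: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {"R": self.r, "MAE": self.mae, "RMSE": self.rmse, "n": self.n}


def band_for_kind(kind: str) -> BandSpec:
    """Analysis band for a trace kind: cardiac for ppg, respiratory otherwise."""
    return HR_BAND if kind == "ppg" else RR_BAND


def _design_sos(band: BandSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"high cutoff {band.high_hz} Hz violates the Nyquist limit "
            f"{nyq} Hz at fs={fs} Hz"
        )
    return sps.butter(
        band.order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(trace: VitalTrace, band: BandSpec) -> VitalTrace:
    """Zero-phase Butterworth bandpass.

    The filter is applied forward and backward (``sosfiltfilt``), so peaks are
    not delayed and the effective magnitude response is the squared design
    response. Output length equals input length.
    """
    sos = _design_sos(band, trace.fs)
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return VitalTrace(samples=filtered, fs=trace.fs, kind=trace.kind)


def detect_peaks(
    trace: VitalTrace,
    band: BandSpec,
    *,
    min_distance_s: float | None = None,
    prominence_factor: float = 0.3,
) -> PeakSeries:
    """Find local maxima of an already-filtered trace.

    Peaks must be separated by at least ``1/high_hz`` seconds (one period of
    the fastest in-band component) and rise at least ``prominence_factor``
    standard deviations above their surroundings. Peak times are
    ``sample_index / fs``.
    """
    if min_distance_s is None:
        min_distance_s = 1.0 / band.high_hz
    distance = max(1, int(round(min_distance_s * trace.fs)))
    sd = float(np.std(trace.samples))
    prominence = prominence_factor * sd if sd > 0 else None
    if prominence is None:
        idx = np.array([], dtype=int)
    else:
        idx, _ = sps.find_peaks(trace.samples, distance=distance, prominence=prominence)
    if idx.size < 2:
        raise ValueError(
            f"insufficient peaks: found {idx.size}, need at least 2 for a rate"
        )
    return PeakSeries(times=idx / trace.fs)


def rate_from_peaks(peaks: PeakSeries) -> float:
    """Rate in events/minute from the mean inter-peak interval.

    60 divided by the mean of the N-1 consecutive intervals; the sum
    telescopes, so this equals ``60 * (N - 1) / (p_N - p_1)``.
    """
    if peaks.n < 2:
        raise ValueError(f"need at least 2 peaks for a rate, got {peaks.n}")
    intervals = np.diff(peaks.times)
    return 60.0 / float(np.mean(intervals))


def estimate_rate(trace: VitalTrace, band: BandSpec | None = None) -> float:
    """Bandpass, detect peaks, and convert mean peak spacing to a rate.

    The band defaults to the trace kind's analysis band: cardiac
    (order 4, 0.66-3.3 Hz) for ``ppg``, respiratory (order 2, 0.1-0.4 Hz)
    for ``respiration``. Returns BPM for ppg, RPM for respiration.
    """
    if band is None:
        band = band_for_kind(trace.kind)
    filtered = bandpass(trace, band)
    peaks = detect_peaks(filtered, band)
    return rate_from_peaks(peaks)


def compute_metrics(
    pred_rates: Sequence[float], true_rates: Sequence[float]
) -> MetricsReport:
    """Pearson R, mean absolute error and root-mean-square error of paired rates."""
    pred = np.asarray(pred_rates, dtype=float)
    true = np.asarray(true_rates, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError(
            f"rate vectors must be 1-D and equal length, got {pred.shape} vs {true.shape}"
        )
    if pred.size < 2:
        raise ValueError("need at least 2 rate pairs")
    dp = pred - pred.mean()
    dt = true - true.mean()
    denom = np.sqrt((dp**2).sum() * (dt**2).sum())
    r = float((dp * dt).sum() / denom) if denom > 0 else 0.0
    err = pred - true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    return MetricsReport(r=r, mae=mae, rmse=rmse, n=pred.size)
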