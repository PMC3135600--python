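"""22-kHz ultrasonic vocalization detection.

The algorithm classifies each spectrogram frame by the standard deviation of
its band-limited power spectrum: a constant-frequency call concentrates power
in a few bins, so call frames have a much higher across-bin SD than frames of
broadband cage noise. Noise frames are silenced, per-frame power is summed
across frequency, the resulting vector is smoothed with a 100-frame moving
average (~66.7 ms at the default hop), and maximal nonzero runs of the
smoothed envelope are counted as calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .audio_io import (
    AudioTrack,
    Spectrogram,
    SpectrogramParams,
    compute_spectrogram,
    to_decibel,
)

__all__ = [
    "DetectionParams",
    "FrameClassification",
    "CallEvent",
    "DetectionResult",
    "frame_power_sd",
    "classify_frames",
    "usv_power_envelope",
    "segment_calls",
    "detect",
    "otsu_threshold",
]

#: default edges for the call-duration histogram (seconds)
DEFAULT_DURATION_EDGES = np.arange(0.0, 3.01, 0.1)


@dataclass
class DetectionParams:
    """Tunable knobs of the detector.

    ``smoothing_frames`` is the moving-average span (100 frames ~= 66.7 ms at
    hop 64 / 96 kHz). The SD threshold separating call from noise frames can
    be chosen automatically (Otsu on the frame-SD distribution), robustly
    (median + k*MAD), or fixed.
    """

    smoothing_frames: int = 100
    sd_threshold_mode: Literal["otsu", "fixed", "robust_k"] = "otsu"
    sd_threshold_value: float | None = None
    robust_k: float = 4.0
    min_call_duration: float = 0.01
    analysis_bins: Sequence[tuple[float, float]] | None = None
    sd_scale: Literal["linear_cv", "linear", "db"] = "linear_cv"
    sd_ddof: int = 1
    db_floor: float = -120.0

    def __post_init__(self) -> None:
        if self.smoothing_frames < 1:
            raise ValueError("smoothing_frames must be >= 1")
        if self.min_call_duration < 0:
            raise ValueError("min_call_duration must be >= 0")
        if self.analysis_bins is not None:
            bins = list(self.analysis_bins)
            for (a, b) in bins:
                if b <= a:
                    raise ValueError(f"analysis bin [{a}, {b}) is empty")
            for (_, b0), (a1, _) in zip(bins, bins[1:]):
                if a1 < b0:
                    raise ValueError("analysis_bins must be sorted and non-overlapping")


@dataclass
class FrameClassification:
    frame_sd: np.ndarray
    is_usv: np.ndarray
    threshold_used: float


@dataclass
class CallEvent:
    onset: float
    offset: float
    peak_power: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class DetectionResult:
    calls: list[CallEvent]
    duration_histogram: tuple[np.ndarray, np.ndarray]
    count_per_analysis_bin: np.ndarray | None = None
    threshold_used: float = float("nan")
    params: DetectionParams = field(default_factory=DetectionParams)

    @property
    def count(self) -> int:
        return len(self.calls)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([c.onset for c in self.calls])

    @property
    def durations(self) -> np.ndarray:
        return np.array([c.duration for c in self.calls])


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's between-class-variance-maximizing threshold for a 1-D sample.

    Histogram the values into ``n_bins`` equal-width bins and return the bin
    center maximizing the between-class variance of the induced 2-class split.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    w = counts / counts.sum()
    w0 = np.cumsum(w)
    w1 = 1.0 - w0
    mu = np.cumsum(w * centers)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    # the criterion is flat across an empty valley; take the plateau center
    best = np.flatnonzero(between >= between.max() * (1 - 1e-12))
    return float(centers[best[len(best) // 2]])


def _guarded_otsu(values: np.ndarray, n_bins: int = 256, valley_frac: float = 0.05) -> float:
    """Otsu threshold accepted only when it sits in a genuine density valley.

    Call-frame SDs form a second mode well separated from the noise cluster,
    leaving an almost empty valley at the Otsu split. A unimodal (all-noise)
    SD distribution has no such valley — Otsu would bisect the noise cluster
    and flag about half the frames. The guard compares the histogram density
    around the threshold to the peak density and, when the valley is not
    empty enough, declares the recording call-free (threshold above max).
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return lo
    thr = otsu_threshold(values, n_bins=n_bins)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    idx = int(np.clip(np.searchsorted(edges, thr) - 1, 1, n_bins - 2))
    valley = counts[idx - 1 : idx + 2].mean()
    if valley > valley_frac * counts.max():
        return float(hi)  # unimodal: nothing to flag
    return thr


def frame_power_sd(spec: Spectrogram, params: DetectionParams | None = None) -> np.ndarray:
    """Per-frame standard deviation of the band power spectrum.

    The default (``linear_cv``) is the sample SD of the linear bin powers
    normalized by the frame's mean power — i.e. the across-bin coefficient
    of variation. A tonal call concentrates power in a few bins (CV far
    above 1) while broadband frames sit near the CV of exponential
    periodogram noise (~1) at ANY loudness, so flat cage-clatter transients
    are rejected by construction. Plain linear SD and dB-scale SD remain
    available via ``sd_scale``; the dB variant separates poorly because the
    log of the noise floor has several dB of spread of its own.
    """
    params = params or DetectionParams()
    if spec.n_bins < 2:
        raise ValueError("need at least 2 frequency bins to compute an SD")
    if params.sd_scale == "db":
        mat = to_decibel(spec.power, floor_db=params.db_floor)
        return np.std(mat, axis=1, ddof=params.sd_ddof)
    sd = np.std(spec.power, axis=1, ddof=params.sd_ddof)
    if params.sd_scale == "linear":
        return sd
    mean = spec.power.mean(axis=1)
    out = np.zeros_like(sd)
    nz = mean > 0
    out[nz] = sd[nz] / mean[nz]
    return out


def classify_frames(frame_sd: np.ndarray, params: DetectionParams | None = None) -> FrameClassification:
    """Flag frames whose spectral SD exceeds the chosen threshold."""
    params = params or DetectionParams()
    frame_sd = np.asarray(frame_sd, dtype=np.float64)
    if frame_sd.size == 0:
        raise ValueError("empty frame-SD sequence")

    mode = params.sd_threshold_mode
    if mode == "fixed":
        if params.sd_threshold_value is None:
            raise ValueError("fixed threshold mode requires sd_threshold_value")
        threshold = float(params.sd_threshold_value)
    elif mode == "otsu":
        threshold = _guarded_otsu(frame_sd)
    elif mode == "robust_k":
        med = float(np.median(frame_sd))
        mad = float(np.median(np.abs(frame_sd - med)))
        threshold = med + params.robust_k * mad
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown sd_threshold_mode {mode!r}")

    return FrameClassification(
        frame_sd=frame_sd, is_usv=frame_sd > threshold, threshold_used=threshold
    )


def _centered_moving_average(x: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average, edge-truncated (average over available frames)."""
    if span == 1:
        return x.copy()
    left = span // 2
    right = span - left  # window [i-left, i+right)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def usv_power_envelope(
    spec: Spectrogram,
    cls: FrameClassification,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Silenced, summed and smoothed per-frame power envelope.

    Frames classified as noise contribute exactly zero; call frames
    contribute their power summed across the retained band. The summed
    vector is smoothed with a centered ``smoothing_frames``-point moving
    average, so an isolated call frame spreads into a low plateau but the
    envelope stays identically zero away from calls.
    """
    params = params or DetectionParams()
    if len(cls.is_usv) != spec.n_frames:
        raise ValueError("classification not aligned to spectrogram frames")
    if params.smoothing_frames > spec.n_frames:
        raise ValueError(
            f"smoothing span {params.smoothing_frames} exceeds {spec.n_frames} frames"
        )
    summed = np.where(cls.is_usv, spec.power.sum(axis=1), 0.0)
    return _centered_moving_average(summed, params.smoothing_frames)


def _positive_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of strictly positive values as half-open index pairs."""
    pos = np.concatenate(([False], x > 0, [False]))
    d = np.diff(pos.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def segment_calls(
    envelope: np.ndarray,
    spec: Spectrogram,
    params: DetectionParams | None = None,
) -> DetectionResult:
    """Turn nonzero envelope runs into call events and summary counts.

    Each maximal run of strictly positive envelope values becomes one call,
    timed from the spectrogram frame grid; runs shorter than
    ``min_call_duration`` are dropped. Calls are attributed to an analysis
    bin by their onset.
    """
    params = params or DetectionParams()
    envelope = np.asarray(envelope, dtype=np.float64)
    if len(envelope) != spec.n_frames:
        raise ValueError("envelope not aligned to spectrogram frames")

    hop_s = spec.hop_seconds
    calls: list[CallEvent] = []
    for i0, i1 in _positive_runs(envelope):
        duration = (i1 - i0) * hop_s
        if duration < params.min_call_duration:
            continue
        onset = spec.frame_times[i0]
        peak = to_decibel(np.array(envelope[i0:i1].max()), floor_db=params.db_floor)
        calls.append(CallEvent(onset=onset, offset=onset + duration, peak_power=float(peak)))

    durations = np.array([c.duration for c in calls])
    edges = DEFAULT_DURATION_EDGES
    if durations.size and durations.max() >= edges[-1]:
        edges = np.arange(0.0, durations.max() + 0.1, 0.1)
    hist = np.histogram(durations, bins=edges)

    per_bin = None
    if params.analysis_bins is not None:
        onsets = np.array([c.onset for c in calls])
        per_bin = np.array(
            [int(np.sum((onsets >= a) & (onsets < b))) for a, b in params.analysis_bins]
        )
    return DetectionResult(
        calls=calls, duration_histogram=hist, count_per_analysis_bin=per_bin, params=params
    )


def detect(
    track: AudioTrack,
    sparams: SpectrogramParams | None = None,
    dparams: DetectionParams | None = None,
) -> DetectionResult:
    """End-to-end call detection on a waveform.

    Deterministic composition of spectrogram computation, frame-SD
    classification, envelope construction and run segmentation.
    """
    sparams = sparams or SpectrogramParams()
    dparams = dparams or DetectionParams()
    spec = compute_spectrogram(track, sparams)
    sd = frame_power_sd(spec, dparams)
    cls = classify_frames(sd, dparams)
    env = usv_power_envelope(spec, cls, dparams)
    result = segment_calls(env, spec, dparams)
    result.threshold_used = cls.threshold_used
    return result
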