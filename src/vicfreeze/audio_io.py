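"""WAV audio I/O and band-limited power spectrograms.

Recordings of rat cage audio are 16-bit PCM WAV digitized at 96 kHz. The
detection substrate is a short-time Fourier power spectrogram computed with
a 256-sample window at 75% overlap and truncated to the 15-30 kHz band in
which 22-kHz alarm calls live.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioTrack",
    "SpectrogramParams",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "compute_spectrogram",
    "to_decibel",
]

log = logging.getLogger(__name__)

_WINDOWS = {
    "hann": np.hanning,
    "hamming": np.hamming,
    "blackman": np.blackman,
    "rectangular": np.ones,
    "boxcar": np.ones,
}


@dataclass
class AudioTrack:
    """A mono waveform with full-scale amplitudes in [-1, 1].

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence, dimensionless full scale.
    sample_rate : int
        Sampling rate in Hz.
    bit_depth : int
        Quantization depth of the source/target PCM encoding.
    """

    samples: np.ndarray
    sample_rate: int
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioTrack holds a single mono channel")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration(self) -> float:
        """Track length in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class SpectrogramParams:
    """Short-time FFT parameters.

    Defaults follow the analysis settings used for 22-kHz call counting:
    a 256-point window with 75% overlap at 96 kHz (hop 64 samples), band
    truncated to 15-30 kHz.
    """

    window_length: int = 256
    overlap_fraction: float = 0.75
    band_low: float = 15_000.0
    band_high: float = 30_000.0
    window_function: str = "hann"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.band_low >= self.band_high:
            raise ValueError("band_low must be below band_high")
        hop = self.window_length * (1 - self.overlap_fraction)
        if abs(hop - round(hop)) > 1e-9 or round(hop) < 1:
            raise ValueError(
                f"window_length*(1-overlap_fraction) must be a positive integer, got {hop}"
            )

    @property
    def hop(self) -> int:
        """Samples advanced between successive frames."""
        return int(round(self.window_length * (1 - self.overlap_fraction)))


@dataclass
class Spectrogram:
    """Frames x bins power matrix restricted to the analysis band.

    ``power`` is linear one-sided power; ``frame_times`` are window-center
    times in seconds; ``bin_freqs`` the retained FFT bin centers in Hz.
    """

    power: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    hop_seconds: float
    params: SpectrogramParams = field(default_factory=SpectrogramParams)

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


def read_wav(path: str | Path, channel: int = 0) -> AudioTrack:
    """Read a PCM WAV file into a normalized :class:`AudioTrack`.

    Integer PCM samples are normalized to full-scale +/-1. Multichannel
    files are reduced to ``channel`` (default 0) with a warning, since the
    recordings of interest are single-microphone.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:  # non-PCM / compressed payload
        raise ValueError(f"not a readable PCM WAV file: {path}: {exc}") from exc

    if data.ndim == 2:
        warnings.warn(
            f"multichannel WAV ({data.shape[1]} channels); taking channel {channel}",
            stacklevel=2,
        )
        data = data[:, channel]

    if data.dtype == np.int16:
        samples, bit_depth = data / 32768.0, 16
    elif data.dtype == np.int32:
        samples, bit_depth = data / 2147483648.0, 32
    elif data.dtype == np.uint8:
        samples, bit_depth = (data.astype(np.float64) - 128.0) / 128.0, 8
    elif data.dtype in (np.float32, np.float64):
        samples, bit_depth = data.astype(np.float64), 32
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return AudioTrack(samples=samples, sample_rate=int(rate), bit_depth=bit_depth)


def write_wav(track: AudioTrack, path: str | Path) -> Path:
    """Write a track as 16-bit PCM WAV; round-trips with :func:`read_wav`.

    Raises if any amplitude exceeds full scale — no silent clipping.
    """
    path = Path(path)
    peak = np.max(np.abs(track.samples)) if track.n_samples else 0.0
    if peak > 1.0:
        raise ValueError(
            f"amplitudes exceed full scale (peak {peak:.3f}); rescale before writing"
        )
    quantized = np.clip(np.round(track.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), track.sample_rate, quantized)
    return path


def _frame_count(n_samples: int, window: int, hop: int) -> int:
    return (n_samples - window) // hop + 1


def compute_spectrogram(
    track: AudioTrack,
    params: SpectrogramParams | None = None,
    chunk_frames: int = 65_536,
) -> Spectrogram:
    """Compute the band-truncated one-sided power spectrogram.

    Frames are taken without padding: ``floor((N - window)/hop) + 1`` frames,
    each tapered and transformed, with frame time at the window center.
    Frequency bins outside ``[band_low, band_high]`` (inclusive) are dropped.
    Long recordings are processed in chunks to bound peak memory.
    """
    params = params or SpectrogramParams()
    w, hop = params.window_length, params.hop
    n = track.n_samples
    if n < w:
        raise ValueError(f"track has {n} samples, shorter than one {w}-sample window")

    try:
        taper = _WINDOWS[params.window_function.lower()](w)
    except KeyError:
        raise ValueError(f"unknown window function {params.window_function!r}") from None

    freqs = np.fft.rfftfreq(w, d=1.0 / track.sample_rate)
    if params.band_high > track.sample_rate / 2:
        raise ValueError("band_high exceeds the Nyquist frequency")
    keep = (freqs >= params.band_low) & (freqs <= params.band_high)
    if not keep.any():
        raise ValueError("no FFT bins fall inside the requested band")

    n_frames = _frame_count(n, w, hop)
    power = np.empty((n_frames, int(keep.sum())), dtype=np.float64)
    frames_view = np.lib.stride_tricks.sliding_window_view(track.samples, w)[::hop]
    for start in range(0, n_frames, chunk_frames):
        stop = min(start + chunk_frames, n_frames)
        spec = np.fft.rfft(frames_view[start:stop] * taper, axis=1)
        power[start:stop] = np.abs(spec[:, keep]) ** 2

    hop_seconds = hop / track.sample_rate
    frame_times = (np.arange(n_frames) * hop + w / 2) / track.sample_rate
    return Spectrogram(
        power=power,
        frame_times=frame_times,
        bin_freqs=freqs[keep],
        hop_seconds=hop_seconds,
        params=params,
    )


def to_decibel(
    power_linear: np.ndarray, reference: float = 1.0, floor_db: float = -120.0
) -> np.ndarray:
    """Convert linear power to dB re ``reference``: 10*log10(p/ref).

    Zero power maps to ``floor_db``; negative power is rejected.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    p = np.asarray(power_linear, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("negative power is not meaningful on a power scale")
    out = np.full_like(p, floor_db)
    nz = p > 0
    out[nz] = np.maximum(10.0 * np.log10(p[nz] / reference), floor_db)
    return out
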