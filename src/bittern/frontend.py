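"""Audio loading, framing, windowing and energy-based frame selection.

The front end of the recognizer: a clip is cut into fixed-length
overlapped frames (30 ms / 50% overlap by default, i.e. 1440 samples and
a 720-sample hop at 48 kHz), the most energetic fraction of frames is
retained as "birdsong" (the rest is treated as silence/background), and
the survivors are Hamming-windowed before spectral analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile


class AudioLoadError(ValueError):
    """Raised when a WAV file cannot be loaded as a mono clip."""


@dataclass
class AudioClip:
    """A labelled mono sample sequence at a fixed rate.

    ``samples`` are linear amplitudes scaled to [-1, 1].
    """

    samples: np.ndarray
    rate: int
    label: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class FrameMatrix:
    """Overlapped fixed-length frames cut from a clip.

    ``frames`` has shape (R, L) with L = ``frame_length``. ``frame_times``
    holds the start offset of each frame in seconds and increases in steps
    of ``hop / rate``.
    """

    frames: np.ndarray
    frame_length: int
    hop: int
    rate: int
    windowed: bool = False
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if self.frames.size == 0:
            self.frames = self.frames.reshape(0, self.frame_length)
        if self.frames.shape[1] != self.frame_length:
            raise ValueError(
                f"frames have length {self.frames.shape[1]}, "
                f"expected frame_length={self.frame_length}"
            )
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) * self.hop / self.rate
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def empty(self) -> bool:
        """True when the source clip was shorter than one frame."""
        return self.n_frames == 0


# PCM integer full-scale divisors by dtype; 24-bit WAV arrives as int32.
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def load_wav(path: str | Path, *, downmix: bool = False,
             label: str | None = None) -> AudioClip:
    """Load a RIFF WAV file as an :class:`AudioClip` scaled to [-1, 1].

    PCM 16/24/32-bit and float32/float64 encodings are supported. A
    multi-channel file is rejected unless ``downmix`` is set, in which
    case channels are averaged.
    """
    path = Path(path)
    if not path.exists():
        raise AudioLoadError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioLoadError(f"{path} is not a readable PCM WAV file: {exc}") from exc
    src_dtype = data.dtype
    if data.ndim == 2:
        if not downmix:
            raise AudioLoadError(
                f"{path} has {data.shape[1]} channels; pass downmix=True to average them"
            )
        data = data.astype(np.float64).mean(axis=1)
    if src_dtype.kind == "f":
        samples = np.asarray(data, dtype=np.float64)
    elif src_dtype == np.uint8:
        samples = (np.asarray(data, dtype=np.float64) - 128.0) / 128.0
    elif src_dtype in _PCM_SCALE:
        samples = np.asarray(data, dtype=np.float64) / _PCM_SCALE[src_dtype]
    else:
        raise AudioLoadError(f"{path}: unsupported sample encoding {src_dtype}")
    return AudioClip(samples=samples, rate=int(rate), label=label,
                     source_path=str(path))


def save_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM mono WAV, clipping amplitudes to [-1, 1]."""
    pcm = np.round(np.clip(clip.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.rate, pcm)


def frame_signal(clip: AudioClip, frame_ms: float = 30.0,
                 overlap: float = 0.5) -> FrameMatrix:
    """Cut a clip into fixed-length overlapped frames.

    The default 30 ms frame with 50% overlap gives a 1440-sample frame
    and a 720-sample hop at 48 kHz. Trailing samples that do not fill a
    whole frame are dropped. A clip shorter than one frame yields an
    empty (zero-frame) matrix, flagged via :attr:`FrameMatrix.empty`.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    exact_len = clip.rate * frame_ms / 1000.0
    frame_length = int(round(exact_len))
    if abs(exact_len - frame_length) > 1e-9 or frame_length < 1:
        raise ValueError(
            f"frame of {frame_ms} ms is not a whole number of samples at {clip.rate} Hz"
        )
    exact_hop = frame_length * (1.0 - overlap)
    hop = int(round(exact_hop))
    if abs(exact_hop - hop) > 1e-9 or hop < 1:
        raise ValueError(
            f"hop {exact_hop} derived from overlap {overlap} is not a whole sample count"
        )
    n = clip.samples.size
    if n < frame_length:
        frames = np.empty((0, frame_length))
    else:
        frames = np.lib.stride_tricks.sliding_window_view(
            clip.samples, frame_length)[::hop].copy()
    return FrameMatrix(frames=frames, frame_length=frame_length, hop=hop,
                       rate=clip.rate, windowed=False)


def hamming_window(length: int) -> np.ndarray:
    """Symmetric Hamming window 0.54 - 0.46*cos(2*pi*n/(L-1))."""
    if length == 1:
        return np.ones(1)
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))


def apply_window(fm: FrameMatrix) -> FrameMatrix:
    """Multiply every frame by a symmetric Hamming window.

    Raises if the frames were already windowed: double windowing is
    always a pipeline bug, never intentional.
    """
    if fm.windowed:
        raise ValueError("FrameMatrix is already windowed")
    w = hamming_window(fm.frame_length)
    return replace(fm, frames=fm.frames * w, windowed=True,
                   frame_times=fm.frame_times)


def frame_energies(fm: FrameMatrix) -> np.ndarray:
    """Per-frame energy: sum of squared samples."""
    return np.einsum("ij,ij->i", fm.frames, fm.frames)


def select_high_energy_frames(fm: FrameMatrix,
                              fraction: float = 0.35) -> np.ndarray:
    """Indices of the ``ceil(fraction * R)`` highest-energy frames.

    This is the corpus annotation rule: the loudest 35% of frames in a
    recording are kept as birdsong and the rest discarded. Energies are
    computed on *unwindowed* frames; indices are returned in ascending
    time order; ties go to the earlier frame.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fm.windowed:
        raise ValueError(
            "energy selection operates on unwindowed frames; gate before apply_window"
        )
    if fm.empty:
        return np.empty(0, dtype=np.intp)
    energies = frame_energies(fm)
    keep = math.ceil(fraction * fm.n_frames)
    order = np.argsort(-energies, kind="stable")[:keep]
    return np.sort(order)


def take_frames(fm: FrameMatrix, indices: np.ndarray) -> FrameMatrix:
    """Restrict a FrameMatrix to the given frame indices (time order kept)."""
    return replace(fm, frames=fm.frames[indices],
                   frame_times=fm.frame_times[indices])
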