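"""Mel-frequency cepstral coefficient extraction.

The feature chain per frame: Hamming window -> zero-padded DFT power
spectrum (nfft = 2048) -> 48-filter triangular bank -> log filter-bank
energies LE(i) -> DCT-II -> first 13 cepstral coefficients.

The filter bank is a hybrid of the common Mel layout: centers are spaced
*linearly* from 20 Hz up to 1 kHz and *Mel-spaced* from 1 kHz up to
16 kHz, with adjacent triangles overlapping 50% (each triangle spans the
previous center to the next). The number of filters falling in the
linear region is the number of centers a pure-Mel layout would place
below the split frequency; setting ``split_freq <= fmin`` recovers a
conventional all-Mel bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct as _scipy_dct
from sklearn.base import BaseEstimator, TransformerMixin

from .frontend import (
    AudioClip,
    FrameMatrix,
    apply_window,
    frame_signal,
    select_high_energy_frames,
    take_frames,
)

LOG_FLOOR = 1e-12  # protects digital-silence frames from log(0)


def hz_to_mel(f):
    """Perceptual Mel scale, mel(f) = 2595*log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclass
class Spectrum:
    """One-sided magnitude-squared spectrum |X[k]|^2 of a single frame."""

    values: np.ndarray
    nfft: int
    rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != self.nfft // 2 + 1:
            raise ValueError(
                f"one-sided spectrum for nfft={self.nfft} must have "
                f"{self.nfft // 2 + 1} bins, got {self.values.size}"
            )

    @property
    def bin_hz(self) -> float:
        return self.rate / self.nfft


@dataclass
class MelFilterBank:
    """Triangular filter bank evaluated at the one-sided DFT bin grid."""

    n_filters: int
    fmin: float
    split_freq: float
    fmax: float
    nfft: int
    rate: int
    weights: np.ndarray = field(repr=False)
    center_freqs: np.ndarray = None  # type: ignore[assignment]

    def apply(self, power: np.ndarray) -> np.ndarray:
        """Filter-bank energies for one spectrum or a stack of spectra."""
        power = np.asarray(power, dtype=np.float64)
        if power.shape[-1] != self.weights.shape[1]:
            raise ValueError(
                f"spectrum has {power.shape[-1]} bins, bank expects "
                f"{self.weights.shape[1]} (nfft={self.nfft})"
            )
        return power @ self.weights.T


@dataclass
class FeatureMatrix:
    """Per-frame cepstral feature vectors (R frames x d coefficients)."""

    vectors: np.ndarray
    frame_times: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors contain non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def power_spectrum(frame: np.ndarray, nfft: int = 2048,
                   rate: int = 48000) -> Spectrum:
    """Zero-pad a (windowed) frame to ``nfft`` and return |X[k]|^2, one-sided."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1:
        raise ValueError("power_spectrum expects a single 1-D frame")
    if frame.size > nfft:
        raise ValueError(f"frame length {frame.size} exceeds nfft={nfft}")
    spec = np.fft.rfft(frame, n=nfft)
    return Spectrum(values=np.abs(spec) ** 2, nfft=nfft, rate=rate)


def _mel_grid(fmin: float, fmax: float, n_points: int) -> np.ndarray:
    return mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_points))


def build_filterbank(n_filters: int = 48, fmin: float = 20.0,
                     split_freq: float = 1000.0, fmax: float = 16000.0,
                     nfft: int = 2048, rate: int = 48000) -> MelFilterBank:
    """Construct the hybrid linear/Mel triangular filter bank.

    Grid points run from ``fmin`` to ``fmax``; filter i is the triangle
    over (p[i-1], p[i], p[i+1]), so neighbouring filters overlap 50%.
    """
    nyquist = rate / 2.0
    if fmax > nyquist:
        raise ValueError(f"fmax={fmax} Hz exceeds Nyquist {nyquist} Hz")
    if not fmin < fmax:
        raise ValueError("need fmin < fmax")
    if split_freq >= fmax:
        raise ValueError("need split_freq < fmax")

    if split_freq <= fmin:
        points = _mel_grid(fmin, fmax, n_filters + 2)
    else:
        # How many of a pure-Mel layout's centers would sit at or below the split.
        ref_centers = _mel_grid(fmin, fmax, n_filters + 2)[1:-1]
        n_low = int(np.count_nonzero(ref_centers <= split_freq))
        n_high = n_filters - n_low
        if n_low == 0:
            points = _mel_grid(fmin, fmax, n_filters + 2)
        elif n_high == 0:
            points = np.linspace(fmin, fmax, n_filters + 2)
        else:
            low = np.linspace(fmin, split_freq, n_low + 1)
            high = _mel_grid(split_freq, fmax, n_high + 2)[1:]
            points = np.concatenate([low, high])

    centers = points[1:-1]
    bin_freqs = np.arange(nfft // 2 + 1) * rate / nfft
    weights = np.zeros((n_filters, bin_freqs.size))
    for i in range(n_filters):
        lo, mid, hi = points[i], points[i + 1], points[i + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        weights[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return MelFilterBank(n_filters=n_filters, fmin=fmin, split_freq=split_freq,
                         fmax=fmax, nfft=nfft, rate=rate, weights=weights,
                         center_freqs=centers)


def log_energies(spec: Spectrum, bank: MelFilterBank,
                 floor: float = LOG_FLOOR) -> np.ndarray:
    """LE(i) = ln(max(filter_i . |X|^2, floor)) for each filter."""
    if bank.nfft != spec.nfft:
        raise ValueError(
            f"bank built for nfft={bank.nfft}, spectrum has nfft={spec.nfft}"
        )
    return np.log(np.maximum(bank.apply(spec.values), floor))


def dct_cepstra(le: np.ndarray, n_coeffs: int = 13) -> np.ndarray:
    """Orthonormal DCT-II of the log energies, truncated to ``n_coeffs``."""
    le = np.asarray(le, dtype=np.float64)
    n = le.shape[-1]
    if n_coeffs > n:
        raise ValueError(f"cannot keep {n_coeffs} coefficients from {n} filters")
    return _scipy_dct(le, type=2, norm="ortho", axis=-1)[..., :n_coeffs]


class MFCCExtractor(TransformerMixin, BaseEstimator):
    """Transformer turning audio clips into per-frame MFCC matrices.

    Parameters mirror the recognizer defaults: 30 ms frames with 50%
    overlap at 48 kHz, 2048-point transform, 48 filters from 20 Hz to
    16 kHz split at 1 kHz, 13 cepstral coefficients. ``energy_fraction``
    optionally applies the high-energy frame gate (e.g. 0.35) before
    windowing; ``None`` keeps every frame.
    """

    def __init__(self, rate: int = 48000, frame_ms: float = 30.0,
                 overlap: float = 0.5, nfft: int = 2048, n_filters: int = 48,
                 fmin: float = 20.0, split_freq: float = 1000.0,
                 fmax: float = 16000.0, n_coeffs: int = 13,
                 energy_fraction: float | None = None,
                 log_floor: float = LOG_FLOOR):
        self.rate = rate
        self.frame_ms = frame_ms
        self.overlap = overlap
        self.nfft = nfft
        self.n_filters = n_filters
        self.fmin = fmin
        self.split_freq = split_freq
        self.fmax = fmax
        self.n_coeffs = n_coeffs
        self.energy_fraction = energy_fraction
        self.log_floor = log_floor

    def fit(self, X=None, y=None) -> "MFCCExtractor":
        """Build the filter bank; X is unused (stateless w.r.t. data)."""
        self.filterbank_ = build_filterbank(
            n_filters=self.n_filters, fmin=self.fmin,
            split_freq=self.split_freq, fmax=self.fmax,
            nfft=self.nfft, rate=self.rate)
        return self

    def _frames_of(self, item) -> tuple[FrameMatrix, str | None]:
        if isinstance(item, FrameMatrix):
            return item, None
        if isinstance(item, AudioClip):
            clip = item
        else:
            clip = AudioClip(samples=np.asarray(item, dtype=np.float64),
                             rate=self.rate)
        return frame_signal(clip, self.frame_ms, self.overlap), clip.label

    def transform_one(self, item) -> FeatureMatrix:
        """Full chain for one clip or frame matrix -> FeatureMatrix."""
        if not hasattr(self, "filterbank_"):
            self.fit()
        fm, label = self._frames_of(item)
        if self.energy_fraction is not None and not fm.empty:
            fm = take_frames(fm, select_high_energy_frames(fm, self.energy_fraction))
        if fm.empty:
            return FeatureMatrix(
                vectors=np.empty((0, self.n_coeffs)),
                frame_times=np.empty(0), label=label)
        if fm.frame_length > self.nfft:
            raise ValueError(
                f"frame length {fm.frame_length} exceeds nfft={self.nfft}")
        windowed = apply_window(fm)
        power = np.abs(np.fft.rfft(windowed.frames, n=self.nfft, axis=1)) ** 2
        le = np.log(np.maximum(self.filterbank_.apply(power), self.log_floor))
        cc = dct_cepstra(le, self.n_coeffs)
        return FeatureMatrix(vectors=cc, frame_times=fm.frame_times, label=label)

    def transform(self, X) -> list[FeatureMatrix]:
        """Transform a sequence of clips/arrays into FeatureMatrix objects."""
        return [self.transform_one(item) for item in X]


def extract_mfcc(clip_or_frames, **config) -> FeatureMatrix:
    """One-shot MFCC extraction with the recognizer defaults.

    Keyword arguments are :class:`MFCCExtractor` parameters.
    """
    return MFCCExtractor(**config).fit().transform_one(clip_or_frames)
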