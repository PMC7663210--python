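"""Spectrogram images from 1-D spectra.

The wavelength axis is treated as a time axis: the raw spectrum is cut into
overlapping frames, each frame is Hamming-windowed and Fourier-transformed,
and the magnitude grid is bilinearly resized and min-max normalized into a
square single-channel image. With the two stock parameterizations
(frame 50 / overlap 20 for 750-channel spectra; frame 100 / overlap 50 for
4200-channel spectra) every sample becomes a 64 x 64 image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .exceptions import ConfigurationError, ValidationError
from .io import SpectrumSet

__all__ = [
    "SpectrogramConfig",
    "SpectrogramImage",
    "frame_signal",
    "hamming_window",
    "stft_magnitude",
    "to_image",
    "spectrogram_image",
    "batch_spectrograms",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """Windowed-Fourier-transform settings.

    frame_length / overlap are in channels; hop = frame_length - overlap.
    """

    frame_length: int = 50
    overlap: int = 20
    window: str = "hamming"
    image_size: int = 64
    log_scale: bool = True
    resize: str = "bilinear"

    def __post_init__(self):
        if not 0 <= self.overlap < self.frame_length:
            raise ConfigurationError(f"need 0 <= overlap < frame_length, got {self.overlap}/{self.frame_length}")
        if self.image_size < 8:
            raise ConfigurationError("image_size must be >= 8")
        if self.window != "hamming":
            raise ConfigurationError(f"unsupported window {self.window!r}")
        if self.resize != "bilinear":
            raise ConfigurationError(f"unsupported resize {self.resize!r}")

    @classmethod
    def small_preset(cls, **kw) -> "SpectrogramConfig":
        """Parameters used for 750-channel spectra (frame 50, overlap 20)."""
        return cls(frame_length=50, overlap=20, **kw)

    @classmethod
    def lucas_preset(cls, **kw) -> "SpectrogramConfig":
        """Parameters used for 4200-channel spectra (frame 100, overlap 50)."""
        return cls(frame_length=100, overlap=50, **kw)


@dataclass
class SpectrogramImage:
    """Square single-channel image in [0, 1] derived from one spectrum."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValidationError(f"spectrogram image must be square, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("spectrogram image contains non-finite pixels")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValidationError("spectrogram pixels must lie in [0, 1]")


def frame_signal(x: np.ndarray, frame_length: int, overlap: int) -> np.ndarray:
    """Slice a 1-D signal into overlapping contiguous frames.

    hop = frame_length - overlap; the number of frames is
    floor((L - frame_length) / hop) + 1 and trailing samples that do not
    fill a frame are dropped.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 0 <= overlap < frame_length:
        raise ConfigurationError(f"need 0 <= overlap < frame_length, got {overlap}/{frame_length}")
    if x.size < frame_length:
        raise ValidationError(f"signal length {x.size} < frame length {frame_length}")
    hop = frame_length - overlap
    return sliding_window_view(x, frame_length)[::hop].copy()


def hamming_window(n: int) -> np.ndarray:
    """Symmetric Hamming window w(k) = 0.54 - 0.46 cos(2 pi k / (N-1))."""
    if n < 2:
        raise ConfigurationError("window length must be >= 2")
    k = np.arange(n)
    return 0.54 - 0.46 * np.cos(2 * np.pi * k / (n - 1))


def stft_magnitude(frames: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Magnitude of the real FFT of each windowed frame.

    Returns a (frame_length // 2 + 1) x n_frames grid: frequency bins down
    the rows, frames (wavelength position) across the columns. No zero
    padding; the transform length equals the frame length.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    window = np.asarray(window, dtype=float)
    if window.shape != (frames.shape[1],):
        raise ValidationError(f"window length {window.size} != frame length {frames.shape[1]}")
    return np.abs(np.fft.rfft(frames * window, axis=1)).T


def to_image(mag: np.ndarray, cfg: SpectrogramConfig, source_id: str = "") -> SpectrogramImage:
    """Render a magnitude grid as a normalized square image.

    Optional log1p compression, bilinear resize to image_size x image_size,
    then per-image min-max normalization to [0, 1]. A constant grid maps to
    the all-zero image.
    """
    mag = np.atleast_2d(np.asarray(mag, dtype=float))
    if mag.size == 0:
        raise ValidationError("empty magnitude grid")
    if not np.all(np.isfinite(mag)):
        raise ValidationError("magnitude grid contains NaN/Inf")
    if cfg.log_scale:
        mag = np.log1p(mag)
    s = cfg.image_size
    span_in = float(mag.max() - mag.min())
    if mag.shape != (s, s):
        mag = ndimage.zoom(mag, (s / mag.shape[0], s / mag.shape[1]), order=1, grid_mode=True, mode="nearest")
    lo, hi = float(mag.min()), float(mag.max())
    # constant input (or resize round-off on one) maps to the all-zero image
    degenerate = span_in <= 1e-12 * max(1.0, abs(hi)) or hi - lo <= 1e-12 * max(1.0, abs(hi))
    pixels = np.zeros((s, s)) if degenerate else (mag - lo) / (hi - lo)
    return SpectrogramImage(np.clip(pixels, 0.0, 1.0), source_id)


def spectrogram_image(x: np.ndarray, cfg: SpectrogramConfig, source_id: str = "") -> SpectrogramImage:
    """Full pipeline for one spectrum: frame, window, FFT, render."""
    frames = frame_signal(x, cfg.frame_length, cfg.overlap)
    mag = stft_magnitude(frames, hamming_window(cfg.frame_length))
    return to_image(mag, cfg, source_id)


def batch_spectrograms(ss: SpectrumSet, cfg: SpectrogramConfig) -> np.ndarray:
    """Spectrogram images for every sample; returns (n, S, S) in [0, 1].

    Images are computed from the spectra as given (by convention the raw,
    un-preprocessed absorbance; the 1-D network branch is the one that sees
    preprocessed sequences).
    """
    out = np.empty((ss.n_samples, cfg.image_size, cfg.image_size))
    for i in range(ss.n_samples):
        out[i] = spectrogram_image(ss.intensities[i], cfg, ss.sample_ids[i]).pixels
    return out
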