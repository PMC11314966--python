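"""Bandpass filtering, sliding-window segmentation, and Morlet scalograms.

The preprocessing chain turns a raw single-channel record into the
GAN's data space: zero-phase FIR bandpass (0.5-40 Hz by default),
fixed-length overlapping windows, and a continuous wavelet transform
rendered as a square 3-channel image with pixel values strictly inside
(-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import zoom as _ndzoom
from scipy.signal import filtfilt, firwin

from .io import SignalRecord

__all__ = [
    "SegmentationConfig",
    "Scalogram",
    "bandpass_filter",
    "segment_signal",
    "cwt_scalogram",
    "scale_to_unit_range",
    "cwt_magnitude",
    "save_scalogram_png",
]

#: margin keeping scaled pixel values strictly inside the open interval
UNIT_RANGE_EPS = 1e-3


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window parameters: window length in seconds and overlap."""

    window_s: float = 2.88
    overlap_frac: float = 0.5

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must lie in [0, 1)")


@dataclass
class Scalogram:
    """A height x width x 3 time-frequency image with values in (-1, 1)."""

    pixels: np.ndarray
    meta: str = ""
    label: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got {self.pixels.shape}")
        if not np.all(np.abs(self.pixels) < 1.0):
            raise ValueError("pixel values must lie strictly inside (-1, 1)")


def bandpass_filter(
    rec: SignalRecord,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    transition_hz: float = 2.0,
) -> SignalRecord:
    """Zero-phase FIR bandpass via forward-backward filtering.

    A Hamming-windowed sinc design with order ~ 3.3 * fs / transition
    width; applying it forward and backward removes the group delay so
    the output has the same length and alignment as the input.
    """
    if not 0 < low_hz < high_hz < rec.fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < fs/2 "
            f"= {rec.fs / 2}"
        )
    numtaps = int(np.ceil(3.3 * rec.fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> linear phase type I
    taps = firwin(numtaps, [low_hz, high_hz], pass_zero="bandpass", fs=rec.fs)
    padlen = min(3 * numtaps, rec.samples.size - 1)
    filtered = filtfilt(taps, [1.0], rec.samples, padlen=padlen)
    return SignalRecord(filtered, fs=rec.fs, source_id=rec.source_id,
                        label=rec.label)


def segment_signal(rec: SignalRecord, cfg: SegmentationConfig) -> list[SignalRecord]:
    """Cut a record into overlapping fixed-length windows.

    The window holds ``round(window_s * fs)`` samples, the hop is
    ``round(window_s * fs * (1 - overlap_frac))`` samples, and a trailing
    partial window is dropped, giving ``floor((L - w) / hop) + 1``
    segments.  Labels and provenance are carried onto every segment.
    """
    w = int(round(cfg.window_s * rec.fs))
    if w > rec.samples.size:
        raise ValueError(
            f"record {rec.source_id!r} has {rec.samples.size} samples, "
            f"shorter than the {w}-sample window"
        )
    hop = int(round(cfg.window_s * rec.fs * (1 - cfg.overlap_frac)))
    hop = max(hop, 1)
    count = (rec.samples.size - w) // hop + 1
    return [
        SignalRecord(
            rec.samples[i * hop : i * hop + w],
            fs=rec.fs,
            source_id=f"{rec.source_id}#{i}",
            label=rec.label,
        )
        for i in range(count)
    ]


def _scale_grid(freq_lo: float, freq_hi: float, n_scales: int, fs: float):
    """Log-spaced analysis frequencies (descending) and Morlet scales."""
    freqs = np.geomspace(freq_hi, freq_lo, n_scales)
    fc = pywt.central_frequency("morl")
    scales = fc * fs / freqs
    return freqs, scales


def cwt_magnitude(
    seg: SignalRecord,
    freq_lo: float = 0.5,
    freq_hi: float = 40.0,
    n_scales: int = 64,
):
    """|CWT| magnitudes on the log-spaced scale grid (rows = descending freq).

    Returns ``(magnitude, grid_freqs)``; this is the pre-colormap stage of
    :func:`cwt_scalogram`, exposed for spectral checks.
    """
    if seg.samples.size < 2:
        raise ValueError("segment must have at least 2 samples")
    if not 0 < freq_lo < freq_hi < seg.fs / 2:
        raise ValueError(f"degenerate frequency band ({freq_lo}, {freq_hi})")
    freqs, scales = _scale_grid(freq_lo, freq_hi, n_scales, seg.fs)
    coef, _ = pywt.cwt(seg.samples, scales, "morl", sampling_period=1.0 / seg.fs)
    return np.abs(coef), freqs


def _colormap_lut(name: str = "jet", n: int = 256) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[name]
    return cmap(np.linspace(0.0, 1.0, n))[:, :3]


_LUT_CACHE: dict = {}


def cwt_scalogram(
    seg: SignalRecord,
    freq_lo: float = 0.5,
    freq_hi: float = 40.0,
    out_size: int = 64,
    n_scales: int = 64,
    colormap: str = "jet",
) -> Scalogram:
    """Render a segment as a square RGB scalogram scaled into (-1, 1).

    Pipeline: |CWT| magnitude on ``n_scales`` log-spaced scales covering
    the band, bilinear resampling to ``out_size`` x ``out_size``, per-image
    normalization through a colormap to 3 channels, then
    :func:`scale_to_unit_range`.  Fully deterministic.
    """
    mag, _ = cwt_magnitude(seg, freq_lo, freq_hi, n_scales)
    z = (out_size / mag.shape[0], out_size / mag.shape[1])
    img = _ndzoom(mag, z, order=1, mode="nearest", grid_mode=True)
    if img.shape != (out_size, out_size):  # pragma: no cover - zoom rounding
        raise RuntimeError(f"resample produced {img.shape}")
    lo, hi = img.min(), img.max()
    norm = np.zeros_like(img) if hi - lo == 0 else (img - lo) / (hi - lo)
    lut = _LUT_CACHE.setdefault(colormap, _colormap_lut(colormap))
    rgb = lut[np.clip((norm * (len(lut) - 1)).round().astype(int), 0, len(lut) - 1)]
    return Scalogram(scale_to_unit_range(rgb), meta=seg.source_id, label=seg.label)


def save_scalogram_png(scalogram: Scalogram, path) -> None:
    """Write a scalogram to PNG for visual inspection."""
    import matplotlib.image

    rgb = (scalogram.pixels + 1.0) / 2.0
    matplotlib.image.imsave(str(path), np.clip(rgb, 0.0, 1.0))


def scale_to_unit_range(image: np.ndarray, eps: float = UNIT_RANGE_EPS) -> np.ndarray:
    """Affinely map [min, max] onto [-1+eps, 1-eps]; constant images -> 0."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo) * 2.0 * (1.0 - eps) - (1.0 - eps)
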