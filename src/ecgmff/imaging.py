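"""2D representations of a lead-II heartbeat.

Two images feed the 2D network branches:

* a Gramian Angular Field (GAF) of the beat's one-sided DFT magnitude
  spectrum — the spectrum is PAA-smoothed to the image side length, rescaled
  to [-1, 1], mapped to polar angles ``phi_i = arccos(x_i)``, and the image
  is the antisymmetric difference field ``G[i, j] = sin(phi_i - phi_j)``;
* the magnitude of the discrete Stockwell (S-) transform of the beat,
  restricted to the diagnostic band (0, f_max] and rendered as a
  frequency x time matrix scaled to [0, 1].

Both operations are deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skimage.transform

from .records import BeatTensor


# ---------------------------------------------------------------------------
# GAF building blocks
# ---------------------------------------------------------------------------

def rescale_minmax(series: np.ndarray) -> np.ndarray:
    """Rescale a series to [-1, 1]:
    ``x_i -> ((x_i - max) + (x_i - min)) / (max - min)``.

    The minimum maps to -1 and the maximum to +1. A constant series has no
    scale and is rejected.
    """
    x = np.asarray(series, dtype=np.float64)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot rescale a constant series")
    return ((x - hi) + (x - lo)) / (hi - lo)


def paa_smooth(series: np.ndarray, target_length: int) -> np.ndarray:
    """Piecewise aggregation approximation: frame means to ``target_length``.

    The series is partitioned into ``target_length`` contiguous frames
    (boundaries at ``round(i * n / m)``) and each frame is replaced by its
    mean.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.size
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if target_length > n:
        raise ValueError("target_length exceeds series length")
    if target_length == n:
        return x.copy()
    edges = np.round(np.linspace(0, n, target_length + 1)).astype(int)
    return np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def polar_encode(series: np.ndarray, normalizer: float | None = None):
    """Polar encoding of a rescaled series: angles ``arccos(x_i)`` in
    [0, pi] and radii ``t_i / N``.

    The radii locate samples on the polar plot; the GAF itself depends only
    on the angles.
    """
    x = np.asarray(series, dtype=np.float64)
    if np.any(x < -1) or np.any(x > 1):
        raise ValueError("series must lie in [-1, 1]; rescale first")
    n = normalizer if normalizer is not None else x.size
    angles = np.arccos(x)
    radii = np.arange(1, x.size + 1) / n
    return angles, radii


def gaf_transform(series: np.ndarray) -> np.ndarray:
    """Gramian angular difference field of a rescaled series.

    ``G[i, j] = sin(phi_i - phi_j)``, computed in closed matrix form as
    ``sqrt(1 - x^2) x' - x sqrt(1 - x^2)'``. The result has a zero
    diagonal, is antisymmetric, and every entry lies in [-1, 1].
    """
    x = np.asarray(series, dtype=np.float64)
    if np.any(x < -1) or np.any(x > 1):
        raise ValueError("series must lie in [-1, 1]; rescale first")
    comp = np.sqrt(np.clip(1.0 - x**2, 0.0, None))  # sin(arccos x)
    g = np.outer(comp, x) - np.outer(x, comp)
    np.fill_diagonal(g, 0.0)
    return g


def beat_spectrum(beat: BeatTensor, sampling_rate: float = 1000.0):
    """One-sided DFT magnitude spectrum of the beat's lead II.

    Returns (magnitudes, frequency step in Hz/bin). DC bin retained.
    """
    x = beat.lead("II")
    mags = np.abs(np.fft.rfft(x))
    return mags, sampling_rate / x.size


def beat_to_spectrum_image(
    beat: BeatTensor, image_size: int = 224, sampling_rate: float = 1000.0
) -> np.ndarray:
    """Lead-II spectrum -> PAA smoothing -> rescale -> GAF image.

    Returns an ``image_size x image_size`` matrix in [-1, 1].
    """
    if image_size < 2:
        raise ValueError("image_size must be >= 2")
    mags, _ = beat_spectrum(beat, sampling_rate)
    smoothed = paa_smooth(mags, image_size)
    return gaf_transform(rescale_minmax(smoothed))


# ---------------------------------------------------------------------------
# S-transform
# ---------------------------------------------------------------------------

def s_transform(signal: np.ndarray, freq_bins: np.ndarray | None = None) -> np.ndarray:
    """Discrete Stockwell transform, computed in the spectral domain.

    For frequency bin ``n > 0`` the time row is the inverse DFT over ``m`` of
    ``X[n + m] * exp(-2 pi^2 m^2 / n^2)`` — a Gaussian "voice" centred on the
    analysis frequency whose width scales inversely with it. The degenerate
    ``n = 0`` row, when requested, is the signal mean. Summing any ``n > 0``
    row over time recovers the DFT coefficient ``X[n]`` exactly.

    Parameters
    ----------
    signal : 1-D array of length L.
    freq_bins : integer DFT bin indices to compute (default: 0..L//2).

    Returns
    -------
    complex ndarray of shape ``(len(freq_bins), L)`` indexed (frequency, time).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    L = x.size
    if freq_bins is None:
        freq_bins = np.arange(L // 2 + 1)
    freq_bins = np.asarray(freq_bins, dtype=np.int64)
    if np.any(freq_bins < 0) or np.any(freq_bins > L // 2):
        raise ValueError("freq_bins must lie in [0, L//2]")

    X = np.fft.fft(x)
    # signed frequency offsets m with wrap-around
    m = np.fft.fftfreq(L, d=1.0 / L)
    out = np.empty((freq_bins.size, L), dtype=np.complex128)
    for row, n in enumerate(freq_bins):
        if n == 0:
            out[row] = np.mean(x)
            continue
        voice = X[(np.arange(L) + n) % L] * np.exp(-2.0 * np.pi**2 * m**2 / n**2)
        out[row] = np.fft.ifft(voice)
    return out


def beat_to_st_image(
    beat: BeatTensor,
    image_size: int = 224,
    f_max: float = 45.0,
    sampling_rate: float = 1000.0,
) -> np.ndarray:
    """S-transform magnitude image of the beat's lead II.

    Frequencies in (0, f_max] are analyzed (f_max defaults to 45 Hz, the
    upper edge of the ECG diagnostic band), the magnitude is resized to
    ``image_size x image_size`` by area interpolation, and values are scaled
    to [0, 1] by the global maximum (an all-zero beat stays all-zero).
    """
    x = beat.lead("II")
    L = x.size
    nyquist = sampling_rate / 2.0
    if f_max <= 0 or f_max > nyquist:
        raise ValueError(f"f_max must lie in (0, {nyquist}]")
    n_max = int(np.floor(f_max * L / sampling_rate))
    if n_max < 1:
        raise ValueError("f_max below the first positive frequency bin")
    st = s_transform(x, np.arange(1, n_max + 1))
    mag = np.abs(st)
    img = skimage.transform.resize(
        mag, (image_size, image_size), order=1, anti_aliasing=True,
        preserve_range=True,
    )
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


# ---------------------------------------------------------------------------
# Feature extraction for the fusion model
# ---------------------------------------------------------------------------

@dataclass
class ImagingConfig:
    """Image side length and S-transform band for feature generation."""

    image_size: int = 224
    f_max: float = 45.0


def beats_to_features(
    beats: list[BeatTensor], config: ImagingConfig | None = None
):
    """Stack (beat tensors, GAF images, ST images) arrays for a beat list.

    Returns float32 arrays shaped ``(n, 12, 651)``, ``(n, 1, s, s)`` and
    ``(n, 1, s, s)`` ready for the three network branches.
    """
    config = config or ImagingConfig()
    xs = np.stack([b.values for b in beats]).astype(np.float32)
    gafs = np.stack(
        [beat_to_spectrum_image(b, config.image_size) for b in beats]
    ).astype(np.float32)[:, None, :, :]
    sts = np.stack(
        [beat_to_st_image(b, config.image_size, config.f_max) for b in beats]
    ).astype(np.float32)[:, None, :, :]
    return xs, gafs, sts
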