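"""ECG preprocessing: baseline removal, wavelet denoising, R-peak detection
and fixed-window beat segmentation.

The denoiser uses an improved soft-threshold rule on the detail coefficients
of a db6 wavelet decomposition: at level ``b`` the threshold is

    TE_b = sigma_b * sqrt(2 * ln ||d_b|| / ln(b + 1)),

where ``||d_b||`` is the L2 norm of the level-b detail coefficients and
``sigma_b = median(|d_b|) / 0.6745`` is the MAD noise estimate (0.6745 is the
0.75 quantile of the standard normal). Coefficients at or below TE_b are
zeroed; those above are shrunk by TE_b with their sign preserved.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
import scipy.signal

from .records import (
    BEAT_LENGTH,
    POST_R_SAMPLES,
    PRE_R_SAMPLES,
    BeatTensor,
    EcgRecord,
    RPeakList,
)

#: MAD-to-sigma normalization: inverse standard-normal CDF at 0.75.
MAD_CONSTANT = 0.6745


# ---------------------------------------------------------------------------
# Baseline removal
# ---------------------------------------------------------------------------

def remove_baseline(
    record: EcgRecord,
    first_window_s: float = 0.2,
    second_window_s: float = 0.6,
) -> EcgRecord:
    """Remove baseline wander with a two-stage median-filter cascade.

    The baseline estimate is ``medfilt(medfilt(x, 200 ms), 600 ms)`` per
    lead — the short window removes P/QRS deflections, the long window the
    T wave — and is subtracted so the isoelectric line sits at zero.
    """
    fs = record.sampling_rate
    w1 = _odd_window(first_window_s, fs)
    w2 = _odd_window(second_window_s, fs)
    if record.n_samples <= max(w1, w2):
        raise ValueError(
            f"record of {record.n_samples} samples shorter than the "
            f"{max(w1, w2)}-sample median-filter window"
        )
    out = np.empty_like(record.signal)
    for i in range(record.n_leads):
        stage1 = scipy.signal.medfilt(record.signal[i], w1)
        baseline = scipy.signal.medfilt(stage1, w2)
        out[i] = record.signal[i] - baseline
    return record.with_signal(out)


def _odd_window(seconds: float, fs: float) -> int:
    w = int(round(seconds * fs))
    return w + 1 if w % 2 == 0 else w


# ---------------------------------------------------------------------------
# Wavelet denoising
# ---------------------------------------------------------------------------

@dataclass
class WaveletDenoiseConfig:
    """Wavelet and decomposition depth for the improved-threshold denoiser."""

    wavelet_name: str = "db6"
    n_levels: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.n_levels <= 9:
            raise ValueError("n_levels must be in 1..9")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}")


def level_threshold(detail: np.ndarray, level: int) -> float:
    """Threshold TE_b for one detail-coefficient array at level ``b >= 1``.

    The radicand is clamped at zero (a coefficient norm below 1 would make
    the logarithm negative), so the threshold is always >= 0.
    """
    detail = np.asarray(detail, dtype=np.float64)
    sigma = np.median(np.abs(detail)) / MAD_CONSTANT
    norm = np.linalg.norm(detail)
    if norm <= 0:
        return 0.0
    radicand = max(2.0 * np.log(norm), 0.0) / np.log(level + 1)
    return float(sigma * np.sqrt(radicand))


def shrink_coefficients(detail: np.ndarray, threshold: float) -> np.ndarray:
    """Soft-threshold with sign preservation.

    ``sgn(d) * (|d| - TE)`` where ``|d| > TE``, zero elsewhere.
    """
    detail = np.asarray(detail, dtype=np.float64)
    mag = np.abs(detail)
    return np.where(mag > threshold, np.sign(detail) * (mag - threshold), 0.0)


def denoise_wavelet(
    record: EcgRecord, config: WaveletDenoiseConfig | None = None
) -> EcgRecord:
    """Denoise every lead by level-dependent soft thresholding.

    Each lead is decomposed to ``config.n_levels`` with ``config.wavelet_name``
    (default db6, whose shape resembles the QRS complex); detail coefficients
    are shrunk by their level threshold, approximation coefficients are left
    untouched, and the lead is reconstructed.
    """
    config = config or WaveletDenoiseConfig()
    max_level = pywt.dwt_max_level(record.n_samples, config.wavelet_name)
    if config.n_levels > max_level:
        raise ValueError(
            f"record of {record.n_samples} samples supports at most "
            f"{max_level} levels ({config.n_levels} requested)"
        )
    out = np.empty_like(record.signal)
    for i in range(record.n_leads):
        coeffs = pywt.wavedec(record.signal[i], config.wavelet_name,
                              level=config.n_levels)
        # coeffs = [cA_n, cD_n, ..., cD_1]; level b=1 is the finest detail
        new = [coeffs[0]]
        for pos, detail in enumerate(coeffs[1:]):
            level = config.n_levels - pos
            te = level_threshold(detail, level)
            new.append(shrink_coefficients(detail, te))
        rec = pywt.waverec(new, config.wavelet_name)
        out[i] = rec[: record.n_samples]
    return record.with_signal(out)


# ---------------------------------------------------------------------------
# Pan-Tompkins R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(record: EcgRecord, lead: str = "II") -> RPeakList:
    """Locate R peaks with the classic Pan-Tompkins chain on one lead.

    Band-pass (5-15 Hz), differentiate, square, integrate over a 150 ms
    moving window, then apply adaptive dual thresholds with search-back and
    a 200 ms refractory period. Each detected peak is refined to the local
    extremum of the band-passed signal within +-50 ms.
    """
    fs = record.sampling_rate
    if record.duration < 2.0:
        raise ValueError("record shorter than 2 s; cannot adapt thresholds")
    x = record.lead(lead)

    sos = scipy.signal.butter(3, [5.0, 15.0], btype="bandpass", fs=fs,
                              output="sos")
    bp = scipy.signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = scipy.signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return RPeakList(np.empty(0, dtype=np.int64), fs)

    spki = float(np.max(mwi[: int(2 * fs)])) * 0.25  # running signal level
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5  # running noise level
    peaks: list[int] = []
    missed: list[int] = []
    last_accepted = -refractory
    rr_history: list[int] = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr and c - last_accepted >= refractory:
            # search-back: a long RR gap may hide a peak above half threshold
            if rr_history and peaks:
                rr_mean = np.mean(rr_history[-8:])
                if c - peaks[-1] > 1.66 * rr_mean and missed:
                    best = max(missed, key=lambda m: mwi[m])
                    if mwi[best] > 0.5 * thr and best - peaks[-1] >= refractory:
                        if peaks:
                            rr_history.append(best - peaks[-1])
                        peaks.append(best)
            if peaks:
                rr_history.append(c - peaks[-1])
            peaks.append(c)
            last_accepted = c
            missed = []
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            missed.append(c)
            npki = 0.125 * mwi[c] + 0.875 * npki

    # flat or noise-only records: no candidate should clear a floor threshold
    if not peaks or np.max(mwi) <= 1e-12:
        return RPeakList(np.empty(0, dtype=np.int64), fs)

    refine = int(round(0.050 * fs))
    refined = []
    for p in sorted(set(peaks)):
        lo, hi = max(0, p - refine), min(record.n_samples, p + refine + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined_arr = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce refractory after refinement
    keep = [int(refined_arr[0])]
    for p in refined_arr[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    return RPeakList(np.asarray(keep, dtype=np.int64), fs)


# ---------------------------------------------------------------------------
# Beat segmentation and resampling
# ---------------------------------------------------------------------------

def segment_beats(
    record: EcgRecord,
    peaks: RPeakList,
    pre: int = PRE_R_SAMPLES,
    post: int = POST_R_SAMPLES,
) -> list[BeatTensor]:
    """Cut one fixed window per R peak across all leads.

    Each beat spans ``[r - pre, r + post]`` inclusive (651 samples with the
    defaults at 1000 Hz). Peaks whose window would cross a record edge are
    dropped rather than padded.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be non-negative")
    beats: list[BeatTensor] = []
    for r in peaks.indices:
        r = int(r)
        if r - pre < 0 or r + post >= record.n_samples:
            continue
        window = record.signal[:, r - pre : r + post + 1].copy()
        beats.append(
            BeatTensor(
                values=window,
                r_index_in_record=r,
                label=record.label,
                patient_id=record.patient_id,
                record_id=record.record_id,
                lead_names=list(record.lead_names),
            )
        )
    return beats


def resample_record(record: EcgRecord, target_rate: float) -> EcgRecord:
    """Band-limited polyphase resampling of every lead."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == record.sampling_rate:
        return record.with_signal(record.signal.copy())
    frac = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    out = scipy.signal.resample_poly(record.signal, frac.numerator,
                                     frac.denominator, axis=1)
    new = record.with_signal(out)
    new.sampling_rate = target_rate
    if "true_r_peaks" in new.meta:
        ratio = target_rate / record.sampling_rate
        new.meta["true_r_peaks"] = np.round(
            np.asarray(record.meta["true_r_peaks"]) * ratio
        ).astype(np.int64)
    return new


def match_peaks(
    detected: RPeakList, truth: np.ndarray, tolerance_s: float = 0.050
) -> float:
    """Fraction of ground-truth peaks matched by a detection within
    ``tolerance_s`` (each detected peak may match at most one truth peak)."""
    truth = np.asarray(truth)
    if truth.size == 0:
        return 1.0
    tol = tolerance_s * detected.sampling_rate
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for tr in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected.indices - tr).astype(float)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            hits += 1
    return hits / truth.size


def preprocess_record(
    record: EcgRecord,
    denoise_config: WaveletDenoiseConfig | None = None,
    detection_lead: str = "II",
) -> tuple[EcgRecord, RPeakList, list[BeatTensor]]:
    """Full preprocessing chain: baseline removal, denoising, R-peak
    detection on lead II, and 250/400-sample beat segmentation.

    Records not already at 1000 Hz are resampled first.
    """
    if record.sampling_rate != 1000.0:
        record = resample_record(record, 1000.0)
    clean = denoise_wavelet(remove_baseline(record), denoise_config)
    peaks = detect_r_peaks(clean, detection_lead)
    beats = segment_beats(clean, peaks)
    assert all(b.values.shape[1] == BEAT_LENGTH for b in beats)
    return clean, peaks, beats
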