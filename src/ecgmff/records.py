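"""Core in-memory containers for multi-lead ECG records and segmented heartbeats.

Amplitudes are millivolts throughout; sample indices are 0-based positions at
the record's sampling rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical 12-lead order used everywhere in the package.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Samples kept before / after the R peak when segmenting at 1000 Hz.
PRE_R_SAMPLES = 250
POST_R_SAMPLES = 400
BEAT_LENGTH = PRE_R_SAMPLES + 1 + POST_R_SAMPLES  # 651


@dataclass
class EcgRecord:
    """A multi-lead ECG record.

    Parameters
    ----------
    signal : ndarray, shape (n_leads, n_samples)
        Lead voltages in mV.
    sampling_rate : float
        Samples per second (Hz).
    lead_names : sequence of str
        One name per signal row; must contain ``"II"``.
    patient_id, record_id : str
        Identifiers; patient_id groups records for inter-patient splitting.
    label : str
        Diagnostic class ("HC" or an MI subtype).
    meta : dict
        Free-form metadata. Synthetic records store ground-truth R-peak
        sample indices under ``"true_r_peaks"``.
    """

    signal: np.ndarray
    sampling_rate: float
    lead_names: Sequence[str]
    patient_id: str = "unknown"
    record_id: str = "unknown"
    label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (leads x samples)")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Return the signal row for a named lead."""
        try:
            idx = list(self.lead_names).index(name)
        except ValueError:
            raise KeyError(f"lead {name!r} not present in record") from None
        return self.signal[idx]

    def with_signal(self, signal: np.ndarray) -> "EcgRecord":
        """Copy of this record with the signal matrix replaced."""
        return replace(self, signal=signal, meta=dict(self.meta))


@dataclass
class RPeakList:
    """Sorted R-peak sample positions with their sampling rate."""

    indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class BeatTensor:
    """One segmented heartbeat: ``n_leads x 651`` samples around an R peak."""

    values: np.ndarray
    r_index_in_record: int
    label: str
    patient_id: str
    record_id: str = "unknown"
    lead_names: Sequence[str] = STANDARD_LEADS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("beat values must be 2-D (leads x samples)")

    def lead(self, name: str) -> np.ndarray:
        try:
            idx = list(self.lead_names).index(name)
        except ValueError:
            raise KeyError(f"lead {name!r} not present in beat") from None
        return self.values[idx]
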