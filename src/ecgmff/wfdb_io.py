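"""Minimal WFDB-format record I/O and plain-text label manifests.

Supports the subset of the WFDB specification the pipeline needs: one
``.hea`` text header per record plus an interleaved 16-bit little-endian
``.dat`` signal file (format 16), with per-signal gain/baseline/units.
Reading canonicalizes to the 12 standard leads in the order
I, II, III, aVR, aVL, aVF, V1-V6 (matching by name, not file position,
since real headers vary) and drops Frank leads (vx, vy, vz) when present.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .records import STANDARD_LEADS, EcgRecord

_CANONICAL = {name.lower(): name for name in STANDARD_LEADS}
_FRANK = {"vx", "vy", "vz"}
_DEFAULT_GAIN = 1000.0  # ADC units per mV when writing


def write_wfdb_record(record: EcgRecord, directory: str | Path) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16).

    Signals are scaled by 1000 ADC units/mV and clipped to the int16 range.
    Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    dat_name = f"{name}.dat"
    n_sig, n_samp = record.signal.shape
    lines = [f"{name} {n_sig} {record.sampling_rate:g} {n_samp}"]
    for lead in record.lead_names:
        lines.append(
            f"{dat_name} 16 {_DEFAULT_GAIN:g}(0)/mV 16 0 0 0 0 {lead}"
        )
    lines.append(f"# patient_id: {record.patient_id}")
    lines.append(f"# label: {record.label}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    adc = np.clip(
        np.round(record.signal * _DEFAULT_GAIN), -32768, 32767
    ).astype("<i2")
    adc.T.reshape(-1).tofile(directory / dat_name)  # sample-interleaved
    return directory / f"{name}.hea"


def read_wfdb_record(path: str | Path) -> EcgRecord:
    """Read a WFDB record (header path or record stem).

    Returns the 12 standard leads in canonical order with units converted
    to mV. Raises if lead II is absent or the signal format is not 16.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FileNotFoundError(f"missing header {path}")
    lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip()
    ]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#")]
    head = body[0].split()
    name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    leads, gains, baselines, dat_files = [], [], [], []
    for ln in body[1 : 1 + n_sig]:
        parts = ln.split()
        dat_files.append(parts[0])
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r}")
        gain_spec = parts[2]
        gain, baseline = _parse_gain(gain_spec)
        gains.append(gain)
        baselines.append(baseline)
        leads.append(parts[-1])
    if len(set(dat_files)) != 1:
        raise ValueError("multi-file records are not supported")
    raw = np.fromfile(path.parent / dat_files[0], dtype="<i2")
    raw = raw.reshape(n_samp, n_sig).T.astype(np.float64)
    signal_mv = (raw - np.array(baselines)[:, None]) / np.array(gains)[:, None]

    by_name: dict[str, np.ndarray] = {}
    for lead, row in zip(leads, signal_mv):
        low = lead.lower()
        if low in _FRANK:
            continue
        if low in _CANONICAL:
            by_name[_CANONICAL[low]] = row
    if "II" not in by_name:
        raise ValueError(f"record {name!r} lacks lead II")
    ordered = [n for n in STANDARD_LEADS if n in by_name]
    meta: dict = {}
    patient_id, label = "unknown", "unknown"
    for c in comments:
        if c.startswith("patient_id:"):
            patient_id = c.split(":", 1)[1].strip()
        elif c.startswith("label:"):
            label = c.split(":", 1)[1].strip()
    return EcgRecord(
        signal=np.stack([by_name[n] for n in ordered]),
        sampling_rate=fs,
        lead_names=ordered,
        patient_id=patient_id,
        record_id=name,
        label=label,
        meta=meta,
    )


def _parse_gain(spec: str) -> tuple[float, float]:
    """Parse a WFDB gain field like ``1000(0)/mV`` -> (gain, baseline)."""
    if "/" in spec:
        spec = spec.split("/", 1)[0]
    baseline = 0.0
    if "(" in spec:
        spec, rest = spec.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(spec) if spec else 200.0  # WFDB default gain
    return gain, baseline


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(records: list[EcgRecord], path: str | Path) -> Path:
    """Plain-text label manifest: record id, patient id, class per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "patient_id", "label"])
        for rec in records:
            writer.writerow([rec.record_id, rec.patient_id, rec.label])
    return path


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    with Path(path).open() as fh:
        return list(csv.DictReader(fh))


def write_dataset(records: list[EcgRecord], directory: str | Path) -> Path:
    """Write every record in WFDB format plus a ``manifest.csv``."""
    directory = Path(directory)
    for rec in records:
        write_wfdb_record(rec, directory)
    return write_manifest(records, directory / "manifest.csv")


def read_dataset(directory: str | Path) -> list[EcgRecord]:
    """Read all records listed in ``manifest.csv`` under a directory."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {directory}")
    records = []
    for row in read_manifest(manifest):
        rec = read_wfdb_record(directory / row["record_id"])
        rec.patient_id = row["patient_id"]
        rec.label = row["label"]
        records.append(rec)
    return records
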