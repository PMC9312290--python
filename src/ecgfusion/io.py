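"""Readers/writers for ECG records and label sidecars.

Two on-disk layouts are supported, both plain text:

* a WFDB-style pair ``<id>.hea`` (header: record id, lead count, sampling
  rate, sample count, then one lead name per line) + ``<id>.sig``
  (whitespace-separated samples x leads matrix, millivolts);
* a bare CSV ``<id>.csv`` with a lead-name header row and samples x leads.

Labels travel in a sidecar CSV with columns ``record_id,labels`` where
``labels`` is a comma-joined class list.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ecgfusion.synthetic import ECGRecord, LEAD_NAMES


def write_wfdb_style(record: ECGRecord, directory: str) -> str:
    """Write ``<record_id>.hea`` + ``<record_id>.sig`` under *directory*."""
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, record.record_id)
    n_leads, n_samples = record.signal.shape
    with open(base + ".hea", "w") as fh:
        fh.write(f"{record.record_id} {n_leads} {record.fs:g} {n_samples}\n")
        for name in record.lead_names:
            fh.write(name + "\n")
    np.savetxt(base + ".sig", record.signal.T, fmt="%.6f")
    return base


def read_wfdb_style(base: str, labels=frozenset({"Normal"})) -> ECGRecord:
    """Read a record written by :func:`write_wfdb_style`; *base* has no extension."""
    with open(base + ".hea") as fh:
        rid, n_leads, fs, n_samples = fh.readline().split()
        lead_names = tuple(fh.readline().strip() for _ in range(int(n_leads)))
    sig = np.loadtxt(base + ".sig", ndmin=2).T
    if sig.shape != (int(n_leads), int(n_samples)):
        raise ValueError(f"signal shape {sig.shape} disagrees with header")
    return ECGRecord(signal=sig, fs=float(fs), labels=frozenset(labels),
                     beat_times=np.array([], dtype=int), record_id=rid,
                     lead_names=lead_names)


def write_csv(record: ECGRecord, directory: str) -> str:
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, record.record_id + ".csv")
    pd.DataFrame(record.signal.T, columns=list(record.lead_names)).to_csv(
        path, index=False, float_format="%.6f")
    return path


def read_csv(path: str, fs: float, labels=frozenset({"Normal"})) -> ECGRecord:
    df = pd.read_csv(path)
    rid = os.path.splitext(os.path.basename(path))[0]
    return ECGRecord(signal=df.to_numpy().T, fs=fs, labels=frozenset(labels),
                     beat_times=np.array([], dtype=int), record_id=rid,
                     lead_names=tuple(df.columns))


def write_labels(records, path: str) -> None:
    rows = [{"record_id": r.record_id,
             "labels": ",".join(sorted(r.labels))} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str) -> dict:
    df = pd.read_csv(path, dtype=str)
    return {row.record_id: frozenset(row.labels.split(","))
            for row in df.itertuples()}


def write_fiducials(fiducials, path: str) -> None:
    """Per-record fiducial table: beat_index, p, q, r, s, t sample indices."""
    n = len(fiducials.r_idx)
    pd.DataFrame({
        "beat_index": np.arange(n),
        "p": fiducials.p_idx, "q": fiducials.q_idx, "r": fiducials.r_idx,
        "s": fiducials.s_idx, "t": fiducials.t_idx,
    }).to_csv(path, index=False)
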