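"""Foetal heart rate (FHR) record container and plain-text readers/writers.

An FHR record is a beats-per-minute time series sampled at 4 Hz (the CTG
monitor output rate), at most ~90 minutes long, with possible signal
dropouts. Dropouts appear in source files as zero-valued runs or empty
fields; internally they are carried as NaN so that every downstream stage
can distinguish "missing" from a genuine sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["FHRRecord", "read_record", "write_record", "ValidationError", "FormatError"]


class ValidationError(ValueError):
    """Input violates a documented precondition (empty signal, bad rate, ...)."""


class FormatError(ValueError):
    """File cannot be parsed as an FHR record."""


#: label values a record may carry
LABELS = ("control", "case", "unknown")


@dataclass
class FHRRecord:
    """One FHR time series plus sampling metadata and (optional) class label.

    Parameters
    ----------
    record_id:
        Identifier, conventionally the source file stem or cohort index.
    signal:
        FHR samples in beats per minute. Missing samples are NaN.
    fs:
        Sampling rate in Hz (4 Hz for CTG monitors).
    label:
        ``"control"`` (normal vaginal delivery), ``"case"`` (caesarean
        section) or ``"unknown"``.
    """

    record_id: str
    signal: np.ndarray
    fs: float = 4.0
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValidationError("signal must be a non-empty 1-D array")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return int(self.signal.size)

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing (NaN) samples."""
        return ~np.isfinite(self.signal)

    def copy_with(self, **changes) -> "FHRRecord":
        if "signal" in changes:
            changes["signal"] = np.array(changes["signal"], dtype=float)
        else:
            changes["signal"] = self.signal.copy()
        return replace(self, **changes)


def _flag_missing(samples: np.ndarray) -> np.ndarray:
    """Zero-valued or non-finite samples become NaN (CTU-UHB dropout convention)."""
    out = np.asarray(samples, dtype=float).copy()
    out[(out == 0.0) | ~np.isfinite(out)] = np.nan
    return out


def read_record(path, format: str = "csv", fs: float = 4.0, label: str = "unknown") -> FHRRecord:
    """Read one FHR record from disk.

    ``csv`` expects a header ``sample_index,fhr_bpm`` with missing samples as
    empty fields or 0. ``wfdb_style`` expects ``<stem>.hea`` containing
    ``<name> 1 <fs> <n_samples>`` on its first line and samples one per line
    in ``<stem>.dat.txt`` (or the path itself if it is the sample file).
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return _read_csv(path, fs=fs, label=label)
    if format == "wfdb_style":
        return _read_wfdb_style(path, label=label)  # path may be the record stem
    raise FormatError(f"unknown format {format!r}")


def _read_csv(path: Path, fs: float, label: str) -> FHRRecord:
    samples: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty file")
        if [h.strip().lower() for h in header[:2]] != ["sample_index", "fhr_bpm"]:
            raise FormatError(f"{path}: expected header 'sample_index,fhr_bpm'")
        for row in reader:
            if not row:
                continue
            cell = row[1].strip() if len(row) > 1 else ""
            if cell == "" or cell.lower() == "nan":
                samples.append(np.nan)
            else:
                try:
                    samples.append(float(cell))
                except ValueError as exc:
                    raise FormatError(f"{path}: bad sample {cell!r}") from exc
    if not samples:
        raise ValidationError(f"{path}: no samples")
    return FHRRecord(record_id=path.stem, signal=_flag_missing(np.array(samples)), fs=fs, label=label)


def _read_wfdb_style(path: Path, label: str) -> FHRRecord:
    """Minimal text reader for a header + samples record pair.

    This is a simplified plain-text layout modelled on physiological signal
    archives (record name, channel count, rate and length in the header),
    not a binary-format parser.
    """
    stem = path.with_suffix("") if path.suffix else path
    hea = stem.with_suffix(".hea")
    dat = stem.with_suffix(".dat.txt")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    fields = hea.read_text().split()
    if len(fields) < 4:
        raise FormatError(f"{hea}: header needs 'name n_sig fs n_samples'")
    name, _, fs_s, n_s = fields[:4]
    try:
        fs, n = float(fs_s), int(n_s)
    except ValueError as exc:
        raise FormatError(f"{hea}: bad fs/n fields") from exc
    if not dat.exists():
        raise FormatError(f"missing sample file {dat}")
    samples = np.array(
        [float(tok) if tok.lower() != "nan" else np.nan for tok in dat.read_text().split()]
    )
    if samples.size != n:
        raise FormatError(f"{dat}: expected {n} samples, found {samples.size}")
    if samples.size == 0:
        raise ValidationError(f"{dat}: no samples")
    return FHRRecord(record_id=name, signal=_flag_missing(samples), fs=fs, label=label)


def write_record(record: FHRRecord, path, format: str = "csv") -> Path:
    """Write a record; ``read_record`` round-trips samples bit-exactly
    (missing samples are written as empty fields)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sample_index", "fhr_bpm"])
            for i, x in enumerate(record.signal):
                writer.writerow([i, "" if not np.isfinite(x) else repr(float(x))])
        return path
    if format == "wfdb_style":
        stem = path.with_suffix("") if path.suffix else path
        stem.with_suffix(".hea").write_text(
            f"{record.record_id} 1 {record.fs:g} {record.n_samples}\n"
        )
        lines = ["nan" if not np.isfinite(x) else repr(float(x)) for x in record.signal]
        stem.with_suffix(".dat.txt").write_text("\n".join(lines) + "\n")
        return stem.with_suffix(".hea")
    raise FormatError(f"unknown format {format!r}")
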