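"""Readers and writers.

Recordings travel in a minimal CSV dialect: a header line
``fs=<Hz>,onset=<index|none>`` followed by one sample (mV) per line.  WFDB
records (header + signal + annotation files, as distributed by PhysioNet)
are read through the optional ``wfdb`` package when it is installed; the
rest of the pipeline never depends on it.  Beats, predictions and reports
use CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classify import CVReport, Prediction
from .errors import FormatError, ValidationError
from .preprocess import Beat, ECGRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_beats",
    "write_beats",
    "write_predictions",
    "write_cv_report",
    "write_manifest",
]


def _read_csv_recording(path: Path, subject_id: str, group: str) -> ECGRecording:
    with open(path) as fh:
        header = fh.readline().strip()
        parts = dict(
            kv.split("=", 1) for kv in header.split(",") if "=" in kv
        )
        if "fs" not in parts or "onset" not in parts:
            raise FormatError(f"{path}: line 1: expected 'fs=<Hz>,onset=<index|none>', got {header!r}")
        try:
            fs = float(parts["fs"])
        except ValueError as err:
            raise FormatError(f"{path}: line 1: bad sampling frequency {parts['fs']!r}") from err
        onset: int | None
        if parts["onset"].lower() == "none":
            onset = None
        else:
            try:
                onset = int(parts["onset"])
            except ValueError as err:
                raise FormatError(f"{path}: line 1: bad onset index {parts['onset']!r}") from err
        samples = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                samples.append(float(line))
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: not a number: {line!r}") from err
    if group == "scd" and onset is None:
        raise ValidationError(f"{path}: scd recording requires an onset annotation")
    return ECGRecording(
        samples=np.asarray(samples),
        fs=fs,
        subject_id=subject_id or path.stem,
        group=group,
        onset_index=onset,
    )


def _read_wfdb_recording(
    path: Path,
    subject_id: str,
    group: str,
    onset_seconds: float | None,
) -> ECGRecording:
    try:
        import wfdb
    except ImportError as err:  # pragma: no cover - wfdb is an optional extra
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install scdsparse[wfdb])"
        ) from err
    record = wfdb.rdrecord(str(path))
    fs = float(record.fs)
    samples = np.asarray(record.p_signal[:, 0], dtype=float)
    onset = None
    if onset_seconds is not None:
        onset = int(round(onset_seconds * fs))
    else:
        try:
            ann = wfdb.rdann(str(path), "atr")
            onset_marks = [
                s for s, sym in zip(ann.sample, ann.symbol) if sym in ("[", "!")
            ]
            if onset_marks:
                onset = int(onset_marks[0])
        except FileNotFoundError:
            pass
    if group == "scd" and onset is None:
        raise ValidationError(
            f"{path}: no onset annotation found; pass onset_seconds explicitly"
        )
    return ECGRecording(
        samples=samples,
        fs=fs,
        subject_id=subject_id or path.stem,
        group=group,
        onset_index=onset,
    )


def read_recording(
    path: str | Path,
    format: str = "csv",
    group: str = "normal",
    subject_id: str = "",
    onset_seconds: float | None = None,
) -> ECGRecording:
    """Read a single-lead recording from CSV or WFDB."""
    path = Path(path)
    if format == "csv":
        return _read_csv_recording(path, subject_id, group)
    if format == "wfdb":
        return _read_wfdb_recording(path, subject_id, group, onset_seconds)
    raise FormatError(f"unknown recording format {format!r}")


def write_recording(rec: ECGRecording, path: str | Path) -> None:
    """Write the documented CSV dialect; round-trips at double precision."""
    path = Path(path)
    onset = "none" if rec.onset_index is None else str(rec.onset_index)
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:g},onset={onset}\n")
        for v in rec.samples:
            fh.write(f"{float(v)!r}\n")


def write_beats(beats: list[Beat], path: str | Path) -> None:
    """Beat table: subject_id, class_label, source R-R length, then the n
    normalized sample values."""
    with open(Path(path), "w") as fh:
        n = beats[0].values.size if beats else 0
        fh.write("subject_id,class_label,source_rr_samples," +
                 ",".join(f"v{i}" for i in range(n)) + "\n")
        for b in beats:
            fh.write(
                f"{b.subject_id},{b.class_label},{b.source_rr_samples},"
                + ",".join(repr(float(v)) for v in b.values) + "\n"
            )


def read_beats(path: str | Path) -> list[Beat]:
    path = Path(path)
    beats: list[Beat] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["subject_id", "class_label", "source_rr_samples"]:
            raise FormatError(f"{path}: line 1: not a beat table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise FormatError(f"{path}: line {lineno}: expected {len(header)} fields")
            beats.append(
                Beat(
                    values=np.asarray([float(v) for v in parts[3:]]),
                    source_rr_samples=int(parts[2]),
                    class_label=parts[1],
                    subject_id=parts[0],
                )
            )
    return beats


def write_predictions(preds: list[Prediction], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        labels = list(preds[0].scores) if preds else []
        fh.write("subject_id,true_label,predicted_label," +
                 ",".join(f"score_{l}" for l in labels) + "\n")
        for p in preds:
            fh.write(
                f"{p.subject_id},{p.true_label},{p.predicted_label},"
                + ",".join(repr(p.scores[l]) for l in labels) + "\n"
            )


def write_cv_report(report: CVReport, path: str | Path) -> None:
    payload = {
        "scheme": report.scheme,
        "folds": report.folds,
        "repeats": report.repeats,
        "seed": report.seed,
        "accuracy_mean": report.mean,
        "accuracy_std": report.std,
        "accuracies": report.accuracies,
        "per_class": {
            label: {"mean": mean, "std": std}
            for label, (mean, std) in report.class_summary().items()
        },
        "fold_assignments": report.fold_assignments,
    }
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_manifest(path: str | Path, **fields) -> None:
    """Run manifest: the configuration and seeds needed to reproduce an
    output artifact bit-for-bit."""
    from . import __version__

    payload = {"scdsparse_version": __version__, **fields}
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
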