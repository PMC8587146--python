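"""Plain-text persistence for recordings, feature matrices and results.

A subject directory holds one CSV-style file per channel (two comment
header lines carrying the channel name and rate, then one sample per row),
a ``labels.csv`` with ``start_s,end_s,activity`` rows and a ``meta.json``
with the subject id.  Floats are serialized with 17 significant digits, so
every round-trip is lossless for float64.

Feature matrices are single CSV files: ``window_id`` and ``activity`` first
(plus ``subject_id`` when present), then feature columns named by the
grammar ``{signal}.{time|freq}.{feature}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNEL_NAMES, CHANNEL_RATES, ChannelSeries, SubjectRecord, validate_labels

_FLOAT_FMT = "%.17g"

#: Feature-name vocabulary per domain (the frequency set is the union over
#: accelerometer and bio-signal variants).
TIME_FEATURES = ("mean", "min", "max", "median", "std", "zero_crossings", "mean_crossings")
FREQ_FEATURES = (
    "mean",
    "min",
    "std",
    "median",
    "mean_crossings",
    "dc_component",
    "max",
    "second_max",
    "dominant_frequency",
)

_META_COLUMNS = ("window_id", "subject_id", "activity")


def parse_feature_column(name: str) -> tuple[str, str, str]:
    """Parse ``{signal}.{time|freq}.{feature}`` into its three parts.

    The domain token ``freq`` is expanded to ``frequency``.  Raises
    ``ValueError`` for anything outside the grammar.
    """
    parts = name.split(".")
    if len(parts) != 3:
        raise ValueError(f"feature column {name!r} does not match signal.domain.feature")
    signal, domain, feature = parts
    if signal not in CHANNEL_NAMES:
        raise ValueError(f"feature column {name!r}: unknown signal {signal!r}")
    if domain not in ("time", "freq"):
        raise ValueError(f"feature column {name!r}: unknown domain {domain!r}")
    vocab = TIME_FEATURES if domain == "time" else FREQ_FEATURES
    if feature not in vocab:
        raise ValueError(f"feature column {name!r}: unknown feature {feature!r}")
    return signal, "time" if domain == "time" else "frequency", feature


def write_subject(record: SubjectRecord, path: str | Path) -> None:
    """Write a subject recording as a directory of plain-text files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in record.channels.items():
        lines = [f"# name: {name}", f"# rate_hz: {_FLOAT_FMT % ch.rate_hz}"]
        lines.extend(_FLOAT_FMT % v for v in ch.samples)
        (path / f"{name}.csv").write_text("\n".join(lines) + "\n")
    label_lines = ["start_s,end_s,activity"]
    label_lines.extend(
        f"{_FLOAT_FMT % s},{_FLOAT_FMT % e},{a}" for s, e, a in record.labels
    )
    (path / "labels.csv").write_text("\n".join(label_lines) + "\n")
    (path / "meta.json").write_text(
        json.dumps({"subject_id": record.subject_id}, sort_keys=True) + "\n"
    )


def _read_channel(path: Path, name: str) -> ChannelSeries:
    lines = path.read_text().splitlines()
    if len(lines) < 2 or not lines[0].startswith("# name:") or not lines[1].startswith("# rate_hz:"):
        raise ValueError(f"channel file {path} is missing its header")
    header_name = lines[0].split(":", 1)[1].strip()
    if header_name != name:
        raise ValueError(f"channel file {path}: header names {header_name!r}, expected {name!r}")
    rate = float(lines[1].split(":", 1)[1])
    if rate != CHANNEL_RATES[name]:
        raise ValueError(f"channel {name}: rate {rate} Hz, expected {CHANNEL_RATES[name]} Hz")
    samples = np.array([float(v) for v in lines[2:] if v], dtype=np.float64)
    return ChannelSeries(name, rate, samples)


def read_subject(path: str | Path) -> SubjectRecord:
    """Read a subject directory written by :func:`write_subject`.

    Raises ``ValueError`` naming any missing channel file and pointing at
    the offending row for malformed or overlapping label intervals.
    """
    path = Path(path)
    channels: dict[str, ChannelSeries] = {}
    for name in sorted(CHANNEL_NAMES):
        f = path / f"{name}.csv"
        if not f.exists():
            raise ValueError(f"missing channel file for {name}: {f}")
        channels[name] = _read_channel(f, name)

    labels_file = path / "labels.csv"
    if not labels_file.exists():
        raise ValueError(f"missing labels file: {labels_file}")
    labels: list[tuple[float, float, str]] = []
    lines = labels_file.read_text().splitlines()
    for i, line in enumerate(lines[1:]):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"labels row {i}: expected 3 fields, got {len(parts)}: {line!r}")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"labels row {i}: non-numeric interval: {line!r}") from exc
        labels.append((start, end, parts[2]))
    validate_labels(labels)

    meta_file = path / "meta.json"
    subject_id = path.name
    if meta_file.exists():
        subject_id = json.loads(meta_file.read_text()).get("subject_id", subject_id)
    return SubjectRecord(subject_id=subject_id, channels=channels, labels=labels)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix CSV (lossless float serialization)."""
    for col in matrix.columns:
        if col not in _META_COLUMNS:
            parse_feature_column(col)
    matrix.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix CSV, validating the column-name grammar."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "window_id" not in df.columns or "activity" not in df.columns:
        raise ValueError("feature matrix must have window_id and activity columns")
    for col in df.columns:
        if col not in _META_COLUMNS:
            parse_feature_column(col)
            df[col] = df[col].astype(np.float64)  # counts serialize as ints
    return df


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """The feature (non-metadata) columns of a matrix, in order."""
    return [c for c in matrix.columns if c not in _META_COLUMNS]


def write_results(results: list[dict], path: str | Path) -> None:
    """Serialize evaluation results as deterministic, sorted-key JSON."""
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_confusion(confusion: np.ndarray, classes: list[str], path: str | Path) -> None:
    """Write a labeled confusion matrix (true labels as rows) to CSV."""
    pd.DataFrame(confusion, index=classes, columns=classes).to_csv(path, index_label="true")
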