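"""Readers and writers for the pipeline's plain-text formats.

All numeric CSV output uses 12 significant digits, '.' decimal and LF
line endings so reruns are byte-stable. Sessions are stored as
two-column CSV (``time_s,amplitude``); the cohort manifest CSV maps
session files to labels. EDF export is not available in this build
(no EDF library in the environment); requesting it raises
UnsupportedFormatError.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UnsupportedFormatError
from .pain import nrs_to_quartile
from .spectral import FEATURE_COLUMNS, FeatureDataset
from .synthetic import CohortManifest, EEGSession

__all__ = [
    "write_session",
    "read_session",
    "write_cohort",
    "read_manifest",
    "write_features",
    "read_features",
    "write_stats",
    "write_report_json",
    "write_session_table",
    "write_windows_csv",
]

_FLOAT_FMT = "%.12g"


def _check_format(fmt: str) -> None:
    if fmt == "edf":
        raise UnsupportedFormatError(
            "EDF support is not available in this build (no EDF library installed); "
            "use format='csv'"
        )
    if fmt != "csv":
        raise UnsupportedFormatError(f"unknown session format {fmt!r}; use 'csv'")


def write_session(session: EEGSession, path: str | Path, fmt: str = "csv") -> Path:
    """Write one session as `time_s,amplitude` CSV (12 significant digits)."""
    _check_format(fmt)
    path = Path(path)
    time_s = np.arange(len(session.samples)) / session.sample_rate_hz
    frame = pd.DataFrame({"time_s": time_s, "amplitude": session.samples})
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_session(
    path: str | Path,
    fmt: str = "csv",
    subject_id: str = "S00",
    phase: str = "pre",
    nrs: int = 0,
    sample_rate_hz: float | None = None,
) -> EEGSession:
    """Read a session CSV back; rate inferred from the time column unless given."""
    _check_format(fmt)
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"cannot parse session file {path}: {exc}") from exc
    for column in ("time_s", "amplitude"):
        if column not in frame.columns:
            raise ParseError(f"{path}: missing column {column!r}")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: a session needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ParseError(f"{path}: time column not strictly increasing at row {bad + 1}")
    if sample_rate_hz is None:
        sample_rate_hz = (len(t) - 1) / (t[-1] - t[0])
        sample_rate_hz = float(np.round(sample_rate_hz, 6))
    return EEGSession(
        subject_id=subject_id,
        phase=phase,
        nrs=nrs,
        sample_rate_hz=sample_rate_hz,
        samples=frame["amplitude"].to_numpy(dtype=float),
    )


def write_cohort(manifest: CohortManifest, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write every session plus a manifest CSV; returns the manifest path.

    Manifest columns: subject_id,phase,nrs,quartile,file.
    """
    _check_format(fmt)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for session in manifest.sessions:
        name = f"{session.subject_id}_{session.phase}.csv"
        write_session(session, out_dir / name, fmt)
        rows.append(
            {
                "subject_id": session.subject_id,
                "phase": session.phase,
                "nrs": session.nrs,
                "quartile": session.quartile.label,
                "file": name,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False, lineterminator="\n")
    return manifest_path


def read_manifest(manifest_path: str | Path) -> list[EEGSession]:
    """Load all sessions listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    try:
        frame = pd.read_csv(manifest_path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse manifest {manifest_path}: {exc}") from exc
    required = {"subject_id", "phase", "nrs", "quartile", "file"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{manifest_path}: missing columns {sorted(missing)}")
    sessions = []
    for record in frame.to_dict("records"):
        nrs = int(record["nrs"])
        if nrs_to_quartile(nrs).label != str(record["quartile"]):
            raise ParseError(
                f"{manifest_path}: NRS {nrs} inconsistent with quartile "
                f"{record['quartile']!r} for {record['subject_id']}/{record['phase']}"
            )
        sessions.append(
            read_session(
                manifest_path.parent / str(record["file"]),
                subject_id=str(record["subject_id"]),
                phase=str(record["phase"]),
                nrs=nrs,
            )
        )
    return sessions


def write_features(dataset: FeatureDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_features(path: str | Path) -> FeatureDataset:
    try:
        frame = pd.read_csv(Path(path))
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse feature table {path}: {exc}") from exc
    return FeatureDataset(frame=frame)


def write_stats(stats_frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stats_frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def write_report_json(report_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_dict, sort_keys=True, indent=2) + "\n")
    return path


def write_session_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def write_windows_csv(segment_sets, path: str | Path) -> Path:
    """Archive preprocessed windows as long-format CSV (opt-in; large)."""
    path = Path(path)
    chunks = []
    for segments in segment_sets:
        n_windows, n_samples = segments.windows.shape
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(segments.subject_id, n_windows * n_samples),
                    "phase": np.repeat(segments.phase, n_windows * n_samples),
                    "window_index": np.repeat(np.arange(n_windows), n_samples),
                    "sample_index": np.tile(np.arange(n_samples), n_windows),
                    "amplitude": segments.windows.ravel(),
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path
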