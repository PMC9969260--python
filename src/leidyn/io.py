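"""Plain-text readers and writers: BOLD matrices, events TSV, manifests,
metric tables. Everything is delimited text so intermediate artifacts diff
cleanly; writers round-trip at 1e-12 or better.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTimeline
from .signal import SubjectRecording

__all__ = [
    "read_bold_matrix",
    "write_bold_matrix",
    "read_events_tsv",
    "write_events_tsv",
    "read_manifest",
    "write_manifest",
    "read_table",
    "write_table",
    "write_cohort",
    "load_cohort",
]

MANIFEST_COLUMNS = ["subject_id", "group", "bold_path", "events_path"]


def read_bold_matrix(path, transpose: bool = False) -> np.ndarray:
    """Read a delimited text matrix (canonical orientation rows = regions)."""
    try:
        mat = np.loadtxt(path, ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err
    return mat.T if transpose else mat


def write_bold_matrix(path, bold: np.ndarray) -> None:
    np.savetxt(path, np.asarray(bold), fmt="%.17g", delimiter="\t")


def read_events_tsv(path, scan_duration: float | None = None) -> EventTimeline:
    """Read a BIDS-style events TSV (columns: onset, duration; seconds)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"events file {path} lacks the {col!r} column")
    if df[["onset", "duration"]].isna().any().any():
        bad = int(df[["onset", "duration"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"events file {path}: missing value near line {bad}")
    episodes = tuple(
        (float(r.onset), float(r.onset) + float(r.duration)) for r in df.itertuples()
    )
    if scan_duration is not None:
        for a, b in episodes:
            if b > scan_duration + 1e-9:
                raise ValueError(
                    f"events file {path}: episode ({a}, {b}) ends after the "
                    f"{scan_duration:.1f} s scan"
                )
    return EventTimeline(episodes)


def write_events_tsv(path, timeline: EventTimeline) -> None:
    df = pd.DataFrame(
        {
            "onset": [a for a, _ in timeline.episodes],
            "duration": [b - a for a, b in timeline.episodes],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest TSV; relative paths resolve against its folder."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    base = Path(path).parent
    for col in ("bold_path", "events_path"):
        df[col] = [str(p) if os.path.isabs(p) else str(base / p) for p in df[col]]
        for sid, p in zip(df["subject_id"], df[col]):
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest entry {sid}: missing file {p}")
    return df


def write_manifest(path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_cohort(out_dir, recordings, timelines, truth=None) -> Path:
    """Write a cohort to disk: matrices, events TSVs, manifest, ground truth.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, tl in zip(recordings, timelines):
        bpath = out / f"{rec.subject_id}_bold.tsv"
        epath = out / f"{rec.subject_id}_events.tsv"
        write_bold_matrix(bpath, rec.bold)
        write_events_tsv(epath, tl)
        rows.append(
            dict(
                subject_id=rec.subject_id,
                group=rec.group,
                bold_path=bpath.name,
                events_path=epath.name,
            )
        )
    manifest = out / "manifest.tsv"
    write_manifest(manifest, rows)
    if truth is not None:
        labels = np.column_stack(truth.state_labels)
        np.savetxt(out / "ground_truth_states.tsv", labels, fmt="%d", delimiter="\t")
    return manifest


def load_cohort(manifest_path, tr: float, transpose: bool = False):
    """Load a cohort from a manifest into recordings and timelines."""
    mf = read_manifest(manifest_path)
    recordings, timelines = [], []
    for row in mf.itertuples():
        bold = read_bold_matrix(row.bold_path, transpose=transpose)
        scan_dur = bold.shape[1] * tr
        recordings.append(
            SubjectRecording(
                subject_id=row.subject_id, group=row.group, bold=bold, tr=tr
            )
        )
        timelines.append(read_events_tsv(row.events_path, scan_duration=scan_dur))
    return recordings, timelines
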