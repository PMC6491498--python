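"""Tab-separated interchange formats for every pipeline stage.

All tabular interfaces are TSV so that runs are diff-able in tests:
``subjects.tsv`` (one row per subject, cognitive scores as ``cog_<test>``
columns), ``timeseries/<subject>.tsv`` (region x time, header row of region
ids), ``connectivity/<subject>.tsv`` (square matrix, region-id header row
and index column), metric tables, and inference result tables.  Floats are
written with full repr precision so that a re-run from cached intermediates
reproduces downstream results bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .connectivity import ConnectivityMatrix, ParcellatedTimeSeries

__all__ = [
    "subjects_to_frame",
    "frame_to_subjects",
    "write_subjects",
    "read_subjects",
    "write_timeseries",
    "read_timeseries",
    "write_connectivity",
    "read_connectivity",
    "write_table",
    "read_table",
    "write_parcellation",
    "read_parcellation",
]

_FLOAT_FMT = "%.17g"


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = dataclasses.asdict(s)
        scores = row.pop("cognitive_scores")
        row.update({f"cog_{k}": v for k, v in scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    cog_cols = [c for c in df.columns if c.startswith("cog_")]
    out = []
    for _, r in df.iterrows():
        out.append(
            SubjectRecord(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                site=str(r["site"]),
                gene=str(r["gene"]),
                years_to_expected_onset=float(r["years_to_expected_onset"]),
                spike_pct=float(r["spike_pct"]),
                brain_volume_pct=float(r["brain_volume_pct"]),
                cognitive_scores={c[4:]: float(r[c]) for c in cog_cols},
            )
        )
    return out


def write_subjects(subjects: list[SubjectRecord], path) -> Path:
    path = Path(path)
    subjects_to_frame(subjects).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_subjects(path) -> list[SubjectRecord]:
    return frame_to_subjects(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_timeseries(ts: ParcellatedTimeSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{ts.subject_id}.tsv"
    header = "\t".join(f"r{i}" for i in range(ts.n_regions))
    # stored region x time; header names the region rows' order
    np.savetxt(path, ts.signal, delimiter="\t", fmt=_FLOAT_FMT,
               header=header + f"\ttr_seconds={ts.tr_seconds}", comments="# ")
    return path


def read_timeseries(path, tr_seconds: float | None = None) -> ParcellatedTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if tr_seconds is None:
        if "tr_seconds=" not in first:
            raise ValueError(f"{path} lacks a tr_seconds header; pass tr_seconds explicitly")
        tr_seconds = float(first.rsplit("tr_seconds=", 1)[1])
    signal = np.loadtxt(path, delimiter="\t")
    return ParcellatedTimeSeries(path.stem, np.atleast_2d(signal), tr_seconds)


def write_connectivity(conn: ConnectivityMatrix, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{conn.subject_id}.tsv"
    ids = [f"r{i}" for i in range(conn.n_regions)]
    pd.DataFrame(conn.values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )
    return path


def read_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(subject_id=path.stem, values=df.to_numpy(dtype=float))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_parcellation(voxels: np.ndarray, labels: np.ndarray, path) -> Path:
    """Write a parcellation as a voxel -> label table (x, y, z, label)."""
    voxels = np.asarray(voxels, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if voxels.shape[0] != labels.shape[0]:
        raise ValueError("one label per voxel required")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"c{i}" for i in range(voxels.shape[1])]
    df = pd.DataFrame(voxels, columns=cols)
    df["label"] = labels
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_parcellation(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a voxel -> label table back as (voxels, labels)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), labels
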