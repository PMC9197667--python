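"""Reading and writing of subject manifests, region x time matrices, and result reports.

A study dataset is a cohort of subjects, each carrying one region x time matrix
of regional BOLD (or other physiological) time series.  Matrices are delimited
text with a leading region-label column and no time header; the delimiter is
auto-detected among tab and comma.  Group labels use the binary coding
0 = poor, 1 = excellent.

All matrices are validated eagerly at load: identical region labels and
time-series length across subjects, binary group labels, no missing values.
The pipeline never silently drops a subject.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "StudyDataset",
    "read_manifest",
    "load_matrix",
    "save_matrix",
    "write_cohort",
    "zscore_series",
    "write_report",
    "read_report",
]

MIN_TIMEPOINTS = 10  # below this, sample entropy is not meaningful


class ValidationError(ValueError):
    """A dataset violated a structural invariant (shape, labels, groups)."""


@dataclass
class SubjectRecord:
    """One subject: identifier, binary group label, region x time matrix."""

    subject_id: str
    group: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.group not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id!r}: group must be 0 or 1, got {self.group!r}"
            )
        if self.matrix.ndim != 2:
            raise ValidationError(
                f"subject {self.subject_id!r}: matrix must be 2-D, got {self.matrix.ndim}-D"
            )
        if not np.isfinite(self.matrix).all():
            raise ValidationError(
                f"subject {self.subject_id!r}: matrix contains missing/non-finite values"
            )


@dataclass
class StudyDataset:
    """A cohort of subjects sharing one region ordering and series length."""

    subjects: list[SubjectRecord]
    region_labels: list[str]
    n_timepoints: int

    def __post_init__(self) -> None:
        n_regions = len(self.region_labels)
        for s in self.subjects:
            if s.matrix.shape != (n_regions, self.n_timepoints):
                raise ValidationError(
                    f"subject {s.subject_id!r}: matrix shape {s.matrix.shape} does not match "
                    f"dataset shape ({n_regions}, {self.n_timepoints})"
                )
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise ValidationError(
                f"n_timepoints = {self.n_timepoints} < {MIN_TIMEPOINTS}: too short for "
                "sample entropy"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def groups(self) -> np.ndarray:
        """Group label per subject, in dataset order."""
        return np.array([s.group for s in self.subjects], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def matrices(self) -> np.ndarray:
        """All matrices stacked as an array of shape (n_subjects, n_regions, n_timepoints)."""
        return np.stack([s.matrix for s in self.subjects])

    def require_both_groups(self, min_per_group: int = 2) -> None:
        """Raise unless both group labels are present with at least ``min_per_group`` subjects."""
        g = self.groups
        for label in (0, 1):
            n = int((g == label).sum())
            if n < min_per_group:
                raise ValidationError(
                    f"group {label} has {n} subjects; need at least {min_per_group} "
                    "for group comparison"
                )


def _detect_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    raise ValidationError("could not detect delimiter (expected tab or comma)")


def load_matrix(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Load one region x time matrix from delimited text.

    Rows are regions; the first field of each row is the region label; the
    remaining fields are the time points.  Returns ``(labels, matrix)``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"matrix file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ValidationError(f"{path}: empty matrix file")
        sep = _detect_delimiter(first)
    df = pd.read_csv(path, sep=sep, header=None, index_col=0, float_precision="round_trip")
    matrix = df.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ValidationError(f"{path}: matrix contains missing values")
    return [str(x) for x in df.index], matrix


def save_matrix(
    path: str | os.PathLike, labels: Sequence[str], matrix: np.ndarray, sep: str = "\t"
) -> None:
    """Write a region x time matrix as delimited text (lossless %.17g floats)."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        for label, row in zip(labels, matrix, strict=True):
            fh.write(str(label) + sep + sep.join("%.17g" % v for v in row) + "\n")


def read_manifest(
    path: str | os.PathLike, group_map: Mapping[str, int] | None = None
) -> StudyDataset:
    """Read a subject manifest and load every matrix.

    The manifest is a CSV with header ``subject_id,group,matrix_path``.
    Relative matrix paths are resolved against the manifest's directory.
    ``group_map`` optionally maps textual group labels to the 0/1 coding
    (e.g. ``{"poor": 0, "excellent": 1}``).

    Region labels are taken from the first subject's matrix and enforced on
    all others; subjects appear in manifest order.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"manifest not found: {path}")
    base = path.parent
    subjects: list[SubjectRecord] = []
    region_labels: list[str] | None = None
    n_timepoints: int | None = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "group", "matrix_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: manifest must have columns subject_id,group,matrix_path"
            )
        for row in reader:
            sid = row["subject_id"].strip()
            raw_group = row["group"].strip()
            if group_map is not None and raw_group in group_map:
                group: Any = group_map[raw_group]
            else:
                try:
                    group = int(raw_group)
                except ValueError:
                    raise ValidationError(
                        f"subject {sid!r}: group {raw_group!r} is not 0/1 and no "
                        "group_map entry matches"
                    ) from None
            mpath = Path(row["matrix_path"].strip())
            if not mpath.is_absolute():
                mpath = base / mpath
            labels, matrix = load_matrix(mpath)
            if region_labels is None:
                region_labels = labels
                n_timepoints = matrix.shape[1]
            elif labels != region_labels or matrix.shape != (
                len(region_labels),
                n_timepoints,
            ):
                raise ValidationError(
                    f"subject {sid!r}: matrix shape {matrix.shape} or region labels do not "
                    f"match the first subject's ({len(region_labels)}, {n_timepoints})"
                )
            subjects.append(SubjectRecord(subject_id=sid, group=group, matrix=matrix))
    if not subjects:
        raise ValidationError(f"{path}: manifest lists no subjects")
    assert region_labels is not None and n_timepoints is not None
    return StudyDataset(
        subjects=subjects, region_labels=region_labels, n_timepoints=n_timepoints
    )


def write_cohort(dataset: StudyDataset, out_dir: str | os.PathLike) -> Path:
    """Write a dataset as manifest.csv plus one TSV matrix per subject.

    Returns the manifest path.  Round-trips losslessly through read_manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "matrix_path"])
        for s in dataset.subjects:
            fname = f"{s.subject_id}.tsv"
            save_matrix(out_dir / fname, dataset.region_labels, s.matrix)
            writer.writerow([s.subject_id, s.group, fname])
    return manifest


def zscore_series(x: np.ndarray) -> np.ndarray:
    """Standardize a series to mean 0 and unit population SD (divisor n).

    A zero-variance input is degenerate for entropy purposes: an all-NaN
    vector is returned as the degenerate marker (callers treat any NaN as
    the undefined flag), never an exception.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore_series expects a 1-D series of length >= 2")
    sd = x.std()  # population convention
    if sd == 0 or not np.isfinite(sd):
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Reports


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_report(result: Any, path: str | os.PathLike) -> None:
    """Serialize a result as structured text.

    DataFrames (and objects exposing ``to_frame_report()``) become TSV tables
    with a header row; everything else (dataclasses, dicts, lists) becomes
    JSON.  Numeric fields round-trip bit-identically: floats are written with
    repr-level precision (JSON) or %.17g (TSV).
    """
    path = Path(path)
    obj = result
    if hasattr(obj, "to_frame_report"):
        obj = obj.to_frame_report()
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=True, float_format="%.17g")
        return
    if hasattr(obj, "to_dict_report"):
        obj = obj.to_dict_report()
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=2)
        fh.write("\n")


def read_report(path: str | os.PathLike) -> Any:
    """Read back a report written by write_report.

    TSV tables come back as DataFrames (first column as index); JSON reports
    come back as plain dicts/lists.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head in "{[":
        with open(path) as fh:
            return json.load(fh)
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
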