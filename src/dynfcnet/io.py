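"""Cohort file formats: delimited ROI matrices plus a manifest table.

One plain-text matrix per subject (rows = regions, columns = time points;
tab- or comma-delimited, optional header row, dialect auto-detected) and a
manifest CSV with columns ``subject_id, label, path`` (paths relative to the
manifest's directory). Matrices are written at full double precision so a
write → read round trip is value-exact.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .simulate import LABELS, RoiTimeSeriesSet, Subject

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "read_cohort", "write_cohort"]


def _detect_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # whitespace


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_matrix(path) -> np.ndarray:
    """Parse one region x time matrix; errors name the offending row/column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])
    rows_raw = [ln.split(delim) if delim else ln.split() for ln in lines]
    start = 0
    if not all(_is_number(tok) for tok in rows_raw[0]):
        start = 1  # header row
        if len(rows_raw) == 1:
            raise ValueError(f"{path}: only a header row, no data")
    width = len(rows_raw[start])
    out = np.empty((len(rows_raw) - start, width))
    for r, row in enumerate(rows_raw[start:]):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged matrix — row {r + 1} has {len(row)} columns, "
                f"expected {width}"
            )
        for c, tok in enumerate(row):
            try:
                out[r, c] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric entry {tok!r} at row {r + 1}, "
                    f"column {c + 1}"
                ) from None
    return out


def write_matrix(matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        for row in matrix:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def write_cohort(cohort: RoiTimeSeriesSet, out_dir) -> Path:
    """Write every subject's matrix plus the manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "timeseries").mkdir(exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path"])
        for sub in cohort:
            rel = f"timeseries/{sub.subject_id}.tsv"
            write_matrix(sub.series, out_dir / rel)
            writer.writerow([sub.subject_id, sub.label, rel])
    logger.info("wrote cohort of %d subjects to %s", len(cohort), out_dir)
    return manifest


def read_cohort(manifest_path) -> RoiTimeSeriesSet:
    """Load a cohort from its manifest, validating labels and region counts."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    subjects = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "label", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{manifest_path}: manifest needs columns {sorted(required)}"
            )
        for row in reader:
            sid, label = row["subject_id"], row["label"]
            if label not in LABELS:
                raise ValueError(
                    f"subject {sid}: unknown label {label!r} (expected one of {LABELS})"
                )
            mpath = Path(row["path"])
            if not mpath.is_absolute():
                mpath = base / mpath
            try:
                series = read_matrix(mpath)
            except (ValueError, FileNotFoundError) as exc:
                raise type(exc)(f"subject {sid}: {exc}") from None
            subjects.append(Subject(subject_id=sid, label=label, series=series))
    if not subjects:
        raise ValueError(f"{manifest_path}: manifest lists no subjects")
    regions = {s.series.shape[0] for s in subjects}
    if len(regions) > 1:
        raise ValueError(
            f"subjects disagree on region count: { {s.subject_id: s.series.shape[0] for s in subjects} }"
        )
    lengths = sorted({s.series.shape[1] for s in subjects})
    logger.info(
        "loaded %d subjects, R=%d, M in %s", len(subjects), regions.pop(), lengths
    )
    return RoiTimeSeriesSet(subjects=subjects)
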