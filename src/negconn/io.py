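"""Readers and writers for every on-disk format the pipeline touches.

Formats: time series are TSV (one row per frame, one column per ROI, with a
header row of 1-based ROI ids); motion is 6-column whitespace-delimited text;
parcellations are two-column TSV (roi_id, network); phenotype tables and
analysis records are CSV; connectivity matrices are TSV with a roi_id header
and NaN on the diagonal.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ConnectivityMatrix,
    FormatError,
    IntegrityError,
    MotionTrace,
    Parcellation,
    ScanTimeSeries,
    validate_records,
)

_GROUP_ALIASES = {"control": "control", "td": "control", "typical": "control", "adhd": "adhd"}
_SEX_ALIASES = {"m": "M", "male": "M", "f": "F", "female": "F"}


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a two-column (roi_id, network) TSV into a :class:`Parcellation`.

    ROI ids must be unique and exactly cover ``1..n_rois``.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"roi_id": int, "network": str})
    if not {"roi_id", "network"}.issubset(tab.columns):
        raise FormatError("parcellation table needs columns roi_id and network")
    ids = tab["roi_id"].to_numpy()
    n = len(ids)
    if len(np.unique(ids)) != n or ids.min() != 1 or ids.max() != n:
        raise FormatError("roi_id must be unique and exactly cover 1..n_rois")
    nets = tab.sort_values("roi_id")["network"].tolist()
    return Parcellation(networks=tuple(nets))


def load_gordon333() -> Parcellation:
    """Packaged 333-region network assignment table (Gordon-scheme compatible).

    This is a synthetic stand-in: it reproduces the published community sizes
    of the 333-region cortical parcellation (41 Default regions and 123
    task-positive regions across the cingulo-opercular, salience, dorsal
    attention, ventral attention and fronto-parietal systems) but assigns
    them to schematic, contiguous ROI-id blocks rather than the original
    per-region order. Any user table with the same two columns is accepted
    by :func:`read_parcellation` in its place.
    """
    ref = importlib.resources.files("negconn.data") / "gordon333_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_parcellation(path)


def read_timeseries(
    path: str | Path,
    parcellation: Parcellation,
    tr_seconds: float,
    scan_id: str = "",
    subject_id: str = "",
) -> ScanTimeSeries:
    """Read a frames x ROIs TSV into a :class:`ScanTimeSeries`.

    The optional header row carries 1-based ROI ids; columns must match the
    parcellation's ROI order and count.
    """
    with open(path) as fh:
        first = fh.readline().split("\t")
    # the optional header is exactly the 1-based roi ids
    has_header = [t.strip() for t in first] == [str(i) for i in range(1, len(first) + 1)]
    try:
        tab = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    except ValueError as exc:
        raise FormatError(f"cannot parse time series {path}: {exc}") from exc
    if tab.shape[1] != parcellation.n_rois:
        raise FormatError(
            f"time series {path} has {tab.shape[1]} columns, "
            f"parcellation has {parcellation.n_rois} ROIs"
        )
    try:
        data = tab.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(data)):
        raise FormatError(f"non-finite cell in {path}")
    return ScanTimeSeries(
        data=data, tr_seconds=tr_seconds, scan_id=scan_id, subject_id=subject_id
    )


def write_timeseries(ts: ScanTimeSeries, path: str | Path) -> None:
    header = "\t".join(str(i) for i in range(1, ts.n_rois + 1))
    np.savetxt(path, ts.data, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_motion(path: str | Path, rotations_in_degrees: bool = False) -> MotionTrace:
    """Read a 6-column realignment-parameter file (whitespace-delimited).

    Columns 1-3 are translations in mm; columns 4-6 rotations in radians,
    or degrees when ``rotations_in_degrees`` (both dialects occur in
    realignment outputs).
    """
    try:
        params = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse motion file {path}: {exc}") from exc
    if params.shape[1] != 6:
        raise FormatError(f"motion file {path} has {params.shape[1]} columns, expected 6")
    if rotations_in_degrees:
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    return MotionTrace(params=params)


def write_motion(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, trace.params, fmt="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV into validated per-scan record stubs.

    Required columns: subject_id, wave, group, sex, age. Group and sex
    labels are normalised to canonical form (``control``/``adhd``,
    ``M``/``F``) case-insensitively; a duplicated (subject, wave) key is an
    integrity error.
    """
    tab = pd.read_csv(path)
    required = {"subject_id", "wave", "group", "sex", "age"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    tab = tab.copy()
    tab["group"] = tab["group"].map(lambda g: _normalise(g, _GROUP_ALIASES, "group"))
    tab["sex"] = tab["sex"].map(lambda s: _normalise(s, _SEX_ALIASES, "sex"))
    tab["subject_id"] = tab["subject_id"].astype(str)
    return validate_records(tab)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-scan analysis records as RFC-4180-style CSV."""
    validate_records(records)
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path, dtype={"subject_id": str}))


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    """Write a Fisher-z matrix as TSV with a 1-based roi_id header.

    The undefined diagonal is emitted as ``nan``.
    """
    header = "\t".join(str(i) for i in range(1, mat.n_rois + 1))
    np.savetxt(path, mat.z, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_matrix(path: str | Path, scan_id: str = "") -> ConnectivityMatrix:
    z = np.loadtxt(path, delimiter="\t", skiprows=1)
    return ConnectivityMatrix(z=z, scan_id=scan_id)


def check_frame_counts(ts: ScanTimeSeries, trace: MotionTrace) -> None:
    """Reject a scan whose time series and motion disagree on frame count."""
    if ts.n_frames != trace.n_frames:
        raise IntegrityError(
            f"scan {ts.scan_id or '?'}: time series has {ts.n_frames} frames "
            f"but motion trace has {trace.n_frames}"
        )


def _normalise(value: object, aliases: dict[str, str], what: str) -> str:
    key = str(value).strip().lower()
    if key not in aliases:
        raise FormatError(f"unrecognised {what} label: {value!r}")
    return aliases[key]


def _is_number(s: object) -> bool:
    try:
        float(str(s))
        return True
    except ValueError:
        return False
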