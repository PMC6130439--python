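"""Core domain types shared across the pipeline.

Conventions used everywhere in this package:

* ROI ids are 1-based in every on-disk format and 0-based internally
  (array column ``k`` holds ROI id ``k + 1``).
* Connectivity lives on the Fisher-z scale (``z = atanh(r)``); the matrix
  diagonal is undefined and stored as NaN.
* Rotations in motion traces are radians unless a reader is told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Task-positive networks: systems that increase activity during externally
#: directed tasks, in opposition to the default-mode ("task negative") system.
TASK_POSITIVE_NETWORKS = frozenset(
    {"CinguloOperc", "Salience", "DorsalAttn", "VentralAttn", "FrontoParietal"}
)

DEFAULT_NETWORK = "Default"

GROUPS = ("control", "adhd")
SEXES = ("M", "F")


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its expected layout."""


class IntegrityError(ValueError):
    """Raised when records violate a uniqueness or consistency contract."""


@dataclass(frozen=True)
class Parcellation:
    """A fixed assignment of ROIs to functional networks.

    Parameters
    ----------
    networks : sequence of str
        Network label per ROI, in ROI-id order (position ``k`` describes
        ROI id ``k + 1``).
    """

    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.networks) == 0:
            raise ValueError("parcellation must contain at least one ROI")

    @property
    def n_rois(self) -> int:
        return len(self.networks)

    @property
    def roi_ids(self) -> np.ndarray:
        """1-based ROI ids, ``1..n_rois``."""
        return np.arange(1, self.n_rois + 1)

    def indices_of(self, network: str) -> np.ndarray:
        """0-based indices of ROIs assigned to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)

    @property
    def default_indices(self) -> np.ndarray:
        return self.indices_of(DEFAULT_NETWORK)

    @property
    def task_positive_indices(self) -> np.ndarray:
        member = np.isin(np.asarray(self.networks), sorted(TASK_POSITIVE_NETWORKS))
        return np.flatnonzero(member)

    def network_of(self, index: int) -> str:
        return self.networks[index]


@dataclass
class ScanTimeSeries:
    """Parcellated BOLD time series for one scan (frames x ROIs)."""

    data: np.ndarray
    tr_seconds: float
    scan_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("time series must be a 2-D frames x ROIs array")
        if self.data.shape[0] < 2:
            raise FormatError("time series needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("time series contains non-finite values")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per frame.

    Columns are translations x, y, z in mm then rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError("motion trace must have exactly 6 columns")
        if not np.all(np.isfinite(self.params)):
            raise FormatError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class FrameMask:
    """Boolean retention flag per frame of a scan."""

    keep: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1:
            raise ValueError("frame mask must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def minutes_kept(self) -> float:
        return self.n_kept * self.tr_seconds / 60.0


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity matrix; NaN diagonal."""

    z: np.ndarray
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(self.z.shape[0], dtype=bool)
        finite = np.isfinite(self.z[off])
        if finite.any() and not np.allclose(
            np.where(np.isfinite(self.z), self.z, 0.0),
            np.where(np.isfinite(self.z.T), self.z.T, 0.0),
        ):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


RECORD_COLUMNS = [
    "subject_id",
    "wave",
    "group",
    "sex",
    "age",
    "mean_fd",
    "avg_neg_conn",
    "dprime_easy",
    "dprime_difficult",
]


def validate_records(records: pd.DataFrame, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Validate a table of per-scan analysis rows.

    One row per scan: identifiers, group, sex, age, mean FD over retained
    frames, the averaged negative-connectivity metric (Fisher-z units) and
    the two d' scores. ``require`` lists columns that must be populated
    (non-null) in addition to being present.
    """
    missing = [c for c in ("subject_id", "wave", "group", "sex", "age") if c not in records]
    if missing:
        raise FormatError(f"record table missing required columns: {missing}")
    dup = records.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        keys = records.loc[dup, ["subject_id", "wave"]].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (subject, wave) scan keys: {keys}")
    bad_group = set(records["group"].unique()) - set(GROUPS)
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}")
    bad_sex = set(records["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise FormatError(f"unknown sex labels: {sorted(bad_sex)}")
    if "mean_fd" in records and (records["mean_fd"].dropna() < 0).any():
        raise IntegrityError("mean_fd must be non-negative")
    for col in require:
        if col not in records:
            raise FormatError(f"record table missing required column: {col}")
        if records[col].isna().any():
            raise IntegrityError(f"column {col!r} has missing values")
    return records
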