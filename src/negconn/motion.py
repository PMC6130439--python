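"""Head-motion quality control.

Framewise displacement (FD) summarises per-frame head motion as the sum of
absolute backward differences of the six realignment parameters, with
rotations converted to arc length on a 50 mm sphere (the conventional
approximate head radius). Frames whose FD exceeds a threshold (0.2 mm by
default) are censored, a fixed duration of clean data is sampled at random
so every scan contributes the same amount, and a secondary scan-level check
removes scans whose averaged connectivity metric remains associated with
mean FD across the cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import FrameMask, MotionTrace

logger = logging.getLogger(__name__)

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_TARGET_MINUTES = 4.0


@dataclass
class FdSeries:
    """Per-frame framewise displacement in mm for one scan."""

    fd_mm: np.ndarray

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if (self.fd_mm < 0).any():
            raise ValueError("FD cannot be negative")

    @property
    def n_frames(self) -> int:
        return self.fd_mm.size

    def mean_over(self, keep: np.ndarray) -> float:
        """Mean FD over retained frames."""
        keep = np.asarray(keep, dtype=bool)
        if keep.sum() == 0:
            return float("nan")
        return float(self.fd_mm[keep].mean())


def compute_fd(trace: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> FdSeries:
    """Framewise displacement from realignment parameters.

    ``FD_t = sum |d trans| + r * sum |d rot|`` over the three translations
    (mm) and three rotations (radians scaled by the head radius to mm of
    arc length), using backward differences; the first frame has FD 0 by
    convention.
    """
    p = trace.params
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters must be finite")
    diffs = np.abs(np.diff(p, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return FdSeries(fd_mm=np.concatenate([[0.0], fd]))


def censor_frames(
    fd: FdSeries, tr_seconds: float, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
) -> FrameMask:
    """Keep frames whose FD does not exceed the threshold.

    "Exceeding" is read strictly: a frame exactly at the threshold is kept.
    """
    return FrameMask(keep=fd.fd_mm <= threshold_mm, tr_seconds=tr_seconds)


class InsufficientCleanDataError(ValueError):
    """A scan lacks enough clean data to contribute the target duration."""


def frames_for_minutes(target_minutes: float, tr_seconds: float) -> int:
    return math.ceil(target_minutes * 60.0 / tr_seconds)


def select_clean_frames(
    mask: FrameMask,
    target_minutes: float = DEFAULT_TARGET_MINUTES,
    rng: np.random.Generator | int | None = None,
) -> FrameMask:
    """Randomly select a fixed duration of clean frames from a scan.

    Eligibility requires strictly more than ``target_minutes`` of retained
    data; eligible scans contribute exactly
    ``ceil(target_minutes * 60 / tr)`` frames, sampled uniformly without
    replacement from the retained set (deterministic for a seeded ``rng``).

    Raises
    ------
    InsufficientCleanDataError
        If the scan has ``target_minutes`` or less of clean data. Callers
        batching many scans should catch this and record the exclusion.
    """
    if mask.minutes_kept <= target_minutes:
        raise InsufficientCleanDataError(
            f"{mask.minutes_kept:.2f} min clean data; need more than {target_minutes} min"
        )
    rng = np.random.default_rng(rng)
    n_target = frames_for_minutes(target_minutes, mask.tr_seconds)
    kept_idx = np.flatnonzero(mask.keep)
    chosen = rng.choice(kept_idx, size=n_target, replace=False)
    keep = np.zeros(mask.n_frames, dtype=bool)
    keep[chosen] = True
    return FrameMask(keep=keep, tr_seconds=mask.tr_seconds)


def fd_connectivity_association(records: pd.DataFrame) -> tuple[float, float]:
    """Across-scan Pearson correlation between mean FD and the averaged metric."""
    r, p = sps.pearsonr(records["mean_fd"], records["avg_neg_conn"])
    return float(r), float(p)


def secondary_fd_qc(
    records: pd.DataFrame,
    alpha: float = 0.05,
    max_removed: int | None = None,
) -> list[int]:
    """Scan-level motion QC on the FD-connectivity association.

    If mean FD predicts the averaged negative-connectivity metric across
    scans, residual motion artifact is contaminating the metric. This
    procedure iteratively removes the scan with the largest leave-one-out
    influence on the Pearson association (the removal that most shrinks the
    absolute correlation) until the association is non-significant at
    ``alpha`` or ``max_removed`` scans are gone. Returns positional indices
    into ``records`` in removal order. The stopping rule is a documented
    package choice and both ``alpha`` and ``max_removed`` are configurable.
    """
    if len(records) < 10:
        raise ValueError("secondary FD QC needs at least 10 scans")
    if max_removed is None:
        max_removed = len(records) // 10
    if max_removed == 0:
        logger.warning("secondary FD QC called with max_removed=0; nothing removed")
        return []

    removed: list[int] = []
    live = records[["mean_fd", "avg_neg_conn"]].reset_index(drop=True)
    live_pos = np.arange(len(records))
    while len(removed) < max_removed:
        _, p = fd_connectivity_association(live)
        if p >= alpha:
            break
        # leave-one-out |r|: drop the scan whose removal shrinks it the most
        best_i, best_abs_r = -1, np.inf
        x = live["mean_fd"].to_numpy()
        y = live["avg_neg_conn"].to_numpy()
        for i in range(len(live)):
            sel = np.ones(len(live), dtype=bool)
            sel[i] = False
            r_i = np.corrcoef(x[sel], y[sel])[0, 1]
            if abs(r_i) < best_abs_r:
                best_abs_r, best_i = abs(r_i), i
        removed.append(int(live_pos[best_i]))
        keep = np.ones(len(live), dtype=bool)
        keep[best_i] = False
        live = live.loc[keep].reset_index(drop=True)
        live_pos = live_pos[keep]
    else:
        logger.warning(
            "secondary FD QC hit max_removed=%d with association still significant",
            max_removed,
        )
    return removed
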