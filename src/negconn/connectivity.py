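"""Per-scan connectivity matrices.

Pearson correlation between the retained-frame time series of every ROI
pair, Fisher r-to-z transformed (``z = atanh(r)``). Frame selection is
scan-level: the identical retained-frame set is used for all pairs.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ConnectivityMatrix, FrameMask, ScanTimeSeries

logger = logging.getLogger(__name__)

#: |r| is capped at 1 - _R_CAP_EPS before atanh so perfect correlations map
#: to a large finite z instead of infinity.
_R_CAP_EPS = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform with capping of |r| = 1."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + _R_CAP_EPS, 1.0 - _R_CAP_EPS)
    return np.arctanh(r)


def correlation_matrix(
    ts: ScanTimeSeries, mask: FrameMask | None = None
) -> ConnectivityMatrix:
    """Fisher-z connectivity matrix over a scan's retained frames.

    Constant ROIs yield undefined (NaN) entries in their row/column with a
    warning; |r| = 1 is capped at ``1 - 1e-7`` before the transform. The
    diagonal is undefined and stored as NaN.
    """
    if mask is None:
        data = ts.data
    else:
        if mask.n_frames != ts.n_frames:
            raise ValueError("frame mask length does not match time series")
        data = ts.data[mask.keep]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 retained frames for correlation")

    sd = data.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "scan %s: %d constant ROI(s) over retained frames; entries undefined",
            ts.scan_id or "?",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan

    capped = np.isfinite(r) & (np.abs(r) >= 1.0 - _R_CAP_EPS)
    np.fill_diagonal(capped, False)
    if capped.any():
        logger.warning(
            "scan %s: %d edge(s) at |r|=1 capped before Fisher transform",
            ts.scan_id or "?",
            int(capped.sum()) // 2,
        )
    z = np.where(np.isfinite(r), fisher_z(r), np.nan)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=z, scan_id=ts.scan_id)
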