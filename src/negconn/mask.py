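"""Reference-defined anticorrelated network masks.

Not every default-mode / task-positive ROI pair is anticorrelated, so the
analysis restricts itself to the edges that are most reliably negative in an
independent reference cohort. Reference matrices are averaged on the
Fisher-z scale, converted back to r, and edges are retained either below a
correlation cut (e.g. r < -0.35) or as the most-negative fixed fraction of
candidates (density rule). The per-scan outcome metric is the arithmetic
mean of Fisher-z values over the retained edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_NETWORK,
    ConnectivityMatrix,
    Parcellation,
)

SCOPES = ("dmn_to_taskpos", "dmn_to_all")


class EmptyMaskError(ValueError):
    """No edge survived the mask rule."""


@dataclass(frozen=True)
class MaskRule:
    """Edge-retention rule: correlation threshold or connection density."""

    kind: str  # "threshold" | "density"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "density"):
            raise ValueError(f"unknown mask rule kind: {self.kind}")
        if self.kind == "threshold" and self.value >= 0:
            raise ValueError("threshold rule needs a negative correlation cut")
        if self.kind == "density" and not (0 < self.value <= 1):
            raise ValueError("density fraction must be in (0, 1]")

    @classmethod
    def parse(cls, text: str) -> "MaskRule":
        """Parse ``threshold:-0.35`` or ``density:0.05``."""
        kind, _, value = text.partition(":")
        return cls(kind=kind, value=float(value))


@dataclass
class EdgeMask:
    """The retained set of anticorrelated (i < j) ROI pairs.

    ``edges`` is an (n_edges, 2) array of 0-based ROI indices; ``ref_mean_r``
    the reference-cohort mean correlation per edge.
    """

    edges: np.ndarray
    ref_mean_r: np.ndarray
    networks: list[tuple[str, str]]
    scope: str
    rule: MaskRule
    n_candidates: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.ref_mean_r = np.asarray(self.ref_mean_r, dtype=float)
        if (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValueError("edges must be stored with i < j")
        pairs = set(map(tuple, self.edges))
        if len(pairs) != len(self.edges):
            raise ValueError("duplicate edges in mask")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density_percent(self) -> float:
        """Connection density of the mask among its candidates, in percent."""
        return 100.0 * self.n_edges / self.n_candidates

    def edge_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.edges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_i": self.edges[:, 0] + 1,  # 1-based on disk
                "roi_j": self.edges[:, 1] + 1,
                "ref_mean_r": self.ref_mean_r,
                "net_i": [a for a, _ in self.networks],
                "net_j": [b for _, b in self.networks],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def candidate_edges(parcellation: Parcellation, scope: str = "dmn_to_taskpos") -> np.ndarray:
    """All candidate (DMN, counterpart) ROI pairs for a scope.

    ``dmn_to_taskpos`` pairs every Default ROI with every task-positive ROI;
    ``dmn_to_all`` pairs every Default ROI with every non-Default ROI.
    Returns an (n, 2) array of 0-based indices with i < j, in lexicographic
    order.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    dmn = parcellation.default_indices
    if scope == "dmn_to_taskpos":
        other = parcellation.task_positive_indices
    else:
        other = np.setdiff1d(np.arange(parcellation.n_rois), dmn)
    if dmn.size == 0 or other.size == 0:
        raise ValueError("scope requires non-empty Default and counterpart sets")
    a = np.repeat(dmn, other.size)
    b = np.tile(other, dmn.size)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    return pairs


def build_mask(
    reference_mats: list[ConnectivityMatrix],
    parcellation: Parcellation,
    scope: str = "dmn_to_taskpos",
    rule: MaskRule = MaskRule("threshold", -0.35),
) -> EdgeMask:
    """Define the anticorrelated edge mask from reference connectivity.

    Candidate-edge z values are averaged across reference scans, converted
    to r by tanh, then retained below the cut (threshold rule) or as the
    ``ceil(fraction * n_candidates)`` most negative (density rule; boundary
    ties broken by (i, j) lexicographic order, deterministically).
    """
    if len(reference_mats) < 2:
        raise ValueError("need at least 2 reference matrices")
    n = parcellation.n_rois
    for m in reference_mats:
        if m.n_rois != n:
            raise ValueError("reference matrix size does not match parcellation")

    pairs = candidate_edges(parcellation, scope)
    zs = np.stack([m.z[pairs[:, 0], pairs[:, 1]] for m in reference_mats])
    mean_r = np.tanh(zs.mean(axis=0))

    if rule.kind == "threshold":
        retain = mean_r < rule.value
    else:
        k = math.ceil(rule.value * len(pairs))
        # lexicographic (i, j) tie-break at the density boundary: pairs are
        # already lexicographically sorted, and stable mergesort preserves
        # that order among equal r values
        order = np.argsort(mean_r, kind="stable")[:k]
        retain = np.zeros(len(pairs), dtype=bool)
        retain[order] = True
    if not retain.any():
        raise EmptyMaskError(
            f"no candidate edge satisfies the rule; minimum reference r is {mean_r.min():.4f}"
        )

    kept = pairs[retain]
    nets = [
        (parcellation.network_of(i), parcellation.network_of(j)) for i, j in kept
    ]
    return EdgeMask(
        edges=kept,
        ref_mean_r=mean_r[retain],
        networks=nets,
        scope=scope,
        rule=rule,
        n_candidates=len(pairs),
    )


def load_mask(path: str | Path, parcellation: Parcellation, scope: str, rule: MaskRule) -> EdgeMask:
    tab = pd.read_csv(path, sep="\t")
    edges = tab[["roi_i", "roi_j"]].to_numpy() - 1
    return EdgeMask(
        edges=edges,
        ref_mean_r=tab["ref_mean_r"].to_numpy(),
        networks=list(zip(tab["net_i"], tab["net_j"])),
        scope=scope,
        rule=rule,
        n_candidates=len(candidate_edges(parcellation, scope)),
    )


def region_importance(mask: EdgeMask, n_rois: int) -> np.ndarray:
    """Per-ROI count of mask edges incident to it (length ``n_rois``).

    A region's importance to the mask is how many of its connections are in
    the retained anticorrelated set; counts sum to twice the edge count.
    """
    if mask.n_edges == 0:
        raise ValueError("mask is empty")
    counts = np.zeros(n_rois, dtype=int)
    np.add.at(counts, mask.edges.ravel(), 1)
    return counts


def edge_values(mat: ConnectivityMatrix, mask: EdgeMask) -> np.ndarray:
    """Fisher-z values of one scan at the mask's edges."""
    if mask.edges.max(initial=-1) >= mat.n_rois:
        raise ValueError("mask edges exceed matrix size")
    z = mat.z[mask.edges[:, 0], mask.edges[:, 1]]
    bad = ~np.isfinite(z)
    if bad.any():
        pairs = (mask.edges[bad] + 1).tolist()
        raise ValueError(f"masked edges undefined in matrix: {pairs}")
    return z


def average_negative_connectivity(mat: ConnectivityMatrix, mask: EdgeMask) -> float:
    """Arithmetic mean of Fisher-z over the mask edges — the scan's metric."""
    return float(edge_values(mat, mask).mean())
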