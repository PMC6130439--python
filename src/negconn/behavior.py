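"""Identical-pairs continuous performance task (IP-CPT) scoring.

The task presents a stream of four-digit numbers; the child responds when
two identical numbers appear back to back. Targets are 20% of trials;
"catch" trials (20%) differ by a single digit and are hard discriminations;
"stim" trials (60%) differ by several digits and are easy. Sensitivity is
summarised by the equal-variance signal-detection index

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate),

computed separately against the stim false alarms (d' easy) and the catch
false alarms (d' difficult). Higher d' means better target/noise
discrimination (vigilance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

CORRECTIONS = ("half_count", "loglinear", "clamp")

TRIAL_TYPES = ("target", "stim", "catch")
#: Default trial mix: 60 targets, 180 easy nontargets, 60 hard nontargets.
DEFAULT_DESIGN = {"target": 60, "stim": 180, "catch": 60}


@dataclass(frozen=True)
class CptCounts:
    """Response counts from one CPT administration."""

    n_target: int
    n_hit: int
    n_stim: int
    n_fa_easy: int
    n_catch: int
    n_fa_difficult: int

    def __post_init__(self) -> None:
        for n, k in (
            (self.n_target, self.n_hit),
            (self.n_stim, self.n_fa_easy),
            (self.n_catch, self.n_fa_difficult),
        ):
            if n <= 0:
                raise ValueError("trial denominators must be positive")
            if not 0 <= k <= n:
                raise ValueError(f"count {k} outside [0, {n}]")


@dataclass(frozen=True)
class DprimeResult:
    dprime_easy: float
    dprime_difficult: float
    hit_rate: float
    fa_rate_easy: float
    fa_rate_difficult: float
    correction: str


def _corrected_rate(k: int, n: int, method: str) -> float:
    raw = k / n
    if method == "half_count":
        # add 0.5 to the count and 1 to the denominator, only for
        # degenerate (0 or 1) rates
        if raw in (0.0, 1.0):
            return (k + 0.5) / (n + 1)
        return raw
    if method == "loglinear":
        return (k + 0.5) / (n + 1)
    if method == "clamp":
        return float(np.clip(raw, 1 / (2 * n), 1 - 1 / (2 * n)))
    raise ValueError(f"unknown correction {method!r}; expected one of {CORRECTIONS}")


def score_cpt(counts: CptCounts, correction: str = "half_count") -> DprimeResult:
    """Score CPT counts into d' per discrimination difficulty.

    Extreme hit/false-alarm rates of exactly 0 or 1 would give infinite
    normal quantiles; the default correction replaces only such degenerate
    rates by ``(k + 0.5) / (n + 1)``. ``loglinear`` applies that adjustment
    to every rate and ``clamp`` truncates to ``[1/2n, 1 - 1/2n]``.
    """
    h = _corrected_rate(counts.n_hit, counts.n_target, correction)
    f_easy = _corrected_rate(counts.n_fa_easy, counts.n_stim, correction)
    f_diff = _corrected_rate(counts.n_fa_difficult, counts.n_catch, correction)
    zh = norm.ppf(h)
    return DprimeResult(
        dprime_easy=float(zh - norm.ppf(f_easy)),
        dprime_difficult=float(zh - norm.ppf(f_diff)),
        hit_rate=h,
        fa_rate_easy=f_easy,
        fa_rate_difficult=f_diff,
        correction=correction,
    )


def sdt_response_probs(dprime: float, criterion: float = 0.0) -> tuple[float, float]:
    """Hit and false-alarm probabilities of an equal-variance SDT observer.

    With sensitivity d' and a symmetric response criterion c, the observer
    responds on signal trials with probability ``Phi(d'/2 - c)`` and on
    noise trials with ``Phi(-d'/2 - c)``; scoring expected counts recovers
    d' exactly in the large-sample limit.
    """
    return float(norm.cdf(dprime / 2 - criterion)), float(norm.cdf(-dprime / 2 - criterion))


def counts_from_trials(trials: pd.DataFrame) -> CptCounts:
    """Collapse a per-trial log into counts.

    The log has columns ``type`` in {target, stim, catch} and ``responded``
    in {0, 1}; trial order is irrelevant to the score.
    """
    bad = set(trials["type"].unique()) - set(TRIAL_TYPES)
    if bad:
        raise ValueError(f"unknown trial types: {sorted(bad)}")
    by = trials.groupby("type")["responded"]
    n = by.count()
    k = by.sum()
    for t in TRIAL_TYPES:
        if t not in n.index:
            raise ValueError(f"trial log has no {t!r} trials")
    return CptCounts(
        n_target=int(n["target"]),
        n_hit=int(k["target"]),
        n_stim=int(n["stim"]),
        n_fa_easy=int(k["stim"]),
        n_catch=int(n["catch"]),
        n_fa_difficult=int(k["catch"]),
    )


def simulate_trials(
    dprime_easy: float,
    dprime_difficult: float,
    criterion: float = 0.0,
    design: dict[str, int] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw a per-trial response log from the SDT model.

    Targets are answered from the easy-condition hit probability (the same
    targets serve both difficulty contrasts); stim and catch nontargets use
    the false-alarm probability of their respective d'.
    """
    rng = np.random.default_rng(rng)
    design = dict(DEFAULT_DESIGN if design is None else design)
    hit_p, fa_easy_p = sdt_response_probs(dprime_easy, criterion)
    _, fa_diff_p = sdt_response_probs(dprime_difficult, criterion)
    probs = {"target": hit_p, "stim": fa_easy_p, "catch": fa_diff_p}
    rows = []
    for ttype in TRIAL_TYPES:
        resp = rng.random(design[ttype]) < probs[ttype]
        rows.append(pd.DataFrame({"type": ttype, "responded": resp.astype(int)}))
    log = pd.concat(rows, ignore_index=True)
    # pseudorandom presentation order, as in the task itself
    log = log.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    log = log.reset_index(drop=True)
    log.insert(0, "trial_index", np.arange(len(log)))
    return log
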