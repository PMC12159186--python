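"""Behavioural summaries: trial exclusion, d-prime, RT descriptives, median splits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RT_EXCLUSION_THRESHOLD = 0.2  # s; implausibly fast responses


@dataclass
class BehaviourCounts:
    """Signal-detection counts for one condition cell."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms,
               self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_present(self) -> int:
        return self.hits + self.misses

    @property
    def n_absent(self) -> int:
        return self.false_alarms + self.correct_rejections

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "BehaviourCounts":
        present = trials["target_present"].to_numpy(dtype=bool)
        said_present = trials["response"].to_numpy() == "present"
        return cls(
            hits=int(np.sum(present & said_present)),
            misses=int(np.sum(present & ~said_present)),
            false_alarms=int(np.sum(~present & said_present)),
            correct_rejections=int(np.sum(~present & ~said_present)),
        )


def exclude_trials(trials: pd.DataFrame, rt_threshold: float = RT_EXCLUSION_THRESHOLD):
    """Drop implausibly fast (rt <= 0.2 s) and no-response trials.

    Returns ``(retained, log)`` where ``log`` lists each excluded trial
    with the reason.  Idempotent: re-applying to the retained table is
    the identity.
    """
    rt = trials["rt"].to_numpy(dtype=float)
    no_response = (trials["response"].to_numpy() == "none") | ~np.isfinite(rt)
    too_fast = np.isfinite(rt) & (rt <= rt_threshold)
    drop = no_response | too_fast
    reasons = np.where(no_response, "no_response", "rt_too_fast")
    log = trials.loc[drop, ["trial_index"]].copy()
    log["reason"] = reasons[drop]
    return trials.loc[~drop].copy(), log.reset_index(drop=True)


def _edge_adjust(rate: float, n: int, correction: str) -> float:
    if 0.0 < rate < 1.0:
        return rate
    if correction == "half-count":
        if rate <= 0.0:
            return 1.0 / (2 * n)
        return 1.0 - 1.0 / (2 * n)
    if correction == "loglinear":
        # add 0.5 to the count, 1 to the denominator
        return (rate * n + 0.5) / (n + 1)
    raise ValueError(f"unknown edge correction {correction!r}")


def dprime(counts: BehaviourCounts, correction: str = "half-count") -> float:
    """Signal-detection sensitivity d' = z(H) - z(FA).

    ``z`` is the standard normal quantile function; hit or false-alarm
    rates of exactly 0 or 1 are first adjusted by ``correction``
    (``"half-count"``: replace 0 with 1/(2N) and 1 with 1 - 1/(2N)).
    """
    if counts.n_present == 0 or counts.n_absent == 0:
        raise ValueError("need at least one target-present and one "
                         "target-absent trial")
    h = _edge_adjust(counts.hits / counts.n_present, counts.n_present, correction)
    fa = _edge_adjust(counts.false_alarms / counts.n_absent,
                      counts.n_absent, correction)
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


def median_split(trials: pd.DataFrame, by=("condition", "set_size"),
                 ties_to: str = "fast") -> pd.Series:
    """Label trials "fast"/"slow" by the within-cell reaction-time median.

    Trials exactly at the median go to ``ties_to`` ("fast" by default),
    subject to keeping the label counts within one of each other.
    """
    if ties_to not in ("fast", "slow"):
        raise ValueError("ties_to must be 'fast' or 'slow'")
    labels = pd.Series(index=trials.index, dtype=object, name="split")
    for _, cell in trials.groupby(list(by)):
        rt = cell["rt"].to_numpy(dtype=float)
        if len(cell) < 2 or not np.all(np.isfinite(rt)):
            raise ValueError("median_split needs >= 2 trials with finite rt "
                             "per cell")
        order = np.argsort(rt, kind="stable")
        n_fast = (len(rt) + 1) // 2 if ties_to == "fast" else len(rt) // 2
        cell_labels = np.full(len(rt), "slow", dtype=object)
        cell_labels[order[:n_fast]] = "fast"
        labels.loc[cell.index] = cell_labels
    return labels


def condition_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per condition cell: trial count, mean RT and d'."""
    rows = []
    for (condition, set_size), cell in trials.groupby(["condition", "set_size"]):
        counts = BehaviourCounts.from_trials(cell)
        rows.append({
            "condition": condition,
            "set_size": set_size,
            "n_trials": len(cell),
            "mean_rt": float(np.nanmean(cell["rt"].to_numpy(dtype=float))),
            "dprime": dprime(counts),
        })
    return pd.DataFrame(rows)
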