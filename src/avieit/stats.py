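"""Contingency statistics and per-recumbency summaries.

The central tool is a two-sided Fisher exact test for general r x c tables:
the p-value is the total conditional probability (fixed margins,
multivariate hypergeometric) of all tables no more probable than the
observed one.  The exact method enumerates tables with a network-style
row-by-row recursion whose states (row index, remaining column sums) are
memoised with the minimum, maximum and log-sum of completion weights, so
whole subtrees are added or pruned without expansion.  A seeded Monte-Carlo
fallback samples fixed-margin tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable",
    "fisher_exact_rxc",
    "summarize",
    "brp_frequency_table",
    "CHICKEN_BRP_COUNTS",
]

# Breathing-pattern frequencies (chickens per BrP category and recumbency)
# observed in the reference study of ten anaesthetised chickens; one left-
# lateral recording was unusable, leaving nine classified subjects there.
# Shipped as a worked example / regression anchor for the exact test.
CHICKEN_BRP_COUNTS = pd.DataFrame(
    [[5, 0, 1, 4], [2, 1, 3, 4], [0, 1, 7, 1], [0, 2, 8, 0]],
    index=["dorsal", "ventral", "right_lateral", "left_lateral"],
    columns=["BrP1", "BrP2", "BrP3", "BrP4"],
)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.size == 0:
            raise ValueError("counts must be a 2-D table")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise ValueError("counts must be non-negative")
        if np.any(c != np.round(c)):
            raise ValueError("counts must be integers")
        self.counts = c.astype(np.int64)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


def _logfact(n: np.ndarray) -> np.ndarray:
    return gammaln(np.asarray(n, float) + 1.0)


def _row_compositions(total: int, bounds: tuple):
    """All vectors k with sum(k) == total and 0 <= k_j <= bounds_j."""
    def rec(j, remaining, prefix):
        if j == len(bounds) - 1:
            if remaining <= bounds[j]:
                yield prefix + (remaining,)
            return
        tail_max = sum(bounds[j + 1 :])
        lo = max(0, remaining - tail_max)
        hi = min(bounds[j], remaining)
        for k in range(lo, hi + 1):
            yield from rec(j + 1, remaining - k, prefix + (k,))
    yield from rec(0, total, ())


def fisher_exact_rxc(
    table,
    method: str = "exact",
    mc_reps: int = 100_000,
    seed: int = 0,
    max_states: int = 2_000_000,
) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    Exact method: sum of the conditional probabilities of all fixed-margin
    tables whose probability does not exceed the observed table's (with the
    customary 1e-7 relative tolerance on the threshold).  Monte-Carlo
    method: the proportion of ``mc_reps`` seeded fixed-margin tables
    (Patefield sampling via scipy) at or below the observed probability.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    elif isinstance(table, pd.DataFrame):
        counts = ContingencyTable.from_frame(table).counts
    else:
        counts = ContingencyTable(np.asarray(table)).counts
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.size == 0:
        raise ValueError("empty contingency table")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    s_obs = float(-_logfact(counts).sum())
    tol = 1e-7 * abs(s_obs) + 1e-12

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        dist = sps.random_table(rows, cols, seed=rng)
        hits = 0
        done = 0
        while done < mc_reps:
            n = min(100_000, mc_reps - done)
            sample = dist.rvs(n)
            s = -_logfact(sample).sum(axis=(1, 2))
            hits += int(np.sum(s <= s_obs + tol))
            done += n
        return hits / mc_reps
    if method != "exact":
        raise ValueError("method must be 'exact' or 'montecarlo'")

    state_bound = int(np.prod([min(c, rows.sum()) + 1.0 for c in cols]))
    if counts.shape[0] > 2 and state_bound * counts.shape[0] > max_states:
        raise ValueError(
            "exact enumeration infeasible for these margins; use method='montecarlo'"
        )

    n_rows = len(rows)
    lf_rows = _logfact(rows)

    @lru_cache(maxsize=None)
    def node(i: int, rem: tuple):
        """(min, max, log-sum) of completion weights sum(-log n_ij!) over all
        ways to fill rows i.. with remaining column sums ``rem``."""
        if i == n_rows - 1:
            w = float(-_logfact(np.array(rem)).sum())
            return w, w, w
        smin, smax = np.inf, -np.inf
        logs = []
        for comp in _row_compositions(int(rows[i]), rem):
            w = float(-_logfact(np.array(comp)).sum())
            new_rem = tuple(r - k for r, k in zip(rem, comp))
            lo, hi, tot = node(i + 1, new_rem)
            smin = min(smin, w + lo)
            smax = max(smax, w + hi)
            logs.append(w + tot)
        return smin, smax, float(logsumexp(logs))

    log_const = float(lf_rows.sum() + _logfact(cols).sum() - _logfact(rows.sum()))

    def accumulate(i: int, rem: tuple, s_partial: float) -> float:
        lo, hi, tot = node(i, rem)
        if s_partial + hi <= s_obs + tol:
            return float(np.exp(log_const + s_partial + tot))
        if s_partial + lo > s_obs + tol:
            return 0.0
        p = 0.0
        if i == n_rows - 1:  # can only happen within tolerance edge cases
            return 0.0
        for comp in _row_compositions(int(rows[i]), rem):
            w = float(-_logfact(np.array(comp)).sum())
            new_rem = tuple(r - k for r, k in zip(rem, comp))
            p += accumulate(i + 1, new_rem, s_partial + w)
        return p

    p = accumulate(0, tuple(int(c) for c in cols), 0.0)
    return min(p, 1.0)


def summarize(results: pd.DataFrame, group_col: str = "recumbency") -> pd.DataFrame:
    """Group means with t-based 95% confidence intervals.

    ``results`` holds one row per recording (the per-recording breath means)
    and a grouping column; output has one row per (group, variable) with
    mean, ci_low, ci_high (CI absent for singleton groups).
    """
    value_cols = [c for c in results.columns if c != group_col
                  and np.issubdtype(results[c].dtype, np.number)]
    rows = []
    for group, sub in results.groupby(group_col, sort=False):
        for col in value_cols:
            x = sub[col].dropna().to_numpy(float)
            mean = float(x.mean()) if len(x) else np.nan
            if len(x) >= 2:
                sem = x.std(ddof=1) / np.sqrt(len(x))
                tcrit = sps.t.ppf(0.975, len(x) - 1)
                lo, hi = mean - tcrit * sem, mean + tcrit * sem
            else:
                lo = hi = np.nan
            rows.append({group_col: group, "variable": col, "n": len(x),
                         "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def brp_frequency_table(labels_by_group: dict) -> ContingencyTable:
    """Counts of recordings per breathing pattern for each group.

    ``labels_by_group`` maps a group name (recumbency) to its per-recording
    labels (BrPLabel or str); ``mixed`` recordings are excluded from the
    table and reported separately by the caller.
    """
    categories = ["BrP1", "BrP2", "BrP3", "BrP4"]
    counts = []
    for group, labels in labels_by_group.items():
        values = [getattr(l, "value", str(l)) for l in labels]
        counts.append([values.count(c) for c in categories])
    return ContingencyTable(
        np.array(counts, dtype=int) if counts else np.zeros((0, 4), int),
        row_labels=list(labels_by_group),
        col_labels=categories,
    )
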