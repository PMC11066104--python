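"""Visit-history matching of progressive and non-progressive subjects.

A progressive subject's history is the vector of day-counts from each visit to
the terminal diagnosis visit (ending in 0).  Non-progressive subjects, having
no diagnosis visit, contribute a set of candidate histories obtained by
varying the start visit and a constructed terminal visit.  Pair cost is the
sum of absolute entry-wise differences between equal-length histories (∞ when
no equal-length candidate exists), and the global pairing is the
minimum-total-cost assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .phantoms import trajectory_labels

INF = math.inf


def progressive_history(visit_days, diagnoses) -> np.ndarray:
    """Days-to-first-dementia-visit for every visit up to and including it."""
    days = np.asarray(visit_days)
    diags = list(diagnoses)
    if "DEM" not in diags:
        raise ValueError("subject has no dementia visit")
    idx = diags.index("DEM")
    if idx == 0:
        raise ValueError("dementia visit must be preceded by >=1 earlier visit")
    term = days[idx]
    return (term - days[: idx + 1]).astype(int)


def enumerate_histories(visit_days) -> list[np.ndarray]:
    """All candidate histories from (start, terminal) visit pairs, start < terminal."""
    days = np.asarray(visit_days)
    if len(days) < 2:
        raise ValueError("need at least 2 visits to form a history")
    out = []
    seen = set()
    for j in range(1, len(days)):
        for i in range(j):
            h = (days[j] - days[i : j + 1]).astype(int)
            key = tuple(h.tolist())
            if key not in seen:
                seen.add(key)
                out.append(h)
    return out


def history_cost(h1, h2) -> float:
    """Sum of absolute pairwise differences between equal-length histories."""
    a = np.asarray(h1)
    b = np.asarray(h2)
    if a.shape != b.shape:
        raise ValueError(f"history length mismatch: {len(a)} vs {len(b)}")
    return float(np.abs(a - b).sum())


def best_pair_cost(progressive_history_vec, candidates) -> tuple[float, np.ndarray | None]:
    """Min cost over equal-length candidates, or (∞, None) when none exists."""
    hp = np.asarray(progressive_history_vec)
    best, best_h = INF, None
    for h in candidates:
        if len(h) != len(hp):
            continue
        c = history_cost(hp, h)
        if c < best:
            best, best_h = c, h
    return best, best_h


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # progressive_id, nonprogressive_id, cost, history
    total_cost: float
    unmatched_progressive: list[str]


def assign_matches(cost: np.ndarray, row_ids=None, col_ids=None) -> MatchResult:
    """Globally optimal assignment on a cost matrix that may contain ∞.

    ∞ entries are never selected: they are replaced by a sentinel strictly
    larger than the total of all finite entries and the matrix is padded with
    sentinel columns, which makes the solver lexicographically maximize the
    number of finite pairs and then minimize their total cost.  Rows with no
    finite pairing are reported as unmatched.
    """
    c = np.asarray(cost, dtype=float)
    nr, nc = c.shape
    row_ids = list(row_ids) if row_ids is not None else list(range(nr))
    col_ids = list(col_ids) if col_ids is not None else list(range(nc))
    finite = c[np.isfinite(c)]
    big = float(finite.sum()) + 1.0 if finite.size else 1.0
    padded = np.full((nr, nc + nr), big)
    padded[:, :nc] = np.where(np.isfinite(c), c, big)
    rows, cols = linear_sum_assignment(padded)
    pair_rows, unmatched = [], []
    total = 0.0
    for r, col in zip(rows, cols):
        if col >= nc or not np.isfinite(c[r, col]) :
            unmatched.append(row_ids[r])
            continue
        pair_rows.append({"progressive_id": row_ids[r],
                          "nonprogressive_id": col_ids[col],
                          "cost": float(c[r, col])})
        total += float(c[r, col])
    pairs = pd.DataFrame(pair_rows, columns=["progressive_id", "nonprogressive_id", "cost"])
    return MatchResult(pairs=pairs, total_cost=total, unmatched_progressive=unmatched)


def match_cohort(visits: pd.DataFrame) -> MatchResult:
    """End-to-end matching from a raw visit table.

    Progressive subjects (trajectory "progressive") get their fixed history;
    non-progressive subjects (stable or improving) contribute candidate sets;
    the optimal assignment is computed over the pair-wise best costs, and each
    selected pair records the non-progressive history variant that realized it.
    """
    traj = trajectory_labels(visits)
    prog_ids = sorted(traj[traj == "progressive"].index)
    nonprog_ids = sorted(traj[traj.isin(["stable", "improving"])].index)
    v = visits.sort_values("visit_date")
    grouped = {sid: grp for sid, grp in v.groupby("subject_id")}

    prog_hist = {
        sid: progressive_history(grouped[sid]["visit_date"].to_numpy(),
                                 grouped[sid]["diagnosis"].tolist())
        for sid in prog_ids
    }
    cand = {}
    for sid in nonprog_ids:
        days = grouped[sid]["visit_date"].to_numpy()
        cand[sid] = enumerate_histories(days) if len(days) >= 2 else []

    cost = np.full((len(prog_ids), len(nonprog_ids)), INF)
    for i, pid in enumerate(prog_ids):
        for j, nid in enumerate(nonprog_ids):
            cost[i, j], _ = best_pair_cost(prog_hist[pid], cand[nid])
    result = assign_matches(cost, row_ids=prog_ids, col_ids=nonprog_ids)
    # attach the realizing history variant per selected pair
    variants = []
    for _, row in result.pairs.iterrows():
        _, h = best_pair_cost(prog_hist[row["progressive_id"]],
                              cand[row["nonprogressive_id"]])
        variants.append(h.tolist())
    result.pairs = result.pairs.assign(history=variants)
    return result
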