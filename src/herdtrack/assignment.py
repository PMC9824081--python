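"""Gated one-to-one assignment shared by the trackers and the metrics.

Given a rectangular cost matrix and a boolean feasibility mask, the
solver returns the assignment that (1) matches as many feasible pairs
as possible and (2) among those, has minimum total cost — the standard
big-M reduction to the Hungarian algorithm.  The solver is fully
deterministic: equal-cost ties resolve the same way on every run.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["gated_assignment"]


def gated_assignment(
    cost: np.ndarray, feasible: np.ndarray | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Solve a gated rectangular assignment problem.

    Parameters
    ----------
    cost
        (n_rows, n_cols) non-negative cost matrix.
    feasible
        Boolean mask of allowed pairs; infeasible pairs can never be
        matched.  ``None`` means all pairs allowed.

    Returns
    -------
    matches, unmatched_rows, unmatched_cols
        ``matches`` is a list of (row, col) pairs of maximum cardinality
        and, within that, minimum total cost.
    """
    cost = np.asarray(cost, dtype=float)
    n_rows, n_cols = cost.shape if cost.ndim == 2 else (0, 0)
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    if feasible is None:
        feasible = np.ones_like(cost, dtype=bool)
    feasible = np.asarray(feasible, dtype=bool)
    if not feasible.any():
        return [], list(range(n_rows)), list(range(n_cols))

    finite = np.where(feasible, cost, 0.0)
    # big-M larger than any feasible total cost so cardinality dominates
    big_m = finite.sum() + np.abs(finite).max() + 1.0
    padded = np.where(feasible, cost, big_m)
    rows, cols = linear_sum_assignment(padded)
    matches = [
        (int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]
    ]
    matches.sort()
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return (
        matches,
        [r for r in range(n_rows) if r not in matched_r],
        [c for c in range(n_cols) if c not in matched_c],
    )
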