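"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from scratch, with its own
bookkeeping, so that agreement with the package is meaningful.  The
only shared primitive is scipy's linear-sum-assignment solver, which
both sides use as a commodity LAP backend for large frames; for small
problems the oracles enumerate exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment


def box_iou(a, b) -> float:
    """IoU on (x, y, w, h) tuples — independent of the package type."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    x0, y0 = max(ax, bx), max(ay, by)
    x1, y1 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    inter = (x1 - x0) * (y1 - y0)
    return inter / (aw * ah + bw * bh - inter)


def best_partial_matching(cost, feasible):
    """Exhaustive optimum over all feasible partial matchings.

    Returns (cardinality, total_cost) of the maximum-cardinality,
    then minimum-cost matching.  Exponential; use only for tiny inputs.
    """
    cost = np.asarray(cost, dtype=float)
    feasible = np.asarray(feasible, dtype=bool)
    n_rows, n_cols = cost.shape
    best_k, best_cost = 0, 0.0
    for k in range(min(n_rows, n_cols), 0, -1):
        found = None
        for rows in itertools.combinations(range(n_rows), k):
            for cols in itertools.permutations(range(n_cols), k):
                if all(feasible[r, c] for r, c in zip(rows, cols)):
                    total = sum(cost[r, c] for r, c in zip(rows, cols))
                    if found is None or total < found:
                        found = total
        if found is not None:
            best_k, best_cost = k, found
            break
    return best_k, best_cost


def clear_events(gt_rows, pred_rows, iou_threshold=0.5):
    """Brute-force CLEAR event counting.

    ``gt_rows`` / ``pred_rows`` are iterables of
    ``(frame, obj_id, x, y, w, h)`` tuples.  Per frame, ground-truth /
    prediction pairs matched in the previous frame are kept while still
    at or above the IoU threshold; the remainder is matched to maximise
    total IoU (exhaustively for up to 5 on a side, LAP above).  Counts
    misses, false positives, identity switches (against the last
    matched prediction per GT id, across gaps) and fragmentations
    (tracked -> untracked -> tracked again).  Returns a dict of totals
    plus MOTA.
    """
    gt_by_frame: dict[int, dict] = {}
    for frame, oid, x, y, w, h in gt_rows:
        gt_by_frame.setdefault(frame, {})[oid] = (x, y, w, h)
    pred_by_frame: dict[int, dict] = {}
    for frame, oid, x, y, w, h in pred_rows:
        pred_by_frame.setdefault(frame, {})[oid] = (x, y, w, h)

    totals = {"fn": 0, "fp": 0, "idsw": 0, "gt": 0, "frag": 0, "matches": 0}
    prev: dict = {}
    last_hyp: dict = {}
    tracked_before: dict = {}
    gap: set = set()

    for frame in sorted(set(gt_by_frame) | set(pred_by_frame)):
        gts = gt_by_frame.get(frame, {})
        preds = pred_by_frame.get(frame, {})
        pairs = {}
        for g, p in prev.items():
            if g in gts and p in preds:
                if box_iou(gts[g], preds[p]) >= iou_threshold:
                    pairs[g] = p
        free_g = [g for g in gts if g not in pairs]
        taken = set(pairs.values())
        free_p = [p for p in preds if p not in taken]
        if free_g and free_p:
            mat = np.array(
                [[box_iou(gts[g], preds[p]) for p in free_p] for g in free_g]
            )
            ok = mat >= iou_threshold
            if ok.any():
                if min(len(free_g), len(free_p)) <= 5:
                    best = None
                    k_max = 0
                    for k in range(min(len(free_g), len(free_p)), 0, -1):
                        for rows in itertools.combinations(range(len(free_g)), k):
                            for cols in itertools.permutations(
                                range(len(free_p)), k
                            ):
                                if all(ok[r, c] for r, c in zip(rows, cols)):
                                    s = sum(mat[r, c]
                                            for r, c in zip(rows, cols))
                                    if best is None or s > best[0]:
                                        best = (s, rows, cols)
                        if best is not None:
                            k_max = k
                            break
                    if best is not None:
                        for r, c in zip(best[1], best[2]):
                            pairs[free_g[r]] = free_p[c]
                else:
                    big = 1e9
                    costm = np.where(ok, 1.0 - mat, big)
                    ri, ci = linear_sum_assignment(costm)
                    for r, c in zip(ri, ci):
                        if ok[r, c]:
                            pairs[free_g[r]] = free_p[c]

        for g, p in pairs.items():
            if g in last_hyp and last_hyp[g] != p:
                totals["idsw"] += 1
            last_hyp[g] = p
        for g in gts:
            now = g in pairs
            if g in gap and now:
                totals["frag"] += 1
                gap.discard(g)
            if tracked_before.get(g, False) and not now:
                gap.add(g)
            tracked_before[g] = now

        totals["matches"] += len(pairs)
        totals["fn"] += len(gts) - len(pairs)
        totals["fp"] += len(preds) - len(pairs)
        totals["gt"] += len(gts)
        prev = pairs

    totals["mota"] = (
        1.0 - (totals["fn"] + totals["fp"] + totals["idsw"]) / totals["gt"]
        if totals["gt"] else float("nan")
    )
    return totals


def average_precision_bruteforce(tp_flags, n_gt):
    """AP from an ordered TP/FP flag list by direct PR-curve summation:
    for each recall step, the maximum precision at recall >= r."""
    tps = 0
    points = []
    for i, flag in enumerate(tp_flags, start=1):
        tps += int(flag)
        points.append((tps / n_gt, tps / i))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            p_max = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap
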