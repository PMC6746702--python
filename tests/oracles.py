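"""Independent oracles used by the test suite.

These deliberately re-derive expected results through a different route
than the library (plain dynamic programming / direct enumeration), so they
can arbitrate the optimised implementations.
"""

import numpy as np

from chorioseg import W_MIN


def oracle_min_path(prob_map: np.ndarray, w_min: float = W_MIN):
    """Dynamic-programming enumeration of all monotone-column paths.

    Walks column by column, tracking for every pixel the cheapest path
    from the top of the left probability-1 auxiliary column, and finishes
    at the bottom of the right one; exact cost ties prefer the smaller
    predecessor row.  O(H*W), independent of the Dijkstra code path.
    """
    h, w = prob_map.shape
    dist = np.full(h, np.inf)
    for r in range(h):
        best = np.inf
        for r_aux in (r - 1, r, r + 1):
            if 0 <= r_aux < h:
                cand = r_aux * w_min + 2.0 - (1.0 + prob_map[r, 0]) + w_min
                if cand < best:
                    best = cand
        dist[r] = best
    paths = [[r] for r in range(h)]
    for c in range(1, w):
        new_dist = np.full(h, np.inf)
        new_paths = [None] * h
        for r in range(h):
            for pr in (r - 1, r, r + 1):  # smaller predecessor row first
                if not 0 <= pr < h:
                    continue
                cand = dist[pr] + 2.0 - (prob_map[pr, c - 1]
                                         + prob_map[r, c]) + w_min
                if cand < new_dist[r]:
                    new_dist[r] = cand
                    new_paths[r] = paths[pr] + [r]
        dist, paths = new_dist, new_paths
    best_cost, best_rows = np.inf, None
    for r in range(h):
        for r_aux in (r - 1, r, r + 1):
            if not 0 <= r_aux < h:
                continue
            cand = dist[r] + 2.0 - (prob_map[r, w - 1] + 1.0) + w_min \
                + (h - 1 - r_aux) * w_min
            if cand < best_cost:
                best_cost = cand
                best_rows = paths[r]
    return np.asarray(best_rows), best_cost
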