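"""Boundary delineation: probability maps and shortest-path graph search.

Each boundary probability map is treated as a graph with one vertex per
pixel and directed edges to the three right-hand neighbours (horizontal,
diagonal up, diagonal down).  Edge weights follow

    w_sd = 2 - (P_s + P_d) + w_min,      w_min = 1e-5,

so paths through high-probability pixels are cheap.  To avoid manual start
and end points, a column of probability-1 vertices is appended at each
side, connected top to bottom internally and fanned into (out of) the
adjacent real column; Dijkstra's algorithm then runs from the top-left
auxiliary vertex to the bottom-right one and the returned path is
restricted to the real columns, one row per column.
"""

from __future__ import annotations

import heapq
import logging

import numpy as np
from scipy import ndimage

from .core import BOUNDARY_NAMES, BScan, BoundarySet, CropRegion
from .nets.autodiff import Tensor
from .nets.models import UNet
from .patchgen import PatchSpec, extract_patches

__all__ = [
    "W_MIN", "edge_weight", "shortest_path_boundary",
    "patch_probability_maps", "semantic_boundary_maps", "segment_scan",
]

logger = logging.getLogger(__name__)

#: Stabilising additive constant of the edge-weight formula.
W_MIN = 1e-5


def edge_weight(p_source, p_dest, w_min: float = W_MIN):
    """Edge weight 2 - (P_s + P_d) + w_min; strictly positive on [0, 1]^2."""
    p_source = np.asarray(p_source, dtype=float)
    p_dest = np.asarray(p_dest, dtype=float)
    if (p_source < 0).any() or (p_source > 1).any() \
            or (p_dest < 0).any() or (p_dest > 1).any():
        raise ValueError("vertex probabilities must lie in [0, 1]")
    out = 2.0 - (p_source + p_dest) + w_min
    return float(out) if out.ndim == 0 else out


def shortest_path_boundary(prob_map: np.ndarray,
                           w_min: float = W_MIN) -> np.ndarray:
    """Delineate one boundary as the min-cost left-to-right pixel path.

    Returns integer rows, one per column of ``prob_map``; consecutive rows
    differ by at most 1.  Exact cost ties are broken toward the smaller
    predecessor row, making the result deterministic.  The auxiliary
    probability-1 columns never appear in the output.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 2:
        raise ValueError("probability map must be 2-D")
    h, w = prob_map.shape
    if w < 2:
        raise ValueError("probability map must have at least 2 columns")
    if not np.isfinite(prob_map).all():
        raise ValueError("probability map must be finite")
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")

    # padded map: auxiliary probability-1 columns at both sides
    padded = np.ones((h, w + 2))
    padded[:, 1:-1] = prob_map
    wp = w + 2
    n = h * wp
    source, target = 0 * wp + 0, (h - 1) * wp + (wp - 1)

    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    dist[source] = 0.0
    heap: list[tuple[float, int, int]] = [(0.0, 0, source)]
    while heap:
        d, _, u = heapq.heappop(heap)
        if d > dist[u]:
            continue  # stale entry
        ur, uc = divmod(u, wp)
        pu = padded[ur, uc]
        # rightward fan
        if uc + 1 < wp:
            for vr in (ur - 1, ur, ur + 1):
                if 0 <= vr < h:
                    v = vr * wp + uc + 1
                    nd = d + 2.0 - (pu + padded[vr, uc + 1]) + w_min
                    if nd < dist[v]:
                        dist[v] = nd
                        pred[v] = u
                        heapq.heappush(heap, (nd, vr, v))
                    elif nd == dist[v] and pred[v] >= 0 and ur < pred[v] // wp:
                        pred[v] = u
        # top-to-bottom edges within the auxiliary columns
        if uc in (0, wp - 1) and ur + 1 < h:
            v = (ur + 1) * wp + uc
            nd = d + 2.0 - (pu + padded[ur + 1, uc]) + w_min
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, ur + 1, v))
            elif nd == dist[v] and pred[v] >= 0 and ur < pred[v] // wp:
                pred[v] = u

    # walk back from the target and keep the real columns only
    rows = np.empty(w, dtype=np.int64)
    node = target
    while node != source:
        r, c = divmod(node, wp)
        if 1 <= c <= w:
            rows[c - 1] = r
        node = pred[node]
        if node < 0:
            raise RuntimeError("graph search failed to reach the source")
    return rows


def path_cost(prob_map: np.ndarray, rows: np.ndarray,
              w_min: float = W_MIN) -> float:
    """Total cost of a monotone-column path through the padded graph.

    The path is assumed to enter from the top of the left auxiliary column
    and exit to the bottom of the right one along the cheapest vertical
    runs; used by tests and diagnostics.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    rows = np.asarray(rows, dtype=int)
    h, w = prob_map.shape
    entry_aux = max(rows[0] - 1, 0)
    exit_aux = min(rows[-1] + 1, h - 1)
    cost = entry_aux * w_min  # vertical hops in the left auxiliary column
    cost += 2.0 - (1.0 + prob_map[rows[0], 0]) + w_min
    for c in range(1, w):
        cost += 2.0 - (prob_map[rows[c - 1], c - 1] + prob_map[rows[c], c]) + w_min
    cost += 2.0 - (prob_map[rows[-1], w - 1] + 1.0) + w_min
    cost += (h - 1 - exit_aux) * w_min
    return float(cost)


def patch_probability_maps(model, scan: BScan, spec: PatchSpec,
                           crop: CropRegion, batch_size: int = 2048,
                           ) -> dict[str, np.ndarray]:
    """Dense patch classification of every crop-region pixel.

    Returns one H x W map per boundary (ILM, RPE, CSI); entries outside
    the crop columns are zero.  ``map[r, c]`` is the classifier's
    probability that the patch anchored at (r, c) is centred on that
    boundary.
    """
    h, w = scan.height, scan.width
    cols = crop.columns(w)
    maps = {name: np.zeros((h, w)) for name in BOUNDARY_NAMES}
    anchors = np.array([(r, c) for r in range(h) for c in cols])
    for start in range(0, len(anchors), batch_size):
        chunk = anchors[start:start + batch_size]
        patches = extract_patches(scan, chunk, spec)
        x = Tensor((patches[:, None] / 255.0).astype(np.float32))
        logits = model(x, training=False)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=1, keepdims=True)
        for b, name in enumerate(BOUNDARY_NAMES):
            maps[name][chunk[:, 0], chunk[:, 1]] = probs[:, b]
    return maps


def semantic_boundary_maps(area_probs: np.ndarray) -> dict[str, np.ndarray]:
    """Convert area-class probabilities (H, W, 4) to boundary maps.

    For the boundary separating region a (above) from region a+1 (below),
    the map is the positive part of the vertical Sobel response of the
    region-(a+1) probability plane, rescaled to [0, 1] by its maximum.

    The Sobel response to a probability step between rows b-1 and b is a
    two-row plateau straddling the half-pixel transition, and which of the
    two rows wins the argmax is decided by noise.  The response is
    therefore aligned by summing each adjacent row pair and assigning the
    sum to the lower row: a crisp step then peaks uniquely at row b, the
    first row of the deeper region, which is the boundary-row convention.
    """
    area_probs = np.asarray(area_probs, dtype=float)
    if area_probs.ndim != 3 or area_probs.shape[2] < 4:
        raise ValueError("area probabilities must have shape (H, W, 4)")
    maps = {}
    for b, name in enumerate(BOUNDARY_NAMES):
        plane = area_probs[:, :, b + 1]
        grad = ndimage.sobel(plane, axis=0, mode="nearest")
        grad = np.maximum(grad, 0.0)
        aligned = np.zeros_like(grad)
        aligned[1:, :] = grad[:-1, :] + grad[1:, :]  # pair-sum to lower row
        peak = aligned.max()
        if peak > 0:
            aligned /= peak
        maps[name] = aligned
    return maps


def segment_scan(model, method: str, scan: BScan,
                 spec: PatchSpec | None = None,
                 crop: CropRegion | None = None) -> BoundarySet:
    """Full segmentation chain: probability maps -> per-boundary graph search.

    ``method`` is ``"patch"`` (dense patch classification; needs ``spec``
    and ``crop``) or ``"semantic"`` (one forward pass of a U-Net).  The
    graph search always runs on the full-size maps.  The three boundaries
    are searched independently; an anatomical ordering violation in the
    result is logged as a warning, not an error.
    """
    if method == "patch":
        if spec is None or crop is None:
            raise ValueError("patch method needs a PatchSpec and CropRegion")
        maps = patch_probability_maps(model, scan, spec, crop)
    elif method == "semantic":
        if not isinstance(model, UNet):
            raise ValueError("semantic method needs a semantic (U-Net) model")
        maps = semantic_boundary_maps(model.predict_probs(scan.pixels))
    else:
        raise ValueError("method must be 'patch' or 'semantic'")

    rows = {name: shortest_path_boundary(maps[name]).astype(float)
            for name in BOUNDARY_NAMES}
    result = BoundarySet(rows["ilm"], rows["rpe"], rows["csi"])
    ordered = (result.ilm < result.rpe) & (result.rpe < result.csi)
    if not ordered.all():
        logger.warning(
            "%s: boundary ordering violated at %d of %d columns "
            "(boundaries are searched independently)",
            scan.identifier, int((~ordered).sum()), scan.width)
    return result
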