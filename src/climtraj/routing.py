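"""Least-cost routing over the grid graph.

Pixels are graph nodes; adjacent pixels (8- or 4-neighbourhood) are joined
by an edge whose weight is the mean of the two pixel costs times the edge
length (``pixel_size`` km for cardinal moves, ``sqrt(2) * pixel_size`` for
diagonal moves).  Accumulated cost is exact single-source Dijkstra
(scipy.sparse.csgraph); all weights are positive.

This edge-weight definition makes two identities hold exactly along any
extracted path: the sum of per-pixel traversal lengths ``l_i`` equals the
path length (MED), and the sum of ``cost_i * l_i`` equals the accumulated
cost — the accounting that lets the exposure module recover °C of
dissimilarity by subtracting MED from the accumulated cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .cost import CostSurface
from .grids import MethodParams

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class Trajectory:
    """An extracted least-exposure path from a source to its destination.

    ``lengths`` holds the per-pixel traversal length ``l_i`` (km): half the
    summed lengths of the path edges incident to each pixel, so endpoints
    carry one half-edge and a diagonal traversal is longer than a cardinal
    one.  ``sum(lengths)`` is the minimum exposure distance (MED) and
    ``sum(costs * lengths)`` equals ``accumulated_cost``.
    """

    source: tuple[int, int]
    destination: tuple[int, int]
    path: np.ndarray                  # (n, 2) row/col indices, source first
    lengths: np.ndarray               # per-pixel l_i, km
    costs: np.ndarray                 # per-pixel cost from the cost surface
    accumulated_cost: float
    med: float
    ed: float | None = None

    def __len__(self) -> int:
        return len(self.path)


def _offsets(neighbourhood: int):
    offs = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbourhood == 8:
        offs += [(1, 1, _SQRT2), (1, -1, _SQRT2)]
    return offs


def build_graph(cost_surface: CostSurface | np.ndarray, pixel_size: float,
                neighbourhood: int = 8) -> sparse.csr_matrix:
    """Sparse symmetric weighted adjacency of the routable grid.

    Pixels with non-finite cost (nodata) get no edges.
    """
    costs = cost_surface.costs if isinstance(cost_surface, CostSurface) \
        else np.asarray(cost_surface, dtype=float)
    nrow, ncol = costs.shape
    n = nrow * ncol
    idx = np.arange(n).reshape(nrow, ncol)
    rows, cols, data = [], [], []
    for dr, dc, f in _offsets(neighbourhood):
        a_r = slice(max(0, -dr), nrow - max(0, dr))
        a_c = slice(max(0, -dc), ncol - max(0, dc))
        b_r = slice(max(0, dr), nrow - max(0, -dr))
        b_c = slice(max(0, dc), ncol - max(0, -dc))
        ca, cb = costs[a_r, a_c], costs[b_r, b_c]
        ok = np.isfinite(ca) & np.isfinite(cb)
        w = 0.5 * (ca + cb) * (f * pixel_size)
        rows.append(idx[a_r, a_c][ok])
        cols.append(idx[b_r, b_c][ok])
        data.append(w[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def accumulated_cost(cost_surface: CostSurface, source: tuple[int, int],
                     params: MethodParams | None = None,
                     pixel_size: float = 1.0,
                     graph: sparse.csr_matrix | None = None):
    """Single-source accumulated-cost field and predecessor structure.

    Returns ``(acc, predecessors)`` where ``acc`` is a 2D array of least
    accumulated cost from ``source`` to every pixel (inf where unreachable)
    and ``predecessors`` is the flat-index predecessor array for path
    extraction.  The source must be a routable land pixel.
    """
    params = params or MethodParams()
    costs = cost_surface.costs
    nrow, ncol = costs.shape
    r, c = source
    if not np.isfinite(costs[r, c]):
        raise ValueError(f"source pixel {source} is nodata and cannot be routed")
    if costs[r, c] >= params.water_cost:
        raise ValueError(f"source pixel {source} is water and cannot be a source")
    if graph is None:
        graph = build_graph(cost_surface, pixel_size, params.neighbourhood)
    acc, pred = _dijkstra(graph, directed=False, indices=r * ncol + c,
                          return_predecessors=True)
    return acc.reshape(nrow, ncol), pred


def dijkstra_batch(graph: sparse.csr_matrix, sources: np.ndarray):
    """Dijkstra from several sources at once; rows align with ``sources``."""
    acc, pred = _dijkstra(graph, directed=False, indices=np.asarray(sources),
                          return_predecessors=True)
    if acc.ndim == 1:
        acc, pred = acc[None, :], pred[None, :]
    return acc, pred


def _tie_break(candidates: np.ndarray, acc_values: np.ndarray,
               d2_values: np.ndarray):
    """Deterministic argmin: least accumulated cost, then least squared
    pixel distance (ED), then row-major order."""
    amin = acc_values.min()
    tol = 1e-9 * max(1.0, abs(amin))
    near = acc_values <= amin + tol
    cand, d2 = candidates[near], d2_values[near]
    order = np.lexsort((cand, d2))
    return int(cand[order[0]])


def select_destination(acc: np.ndarray, analogue_mask: np.ndarray,
                       source: tuple[int, int]):
    """Destination = analogue pixel with least accumulated cost.

    Ties broken by smaller straight-line distance to the source, then
    row-major pixel order.  Returns ``None`` when the analogue set is empty
    or entirely unreachable (the caller flags the source pixel instead of
    failing).
    """
    nrow, ncol = acc.shape
    flat = np.flatnonzero(analogue_mask.ravel())
    if flat.size == 0:
        return None
    vals = acc.ravel()[flat]
    ok = np.isfinite(vals)
    if not ok.any():
        return None
    flat, vals = flat[ok], vals[ok]
    rr, cc = np.divmod(flat, ncol)
    d2 = (rr - source[0]) ** 2 + (cc - source[1]) ** 2
    best = _tie_break(flat, vals, d2)
    return best // ncol, best % ncol


def nearest_euclidean(source: tuple[int, int], analogue_mask: np.ndarray,
                      pixel_size: float):
    """Straight-line nearest analogue: ``(destination, ED in km)``.

    Centre-to-centre planar distance; squared distances are integers in
    pixel units, so ties are exact and broken row-major.  Returns
    ``(None, None)`` for an empty analogue set.
    """
    ncol = analogue_mask.shape[1]
    flat = np.flatnonzero(analogue_mask.ravel())
    if flat.size == 0:
        return None, None
    rr, cc = np.divmod(flat, ncol)
    d2 = (rr - source[0]) ** 2 + (cc - source[1]) ** 2
    order = np.lexsort((flat, d2))
    best = int(flat[order[0]])
    ed = float(np.sqrt(d2[order[0]])) * pixel_size
    return (best // ncol, best % ncol), ed


def extract_path(predecessors: np.ndarray, source: tuple[int, int],
                 destination: tuple[int, int], cost_surface: CostSurface,
                 pixel_size: float, acc_at_destination: float | None = None
                 ) -> Trajectory:
    """Walk the predecessor structure from destination back to source.

    Produces the ordered pixel path with per-pixel traversal lengths
    (half-edge accounting) satisfying ``sum(l_i) = MED`` and
    ``sum(cost_i * l_i) = accumulated_cost`` exactly up to float summation.
    """
    costs = cost_surface.costs
    nrow, ncol = costs.shape
    s = source[0] * ncol + source[1]
    d = destination[0] * ncol + destination[1]
    chain = [d]
    while chain[-1] != s:
        p = predecessors[chain[-1]]
        if p < 0:
            raise ValueError(
                f"destination {destination} unreachable from source {source}")
        chain.append(int(p))
    chain.reverse()
    path = np.array([(i // ncol, i % ncol) for i in chain])
    n = len(chain)
    lengths = np.zeros(n)
    if n > 1:
        steps = np.abs(np.diff(path, axis=0))
        elen = np.where(steps.sum(axis=1) == 2, _SQRT2, 1.0) * pixel_size
        lengths[:-1] += 0.5 * elen
        lengths[1:] += 0.5 * elen
    pcosts = costs[path[:, 0], path[:, 1]]
    med = float(lengths.sum())
    acc = float(np.sum(pcosts * lengths)) if acc_at_destination is None \
        else float(acc_at_destination)
    return Trajectory(source=tuple(source), destination=tuple(destination),
                      path=path, lengths=lengths, costs=pcosts,
                      accumulated_cost=acc, med=med)
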