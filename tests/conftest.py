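"""Shared fixtures and the independent brute-force routing oracle.

The oracle builds the grid graph explicitly with networkx and runs its
Dijkstra — a fully independent route from the scipy.sparse.csgraph path used
by the package — so routing results can be cross-checked on small grids.
"""

import networkx as nx
import numpy as np
import pytest

from climtraj import MethodParams, make_flat_gradient, make_peninsula, \
    make_ridge_valley

SQRT2 = float(np.sqrt(2.0))


def oracle_graph(costs, pixel_size, neighbourhood=8):
    """Explicit weighted grid graph: edge = mean endpoint cost * length."""
    nrow, ncol = costs.shape
    g = nx.Graph()
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbourhood == 8:
        offsets += [(1, 1, SQRT2), (1, -1, SQRT2)]
    for r in range(nrow):
        for c in range(ncol):
            if not np.isfinite(costs[r, c]):
                continue
            g.add_node((r, c))
            for dr, dc, f in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and np.isfinite(costs[rr, cc]):
                    w = 0.5 * (costs[r, c] + costs[rr, cc]) * f * pixel_size
                    g.add_edge((r, c), (rr, cc), weight=w)
    return g


def oracle_distances(costs, pixel_size, source, neighbourhood=8):
    """Single-source least accumulated cost to every pixel (dict)."""
    g = oracle_graph(costs, pixel_size, neighbourhood)
    return nx.single_source_dijkstra_path_length(g, source)


@pytest.fixture(scope="session")
def default_params():
    return MethodParams()


@pytest.fixture(scope="session")
def flat_pair():
    return make_flat_gradient(shape=(40, 10), pixel_size=5.0,
                              gradient=0.05, warming=1.0)


@pytest.fixture(scope="session")
def ridge_pair():
    return make_ridge_valley(valley_width=1)


@pytest.fixture(scope="session")
def peninsula_pair():
    return make_peninsula()
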