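"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the
implementation it checks: dense exhaustive grid search for the spring
equilibrium, a naive double-loop kernel sum for density grids, and a
direct linear solve for the synonym-only centroid fixed point.
"""

from __future__ import annotations

import numpy as np


def grid_search_equilibrium(syn_neighbors, ant_neighbors, config,
                            syn_weights=None, ant_weights=None,
                            step: float = 0.001):
    """Exhaustive minimisation of the node spring energy on a dense grid
    over [-2, 2]^2.  Returns (position, energy) at the best grid node.

    The synonym part is separable across axes and evaluated as an outer
    sum; each antonym term is evaluated on the full grid.
    """
    syn = np.asarray(list(syn_neighbors), dtype=float).reshape(-1, 2)
    ant = np.asarray(list(ant_neighbors), dtype=float).reshape(-1, 2)
    sw = np.ones(len(syn)) if syn_weights is None else np.asarray(syn_weights, float)
    aw = np.ones(len(ant)) if ant_weights is None else np.asarray(ant_weights, float)
    ax = np.arange(-2.0, 2.0 + step / 2, step)
    E = np.zeros((len(ax), len(ax)))
    if len(syn):
        ex = 0.5 * config.k_syn * (sw * (ax[:, None] - syn[None, :, 0]) ** 2).sum(axis=1)
        ey = 0.5 * config.k_syn * (sw * (ax[:, None] - syn[None, :, 1]) ** 2).sum(axis=1)
        E += ex[:, None]
        E += ey[None, :]
    for (qx, qy), w in zip(ant, aw):
        d = np.sqrt((ax - qx)[:, None] ** 2 + (ax - qy)[None, :] ** 2)
        pen = np.maximum(config.antonym_rest_length - d, 0.0)
        E += 0.5 * config.k_ant * w * pen ** 2
    flat = int(E.argmin())
    i, j = divmod(flat, len(ax))
    return (float(ax[i]), float(ax[j])), float(E[i, j])


def direct_kernel_sum(points, bandwidth, x, y):
    """Naive double-loop Gaussian kernel sum on the grid nodes (no
    normalisation): the reference for density_grid's vectorised path."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    bx, by = bandwidth
    out = np.zeros((len(x), len(y)))
    for i, xv in enumerate(x):
        for j, yv in enumerate(y):
            s = 0.0
            for px, py in points:
                s += np.exp(-0.5 * (((xv - px) / bx) ** 2
                                    + ((yv - py) / by) ** 2))
            out[i, j] = s / (2 * np.pi * bx * by * len(points))
    return out


def centroid_fixed_point(lexicon, graph, weight_by_sources=True):
    """Solve the synonym-only equilibrium exactly as a linear system.

    With k_ant = 0 the converged position of every non-anchor equals the
    weighted average of its neighbours' positions; that fixed point is
    the solution of a Laplacian system with anchors as boundary values.
    Only valid when every non-anchor is connected to an anchor through
    synonym edges.
    """
    keys = [e.key for e in lexicon]
    idx = {k: i for i, k in enumerate(keys)}
    fixed = {i for i, k in enumerate(keys) if lexicon[k].anchor}
    # only words synonym-connected to an anchor are determined; pin the rest
    reachable = set(fixed)
    frontier = list(fixed)
    while frontier:
        i = frontier.pop()
        for nbr, relation, _ in graph.neighbors(keys[i]):
            j = idx[nbr]
            if relation == "synonym" and j not in reachable:
                reachable.add(j)
                frontier.append(j)
    n = len(keys)
    A = np.zeros((n, n))
    b = np.zeros((n, 2))
    for i, k in enumerate(keys):
        if i in fixed:
            A[i, i] = 1.0
            b[i] = lexicon[k].position
            continue
        if i not in reachable:
            A[i, i] = 1.0
            continue
        wsum = 0.0
        for nbr, relation, sources in graph.neighbors(k):
            if relation != "synonym":
                continue
            w = float(sources) if weight_by_sources else 1.0
            A[i, idx[nbr]] -= w
            wsum += w
        A[i, i] += wsum
    sol = np.linalg.solve(A, b)
    return {k: (float(sol[i, 0]), float(sol[i, 1])) for i, k in enumerate(keys)}
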