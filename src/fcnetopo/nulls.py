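"""Surrogate random networks and small-world normalization.

The null model is degree-preserving Maslov-Sneppen double-edge rewiring: the
topology is randomized by repeated two-edge swaps that keep every node's
degree exact, then the original weight multiset is reassigned to the surrogate
edges in random order.  Normalized clustering and path length divide the
empirical values by the surrogate-distribution means; their ratio is the
small-world index.

An Erdős–Rényi same-density alternative (same node and edge count, shuffled
weights) is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from fcnetopo.graph import WeightedGraph
from fcnetopo.metrics import (
    characteristic_path_length,
    shortest_path_lengths,
    weighted_clustering,
)


@dataclass(frozen=True)
class SurrogateSpec:
    n_surrogates: int = 500
    rewires_per_edge: int = 10
    seed: int = 0
    null_model: str = "rewire"  # or "erdos_renyi"

    def validate(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.rewires_per_edge < 1:
            raise ValueError("rewires_per_edge must be >= 1")
        if self.null_model not in ("rewire", "erdos_renyi"):
            raise ValueError("null_model must be 'rewire' or 'erdos_renyi'")


def _graph_from_edges(n: int, edges: np.ndarray, weights: np.ndarray) -> WeightedGraph:
    W = np.zeros((n, n))
    W[edges[:, 0], edges[:, 1]] = weights
    W[edges[:, 1], edges[:, 0]] = weights
    return WeightedGraph(W)


def rewire_surrogate(
    g: WeightedGraph,
    seed: int | np.random.Generator,
    rewires_per_edge: int = 10,
) -> WeightedGraph:
    """Degree-preserving randomized surrogate of ``g``.

    Attempts ``rewires_per_edge * n_edges`` double-edge swaps; swaps that
    would create a self-loop or duplicate edge are rejected.  After topology
    randomization the original weight multiset is shuffled onto the surrogate
    edges.  If no legal swap exists (e.g. a complete graph), the surrogate is
    a weight-shuffled copy and a warning is issued.
    """
    edges = np.array([(i, j) for i, j, _ in g.edge_list()], dtype=int)
    m = len(edges)
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    adj = {i: set() for i in range(g.n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    n_attempts = rewires_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    successes = 0
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].remove(b), adj[b].remove(a)
        adj[c].remove(d), adj[d].remove(c)
        adj[a].add(d), adj[d].add(a)
        adj[c].add(b), adj[b].add(c)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        successes += 1
    if successes == 0:
        warnings.warn(
            "no legal edge swap found; returning weight-shuffled copy", stacklevel=2
        )
    weights = np.array([w for _, _, w in g.edge_list()])
    rng.shuffle(weights)
    surr = _graph_from_edges(g.n_nodes, edges, weights)
    surr.meta.update(null_model="rewire", rewires_per_edge=rewires_per_edge, swaps=successes)
    return surr


def erdos_renyi_surrogate(g: WeightedGraph, seed: int | np.random.Generator) -> WeightedGraph:
    """Same node and edge count, uniformly random topology, shuffled weights."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, m = g.n_nodes, g.n_edges
    iu = np.triu_indices(n, k=1)
    chosen = rng.choice(len(iu[0]), size=m, replace=False)
    edges = np.column_stack([iu[0][chosen], iu[1][chosen]])
    weights = np.array([w for _, _, w in g.edge_list()])
    rng.shuffle(weights)
    surr = _graph_from_edges(n, edges, weights)
    surr.meta.update(null_model="erdos_renyi")
    return surr


def normalized_metrics(
    g: WeightedGraph,
    spec: SurrogateSpec,
    clustering_variant: str = "onnela",
    length_map: str = "inverse",
    return_distributions: bool = False,
):
    """Surrogate-normalized clustering, path length, and small-world index.

    C_norm = C / mean(C_surrogate); L_norm = L / mean(L_surrogate);
    small_world = C_norm / L_norm.  Surrogate seeds derive deterministically
    from ``spec.seed``.  Disconnected surrogate pairs are excluded from L the
    same way as in the empirical graph.
    """
    spec.validate()
    _, c_emp = weighted_clustering(g, clustering_variant)
    l_emp, _ = characteristic_path_length(shortest_path_lengths(g, length_map))

    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_surrogates)
    c_surr = np.empty(spec.n_surrogates)
    l_surr = np.empty(spec.n_surrogates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rigid graphs warn once per surrogate
        for k, child in enumerate(child_seeds):
            rng = np.random.default_rng(child)
            if spec.null_model == "rewire":
                surr = rewire_surrogate(g, rng, spec.rewires_per_edge)
            else:
                surr = erdos_renyi_surrogate(g, rng)
            _, c_surr[k] = weighted_clustering(surr, clustering_variant)
            l_surr[k], _ = characteristic_path_length(
                shortest_path_lengths(surr, length_map)
            )

    c_bar, l_bar = c_surr.mean(), l_surr.mean()
    if c_bar == 0 or l_bar == 0:
        raise ValueError("mean surrogate clustering or path length is zero")
    c_norm = c_emp / c_bar
    l_norm = l_emp / l_bar
    sw = c_norm / l_norm
    if return_distributions:
        return c_norm, l_norm, sw, c_surr, l_surr
    return c_norm, l_norm, sw
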