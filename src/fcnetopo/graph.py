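"""Sign-mode handling and thresholding of connectivity matrices.

Two sign modes mirror the two parallel analyses: ``positive_only`` discards
anticorrelations and keeps weights w > tau; ``absolute`` treats
anticorrelations as connectivity strength and keeps |w| > tau at weight |w|.
The threshold excludes the open interval (-tau, +tau) strictly: a weight
exactly equal to tau is excluded.  Thresholds apply to the Fisher-z weights.
Isolated nodes are retained so nodal metric vectors always have length
n_nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from fcnetopo.connectivity import ConnectivityMatrix

SIGN_MODES = ("positive_only", "absolute")
DEFAULT_TAU_GRID = (0.0, 0.125, 0.25, 0.375)


@dataclass(frozen=True)
class ThresholdSpec:
    tau: float = 0.25
    sign_mode: str = "absolute"

    def validate(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sign_mode not in SIGN_MODES:
            raise ValueError(f"sign_mode must be one of {SIGN_MODES}")


@dataclass
class WeightedGraph:
    """Undirected weighted graph on a fixed node set.

    Stored as a dense symmetric weight matrix with zeros for absent edges; all
    retained weights are strictly positive after sign-mode mapping.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if (W < 0).any():
            raise ValueError("edge weights must be positive (apply a sign mode first)")
        if np.diag(W).any():
            raise ValueError("self-loops are not allowed")
        self.weights = W
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(W.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        for i, j, w in self.edge_list():
            G.add_edge(i, j, weight=w, length=1.0 / w)
        return G


def apply_threshold(cm: ConnectivityMatrix, spec: ThresholdSpec) -> WeightedGraph:
    """Map a connectivity matrix to a weighted graph in one sign mode.

    ``positive_only``: keep w > tau at weight w.  ``absolute``: keep |w| > tau
    at weight |w|.  Edge count and density are recorded in the graph metadata.
    """
    spec.validate()
    W = cm.weights.copy()
    if spec.sign_mode == "absolute":
        W = np.abs(W)
        keep = W > spec.tau
    else:
        keep = W > spec.tau
    W = np.where(keep, W, 0.0)
    np.fill_diagonal(W, 0.0)
    g = WeightedGraph(W, list(cm.node_labels))
    g.meta.update(
        tau=spec.tau,
        sign_mode=spec.sign_mode,
        subject_id=cm.subject_id,
        n_edges=g.n_edges,
        density=graph_density(g),
    )
    return g


def graph_density(g: WeightedGraph) -> float:
    """Fraction of possible edges present: edges / (n(n-1)/2)."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return g.n_edges / (n * (n - 1) / 2)


def write_edgelist(g: WeightedGraph, path: str | Path) -> None:
    """Edge-list TSV (i, j, weight) with a header recording graph provenance."""
    with open(path, "w") as fh:
        fh.write(
            f"# n_nodes={g.n_nodes} tau={g.meta.get('tau')} "
            f"sign_mode={g.meta.get('sign_mode')} subject={g.meta.get('subject_id', '')}\n"
        )
        fh.write("i\tj\tweight\n")
        for i, j, w in g.edge_list():
            fh.write(f"{i}\t{j}\t{w:.10g}\n")


def read_edgelist(path: str | Path) -> WeightedGraph:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing provenance header")
        kv = dict(item.split("=", 1) for item in header[1:].split() if "=" in item)
        n = int(kv["n_nodes"])
        fh.readline()  # column names
        W = np.zeros((n, n))
        for line in fh:
            i, j, w = line.split("\t")
            W[int(i), int(j)] = W[int(j), int(i)] = float(w)
    g = WeightedGraph(W)
    g.meta.update(
        tau=float(kv["tau"]) if kv.get("tau") not in (None, "None") else None,
        sign_mode=kv.get("sign_mode"),
        subject_id=kv.get("subject", ""),
    )
    return g
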