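"""Weighted functional connectivity: Pearson correlation and Fisher z weights.

The connectivity matrix Z holds Fisher-transformed (atanh) Pearson
correlations between every pair of node time series.  The diagonal is
undefined by convention and stored as 0; it is excluded from all downstream
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fcnetopo.preprocess import BandpassSpec, bandpass_filter, regress_confounds

_R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node matrix of Fisher-z connectivity weights."""

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric (within 1e-12)")
        if not np.isfinite(W).all():
            raise ValueError("weights must be finite")
        self.weights = W
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(W.shape[0])]
        elif len(self.node_labels) != W.shape[0]:
            raise ValueError("node_labels length must match matrix dimension")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def pearson_matrix(ts: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of node time series (nodes x time)."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D nodes x time matrix")
    if ts.shape[1] < 3:
        raise ValueError(f"need at least 3 time points (got {ts.shape[1]})")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node series at indices {dead.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(
    r_matrix: np.ndarray,
    node_labels: list[str] | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Fisher z transform (atanh) of a correlation matrix.

    |r| is clamped to 1 - 1e-7 before the transform so weights stay finite;
    the diagonal is set to 0.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.abs(r).max() > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, node_labels or [], subject_id)


def connectivity_from_timeseries(
    ts: np.ndarray,
    confounds: np.ndarray | None = None,
    bandpass: BandpassSpec | None = None,
    node_labels: list[str] | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Full per-subject connectivity construction.

    Order is fixed: confound regression, band-pass filter, Pearson
    correlation, Fisher z.  The steps and parameters actually applied are
    recorded in the output's ``meta`` for provenance.
    """
    steps: list[str] = []
    out = np.asarray(ts, dtype=float)
    if confounds is not None and np.size(confounds):
        out = regress_confounds(out, confounds)
        steps.append(f"regress_confounds(k={np.atleast_2d(confounds).shape[0]})")
    if bandpass is not None:
        out = bandpass_filter(out, bandpass)
        steps.append(f"bandpass({bandpass.low_hz}-{bandpass.high_hz}Hz,tr={bandpass.tr})")
    steps += ["pearson", "fisher_z"]
    cm = fisher_z(pearson_matrix(out), node_labels, subject_id)
    cm.meta["steps"] = steps
    return cm


def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Square TSV with node labels as first row and column."""
    frame = pd.DataFrame(cm.weights, index=cm.node_labels, columns=cm.node_labels)
    frame.to_csv(path, sep="\t")


def read_matrix(path: str | Path, subject_id: str = "") -> ConnectivityMatrix:
    """Read a labeled square TSV; validates symmetry and shape."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return ConnectivityMatrix(
        frame.to_numpy(dtype=float), [str(c) for c in frame.columns], subject_id
    )
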