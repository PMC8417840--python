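"""Temporal preprocessing of parcellated BOLD time series.

Covers the stages that act on already-parcellated signals: nuisance
(confound) regression, CompCor-style principal-component extraction from
noise-region signals, zero-phase band-pass filtering, and motion quality
control.  The pipeline order is fixed: regress confounds first, then
band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandpassSpec:
    """Pass band in Hz for signals sampled every ``tr`` seconds.

    Defaults bracket the 0.01-0.08 Hz band conventionally taken to carry
    resting-state fluctuations.
    """

    low_hz: float = 0.01
    high_hz: float = 0.08
    tr: float = 2.0

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"require 0 <= low_hz < high_hz (got {self.low_hz}, {self.high_hz})")
        if self.high_hz > nyquist:
            raise ValueError(f"high_hz {self.high_hz} exceeds Nyquist {nyquist:.4g} Hz at TR={self.tr}")


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Indices of a maximal linearly independent subset of columns (greedy,
    left to right, via rank-revealing QR on the growing subset)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    return np.array(keep, dtype=int)


def regress_confounds(ts: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """Residualize each node series against the confound regressors.

    ``ts`` is nodes x time; ``confounds`` is regressors x time (may be empty
    or None).  An intercept is always appended, so the output is demeaned even
    with no confounds.  Rank-deficient confound sets are reduced to an
    independent subset with a warning.  Residuals are exactly orthogonal to
    every retained regressor.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[1]
    if confounds is None or confounds.size == 0:
        X = np.ones((T, 1))
    else:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[1] != T:
            raise ValueError(
                f"confounds have {confounds.shape[1]} time points, series have {T}"
            )
        X = np.column_stack([np.ones(T), confounds.T])
        keep = _independent_columns(X)
        if len(keep) < X.shape[1]:
            dropped = sorted(set(range(X.shape[1])) - set(keep))
            warnings.warn(
                f"confound matrix is rank deficient; dropping dependent columns {dropped}",
                stacklevel=2,
            )
            X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def compcor_components(noise_roi_ts: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component time courses of noise-region signals (aCompCor style).

    Input is signals x time.  Each signal is demeaned and variance-normalized,
    then the top right singular vectors (component time courses, by explained
    variance) are returned as a regressors x time matrix.  Components are
    mutually orthogonal; the sign convention makes the largest-magnitude
    signal loading positive, so results are deterministic.
    """
    X = np.asarray(noise_roi_ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("noise_roi_ts must be a 2-D signals x time matrix")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        n_components = rank
    comps = Vt[:n_components].copy()
    for i in range(n_components):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            comps[i] *= -1.0
    return comps


def bandpass_filter(ts: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase band-pass filter along the time axis.

    4th-order Butterworth applied forward and backward (``filtfilt``), so the
    phase response is flat and inter-regional correlation structure is not
    distorted by phase shifts.
    """
    spec.validate()
    ts = np.asarray(ts, dtype=float)
    if ts.shape[-1] < 16:
        raise ValueError("need at least 16 time points to band-pass filter")
    fs = 1.0 / spec.tr
    sos = signal.butter(
        4, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    # even-extension padding keeps edge transients from leaking stop-band power
    return signal.sosfiltfilt(sos, ts, axis=-1, padtype="even")


def motion_rms(params: np.ndarray) -> float:
    """Mean per-volume translation displacement magnitude, in mm.

    ``params`` is volumes x 6 (tx, ty, tz in mm; rx, ry, rz in degrees); only
    the translations enter, as a single summary in mm.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion params must be volumes x 6")
    disp = np.linalg.norm(params[:, :3], axis=1)
    return float(disp.mean())


_AXES = ("tx", "ty", "tz", "rx", "ry", "rz")


def motion_exclude(params: np.ndarray) -> tuple[bool, str]:
    """Exclusion rule: any translation > 3 mm or any rotation > 1 degree.

    Strict inequalities: a volume at exactly 3 mm or 1 degree is kept.
    Returns ``(exclude, reason)``; the reason names the first offending volume
    and axis.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion params must be volumes x 6")
    limits = np.array([3.0, 3.0, 3.0, 1.0, 1.0, 1.0])
    over = np.abs(params) > limits
    if over.any():
        vol, axis = np.argwhere(over)[0]
        unit = "mm" if axis < 3 else "deg"
        return True, (
            f"volume {vol}: |{_AXES[axis]}| = {abs(params[vol, axis]):.3g} {unit} "
            f"exceeds {limits[axis]:g} {unit}"
        )
    return False, "within motion limits"
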