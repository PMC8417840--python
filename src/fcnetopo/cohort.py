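"""Synthetic multi-group cohort generator for parcellated BOLD time series.

The generator emulates a three-group resting-state fMRI cohort (well-controlled
IGE, drug-resistant IGE, healthy controls: 10 / 23 / 34 subjects) scanned with a
384-region parcellation, 180 volumes at TR = 2 s.  Each group has a block-modular
population correlation matrix; subject time series are multivariate Gaussian
draws from it, optionally contaminated with shared confound signals.  Group
effects enter as additive shifts to within-module correlation, which raises
overall connectivity — the direction of effect the pipeline is designed to
detect downstream.

All randomness flows from a single master seed; subject ``i`` draws from
``seed + i`` so cohorts are reproducible and subjects independent.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("WC", "DR", "CTRL")

_EIG_FLOOR = 1e-6


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Correlation levels are Pearson r in the population matrix.
    ``group_connectivity_shift`` is added to within-module correlations of that
    group; positive shifts in the patient groups emulate the globally elevated
    connectivity reported in generalized epilepsy.
    """

    n_nodes: int = 384
    n_timepoints: int = 180
    tr: float = 2.0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"WC": 10, "DR": 23, "CTRL": 34}
    )
    n_modules: int = 8
    base_within_r: float = 0.35
    base_between_r: float = 0.10
    group_connectivity_shift: dict[str, float] = field(
        default_factory=lambda: {"WC": 0.08, "DR": 0.08, "CTRL": 0.0}
    )
    negative_block_fraction: float = 0.2
    confound_amplitude: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        shifted = [self.base_within_r + s for s in self.group_connectivity_shift.values()]
        if not all(0 <= v < 1 for v in shifted):
            raise ValueError("within-module correlation (base + shift) must stay in [0, 1)")
        if not 0 <= self.base_between_r < 1:
            raise ValueError("base_between_r must be in [0, 1)")
        if not 0 <= self.negative_block_fraction <= 1:
            raise ValueError("negative_block_fraction must be in [0, 1]")
        if self.confound_amplitude < 0:
            raise ValueError("confound_amplitude must be >= 0")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 2:
                raise ValueError(f"group {g!r} must have >= 2 subjects (got {n})")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SubjectRecord:
    """Demographics and QC fields for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    onset_age: float | None = None
    n_aeds: int | None = None
    mean_rms_motion: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.onset_age is not None and self.age - self.onset_age < 0:
            raise ValueError(
                f"subject {self.subject_id}: onset_age {self.onset_age} exceeds age {self.age}"
            )

    @property
    def duration(self) -> float | None:
        """Disease duration in years (age - onset age); None for controls."""
        if self.onset_age is None:
            return None
        return self.age - self.onset_age


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal-size module labels for each node."""
    return np.floor(np.arange(n_nodes) * n_modules / n_nodes).astype(int)


def _between_block_signs(n_modules: int, negative_fraction: float, seed: int) -> np.ndarray:
    """Symmetric sign matrix over module pairs; a fixed fraction of the
    off-diagonal blocks is negative.  Deterministic in the spec seed so all
    groups share the same sign pattern."""
    rng = np.random.default_rng(seed)
    signs = np.ones((n_modules, n_modules))
    pairs = [(a, b) for a in range(n_modules) for b in range(a + 1, n_modules)]
    n_neg = int(round(negative_fraction * len(pairs)))
    if n_neg:
        neg_idx = rng.choice(len(pairs), size=n_neg, replace=False)
        for k in neg_idx:
            a, b = pairs[k]
            signs[a, b] = signs[b, a] = -1.0
    return signs


def nearest_positive_definite(corr: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Repair an indefinite correlation matrix by flooring its eigenvalues and
    rescaling back to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.maximum(vals, eig_floor)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_population_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Block-modular population correlation matrix for one group.

    Within-module entries are ``base_within_r + shift(group)``; between-module
    entries are ``±base_between_r`` with signs fixed per module pair.  The
    result is clipped to (-0.99, 0.99) and repaired to positive definiteness
    (eigenvalue floor 1e-6) if needed; repairs are logged.
    """
    spec.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    shift = spec.group_connectivity_shift.get(group, 0.0)
    modules = _module_assignment(spec.n_nodes, spec.n_modules)
    signs = _between_block_signs(spec.n_modules, spec.negative_block_fraction, spec.seed)

    same = modules[:, None] == modules[None, :]
    corr = np.where(
        same,
        spec.base_within_r + shift,
        signs[modules[:, None], modules[None, :]] * spec.base_between_r,
    )
    corr = np.clip(corr, -0.99, 0.99)
    np.fill_diagonal(corr, 1.0)

    min_eig = np.linalg.eigvalsh(corr).min()
    if min_eig < _EIG_FLOOR:
        logger.warning(
            "population correlation for group %s indefinite (min eig %.3g); "
            "applying nearest-positive-definite repair",
            group,
            min_eig,
        )
        corr = nearest_positive_definite(corr)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError(
                f"cannot repair population correlation for group {group!r} "
                f"(base_within_r={spec.base_within_r}, "
                f"base_between_r={spec.base_between_r}, shift={shift})"
            )
    return corr


def sample_timeseries(
    popcorr: np.ndarray, n_timepoints: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a zero-mean Gaussian node x time matrix with the given population
    correlation.  Reproducible given the seed."""
    vals = np.linalg.eigvalsh(popcorr)
    if vals.min() <= 0:
        raise ValueError(f"population correlation not positive definite (min eig {vals.min():.3g})")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chol = np.linalg.cholesky(popcorr)
    return chol @ rng.standard_normal((popcorr.shape[0], n_timepoints))


def _confound_courses(n_confounds: int, n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency drift plus slow sinusoids, each standardized to unit SD.
    Rows are regressors, columns time points."""
    t = np.arange(n_timepoints, dtype=float)
    courses = np.empty((n_confounds, n_timepoints))
    for k in range(n_confounds):
        if k == 0:
            c = t - t.mean()  # linear drift
        else:
            period = n_timepoints / (0.5 + 0.75 * k)  # slow oscillations
            phase = rng.uniform(0, 2 * np.pi)
            c = np.sin(2 * np.pi * t / period + phase)
        c = c - c.mean()
        sd = c.std()
        courses[k] = c / sd if sd > 0 else c
    return courses


def add_confounds(
    ts: np.ndarray,
    n_confounds: int,
    amplitude: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Contaminate a time-series matrix with shared confound signals.

    Each node receives a random linear combination of ``n_confounds`` shared
    time courses (drift + sinusoids), scaled so the added component has a
    standard deviation of about ``amplitude`` times the node's own signal SD.
    Returns the contaminated series and the confound regressor matrix
    (regressors x time), suitable for :func:`fcnetopo.preprocess.regress_confounds`.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    courses = _confound_courses(n_confounds, ts.shape[1], rng)
    if amplitude == 0 or n_confounds == 0:
        return ts.copy(), courses
    # loadings centred on +1: shared noise hits most nodes with the same sign
    # (global-signal-like), so contamination inflates mean pairwise correlation
    loadings = 1.0 + 0.5 * rng.standard_normal((ts.shape[0], n_confounds))
    node_sd = ts.std(axis=1, keepdims=True)
    added = amplitude * node_sd * (loadings @ courses) / np.sqrt(n_confounds)
    return ts + added, courses


def generate_manifest(spec: CohortSpec, seed: int | None = None) -> list[SubjectRecord]:
    """One SubjectRecord per subject; group counts match the spec.

    Patient ages are drawn uniformly from 18-60 y, onset between 2 y and the
    current age, medication counts 1-2 (WC) or 1-4 (DR), roughly 60% female —
    ranges matching the clinical cohort this generator emulates.  Controls have
    no onset age or medication count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        for _ in range(spec.group_sizes.get(group, 0)):
            idx += 1
            age = int(rng.integers(18, 61))
            sex = "F" if rng.random() < 0.6 else "M"
            if group == "CTRL":
                onset: float | None = None
                n_aeds: int | None = None
            else:
                onset = int(rng.integers(2, age))
                n_aeds = int(rng.integers(1, 3 if group == "WC" else 5))
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    onset_age=onset,
                    n_aeds=n_aeds,
                    mean_rms_motion=float(np.abs(rng.normal(0.3, 0.1))),
                )
            )
    return records


def manifest_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "onset_age": [r.onset_age for r in records],
            "n_aeds": [r.n_aeds for r in records],
            "mean_rms_motion": [r.mean_rms_motion for r in records],
        }
    )


def simulate_cohort(
    spec: CohortSpec,
    n_confounds: int = 3,
) -> tuple[list[SubjectRecord], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Generate a full in-memory cohort.

    Returns ``(records, timeseries, confounds)`` where the dicts map subject id
    to the contaminated node x time matrix and to its confound regressor
    matrix.  Subject ``i`` (0-based, in manifest order) uses seed
    ``spec.seed + i + 1``; the manifest uses ``spec.seed`` itself.
    """
    spec.validate()
    records = generate_manifest(spec)
    popcorrs = {g: build_population_correlation(spec, g) for g in GROUPS}
    timeseries: dict[str, np.ndarray] = {}
    confounds: dict[str, np.ndarray] = {}
    for i, rec in enumerate(records):
        subj_seed = spec.seed + i + 1
        ts = sample_timeseries(popcorrs[rec.group], spec.n_timepoints, subj_seed)
        ts_noisy, conf = add_confounds(
            ts, n_confounds, spec.confound_amplitude, subj_seed + spec.n_subjects
        )
        timeseries[rec.subject_id] = ts_noisy
        confounds[rec.subject_id] = conf
    return records, timeseries, confounds


def write_cohort(
    out_dir,
    records: list[SubjectRecord],
    timeseries: dict[str, np.ndarray],
    confounds: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Write per-subject time-series and confound TSVs plus a manifest CSV.

    Time-series files are rows = nodes, columns = time points, no header;
    confound files are rows = regressors.  Returns the manifest frame with
    file paths filled in.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = manifest_to_frame(records)
    ts_paths, conf_paths = [], []
    for rec in records:
        ts_path = out / f"{rec.subject_id}_timeseries.tsv"
        conf_path = out / f"{rec.subject_id}_confounds.tsv"
        np.savetxt(ts_path, timeseries[rec.subject_id], delimiter="\t")
        np.savetxt(conf_path, confounds[rec.subject_id], delimiter="\t")
        ts_paths.append(str(ts_path))
        conf_paths.append(str(conf_path))
    frame["timeseries_path"] = ts_paths
    frame["confounds_path"] = conf_paths
    frame.to_csv(out / "manifest.csv", index=False)
    return frame


def load_reference_demographics() -> pd.DataFrame:
    """Bundled clinical demographics of the IGE reference cohort.

    Columns: subject_id, group (WC = well-controlled, DR = drug-resistant),
    age (years), sex, onset_age (years), n_aeds (number of antiepileptic
    drugs).  Disease duration is ``age - onset_age``.
    """
    ref = importlib.resources.files("fcnetopo.data") / "ige_clinical_details.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
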