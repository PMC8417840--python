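"""Group-level statistical comparison scheme for network metrics.

Implements the study's testing plan over per-subject metrics: Lilliefors
normality screening; Kruskal-Wallis across the three groups (well-controlled
IGE, drug-resistant IGE, controls) or covariate-adjusted linear models
(ANCOVA) as appropriate; pairwise Mann-Whitney tests with a Bonferroni factor
of six; a combined-IGE vs control contrast as an age-controlled t-test
(linear model with age covariate); mass-univariate nodal Mann-Whitney tests
with Benjamini-Hochberg FDR at q = 0.1 plus uncorrected hits with rank-
biserial effect sizes; hub-frequency comparisons; cohort demographics; and
Pearson metric-covariate correlations.

Conventions not pinned down by the reporting style being emulated: the
epilepsy-duration covariate enters only patient-only contrasts (it is
undefined for controls); dummy coding uses the control group (or the first
group present) as reference; the three-group ANCOVA F uses Type-II sums of
squares; the sex chi-square is the Pearson statistic without continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.multitest import multipletests

DEFAULT_BONFERRONI_FACTOR = 6
DEFAULT_FDR_Q = 0.1


@dataclass
class TestResult:
    statistic_name: str  # H, U, F, t, W, r, chi2
    statistic: float
    p: float
    df: float | tuple | None = None
    group_sizes: tuple[int, ...] | None = None
    adjusted_p: float | None = None
    covariates: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


@dataclass(frozen=True)
class ComparisonPlan:
    """Which contrast to run and how to correct it."""

    grouping: str = "three_group"  # or "two_group" (combined IGE vs CTRL)
    covariates: tuple[str, ...] = ("age",)
    bonferroni_factor: int = DEFAULT_BONFERRONI_FACTOR
    fdr_q: float = DEFAULT_FDR_Q

    def validate(self) -> None:
        if self.grouping not in ("three_group", "two_group"):
            raise ValueError("grouping must be 'three_group' or 'two_group'")
        if self.bonferroni_factor < 1:
            raise ValueError("bonferroni_factor must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


def normality_check(x: Sequence[float], alpha: float = 0.05) -> tuple[bool, float, float]:
    """Lilliefors test (KS against a normal with estimated mean/SD).

    Returns ``(is_normal, statistic, p)``; ``is_normal`` is the decision at
    ``alpha``.  Critical values come from the simulated table behind the
    standard implementation.  A constant sample is reported non-normal.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("normality check requires n >= 5")
    if np.ptp(x) == 0:
        return False, np.inf, 0.0
    stat, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return bool(p >= alpha), float(stat), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p, df = groups - 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    if sum(a.size for a in arrays) < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, 1.0, df=len(arrays) - 1,
                          group_sizes=tuple(a.size for a in arrays))
    stat, p = sps.kruskal(*arrays)
    return TestResult("H", float(stat), float(p), df=len(arrays) - 1,
                      group_sizes=tuple(a.size for a in arrays))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact p when min(n) <= 8 and there are no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("U", float(res.statistic), float(res.pvalue),
                      group_sizes=(x.size, y.size), extra={"method": method})


def _design_frame(group: Sequence, covariates: np.ndarray | None,
                  covariate_names: Sequence[str] | None) -> tuple[pd.DataFrame, list[str]]:
    group = pd.Series(group, name="group").astype(str)
    frame = pd.DataFrame({"group": group})
    names: list[str] = []
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(group) and cov.shape[1] != len(group):
            cov = cov.T  # accept subjects x k as well
        if cov.shape[1] != len(group):
            raise ValueError("covariate rows must align with subjects")
        names = list(covariate_names or [f"cov{i}" for i in range(cov.shape[0])])
        for nm, col in zip(names, cov):
            frame[nm] = col
    return frame, names


def ancova(
    metric: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
    reference: str | None = None,
) -> TestResult:
    """Linear model ``metric ~ group + covariates``.

    With three or more groups the result is the Type-II F test on the group
    factor; with two groups it is the t statistic on the group coefficient —
    the covariate-adjusted two-sample test ("t-test controlled for age" when
    age is the covariate).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(metric, dtype=float)
    frame, cov_names = _design_frame(group, covariates, covariate_names)
    frame = frame.copy()
    frame["metric"] = y
    levels = list(pd.unique(frame["group"]))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if y.size <= len(levels) + len(cov_names) + 1:
        raise ValueError("too few subjects for the design")
    ref = reference or ("CTRL" if "CTRL" in levels else levels[0])
    rhs = [f'C(group, Treatment(reference="{ref}"))'] + cov_names
    model = ols("metric ~ " + " + ".join(rhs), data=frame).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(
            f"collinear design columns: {model.model.exog_names}"
        )
    if len(levels) == 2:
        term = [nm for nm in model.params.index if nm.startswith("C(group")][0]
        t = float(model.tvalues[term])
        p = float(model.pvalues[term])
        return TestResult("t", t, p, df=float(model.df_resid),
                          group_sizes=tuple(frame.group.value_counts()[lv] for lv in levels),
                          covariates=tuple(cov_names),
                          extra={"coef": float(model.params[term]),
                                 "residual_ss": float(model.ssr)})
    table = anova_lm(model, typ=2)
    row = [idx for idx in table.index if idx.startswith("C(group")][0]
    F = float(table.loc[row, "F"])
    p = float(table.loc[row, "PR(>F)"])
    df = (float(table.loc[row, "df"]), float(table.loc["Residual", "df"]))
    return TestResult("F", F, p, df=df,
                      group_sizes=tuple(frame.group.value_counts()[lv] for lv in levels),
                      covariates=tuple(cov_names))


def bonferroni(p: float, factor: int = DEFAULT_BONFERRONI_FACTOR) -> float:
    """min(1, p * factor)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return min(1.0, p * factor)


def bh_fdr(p_values: Sequence[float], q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns ``(reject_mask, adjusted_p)`` with the usual monotone adjusted
    values min_{j>=i} m p_(j) / j.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def rank_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-biserial effect size r = 2U/(n1 n2) - 1 (positive: x tends larger)."""
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    return float(2.0 * u / (len(x) * len(y)) - 1.0)


def nodal_comparison(
    nodal: pd.DataFrame,
    groups: Sequence,
    q: float = DEFAULT_FDR_Q,
    alpha_uncorrected: float = 0.05,
) -> pd.DataFrame:
    """Mass-univariate two-group Mann-Whitney tests, one per node.

    ``nodal`` is subjects x nodes (one metric); ``groups`` a two-level label
    per subject.  BH-FDR at ``q`` is applied across the node family; nodes
    significant before correction are flagged with direction and rank-biserial
    effect size, mirroring exploratory reporting when nothing survives FDR.
    """
    groups = np.asarray([str(g) for g in groups])
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    if nodal.shape[0] != len(groups):
        raise ValueError("nodal table rows must align with group labels")
    a = nodal.loc[groups == levels[0]].to_numpy(dtype=float)
    b = nodal.loc[groups == levels[1]].to_numpy(dtype=float)
    rows = []
    for j, col in enumerate(nodal.columns):
        res = mann_whitney(a[:, j], b[:, j])
        rows.append(
            {
                "node": col,
                "U": res.statistic,
                "p": res.p,
                "effect_rank_biserial": rank_biserial(a[:, j], b[:, j]),
                "direction": f"{levels[0]}>{levels[1]}"
                if np.median(a[:, j]) >= np.median(b[:, j])
                else f"{levels[1]}>{levels[0]}",
            }
        )
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p"].to_numpy(), q)
    table["p_fdr"] = p_adj
    table["significant_fdr"] = reject
    table["significant_uncorrected"] = table["p"] < alpha_uncorrected
    return table


def hub_frequency(
    hub_sets: dict[str, set[int]],
    groups: dict[str, str],
    n_nodes: int,
) -> dict:
    """Per-node hub counts per group and group comparisons of hub-set size.

    Returns a dict with the node x group count matrix, per-subject hub-set
    cardinalities, group medians, a three-group Kruskal-Wallis and (when both
    patient groups and controls are present) a combined-IGE vs control
    Mann-Whitney test on cardinality.
    """
    group_levels = sorted(set(groups.values()))
    counts = pd.DataFrame(0, index=range(n_nodes), columns=group_levels)
    card = {}
    for subj, hubs in hub_sets.items():
        grp = groups[subj]
        card[subj] = len(hubs)
        for node in hubs:
            counts.loc[node, grp] += 1
    card_by_group = {
        g: np.array([card[s] for s in hub_sets if groups[s] == g]) for g in group_levels
    }
    medians = {g: float(np.median(v)) if v.size else np.nan for g, v in card_by_group.items()}
    out = {"counts": counts, "cardinality": card, "medians": medians}
    nonempty = [v for v in card_by_group.values() if v.size]
    if len(nonempty) >= 2 and sum(v.size for v in nonempty) >= 5:
        if np.ptp(np.concatenate(nonempty)) == 0:
            out["three_group_test"] = TestResult(
                "H", 0.0, 1.0, df=len(nonempty) - 1,
                group_sizes=tuple(v.size for v in nonempty))
        else:
            out["three_group_test"] = kruskal_wallis(nonempty)
    patient = np.concatenate([card_by_group.get(g, np.array([])) for g in ("WC", "DR")])
    ctrl = card_by_group.get("CTRL", np.array([]))
    if patient.size and ctrl.size:
        if np.ptp(np.concatenate([patient, ctrl])) == 0:
            out["two_group_test"] = TestResult(
                "U", patient.size * ctrl.size / 2.0, 1.0,
                group_sizes=(patient.size, ctrl.size))
        else:
            out["two_group_test"] = mann_whitney(patient, ctrl)
    return out


def cohort_descriptives(manifest: pd.DataFrame) -> dict:
    """Per-group demographics and the demographic hypothesis tests.

    Expects columns subject_id, group, age, sex and optionally onset_age and
    n_aeds.  Duration is age - onset_age.  Reports per-group median age,
    percent female, median duration, mean and range of medication count; a
    Kruskal-Wallis on age across groups and a Pearson chi-square on sex.
    """
    frame = manifest.copy()
    if "onset_age" in frame:
        frame["duration"] = frame["age"] - frame["onset_age"]
    summary = {}
    for grp, sub in frame.groupby("group"):
        entry = {
            "n": int(len(sub)),
            "median_age": float(sub["age"].median()),
            "percent_female": float(100.0 * (sub["sex"] == "F").mean()),
        }
        if "duration" in sub and sub["duration"].notna().any():
            entry["median_duration"] = float(sub["duration"].median())
        if "n_aeds" in sub and sub["n_aeds"].notna().any():
            entry["mean_n_aeds"] = float(sub["n_aeds"].mean())
            entry["aed_range"] = (int(sub["n_aeds"].min()), int(sub["n_aeds"].max()))
        summary[grp] = entry
    tests = {}
    age_groups = [sub["age"].to_numpy(dtype=float) for _, sub in frame.groupby("group")]
    if len(age_groups) >= 2:
        tests["age_kruskal"] = kruskal_wallis(age_groups)
    contingency = pd.crosstab(frame["group"], frame["sex"])
    if contingency.shape == (len(age_groups), 2) and len(age_groups) >= 2:
        chi2, p, dof, _ = sps.chi2_contingency(contingency, correction=False)
        tests["sex_chi2"] = TestResult("chi2", float(chi2), float(p), df=dof)
    return {"summary": summary, "tests": tests}


def metric_covariate_correlation(metric: Sequence[float], covariate: Sequence[float]) -> TestResult:
    """Pearson r with two-sided p (t transform)."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult("r", float(r), float(p), df=x.size - 2)
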