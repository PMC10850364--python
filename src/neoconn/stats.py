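"""Group-level statistics: metric t-tests, partition consistency, volume regression.

Case/control differences in the graph metrics are tested per (metric,
signal type, sparsity) cell with a two-sided two-sample t-test (Welch by
default; no multiple-testing correction by default, matching the per-cell
reporting convention, with Benjamini-Hochberg available). Within-group
partition consistency is the mean pairwise normalized mutual information
between subjects' community partitions. Overall connectivity strength is
regressed on a brain-volume predictor by OLS, adjusted for gestational age
at birth, postmenstrual age at scan and sex.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _st

from .exceptions import CompletenessError, ComparisonError, StatisticalError
from .graphs import CommunityPartition, partition_mutual_information

METRIC_COLUMNS = ("clustering_coefficient", "network_efficiency", "modularity")


def two_sample_ttest(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> Tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default; pooled via equal_var=True)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise StatisticalError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise StatisticalError("zero variance in both samples with unequal means")
    t, p = _st.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def groupwise_metric_comparison(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
    correct: bool = False,
) -> pd.DataFrame:
    """t-test every (metric, signal_type, sparsity) cell between groups.

    ``table`` is a metric-profile frame (from :func:`neoconn.graphs.metric_profile`);
    ``cohort`` maps subject_id to group. Returns one tidy row per cell with
    group means, t, p and a significance flag at ``alpha``.
    """
    merged = table.merge(cohort[["subject_id", "group"]], on="subject_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject_id"].unique()
        raise CompletenessError(f"subjects missing from cohort table: {list(missing)}")
    rows = []
    for (signal, sparsity), cell in merged.groupby(["signal_type", "sparsity"], sort=True):
        case = cell[cell.group == "case"]
        control = cell[cell.group == "control"]
        if len(case) < 2 or len(control) < 2:
            raise CompletenessError(
                f"both groups must be present at signal={signal}, sparsity={sparsity}"
            )
        for metric in METRIC_COLUMNS:
            t, p = two_sample_ttest(case[metric], control[metric], equal_var=equal_var)
            rows.append(
                {
                    "metric": metric,
                    "signal_type": signal,
                    "sparsity": sparsity,
                    "mean_case": case[metric].mean(),
                    "mean_control": control[metric].mean(),
                    "t_statistic": t,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if correct:
        out["p_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    return out


@dataclass
class ConsistencyResult:
    """Within-group partition agreement and its case/control comparison."""

    mean_case: float
    mean_control: float
    t_statistic: float
    p_value: float
    pair_values: Dict[str, np.ndarray]
    method: str  # "pairs" | "jackknife"


def within_group_consistency(
    partitions: Dict[str, CommunityPartition],
    cohort: pd.DataFrame,
    equal_var: bool = False,
    method: str = "pairs",
) -> ConsistencyResult:
    """Mean pairwise mutual information within each group, compared by t-test.

    ``method="pairs"`` treats each unordered subject pair's MI as one
    observation (simple, but pairs sharing a subject are not independent);
    ``method="jackknife"`` first averages each subject's MI to all other
    group members and tests those subject-level values.
    """
    groups: Dict[str, List[str]] = {"case": [], "control": []}
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        if sid in partitions:
            groups[row["group"]].append(sid)
    for g, members in groups.items():
        if len(members) < 2:
            raise StatisticalError(f"group {g!r} needs >= 2 subjects with partitions")

    node_sets = {tuple(p.node_labels) for p in partitions.values()}
    if len(node_sets) > 1:
        raise ComparisonError("partitions span inconsistent node sets")

    pair_values: Dict[str, np.ndarray] = {}
    samples: Dict[str, np.ndarray] = {}
    for g, members in groups.items():
        mis = {}
        for a, b in combinations(members, 2):
            mis[(a, b)] = partition_mutual_information(partitions[a], partitions[b])
        pair_values[g] = np.array(list(mis.values()))
        if method == "jackknife":
            per_subject = [
                np.mean([v for k, v in mis.items() if s in k]) for s in members
            ]
            samples[g] = np.array(per_subject)
        else:
            samples[g] = pair_values[g]
    if min(samples["case"].size, samples["control"].size) >= 2:
        t, p = two_sample_ttest(samples["case"], samples["control"], equal_var=equal_var)
    else:  # a single pair per group: means are reported, the test is undefined
        t, p = float("nan"), float("nan")
    return ConsistencyResult(
        mean_case=float(pair_values["case"].mean()),
        mean_control=float(pair_values["control"].mean()),
        t_statistic=t,
        p_value=p,
        pair_values=pair_values,
        method=method,
    )


@dataclass
class RegressionResult:
    """OLS of connectivity strength on a volume predictor with covariate adjustment."""

    outcome: str
    predictor: str
    slope: float
    slope_p: float
    params: Dict[str, float]
    pvalues: Dict[str, float]
    n: int
    covariates: Tuple[str, ...] = ("ga_birth", "pma_scan", "sex")


def covariate_adjusted_regression(
    cohort: pd.DataFrame,
    strengths: Sequence[float],
    predictor: str = "gm_volume",
    outcome: str = "strength",
) -> RegressionResult:
    """Regress strength on ``predictor`` + GA at birth + PMA at scan + sex (OLS).

    Sex is coded M=1, F=0. Raises on rank-deficient designs.
    """
    import statsmodels.api as sm

    if predictor not in ("gm_volume", "wm_volume"):
        raise StatisticalError(f"predictor must be gm_volume or wm_volume, got {predictor!r}")
    y = np.asarray(strengths, float)
    n = len(y)
    if n != len(cohort):
        raise StatisticalError("one strength value per cohort row required")
    if n < 6:
        raise StatisticalError(f"need n >= 6 subjects, got {n}")
    cols = ["ga_birth", "pma_scan", predictor]
    if cohort[cols].isna().any().any() or cohort["sex"].isna().any():
        raise StatisticalError("covariates contain missing values")
    x = pd.DataFrame(
        {
            predictor: cohort[predictor].to_numpy(float),
            "ga_birth": cohort["ga_birth"].to_numpy(float),
            "pma_scan": cohort["pma_scan"].to_numpy(float),
            "sex": (cohort["sex"].astype(str) == "M").astype(float).to_numpy(),
        }
    )
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise StatisticalError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        slope=float(fit.params[predictor]),
        slope_p=float(fit.pvalues[predictor]),
        params={k: float(v) for k, v in fit.params.items()},
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
        n=n,
    )
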