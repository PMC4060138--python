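"""Association of mutation loads and pathway clusters with clinical outcome.

Wraps the standard tests the analysis needs — Kruskal-Wallis for loads
across clusters, exact Fisher tests for categorical cluster composition,
Pearson correlation for load vs mean deregulation score, Kaplan-Meier with
log-rank for cluster survival, and Cox proportional hazards for continuous
covariates (Efron tie handling).  Survival records carry an event indicator
(``status``: 1 = died) and the time to last follow-up in years (``ttlf``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.special import gammaln
from scipy.stats import kruskal, pearsonr


@dataclass
class SurvivalResult:
    test: str
    statistic: float
    p_value: float
    hazard_ratio: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    coef: float | None = None
    se: float | None = None
    group_sizes: dict | None = None


def _check_clinical(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("ttlf", "status"):
        if col not in records.columns:
            raise ValueError(f"clinical records lack the {col!r} column")
    if (records["ttlf"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not records["status"].isin([0, 1]).all():
        raise ValueError("status must be 0/1")
    return records


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All-identical pooled values yield H = 0, p = 1.  Empty groups are
    rejected.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} has no observations")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = kruskal(*groups)
    return float(stat), float(p)


def _exact_2xk_pvalue(table: np.ndarray) -> float:
    """Exact conditional test for a 2 x k table by the point-probability rule.

    Enumerates every table with the observed margins; the p-value is the
    total conditional probability of tables no more probable than the
    observed one.  Probabilities are multivariate hypergeometric,
    conditional on the first-row total.
    """
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    r1 = int(row[0])

    def log_table_prob(first_row: tuple[int, ...]) -> float:
        # P(row1 cells | margins) = prod C(c_j, a_j) / C(n, r1)
        lp = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        for a, c in zip(first_row, col):
            lp += gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
        return lp

    lp_obs = log_table_prob(tuple(int(x) for x in table[0]))
    total = 0.0
    ranges = [range(int(c) + 1) for c in col[:-1]]
    for partial in itertools.product(*ranges):
        a_last = r1 - sum(partial)
        if a_last < 0 or a_last > col[-1]:
            continue
        lp = log_table_prob(partial + (a_last,))
        if lp <= lp_obs + 1e-7:
            total += np.exp(lp)
    return min(total, 1.0)


def fisher_cluster_enrichment(table) -> float:
    """Exact p for homogeneity of a 2 x k contingency table.

    Two-sided by the point-probability rule (the convention of standard
    statistical packages for 2 x 2 tables), extended to k > 2 columns by
    enumerating all tables with the observed margins.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    return float(_exact_2xk_pvalue(t))


def pearson_load_vs_score(load: np.ndarray, mean_score: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, p) between per-sample mutation load and mean deregulation score."""
    load = np.asarray(load, dtype=float)
    mean_score = np.asarray(mean_score, dtype=float)
    if len(load) != len(mean_score) or len(load) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.std(load) == 0 or np.std(mean_score) == 0:
        raise ValueError("zero-variance input")
    r, p = pearsonr(load, mean_score)
    return float(r), float(p)


def km_logrank(
    records: pd.DataFrame, labels: pd.Series
) -> tuple[dict[object, pd.DataFrame], SurvivalResult]:
    """Kaplan-Meier curves per group plus the log-rank test across groups.

    ``labels`` maps sample id (the records index) to a group.  Returns
    ({group: DataFrame(time, survival, at_risk)}, SurvivalResult); the
    statistic is NaN when no group has any event.
    """
    records = _check_clinical(records)
    labels = labels.reindex(records.index)
    if labels.isna().any():
        raise ValueError("every record needs a group label")
    if labels.nunique() < 2:
        raise ValueError("km_logrank needs >= 2 groups")

    curves: dict[object, pd.DataFrame] = {}
    sizes: dict[object, int] = {}
    for group, sub in records.groupby(labels):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["ttlf"], event_observed=sub["status"])
        tbl = kmf.event_table
        curves[group] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        sizes[group] = len(sub)

    if records["status"].sum() == 0:
        res = SurvivalResult("logrank", float("nan"), float("nan"), group_sizes=sizes)
        return curves, res
    lr = multivariate_logrank_test(records["ttlf"], labels, records["status"])
    res = SurvivalResult("logrank", float(lr.test_statistic), float(lr.p_value), group_sizes=sizes)
    return curves, res


def cox_ph(records: pd.DataFrame, covariate: pd.Series, name: str = "x") -> SurvivalResult:
    """Univariate Cox proportional hazards fit (Efron ties); HR per covariate unit."""
    records = _check_clinical(records)
    cov = pd.to_numeric(covariate.reindex(records.index))
    if cov.isna().any():
        raise ValueError("covariate missing for some samples")
    if cov.nunique() < 2:
        raise ValueError("covariate is constant; Cox model not identifiable")
    if records["status"].sum() == 0:
        raise ValueError("no events observed; Cox model not identifiable")
    df = pd.DataFrame({"ttlf": records["ttlf"], "status": records["status"], name: cov})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="ttlf", event_col="status")
    s = cph.summary.loc[name]
    return SurvivalResult(
        test="cox",
        statistic=float(s["z"]),
        p_value=float(s["p"]),
        hazard_ratio=float(np.exp(s["coef"])),
        ci_lower=float(np.exp(s["coef lower 95%"])),
        ci_upper=float(np.exp(s["coef upper 95%"])),
        coef=float(s["coef"]),
        se=float(s["se(coef)"]),
    )
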