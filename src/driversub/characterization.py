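"""Subtype characterization: chromosomal instability, mutation associations
and survival separation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import OmicsMatrix, SurvivalRecord

logger = logging.getLogger(__name__)

CIN_THRESHOLD = 0.1


@dataclass
class CinResult:
    sample_id: str
    n_arms_total: int
    n_arms_altered: int

    @property
    def cin_ratio(self) -> float:
        return self.n_arms_altered / self.n_arms_total


def cin_ratio(arm_scores: pd.Series, threshold: float = CIN_THRESHOLD) -> CinResult:
    """Fraction of chromosome arms with |score| strictly beyond the threshold.

    Arms with missing scores are excluded from numerator and denominator.
    """
    scores = arm_scores.dropna()
    if scores.empty:
        raise ValueError("empty arm score vector")
    vals = scores.to_numpy(dtype=float)
    altered = int(np.count_nonzero((vals > threshold) | (vals < -threshold)))
    return CinResult(str(arm_scores.name), len(vals), altered)


def cin_table(cnv_arm: OmicsMatrix, threshold: float = CIN_THRESHOLD) -> pd.DataFrame:
    rows = []
    for s in cnv_arm.sample_ids:
        r = cin_ratio(cnv_arm.data[s], threshold)
        rows.append(
            {
                "sample_id": s,
                "n_arms_total": r.n_arms_total,
                "n_arms_altered": r.n_arms_altered,
                "cin_ratio": r.cin_ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    feature_id: str
    table: np.ndarray  # subtypes x {mutated, not}
    test: str  # "chi_square" | "fisher_exact"
    p_value: float
    p_adjusted: float = float("nan")


def mutation_association(
    assignment: pd.Series, binary_matrix: pd.DataFrame
) -> list[AssociationResult]:
    """Subtype x mutated contingency tests per feature.

    Chi-square with continuity correction for 2x2 tables; Fisher's exact
    test substituted when any expected count falls below 5 (2x2 only).
    Features mutated in no sample are skipped. BH adjustment across the
    tested features.
    """
    samples = [s for s in binary_matrix.index if s in assignment.index]
    labels = assignment.loc[samples]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two subtypes")
    results = []
    for feat in binary_matrix.columns:
        mutated = binary_matrix.loc[samples, feat].to_numpy() > 0
        if not mutated.any():
            continue
        table = np.array(
            [
                [int(mutated[labels.to_numpy() == g].sum()), int((~mutated)[labels.to_numpy() == g].sum())]
                for g in groups
            ]
        )
        chi2, p, _, expected = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
        test = "chi_square"
        if table.shape == (2, 2) and (expected < 5).any():
            _, p = stats.fisher_exact(table)
            test = "fisher_exact"
        results.append(AssociationResult(str(feat), table, test, float(p)))
    if results:
        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
    return results


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "test": r.test,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )


def logrank_compare(
    survival: Sequence[SurvivalRecord], assignment: pd.Series
):
    """Log-rank comparison of subtype survival with per-group KM medians.

    Returns ``(statistic, p_value, medians)`` where ``medians`` maps group
    name to the Kaplan-Meier median (smallest time with survival <= 0.5;
    NaN when never reached).
    """
    recs = [r for r in survival if r.sample_id in assignment.index]
    if not recs:
        raise ValueError("no survival records for the assigned samples")
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])
    if events.sum() == 0:
        raise ValueError("no events")
    groups = np.array([assignment.loc[r.sample_id] for r in recs])
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if len(uniq) == 2:
        m0, m1 = groups == uniq[0], groups == uniq[1]
        res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    else:
        res = multivariate_logrank_test(times, groups, events)
    medians = {}
    for g in uniq:
        m = groups == g
        kmf = KaplanMeierFitter().fit(times[m], events[m])
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
    return float(res.test_statistic), float(res.p_value), medians


def compare_continuous_by_subtype(
    values: pd.Series, assignment: pd.Series
) -> dict:
    """Mann-Whitney U comparison of a per-sample quantity (TMB, CIN, ...)
    between two subtypes."""
    common = [s for s in values.index if s in assignment.index]
    labels = assignment.loc[common]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("two subtypes required")
    x = values.loc[common][labels == groups[0]].to_numpy(dtype=float)
    y = values.loc[common][labels == groups[1]].to_numpy(dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return {
        "groups": groups,
        "means": {groups[0]: float(x.mean()), groups[1]: float(y.mean())},
        "p_value": float(p),
    }
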