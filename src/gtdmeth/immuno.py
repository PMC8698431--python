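"""Tissue-microarray immunoscore aggregation and group comparison.

Scores are recorded per annotation within cores within donors; the
composite donor score is the unweighted mean of core means, each core mean
being the mean of its annotations. Groups (control placenta vs complete
mole) are compared with the Mann–Whitney U test (exact for small samples
without ties, normal approximation with tie correction otherwise); an
unpaired t-test is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("donor", "group", "core", "annotation", "score")
EXACT_MAX_N = 20  # combined sample size below which the exact MW p is used


def aggregate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Composite donor scores: mean of annotations per core, then mean of
    core means per donor. Returns columns donor, group, score."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"immunoscore table missing columns {missing}")
    if table.empty:
        raise ValueError("empty immunoscore table")
    if table["score"].isna().any() or (table["score"] < 0).any():
        raise ValueError("scores must be non-negative and present")
    core_means = (
        table.groupby(["donor", "group", "core"], sort=True)["score"].mean().reset_index()
    )
    donor_means = core_means.groupby(["donor", "group"], sort=True)["score"].mean().reset_index()
    return donor_means


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    method: str  # 'exact', 'asymptotic' or 'ttest'


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float], test: str = "mannwhitney"
) -> GroupComparison:
    """Nonparametric (default) or t-test comparison of two score groups.

    Mann–Whitney uses the exact null distribution when the combined sample
    size is ≤ 20 and there are no ties, otherwise the tie-corrected normal
    approximation. Identical pooled scores yield p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one score")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            u_statistic=a.size * b.size / 2.0,
            p_value=1.0,
            mean_a=float(a.mean()),
            sem_a=_sem(a),
            mean_b=float(b.mean()),
            sem_b=_sem(b),
            method="degenerate",
        )
    if test == "ttest":
        t, p = stats.ttest_ind(a, b)
        return GroupComparison(float(t), float(p), float(a.mean()), _sem(a),
                               float(b.mean()), _sem(b), "ttest")
    if test != "mannwhitney":
        raise ValueError(f"unknown test {test!r}")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        sem_a=_sem(a),
        mean_b=float(b.mean()),
        sem_b=_sem(b),
        method=method,
    )


def compare_immunoscores(
    table: pd.DataFrame, group_a: str = "mole", group_b: str = "control", test: str = "mannwhitney"
) -> Tuple[GroupComparison, pd.DataFrame]:
    """Aggregate an immunoscore table and compare two donor groups."""
    donors = aggregate_scores(table)
    a = donors.loc[donors["group"] == group_a, "score"].to_numpy()
    b = donors.loc[donors["group"] == group_b, "score"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("one of the requested groups has no donors")
    return compare_groups(a, b, test=test), donors
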