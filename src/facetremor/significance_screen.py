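"""Two-group significance screening of the feature table.

Each of the 848 features is tested for a PD-vs-control difference; the
report counts, per feature family, how many of the 106 key points reach
significance at each requested alpha level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory_features import FEATURE_NAMES, META_COLUMNS


@dataclass(frozen=True)
class SignificanceReport:
    """Per-family significant-keypoint counts plus the full p-value table."""

    counts: pd.DataFrame    # index: feature family; one column per alpha
    p_values: pd.Series     # index: full feature column name

    def count(self, family: str, alpha: float) -> int:
        return int(self.counts.loc[family, alpha])


def feature_test(
    values_pd, values_ctrl, method: str = "welch"
) -> float:
    """Two-sided p-value for a group difference in one feature.

    ``welch`` (default) is the unequal-variance t-test; ``mannwhitney``
    is the rank-sum alternative. Degenerate input (zero variance in both
    groups with equal means) yields p = 1.
    """
    a = np.asarray(values_pd, dtype=float)
    b = np.asarray(values_ctrl, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 records")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if method == "welch":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif method == "mannwhitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test method {method!r}")
    return float(1.0 if np.isnan(p) else p)


def p_value_table(
    table: pd.DataFrame,
    method: str = "welch",
    aggregate_subjects: bool = False,
) -> pd.Series:
    """p-value for every feature column of a FeatureTable.

    With ``aggregate_subjects`` each subject's records are averaged
    first, so subjects rather than records become the test units
    (repeated records per subject are not independent).
    """
    if aggregate_subjects:
        feats = [c for c in table.columns if c not in META_COLUMNS]
        table = (
            table.groupby(["subject_id", "label"], as_index=False)[feats].mean()
        )
    is_pd = table["label"] == "PD"
    feats = [c for c in table.columns if c not in META_COLUMNS]
    pvals = {
        c: feature_test(table.loc[is_pd, c], table.loc[~is_pd, c], method=method)
        for c in feats
    }
    return pd.Series(pvals, name="p_value")


def count_significant(
    table: pd.DataFrame,
    alphas=(0.05, 0.005),
    method: str = "welch",
    aggregate_subjects: bool = False,
) -> SignificanceReport:
    """Count, per feature family, key points significant at each alpha."""
    pvals = p_value_table(table, method=method, aggregate_subjects=aggregate_subjects)
    alphas = list(alphas)
    family = pvals.index.str.rsplit("__", n=1).str[-1]
    counts = pd.DataFrame(
        {alpha: pvals.groupby(family).apply(lambda p: int((p < alpha).sum()))
         for alpha in alphas}
    )
    counts = counts.reindex(list(FEATURE_NAMES)) if len(alphas) else pd.DataFrame(
        index=list(FEATURE_NAMES)
    )
    counts.index.name = "feature"
    return SignificanceReport(counts=counts, p_values=pvals)
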