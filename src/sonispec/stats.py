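"""Group comparison of probe-to-background ratios.

Per-ROI ratios are tabulated with subject and replicate identifiers,
replicates are averaged within subject (so repeated probing of one animal
is not treated as independent evidence), and groups are compared with the
two-sample Wilcoxon rank-sum (Mann-Whitney) test. For small untied samples
the exact null distribution is used; otherwise the normal approximation
with midranks, tie correction and continuity correction. A paired
signed-rank mode is available for per-subject probe-vs-background designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "make_ratio_table",
    "summarize",
    "rank_sum_test",
    "signed_rank_test",
    "compare_groups",
]

#: combined sample size up to which the exact rank-sum null is used (no ties)
EXACT_LIMIT = 12

TABLE_COLUMNS = ("subject_id", "roi_name", "role", "replicate_index", "ratio")


@dataclass
class TestResult:
    """Outcome of a two-group comparison."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    degenerate: bool = False  # all values identical across both groups

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both groups must be non-empty")


def make_ratio_table(records) -> pd.DataFrame:
    """Normalize records into the ratio table schema.

    Each record: (subject_id, roi_name, role, replicate_index, ratio) or a
    mapping with those keys.
    """
    df = pd.DataFrame(list(records), columns=TABLE_COLUMNS) \
        if records and not isinstance(records[0], dict) else pd.DataFrame(list(records))
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratio table missing columns: {sorted(missing)}")
    df = df.loc[:, list(TABLE_COLUMNS)]
    if not np.all(np.isfinite(df["ratio"].to_numpy(dtype=float))):
        raise ValueError("ratios must be finite")
    if (df["replicate_index"].to_numpy(dtype=int) < 1).any():
        raise ValueError("replicate_index must be >= 1")
    return df


def summarize(values) -> dict[str, float]:
    """Median, range, mean and sd of a measurement vector.

    Median of an even-length vector is the midpoint of the central order
    statistics; sd is the sample standard deviation (0 for a single value).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    return {
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "n": int(v.size),
    }


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(group_a, group_b, exact_limit: int = EXACT_LIMIT) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the Mann-Whitney U of ``group_a``. Exact enumeration
    null when ``n1 + n2 <= exact_limit`` and the pooled sample has no ties;
    normal approximation with midranks, tie correction and continuity
    correction otherwise. The p-value is symmetric under group exchange.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1",
                      RuntimeWarning, stacklevel=2)
        return TestResult(statistic=float(a.size * b.size / 2.0), p_value=1.0,
                          method="rank-sum (degenerate: all values tied)",
                          n1=int(a.size), n2=int(b.size), degenerate=True)
    if a.size + b.size <= exact_limit and not _has_ties(pooled):
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "rank-sum (exact)"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
        method = "rank-sum (normal approximation, tie-corrected)"
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), method=method,
                      n1=int(a.size), n2=int(b.size))


def signed_rank_test(group_a, group_b) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test on per-subject differences."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired test requires equal-length groups")
    if a.size == 0:
        raise ValueError("both groups must be non-empty")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1",
                      RuntimeWarning, stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0,
                          method="signed-rank (degenerate: all differences zero)",
                          n1=int(a.size), n2=int(b.size), degenerate=True)
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="signed-rank", n1=int(a.size), n2=int(b.size))


def compare_groups(table: pd.DataFrame, role_a: str = "probe",
                   role_b: str = "background", paired: bool = False,
                   exact_limit: int = EXACT_LIMIT) -> dict:
    """Compare two ROI roles after averaging replicates within subject.

    Returns ``{"test": TestResult, "summary_a": ..., "summary_b": ...}``,
    where the summaries are Table-1-style median/range/mean/sd of the
    per-subject means of each role.
    """
    table = make_ratio_table(table.to_dict("records")) \
        if isinstance(table, pd.DataFrame) else make_ratio_table(table)
    for role in (role_a, role_b):
        if role not in set(table["role"]):
            raise ValueError(
                f"role {role!r} not present in table; available roles: "
                f"{sorted(set(table['role']))}"
            )
    per_subject = (table.groupby(["role", "subject_id"])["ratio"]
                   .mean().reset_index())
    a = per_subject.loc[per_subject["role"] == role_a, ["subject_id", "ratio"]]
    b = per_subject.loc[per_subject["role"] == role_b, ["subject_id", "ratio"]]
    if paired:
        merged = a.merge(b, on="subject_id", suffixes=("_a", "_b"))
        if merged.empty:
            raise ValueError("paired comparison requires shared subject_ids")
        test = signed_rank_test(merged["ratio_a"], merged["ratio_b"])
    else:
        test = rank_sum_test(a["ratio"], b["ratio"], exact_limit=exact_limit)
    return {
        "test": test,
        "summary_a": summarize(a["ratio"]),
        "summary_b": summarize(b["ratio"]),
    }
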