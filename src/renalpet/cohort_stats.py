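"""Nonparametric cohort statistics for LRU% tables.

Procedure: LRU% measurements are normalized against the median measurement
in each patient (removing the large between-patient differences in true
split function), gated through a Shapiro-Wilk normality check, then tested
for dependence on acquisition duration and on time p.i. with
Kruskal-Wallis rank-sum tests; post-hoc pairwise comparisons use Dunn's
test with Bonferroni correction.  Tests are two-sided at family level
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalityResult",
    "TestResult",
    "normalize_to_patient_median",
    "normality_gate",
    "kruskal_wallis",
    "dunn_posthoc",
    "run_study_tests",
]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # Shapiro-Wilk W
    p_value: float
    use_nonparametric: bool


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    raw_p: float
    groups: dict = field(default_factory=dict)  # label -> group size
    adjusted_p: float | None = None


def normalize_to_patient_median(
    records: pd.DataFrame,
    value_col: str = "lru_percent",
    method: str = "ratio",
) -> pd.DataFrame:
    """Normalize each value against its patient's median measurement.

    ``method="ratio"`` divides by the patient median (the default; the
    result is dimensionless with per-patient median exactly 1);
    ``method="difference"`` subtracts it instead (per-patient median 0).
    """
    if method not in ("ratio", "difference"):
        raise ValueError(f"unknown normalization method {method!r}")
    out = records.copy()
    med = out.groupby("patient_id")[value_col].transform("median")
    if method == "ratio":
        if (med == 0).any():
            raise ValueError("patient median is zero; ratio normalization undefined")
        out["normalized_lru"] = out[value_col] / med
    else:
        out["normalized_lru"] = out[value_col] - med
    return out


def normality_gate(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk test; flags when nonparametric methods should be used."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("values are all identical; normality test undefined")
    w, p = stats.shapiro(arr)
    return NormalityResult(float(w), float(p), bool(p < alpha))


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    for label, arr in out.items():
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
    return out


def kruskal_wallis(groups, comparison: str = "") -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df.

    Convention: if every value in every group is identical the test is
    degenerate and (H, p) = (0, 1) is returned.
    """
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(gdict.values()))
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    sizes = {k: int(v.size) for k, v in gdict.items()}
    if np.ptp(pooled) == 0:
        return TestResult(comparison, 0.0, 1.0, sizes)
    h, p = stats.kruskal(*gdict.values())
    return TestResult(comparison, float(h), float(p), sizes)


def dunn_posthoc(
    groups, comparison_prefix: str = "", p_adjust: str = "bonferroni"
) -> list[TestResult]:
    """Dunn's test: all pairwise z statistics on mean ranks, tie-corrected.

    adjusted_p = min(1, m * raw_p) with m = k(k-1)/2 (Bonferroni), or the
    raw p when ``p_adjust`` is "none".  Two-sided.
    """
    if p_adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown p adjustment {p_adjust!r}")
    gdict = _as_groups(groups)
    labels = list(gdict)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([gdict[l] for l in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # Tie correction term sum(t^3 - t) over tie groups.
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var_const = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    start = 0
    for label in labels:
        n = gdict[label].size
        mean_ranks[label] = ranks[start : start + n].mean()
        sizes[label] = int(n)
        start += n

    m = k * (k - 1) // 2
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            se = np.sqrt(var_const * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            raw_p = float(2.0 * stats.norm.sf(abs(z)))
            adj = raw_p if p_adjust == "none" else min(1.0, m * raw_p)
            name = f"{comparison_prefix}{a} vs {b}"
            results.append(
                TestResult(name, float(z), raw_p, {a: sizes[a], b: sizes[b]}, adj)
            )
    return results


def _grouped(df: pd.DataFrame, by: str, value_col: str) -> dict:
    return {
        str(level): grp[value_col].to_numpy()
        for level, grp in df.groupby(by, sort=True)
    }


def run_study_tests(
    records: pd.DataFrame,
    value_col: str = "lru_percent",
    normalization: str = "ratio",
) -> dict:
    """Full statistical report on a long-format LRU table.

    Runs Kruskal-Wallis by acquisition duration and by time point, on both
    median-normalized and raw LRU%, plus Dunn's Bonferroni-corrected
    post-hoc comparisons (both factors) on the normalized values, and the
    Shapiro-Wilk normality gate for raw and normalized data.
    """
    for col in ("patient_id", "time_pi", "duration", value_col):
        if col not in records.columns:
            raise ValueError(f"records table lacks column {col!r}")
    if records["duration"].nunique() < 2 or records["time_pi"].nunique() < 2:
        raise ValueError("table must span >= 2 durations and >= 2 time points")

    normalized = normalize_to_patient_median(records, value_col, normalization)

    def kw(df, by, col, tag):
        return kruskal_wallis(_grouped(df, by, col), comparison=tag)

    report = {
        "normalization": normalization,
        "shapiro": {
            "raw": normality_gate(records[value_col]),
            "normalized": normality_gate(normalized["normalized_lru"]),
        },
        "kruskal_wallis": {
            "normalized": {
                "duration": kw(normalized, "duration", "normalized_lru",
                               "normalized by duration"),
                "time_pi": kw(normalized, "time_pi", "normalized_lru",
                              "normalized by time p.i."),
            },
            "raw": {
                "duration": kw(records, "duration", value_col, "raw by duration"),
                "time_pi": kw(records, "time_pi", value_col, "raw by time p.i."),
            },
        },
        "dunn": {
            "time_pi": dunn_posthoc(
                _grouped(normalized, "time_pi", "normalized_lru"), "time "
            ),
            "duration": dunn_posthoc(
                _grouped(normalized, "duration", "normalized_lru"), "duration "
            ),
        },
    }
    return report


def report_to_json_dict(report: dict) -> dict:
    """Convert a run_study_tests report into plain JSON-serializable types."""

    def conv(obj):
        if isinstance(obj, (NormalityResult, TestResult)):
            return {k: conv(v) for k, v in vars(obj).items()}
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return conv(report)


def pairwise_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tabulate Dunn post-hoc results as a CSV-ready DataFrame."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "z": [r.statistic for r in results],
            "raw_p": [r.raw_p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
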