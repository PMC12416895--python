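"""Nonparametric statistical battery over paired-condition cohort tables.

The cohort table is a long-format pandas DataFrame with columns
``subject_id, sex, condition, metric, value`` where condition is
``baseline`` or ``norepinephrine``. Conventions, chosen for a small-sample
physiological cohort and surfaced in the report metadata:

* within-subject change is per-subject relative change
  ``(post - pre)/pre * 100`` summarized as median (IQR) — this is *not* the
  ratio of the two condition medians, and the two can differ noticeably;
* paired condition comparisons use the Wilcoxon signed-rank test
  (exact null distribution for n <= 25 without ties, normal approximation
  with tie correction otherwise; zero differences dropped, the classic
  convention);
* between-group (sex) comparisons use the Mann-Whitney U test on relative
  changes; monotone associations use Spearman's rho with tie-corrected
  ranks;
* quartiles use the linear-interpolation convention;
* no multiple-testing correction; each comparison is judged at two-sided
  alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from .hemodynamics import Condition

REQUIRED_COLUMNS = ("subject_id", "sex", "condition", "metric", "value")

#: sample size up to which the exact signed-rank / U null is used
EXACT_N_MAX = 25

ALPHA = 0.05


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format cohort table and return it (unchanged)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"cohort table is missing columns {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise InvalidInputError("cohort table values must be numeric and finite")
    dup = table.duplicated(subset=["subject_id", "condition", "metric"])
    if dup.any():
        row = table[dup].iloc[0]
        raise InvalidInputError(
            f"duplicate record for subject={row['subject_id']!r} "
            f"condition={row['condition']!r} metric={row['metric']!r}"
        )
    return table


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """(median, q1, q3) with linear-interpolation quartiles."""
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


def _pairs(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Wide per-subject (baseline, post) values for one metric; complete pairs only."""
    sub = table[table["metric"] == metric]
    wide = sub.pivot_table(
        index="subject_id", columns="condition", values="value", aggfunc="first"
    )
    for cond in (Condition.BASELINE.value, Condition.NOREPINEPHRINE.value):
        if cond not in wide.columns:
            wide[cond] = np.nan
    wide = wide.dropna(
        subset=[Condition.BASELINE.value, Condition.NOREPINEPHRINE.value]
    )
    sexes = sub.drop_duplicates("subject_id").set_index("subject_id")["sex"]
    wide = wide.join(sexes)
    return wide.sort_index()


def relative_changes(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-subject relative change (post - pre)/pre * 100 for one metric.

    Subjects with a zero baseline are excluded (their relative change is
    undefined).
    """
    wide = _pairs(table, metric)
    pre = wide[Condition.BASELINE.value].to_numpy(dtype=float)
    post = wide[Condition.NOREPINEPHRINE.value].to_numpy(dtype=float)
    ok = pre != 0
    out = pd.DataFrame(
        {
            "subject_id": wide.index[ok],
            "sex": wide["sex"].to_numpy()[ok],
            "rel_change_pct": (post[ok] - pre[ok]) / pre[ok] * 100.0,
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired baseline vs hypertension comparison of one metric."""

    metric: str
    n_pairs: int
    median_baseline: float
    iqr_baseline: tuple[float, float]
    median_increased: float
    iqr_increased: tuple[float, float]
    median_rel_change_pct: float
    iqr_rel_change_pct: tuple[float, float]
    p_value: float
    test_name: str
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _wilcoxon(d: np.ndarray) -> tuple[float, str, str]:
    """Two-sided signed-rank p on paired differences; returns (p, test, note)."""
    nonzero = d[d != 0]
    note = ""
    if len(nonzero) < len(d):
        note = f"{len(d) - len(nonzero)} zero difference(s) dropped"
    if len(nonzero) == 0:
        return 1.0, "wilcoxon signed-rank (degenerate: all differences zero)", note
    ranks = sps.rankdata(np.abs(nonzero))
    has_ties = len(np.unique(ranks)) < len(ranks)
    if len(nonzero) <= EXACT_N_MAX and not has_ties:
        method, name = "exact", "wilcoxon signed-rank (exact)"
    else:
        method, name = "approx", "wilcoxon signed-rank (normal approximation)"
    p = float(sps.wilcoxon(nonzero, method=method).pvalue)
    return p, name, note


def paired_compare(table: pd.DataFrame, metric: str) -> ComparisonResult:
    """Wilcoxon signed-rank comparison of one metric across conditions."""
    wide = _pairs(table, metric)
    if len(wide) < 2:
        raise InsufficientDataError(
            f"metric {metric!r}: need >= 2 complete pairs, have {len(wide)}"
        )
    pre = wide[Condition.BASELINE.value].to_numpy(dtype=float)
    post = wide[Condition.NOREPINEPHRINE.value].to_numpy(dtype=float)
    p, test_name, note = _wilcoxon(post - pre)
    rel = relative_changes(table, metric)["rel_change_pct"].to_numpy()
    if len(rel):
        m_rel, q1_rel, q3_rel = _median_iqr(rel)
    else:
        m_rel = q1_rel = q3_rel = float("nan")
        note = (note + "; " if note else "") + "relative change undefined (zero baselines)"
    m_pre, q1_pre, q3_pre = _median_iqr(pre)
    m_post, q1_post, q3_post = _median_iqr(post)
    return ComparisonResult(
        metric=metric,
        n_pairs=len(wide),
        median_baseline=m_pre,
        iqr_baseline=(q1_pre, q3_pre),
        median_increased=m_post,
        iqr_increased=(q1_post, q3_post),
        median_rel_change_pct=m_rel,
        iqr_rel_change_pct=(q1_rel, q3_rel),
        p_value=p,
        test_name=test_name,
        note=note,
    )


@dataclass(frozen=True)
class GroupComparisonResult:
    """Between-group (e.g. by sex) comparison of per-subject relative changes."""

    metric: str
    group_column: str
    groups: tuple[str, str]
    n_per_group: tuple[int, int]
    median_per_group: tuple[float, float]
    iqr_per_group: tuple[tuple[float, float], tuple[float, float]]
    p_value: float
    test_name: str


def group_compare(
    table: pd.DataFrame, metric: str, group: str = "sex"
) -> GroupComparisonResult:
    """Mann-Whitney U on per-subject relative changes between two groups."""
    rel = relative_changes(table, metric)
    if group not in rel.columns:
        raise InvalidInputError(f"unknown grouping column {group!r}")
    labels = sorted(rel[group].unique())
    if len(labels) != 2:
        raise InsufficientDataError(
            f"metric {metric!r}: need exactly 2 non-empty groups, have {labels}"
        )
    x = rel.loc[rel[group] == labels[0], "rel_change_pct"].to_numpy()
    y = rel.loc[rel[group] == labels[1], "rel_change_pct"].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError(f"metric {metric!r}: a group is empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= EXACT_N_MAX and not has_ties:
        method, name = "exact", "mann-whitney U (exact)"
    else:
        method, name = "asymptotic", "mann-whitney U (normal approximation)"
    p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    mx, q1x, q3x = _median_iqr(x)
    my, q1y, q3y = _median_iqr(y)
    return GroupComparisonResult(
        metric=metric,
        group_column=group,
        groups=(str(labels[0]), str(labels[1])),
        n_per_group=(len(x), len(y)),
        median_per_group=(mx, my),
        iqr_per_group=((q1x, q3x), (q1y, q3y)),
        p_value=p,
        test_name=name,
    )


def correlate(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    level: str = "baseline",
) -> tuple[float, float]:
    """Spearman correlation between two metrics at a given level.

    ``level`` is ``baseline``, ``increased`` (the hypertension condition) or
    ``change`` (per-subject relative changes). Returns (rho, two-sided p).
    """
    def values(metric: str) -> pd.Series:
        if level == "change":
            rel = relative_changes(table, metric)
            return rel.set_index("subject_id")["rel_change_pct"]
        cond = {
            "baseline": Condition.BASELINE.value,
            "increased": Condition.NOREPINEPHRINE.value,
        }.get(level)
        if cond is None:
            raise InvalidInputError(f"unknown level {level!r}")
        sub = table[(table["metric"] == metric) & (table["condition"] == cond)]
        return sub.set_index("subject_id")["value"]

    joined = pd.concat(
        [values(metric_x).rename("x"), values(metric_y).rename("y")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired observations, have {len(joined)}"
        )
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "Spearman correlation undefined for a constant input"
        )
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metric median (IQR) by condition with paired-test p-values.

    One row per metric, mirroring a clinical characteristics table:
    condition medians with linear-interpolation quartiles, the median (IQR)
    per-subject relative change, the signed-rank p and a significance flag
    at two-sided alpha = 0.05 (no multiple-testing correction).
    Metrics without >= 2 complete pairs get descriptive columns only.
    """
    validate_cohort_table(table)
    rows = []
    for metric in sorted(table["metric"].unique()):
        try:
            c = paired_compare(table, metric)
            rows.append(
                {
                    "metric": metric,
                    "n_pairs": c.n_pairs,
                    "baseline_median": c.median_baseline,
                    "baseline_q1": c.iqr_baseline[0],
                    "baseline_q3": c.iqr_baseline[1],
                    "increased_median": c.median_increased,
                    "increased_q1": c.iqr_increased[0],
                    "increased_q3": c.iqr_increased[1],
                    "rel_change_median_pct": c.median_rel_change_pct,
                    "rel_change_q1_pct": c.iqr_rel_change_pct[0],
                    "rel_change_q3_pct": c.iqr_rel_change_pct[1],
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "test": c.test_name,
                    "note": c.note,
                }
            )
        except InsufficientDataError:
            sub = table[table["metric"] == metric]
            vals = sub["value"].to_numpy(dtype=float)
            med, q1, q3 = _median_iqr(vals)
            rows.append(
                {
                    "metric": metric,
                    "n_pairs": 0,
                    "baseline_median": med,
                    "baseline_q1": q1,
                    "baseline_q3": q3,
                    "increased_median": float("nan"),
                    "increased_q1": float("nan"),
                    "increased_q3": float("nan"),
                    "rel_change_median_pct": float("nan"),
                    "rel_change_q1_pct": float("nan"),
                    "rel_change_q3_pct": float("nan"),
                    "p_value": float("nan"),
                    "significant": False,
                    "test": "",
                    "note": "insufficient pairs; descriptive only"
                    + (" (single value)" if len(vals) == 1 else ""),
                }
            )
    return pd.DataFrame(rows)
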