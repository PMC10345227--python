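"""Descriptive cohort statistics and two-group comparisons.

Per-stratum (A-tetra detectable vs not) summaries of MSEL scores, HMO
concentrations and species abundances, pooled totals recoverable exactly
from per-stratum (n, mean, SD), Welch t-tests, and Pearson chi-square tests
of independence.  Visits are treated as independent for these marginal
comparisons, matching how the cohort tables are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "group_summary", "pooled_summary",
           "welch_t", "pooled_t", "chisq_independence", "cohort_tables"]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("GroupSummary requires n >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def group_summary(values, labels) -> dict[str, GroupSummary]:
    """Per-stratum n / mean / sample-SD (n-1 denominator).

    Missing values are dropped within stratum; an empty stratum raises.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if x.shape != lab.shape:
        raise ValueError("values and labels must have the same length")
    out: dict[str, GroupSummary] = {}
    for g in pd.unique(lab):
        vals = x[lab == g]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"stratum {g!r} has no non-missing values")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[str(g)] = GroupSummary(n=int(vals.size),
                                   mean=float(np.mean(vals)), sd=sd)
    return out


def pooled_summary(s1: GroupSummary, s2: GroupSummary) -> GroupSummary:
    """Exact combined (n, mean, SD) of two groups from their summaries."""
    n = s1.n + s2.n
    if n < 2:
        raise ValueError("pooled SD undefined for n < 2")
    mean = (s1.n * s1.mean + s2.n * s2.mean) / n
    ss = ((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2
          + s1.n * (s1.mean - mean) ** 2 + s2.n * (s2.mean - mean) ** 2)
    return GroupSummary(n=n, mean=mean, sd=float(np.sqrt(ss / (n - 1))))


def welch_t(s1: GroupSummary, s2: GroupSummary) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summaries: (t, df, p)."""
    if s1.n < 2 or s2.n < 2:
        raise ValueError("welch_t requires n >= 2 in both groups")
    v1, v2 = s1.sd ** 2 / s1.n, s2.sd ** 2 / s2.n
    if v1 + v2 == 0:
        if s1.mean == s2.mean:
            raise ValueError("zero variance in both groups with equal means")
        return np.inf, float(s1.n + s2.n - 2), 0.0
    t = (s1.mean - s2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (s1.n - 1) + v2 ** 2 / (s2.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def pooled_t(s1: GroupSummary, s2: GroupSummary) -> tuple[float, float, float]:
    """Student's pooled-variance t-test from summaries: (t, df, p)."""
    if s1.n < 2 or s2.n < 2:
        raise ValueError("pooled_t requires n >= 2 in both groups")
    df = s1.n + s2.n - 2
    sp2 = ((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2) / df
    if sp2 == 0:
        if s1.mean == s2.mean:
            raise ValueError("zero variance in both groups with equal means")
        return np.inf, float(df), 0.0
    t = (s1.mean - s2.mean) / np.sqrt(sp2 * (1 / s1.n + 1 / s2.n))
    return float(t), float(df), 2.0 * float(stats.t.sf(abs(t), df))


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must all be positive")
    return float(stat), int(df), float(p)


def _summary_table(df, columns, labels) -> pd.DataFrame:
    rows = []
    for col in columns:
        by = group_summary(df[col].to_numpy(dtype=float), labels)
        pos, neg = by.get("positive"), by.get("negative")
        row = dict(variable=col)
        if pos and neg:
            total = pooled_summary(pos, neg)
            _, _, p = welch_t(pos, neg)
            row.update(total_n=total.n, total_mean=total.mean, total_sd=total.sd,
                       pos_n=pos.n, pos_mean=pos.mean, pos_sd=pos.sd,
                       neg_n=neg.n, neg_mean=neg.mean, neg_sd=neg.sd, p=p)
        else:  # single-stratum cohort: totals only
            only = pos or neg
            row.update(total_n=only.n, total_mean=only.mean, total_sd=only.sd)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_tables(dataset, lod: float | None = None) -> dict[str, pd.DataFrame]:
    """Per-stratum descriptive tables: demographics, MSEL scores, abundances.

    Strata are A-tetra detectability of each milk sample; visits are treated
    as independent.  Returns frames keyed ``demographics`` / ``msel`` /
    ``abundance`` / ``hmo``.
    """
    from .preprocess import atetra_status
    from .synthdata import ATETRA_LOD_MGL, MSEL_OUTCOMES

    df = dataset.df
    lod = ATETRA_LOD_MGL if lod is None else lod
    labels = np.array([atetra_status(v, lod) for v in df["atetra_mgL"]])

    demo_rows = []
    for name, col, level in (("sex_male", "sex", "male"),
                             ("vaginal_birth", "delivery", "vaginal"),
                             ("graduate_education", "maternal_education", "graduate")):
        ind = (df[col] == level).astype(int)
        tab = pd.crosstab(ind, labels)
        row = dict(variable=name,
                   total_n=int(ind.sum()),
                   total_pct=float(ind.mean()))
        if tab.shape[1] == 2 and (tab.to_numpy().sum(axis=0) > 0).all() \
                and tab.shape[0] == 2:
            _, _, p = chisq_independence(tab.to_numpy())
            row["p"] = p
        demo_rows.append(row)
    age = _summary_table(df, ["age_months"], labels)
    tables = {
        "demographics": pd.DataFrame(demo_rows),
        "age": age,
        "msel": _summary_table(df, [f"msel_{o}" for o in MSEL_OUTCOMES
                                    if f"msel_{o}" in df.columns], labels),
        "abundance": _summary_table(df, dataset.species_columns, labels),
        "hmo": _summary_table(df, [f"{h}_mgL" for h in dataset.hmo_names], labels),
    }
    return tables
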