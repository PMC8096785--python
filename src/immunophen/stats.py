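"""Downstream group comparisons for the immunophenotype classes.

Kaplan-Meier recurrence-free survival curves with log-rank tests,
Fisher's exact test for differential mutation, tumor mutation burden
(nonsynonymous mutations per covered megabase), generic two/three-group
difference tests with a normality-gated method choice, and per-gene
per-class mutation frequency tables with BH correction.

The survival machinery rides on ``lifelines`` and the classical tests on
``scipy``/``statsmodels``; this module fixes the conventions (0/1 event
coding, days, two-sided tests, Shapiro-Wilk normality gate at 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

from .io import MutationTable

logger = logging.getLogger("immunophen.stats")

__all__ = [
    "TestResult",
    "SurvivalSummary",
    "km_estimate",
    "logrank_test",
    "fisher_exact_2x2",
    "tumor_mutation_burden",
    "group_difference_test",
    "mutation_frequency_table",
]


@dataclass
class TestResult:
    """A hypothesis-test outcome with per-group summaries."""

    method: str
    statistic: float
    p: float
    df: int | None = None
    group_summaries: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class SurvivalSummary:
    """Per-group Kaplan-Meier step functions.

    ``curves`` maps group -> DataFrame with columns ``time`` and
    ``survival``; rows start at (0, 1) and steps occur only at event
    times.
    """

    curves: dict[str, pd.DataFrame]
    group_sizes: dict[str, int] = field(default_factory=dict)

    def survival_at(self, group: str, t: float) -> float:
        curve = self.curves[group]
        below = curve[curve["time"] <= t]
        return float(below["survival"].iloc[-1]) if len(below) else 1.0


def _clean_survival_inputs(times, events, groups):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be coded 0/1")
    return times, events.astype(int), groups


def km_estimate(times, events, groups) -> SurvivalSummary:
    """Product-limit survival curves per group (censoring creates no steps)."""
    times, events, groups = _clean_survival_inputs(times, events, groups)
    if times.size == 0:
        raise ValueError("no subjects")
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        surv = sf.iloc[:, 0].to_numpy()
        tline = sf.index.to_numpy(dtype=float)
        # keep t=0 and the times where the estimate actually drops
        keep = np.concatenate(([True], np.diff(surv) != 0))
        keep[0] = True
        curve = pd.DataFrame({"time": tline[keep], "survival": surv[keep]})
        if curve["time"].iloc[0] != 0:
            curve = pd.concat(
                [pd.DataFrame({"time": [0.0], "survival": [1.0]}), curve],
                ignore_index=True,
            )
        curves[g] = curve
        sizes[g] = int(mask.sum())
    return SurvivalSummary(curves=curves, group_sizes=sizes)


def logrank_test(times, events, groups) -> TestResult:
    """Multi-group log-rank test (chi-square, df = groups - 1)."""
    times, events, groups = _clean_survival_inputs(times, events, groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined with no events")
    res = multivariate_logrank_test(times, groups, events)
    summaries = {
        str(g): {"n": int((groups == g).sum()), "events": int(events[groups == g].sum())}
        for g in uniq
    }
    return TestResult(
        method="logrank",
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=len(uniq) - 1,
        group_summaries=summaries,
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test with the conditional-MLE odds ratio."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    arr = arr.astype(int)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        orat = np.nan
    else:
        orat = float(odds_ratio(arr, kind="conditional").statistic)
    return TestResult(
        method="fisher_exact",
        statistic=float(orat) if np.isfinite(orat) else 0.0,
        p=float(p),
        extra={"odds_ratio": orat},
    )


def tumor_mutation_burden(
    mutations: MutationTable, default_megabases: float | None = None
) -> pd.Series:
    """Per-sample TMB: nonsynonymous mutation count / covered megabases."""
    df = mutations.data
    mb = df.groupby("sample_id")["covered_megabases"].first()
    if mb.isna().any():
        if default_megabases is None:
            raise ValueError(
                "covered_megabases missing for some samples and no default configured"
            )
        mb = mb.fillna(float(default_megabases))
    if (mb <= 0).any():
        raise ValueError("covered_megabases must be positive")
    counts = mutations.nonsynonymous_counts().reindex(mb.index, fill_value=0)
    tmb = counts / mb
    tmb.name = "tmb"
    return tmb


def _summaries(groups: dict[str, np.ndarray]) -> dict:
    return {
        str(g): {"n": int(v.size), "mean": float(np.mean(v)), "median": float(np.median(v))}
        for g, v in groups.items()
    }


def group_difference_test(values, labels, mode: str = "auto") -> TestResult:
    """Compare a continuous per-sample quantity between classes.

    ``mode="auto"`` runs a two-sample t-test when both groups pass
    Shapiro-Wilk normality at 0.05, otherwise the Wilcoxon rank-sum test
    (two groups) or Kruskal-Wallis (>= 3 groups).  ``mode="chi2"``
    expects ``values`` to be a contingency table instead.
    """
    if mode == "chi2":
        table = np.asarray(values)
        stat, p, df, _ = sps.chi2_contingency(table)
        return TestResult(method="chi2", statistic=float(stat), p=float(p), df=int(df))

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    groups = {g: values[labels == g] for g in uniq}
    arrs = list(groups.values())

    if mode == "auto":
        if any(a.size < 3 for a in arrs):
            logger.warning("group with <3 values: falling back to rank-based test")
            mode = "wilcoxon" if len(uniq) == 2 else "kruskal"
        elif len(uniq) == 2:
            normal = all(sps.shapiro(a).pvalue > 0.05 for a in arrs)
            mode = "t" if normal else "wilcoxon"
        else:
            mode = "kruskal"

    if mode == "t":
        if len(uniq) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = sps.ttest_ind(arrs[0], arrs[1])
        df = arrs[0].size + arrs[1].size - 2
        return TestResult("t", float(stat), float(p), df, _summaries(groups))
    if mode == "wilcoxon":
        if len(uniq) != 2:
            raise ValueError("rank-sum test requires exactly 2 groups")
        stat, p = sps.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
        return TestResult("wilcoxon", float(stat), float(p), None, _summaries(groups))
    if mode == "kruskal":
        stat, p = sps.kruskal(*arrs)
        return TestResult("kruskal", float(stat), float(p), len(uniq) - 1, _summaries(groups))
    raise ValueError(f"unknown mode {mode!r}")


def mutation_frequency_table(
    mutations: MutationTable,
    labels: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mutation frequency by class with class-vs-rest Fisher tests.

    ``labels`` maps sample id -> class; samples absent from the mutation
    table count as unmutated (logged).  Returns one row per gene with
    ``freq_<class>``, ``p_<class>`` (class vs rest, Fisher) and
    ``fdr_<class>`` (BH across genes within each class).
    """
    labels = labels.dropna()
    classes = sorted(labels.unique())
    if not classes:
        raise ValueError("empty class labels")
    if any((labels == c).sum() == 0 for c in classes):
        raise ValueError("empty class")
    presence = mutations.presence_matrix(nonsynonymous_only=True)
    absent = [s for s in labels.index if s not in presence.index]
    if absent:
        logger.info("%d labeled samples have no mutation records (counted unmutated)", len(absent))
    presence = presence.reindex(index=labels.index, fill_value=False)
    if genes is None:
        genes = sorted(presence.columns)
    rows = []
    for gene in genes:
        mutated = (
            presence[gene] if gene in presence.columns
            else pd.Series(False, index=labels.index)
        )
        row: dict = {"gene": gene}
        for c in classes:
            in_c = labels == c
            a = int((mutated & in_c).sum())
            b = int((~mutated & in_c).sum())
            cc = int((mutated & ~in_c).sum())
            d = int((~mutated & ~in_c).sum())
            row[f"freq_{c}"] = a / (a + b)
            row[f"n_mutated_{c}"] = a
            row[f"p_{c}"] = fisher_exact_2x2([[a, b], [cc, d]]).p
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    for c in classes:
        _, fdr, _, _ = multipletests(out[f"p_{c}"], method="fdr_bh")
        out[f"fdr_{c}"] = fdr
    return out
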