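"""Subclass mapping: do subtypes of two expression cohorts correspond?

For each subtype ``a`` of cohort A, marker genes are the top
signal-to-noise ratio genes of ``a`` versus the rest of A,

    SNR = (mean_a - mean_rest) / (sd_a + sd_rest),

computed on the shared gene universe.  The enrichment of those markers
near the top of cohort B's subtype-``b`` SNR-ranked gene list is measured
with a Kolmogorov-Smirnov running-sum statistic, and its significance by
permuting B's subtype labels.  The symmetric B->A pass is combined per
cell, floored at the Monte-Carlo resolution 1/(n_perm+1), and
Bonferroni-corrected over all subtype pairs.  A small Bonferroni p for
cell (a, b) is evidence that subtype ``a`` in cohort A and subtype ``b``
in cohort B share an expression profile — e.g. linking an
immune-activated tumor subtype to immunotherapy responders in an
independent cohort.

Two combination rules are offered.  The default, ``"max"``, takes the
larger of the two directional p-values (an intersection-union test):
both directions are computed from the same pair of matrices and are
strongly positively dependent under the null, and the max-combination
stays valid under arbitrary dependence.  ``"fisher"`` is the classical
chi-square(4) combination of the two log p-values; it is sharper but
anti-conservative exactly when the two directions co-fluctuate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import ExpressionMatrix

logger = logging.getLogger("immunophen.submap")

__all__ = ["SubMapResult", "submap_compare", "fisher_combine"]

_EPS = 1e-8


def fisher_combine(p1, p2):
    """Fisher's method for two p-values: chi-square(4) tail of
    -2(ln p1 + ln p2).  Assumes the two are independent."""
    return chi2.sf(-2.0 * (np.log(p1) + np.log(p2)), df=4)


@dataclass
class SubMapResult:
    """Correspondence p-values between subtypes of two cohorts.

    ``nominal_p[a, b]`` combines the two directional permutation
    p-values (A-markers in B's ranking and vice versa) by the selected
    rule, floored at 1/(n_perm+1); ``bonferroni_p`` multiplies by the
    number of cells, capped at 1.
    """

    nominal_p: pd.DataFrame  # subtypes_A x subtypes_B
    bonferroni_p: pd.DataFrame
    p_a_in_b: pd.DataFrame  # directional permutation p-values, A markers in B
    p_b_in_a: pd.DataFrame
    n_perm: int
    marker_count: int
    combination: str = "max"


def _snr(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio of samples in ``mask`` vs the rest."""
    a, rest = X[:, mask], X[:, ~mask]
    return (a.mean(axis=1) - rest.mean(axis=1)) / (
        a.std(axis=1, ddof=0) + rest.std(axis=1, ddof=0) + _EPS
    )


def _rank_order(snr: np.ndarray) -> np.ndarray:
    """Descending-SNR gene ordering, ties broken by gene index."""
    return np.lexsort((np.arange(snr.size), -snr))


def _ks_enrichment(order: np.ndarray, marker_mask: np.ndarray) -> float:
    """Max positive running-sum deviation of markers in the ranked list."""
    hits = marker_mask[order]
    n_hit = int(hits.sum())
    n_miss = hits.size - n_hit
    running = np.cumsum(np.where(hits, 1.0 / n_hit, -1.0 / n_miss))
    return float(running.max())


def _directional_pass(
    X_src: np.ndarray,
    labels_src: np.ndarray,
    subtypes_src: list,
    X_dst: np.ndarray,
    labels_dst: np.ndarray,
    subtypes_dst: list,
    n_marker: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation p-values for src-subtype markers enriched in dst-subtype
    rankings; returns matrix (subtypes_src x subtypes_dst)."""
    n_genes = X_src.shape[0]
    marker_masks = []
    for a in subtypes_src:
        snr = _snr(X_src, labels_src == a)
        top = _rank_order(snr)[:n_marker]
        mask = np.zeros(n_genes, dtype=bool)
        mask[top] = True
        marker_masks.append(mask)

    def es_matrix(dst_labels: np.ndarray) -> np.ndarray:
        es = np.empty((len(subtypes_src), len(subtypes_dst)))
        for j, b in enumerate(subtypes_dst):
            order = _rank_order(_snr(X_dst, dst_labels == b))
            for i, mask in enumerate(marker_masks):
                es[i, j] = _ks_enrichment(order, mask)
        return es

    obs = es_matrix(labels_dst)
    exceed = np.ones_like(obs)
    perm_labels = labels_dst.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        exceed += es_matrix(perm_labels) >= obs
    return exceed / (n_perm + 1)


def submap_compare(
    expr_a: ExpressionMatrix,
    labels_a: pd.Series,
    expr_b: ExpressionMatrix,
    labels_b: pd.Series,
    n_marker: int = 100,
    n_perm: int = 100,
    seed: int = 0,
    min_group: int = 5,
    min_shared_genes: int = 500,
    combination: str = "max",
) -> SubMapResult:
    """Subclass-mapping correspondence test between two labeled cohorts.

    ``labels_a`` / ``labels_b`` map sample id -> subtype.  Requires >= 2
    subtypes per cohort with >= ``min_group`` samples each and
    >= ``min_shared_genes`` genes in the intersected universe.
    ``combination`` is ``"max"`` (dependence-robust default) or
    ``"fisher"`` (classical chi-square(4) combination).
    """
    shared = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes (< {min_shared_genes}) between cohorts"
        )
    labels_a = labels_a.reindex(expr_a.sample_ids)
    labels_b = labels_b.reindex(expr_b.sample_ids)
    if labels_a.isna().any() or labels_b.isna().any():
        raise ValueError("labels missing for some cohort samples")

    subtypes_a = sorted(labels_a.unique())
    subtypes_b = sorted(labels_b.unique())
    for name, labels, subtypes in (("A", labels_a, subtypes_a), ("B", labels_b, subtypes_b)):
        if len(subtypes) < 2:
            raise ValueError(f"cohort {name} needs >= 2 subtypes")
        counts = labels.value_counts()
        small = counts[counts < min_group]
        if not small.empty:
            raise ValueError(
                f"cohort {name} subtypes below minimum size {min_group}: {dict(small)}"
            )

    Xa = expr_a.data.loc[shared].to_numpy(dtype=float)
    Xb = expr_b.data.loc[shared].to_numpy(dtype=float)
    la = labels_a.to_numpy()
    lb = labels_b.to_numpy()
    n_marker = min(n_marker, len(shared))

    rng = np.random.default_rng(seed)
    p_ab = _directional_pass(Xa, la, subtypes_a, Xb, lb, subtypes_b, n_marker, n_perm, rng)
    p_ba = _directional_pass(Xb, lb, subtypes_b, Xa, la, subtypes_a, n_marker, n_perm, rng)

    # combine the two directions per (a, b) cell
    if combination == "max":
        combined = np.maximum(p_ab, p_ba.T)
    elif combination == "fisher":
        combined = fisher_combine(p_ab, p_ba.T)
    else:
        raise ValueError(f"unknown combination {combination!r}")
    combined = np.maximum(combined, 1.0 / (n_perm + 1))  # Monte-Carlo floor
    cells = combined.size
    bonf = np.minimum(1.0, combined * cells)

    idx_a = pd.Index(subtypes_a, name="subtype_a")
    idx_b = pd.Index(subtypes_b, name="subtype_b")
    return SubMapResult(
        nominal_p=pd.DataFrame(combined, index=idx_a, columns=idx_b),
        bonferroni_p=pd.DataFrame(bonf, index=idx_a, columns=idx_b),
        p_a_in_b=pd.DataFrame(p_ab, index=idx_a, columns=idx_b),
        p_b_in_a=pd.DataFrame(p_ba, index=idx_b, columns=idx_a),
        n_perm=n_perm,
        marker_count=n_marker,
        combination=combination,
    )
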