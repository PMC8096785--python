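"""Single-sample gene set enrichment (ssGSEA) scoring.

For one sample, genes are ranked by expression in descending order and
the enrichment score of a gene set G is the running-sum difference

    ES = sum_{i=1..N} [ P_G^w(i) - P_NG(i) ]

where ``P_G^w(i)`` is the weighted cumulative fraction of set genes at or
above position ``i`` (weights ``rank^alpha``, using within-sample ranks
rather than raw values so scores are comparable across platforms) and
``P_NG(i)`` is the unweighted cumulative fraction of non-set genes.

The immune enrichment score (IES) and stromal enrichment score (SES) are
ssGSEA scores of the designated immune and activated-stroma signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, SignatureCollection

logger = logging.getLogger("immunophen.ssgsea")

__all__ = ["EnrichmentMatrix", "ssgsea_enrichment", "score_matrix"]

#: established ssGSEA weighting exponent
DEFAULT_ALPHA = 0.25


@dataclass
class EnrichmentMatrix:
    """ssGSEA scores, signatures x samples.

    When ``normalized`` the scores were divided by the global
    (max - min) spread of the matrix, so their range spread is <= 1.
    ``ies_name`` / ``ses_name`` designate which rows act as the immune
    and stromal enrichment scores.
    """

    scores: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    normalized: bool = False
    ies_name: str | None = None
    ses_name: str | None = None

    @property
    def ies(self) -> pd.Series:
        if self.ies_name is None or self.ies_name not in self.scores.index:
            raise KeyError("no IES signature designated")
        return self.scores.loc[self.ies_name]

    @property
    def ses(self) -> pd.Series:
        if self.ses_name is None or self.ses_name not in self.scores.index:
            raise KeyError("no SES signature designated")
        return self.scores.loc[self.ses_name]


def _sample_order_and_ranks(
    values: np.ndarray, gene_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Descending-expression ordering (gene-id tie-break) and ascending
    average ranks (ties share their average rank)."""
    if np.ptp(values) == 0:
        raise ValueError("constant expression vector: ranks undefined")
    order = np.lexsort((gene_ids, -values))
    ranks = rankdata(values, method="average")
    return order, ranks


def _es_from_ordered(
    in_set: np.ndarray, weights: np.ndarray, alpha: float
) -> float:
    """ES given the set-membership mask and rank weights, both in ranked
    (descending-expression) order."""
    n = in_set.size
    n_set = int(in_set.sum())
    if n_set == 0 or n_set == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.where(in_set, np.abs(weights) ** alpha, 0.0)
    denom = w.sum()
    p_hit = np.cumsum(w) / denom
    p_miss = np.cumsum(~in_set) / (n - n_set)
    return float(np.sum(p_hit - p_miss))


def ssgsea_enrichment(
    sample_expression: pd.Series,
    gene_set: list[str],
    alpha: float = DEFAULT_ALPHA,
    set_name: str = "gene_set",
    min_genes: int = 3,
) -> float:
    """Enrichment score of one gene set in one sample's expression vector.

    Requires at least ``min_genes`` set genes present after intersecting
    with the expression index (default 3, the scoring precondition);
    raises :class:`ValueError` naming the set otherwise.  ``min_genes=1``
    admits the degenerate singleton cases useful for hand verification.
    """
    values = sample_expression.to_numpy(dtype=float)
    gene_ids = sample_expression.index.to_numpy(dtype=object)
    members = set(gene_set) & set(gene_ids)
    if len(members) < min_genes:
        raise ValueError(
            f"signature {set_name!r}: only {len(members)} genes present "
            f"(need >= {min_genes})"
        )
    order, ranks = _sample_order_and_ranks(values, gene_ids)
    in_set = np.isin(gene_ids[order], list(members))
    return _es_from_ordered(in_set, ranks[order], alpha)


def score_matrix(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
    ies_name: str | None = None,
    ses_name: str | None = None,
) -> EnrichmentMatrix:
    """ssGSEA scores for every (signature, sample) pair.

    Signatures with an empty intersection (or < 3 genes present) raise an
    error listing them; signatures covering < 50% of their genes only
    trigger a warning.  With ``normalize`` the full matrix is divided by
    its global (max - min) after all scores are computed.
    """
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    gene_index = set(expr.gene_ids)

    masks = {}
    low_coverage = []
    missing = []
    for name, genes in sigs.sets.items():
        present = [g for g in genes if g in gene_index]
        if len(present) < 3:
            missing.append(name)
            continue
        if len(present) < 0.5 * len(genes):
            low_coverage.append(name)
        masks[name] = np.isin(gene_ids, present)
    if missing:
        raise ValueError(
            f"signatures with <3 genes present in the expression matrix: {missing}"
        )
    if low_coverage:
        logger.warning("signatures covering <50%% of their genes: %s", low_coverage)

    values = expr.values
    out = np.empty((len(masks), expr.n_samples))
    names = list(masks)
    for j in range(expr.n_samples):
        col = values[:, j]
        order, ranks = _sample_order_and_ranks(col, gene_ids)
        ranks_ordered = ranks[order]
        for i, name in enumerate(names):
            out[i, j] = _es_from_ordered(masks[name][order], ranks_ordered, alpha)

    scores = pd.DataFrame(out, index=names, columns=expr.sample_ids)
    if normalize:
        spread = float(out.max() - out.min())
        if spread > 0:
            scores = scores / spread
    return EnrichmentMatrix(
        scores=scores,
        alpha=alpha,
        normalized=normalize,
        ies_name=ies_name,
        ses_name=ses_name,
    )
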