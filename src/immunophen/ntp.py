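"""Nearest template prediction (NTP) with resampling significance.

A template is a marker gene list with per-gene directions (+1/-1).  Each
sample's expression is standardized per gene across the cohort, and the
sample's distance to the template is the cosine distance between its
standardized template-gene vector and the direction vector (range [0, 2];
0 means the sample matches the template exactly up to positive scaling).

Significance is resampling-based: the same distance is computed for
``n_perm`` random gene sets of the template's size drawn from the genes
present in the cohort, giving a per-sample nominal p-value

    p = (1 + #{random sets with distance <= d}) / (n_perm + 1)

followed by Benjamini-Hochberg FDR across samples.  A sample is called
template-positive when its FDR falls below the threshold.  In the
immune-subtyping pipeline the single template is the activated-stroma
signature: positive = immune-suppressed, negative = immune-activated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger("immunophen.ntp")

__all__ = ["Template", "NTPResult", "ntp_predict"]


@dataclass
class Template:
    """A marker-gene template: unique genes with +1/-1 directions."""

    name: str
    genes: list[str]
    directions: np.ndarray | None = None  # default all +1

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("template has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("template genes must be unique")
        if self.directions is None:
            self.directions = np.ones(len(self.genes))
        else:
            self.directions = np.asarray(self.directions, dtype=float)
            if self.directions.shape != (len(self.genes),):
                raise ValueError("directions must align with genes")
            if not np.isin(self.directions, [-1.0, 1.0]).all():
                raise ValueError("directions must be +1 or -1")


@dataclass
class NTPResult:
    """Per-sample template distances, resampling p-values and calls."""

    table: pd.DataFrame  # index sample_id; columns distance, nominal_p, fdr, positive
    template_name: str
    n_perm: int
    fdr_threshold: float
    genes_used: list[str] = field(default_factory=list)

    @property
    def positive(self) -> pd.Series:
        return self.table["positive"]

    @property
    def distance(self) -> pd.Series:
        return self.table["distance"]


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    nonzero = sd[:, 0] > 0
    z = np.zeros_like(values)
    z[nonzero] = (values[nonzero] - mean[nonzero]) / sd[nonzero]
    return z, nonzero


def _cosine_distance(z_block: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Cosine distance of each sample column of ``z_block`` to ``directions``."""
    num = directions @ z_block
    denom = np.linalg.norm(directions) * np.linalg.norm(z_block, axis=0)
    denom = np.where(denom > 0, denom, np.inf)  # zero vector -> maximal uncertainty
    return np.clip(1.0 - num / denom, 0.0, 2.0)


def ntp_predict(
    expr: ExpressionMatrix,
    template: Template,
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    standardize: bool = True,
) -> NTPResult:
    """Call template positivity for every sample of a cohort.

    Requires >= 3 template genes present with non-zero variance and >= 2
    samples (standardization needs variance).  Zero-variance template
    genes are dropped with a warning.  Pass ``standardize=False`` when the
    matrix is already gene-standardized against a reference population
    (e.g. z-scores over a full cohort before restricting to a subclass).
    """
    if expr.n_samples < 2:
        raise ValueError("NTP needs >= 2 samples for gene-wise standardization")
    values = expr.values.astype(float)
    if standardize:
        z, nonzero = _standardize_rows(values)
    else:
        z = values
        nonzero = np.ones(values.shape[0], dtype=bool)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    keep_idx = []
    keep_dir = []
    dropped = []
    for g, d in zip(template.genes, template.directions):
        i = gene_pos.get(g)
        if i is None:
            continue
        if not nonzero[i]:
            dropped.append(g)
            continue
        keep_idx.append(i)
        keep_dir.append(d)
    if dropped:
        logger.warning("dropped %d zero-variance template genes: %s", len(dropped), dropped[:5])
    if len(keep_idx) < 3:
        raise ValueError(
            f"template {template.name!r}: only {len(keep_idx)} usable genes present (need >= 3)"
        )
    keep_idx = np.asarray(keep_idx)
    directions = np.asarray(keep_dir, dtype=float)
    size = keep_idx.size

    d_obs = _cosine_distance(z[keep_idx], directions)

    candidates = np.flatnonzero(nonzero)
    if candidates.size < size:
        raise ValueError("not enough variable genes to draw random template-size sets")
    rng = np.random.default_rng(seed)
    exceed = np.ones(expr.n_samples, dtype=np.int64)  # the +1 of the p-value formula
    for _ in range(n_perm):
        idx = rng.choice(candidates, size=size, replace=False)
        d_null = _cosine_distance(z[idx], directions)
        exceed += d_null <= d_obs
    nominal_p = exceed / (n_perm + 1)

    _, fdr, _, _ = multipletests(nominal_p, method="fdr_bh")
    positive = fdr < fdr_threshold
    table = pd.DataFrame(
        {
            "distance": d_obs,
            "nominal_p": nominal_p,
            "fdr": fdr,
            "positive": positive,
        },
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )
    genes_used = [expr.gene_ids[i] for i in keep_idx]
    return NTPResult(
        table=table,
        template_name=template.name,
        n_perm=n_perm,
        fdr_threshold=fdr_threshold,
        genes_used=genes_used,
    )
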