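"""Non-negative matrix factorization for virtual microdissection.

Factorizes a non-negative expression matrix ``V`` (n genes x m samples)
into ``W`` (genes x factors) and ``H`` (factors x samples) by minimizing
the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

with the classic multiplicative update rules, whose per-iteration
divergence is non-increasing.  Multi-restart fitting keeps the lowest
divergence; consensus clustering over repeated factorizations yields the
averaged connectivity matrix, hierarchical consensus labels and the
cophenetic correlation used as a cluster-stability diagnostic.

The recovered programs in tumor expression correspond to additive tissue
compartments (tumor, immune, stroma), and the top-weighted genes of a
factor serve as its exemplar marker set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger("immunophen.nmf")

__all__ = [
    "NMFResult",
    "ConsensusResult",
    "nmf_factorize",
    "nmf_consensus",
    "top_weighted_genes",
]

_EPS = 1e-12


@dataclass
class NMFResult:
    """Best-restart KL-NMF factorization.

    ``W`` columns are normalized to unit sum after the fit with ``H``
    rescaled so the product ``WH`` is unchanged (resolving the scale
    indeterminacy of NMF).  ``trace`` is the per-iteration divergence of
    the winning restart.
    """

    W: np.ndarray  # genes x k
    H: np.ndarray  # k x samples
    k: int
    divergence: float
    n_iter: int
    seed: int
    trace: np.ndarray = field(repr=False, default=None)
    gene_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConsensusResult:
    """Averaged co-clustering over repeated NMF runs.

    ``consensus`` is the symmetric m x m matrix in [0, 1] with unit
    diagonal; ``labels`` is the per-sample cluster id in {1..k} from
    average-linkage hierarchical clustering of (1 - consensus);
    ``cophenetic`` is the cophenetic correlation coefficient of that
    dendrogram against (1 - consensus).
    """

    consensus: np.ndarray
    labels: np.ndarray
    cophenetic: float
    n_runs: int
    sample_ids: list[str] | None = None

    def labels_series(self) -> pd.Series:
        idx = self.sample_ids if self.sample_ids is not None else range(len(self.labels))
        return pd.Series(self.labels, index=idx, name="cluster")


def _as_matrix(V) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(V, ExpressionMatrix):
        return V.values.astype(float), V.gene_ids, V.sample_ids
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(dtype=float), list(V.index), list(V.columns)
    arr = np.asarray(V, dtype=float)
    return arr, None, None


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V||WH) with the 0*log0 := 0 convention."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(term.sum() - V.sum() + WH.sum())


def _fit_single(
    V: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, np.ndarray]:
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, (n, k)) * scale
    H = rng.uniform(_EPS, 1.0, (k, m)) * scale

    trace = np.empty(max_iter)
    prev = np.inf
    n_iter = 0
    for it in range(max_iter):
        WH = W @ H
        # multiplicative updates (Lee-Seung / Brunet form)
        H *= (W.T @ (V / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= ((V / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        div = kl_divergence(V, W @ H)
        trace[it] = div
        n_iter = it + 1
        if np.isfinite(prev) and abs(prev - div) < tol * max(abs(prev), _EPS):
            break
        prev = div
    return W, H, float(trace[n_iter - 1]), n_iter, trace[:n_iter].copy()


def _normalize_scale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize W columns to unit sum, rescaling H rows so WH is unchanged."""
    s = W.sum(axis=0)
    s_safe = np.where(s > 0, s, 1.0)
    return W / s_safe, H * s_safe[:, None]


def nmf_factorize(
    V,
    k: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFResult:
    """Best-of-``n_restarts`` KL-NMF of a non-negative matrix.

    Parameters
    ----------
    V
        :class:`ExpressionMatrix`, DataFrame or array, genes x samples,
        elementwise non-negative.
    k
        Factorization rank, ``1 <= k < min(n_genes, n_samples)``.
    tol
        Stop a restart once the relative divergence change per iteration
        falls below this value (or at ``max_iter``).
    """
    arr, gene_ids, sample_ids = _as_matrix(V)
    if (arr < 0).any():
        raise ValueError("NMF input must be non-negative")
    n, m = arr.shape
    if not (1 <= k < min(n, m)):
        raise ValueError(f"rank k={k} out of range for a {n}x{m} matrix")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    for s in child_seeds:
        W, H, div, n_iter, trace = _fit_single(
            arr, k, max_iter, tol, np.random.default_rng(int(s))
        )
        if best is None or div < best[2]:
            best = (W, H, div, n_iter, trace, int(s))
    W, H, div, n_iter, trace, win_seed = best
    W, H = _normalize_scale(W, H)
    return NMFResult(
        W=W,
        H=H,
        k=k,
        divergence=div,
        n_iter=n_iter,
        seed=win_seed,
        trace=trace,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


def nmf_consensus(
    V,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    max_retries: int = 10,
) -> ConsensusResult:
    """Consensus clustering over ``n_runs`` independent NMF fits.

    Each run assigns sample ``j`` to ``argmax_f H[f, j]``; the consensus
    matrix is the run-average of the co-assignment indicator.  Final
    labels come from average-linkage hierarchical clustering of
    ``1 - consensus`` cut at ``k`` clusters.  A run that leaves a cluster
    empty is redrawn with a fresh seed (up to ``max_retries`` per run).
    """
    arr, _, sample_ids = _as_matrix(V)
    if (arr < 0).any():
        raise ValueError("NMF input must be non-negative")
    n, m = arr.shape
    if not (1 <= k < min(n, m)):
        raise ValueError(f"rank k={k} out of range for a {n}x{m} matrix")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    root = np.random.default_rng(seed)
    consensus = np.zeros((m, m))
    for _ in range(n_runs):
        for attempt in range(max_retries + 1):
            rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
            _, H, _, _, _ = _fit_single(arr, k, max_iter, tol, rng)
            assign = H.argmax(axis=0)
            if len(np.unique(assign)) == k:
                break
        else:
            raise RuntimeError(
                f"NMF consensus: empty cluster persisted over {max_retries} retries"
            )
        consensus += assign[:, None] == assign[None, :]
    consensus /= n_runs
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if condensed.size and np.ptp(condensed) > 0:
        coph, _ = cophenet(Z, condensed)
        coph = float(np.clip(coph, 0.0, 1.0)) if np.isfinite(coph) else 1.0
    else:
        coph = 1.0  # degenerate dendrogram: all distances equal (e.g. perfect consensus)
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        cophenetic=coph,
        n_runs=n_runs,
        sample_ids=sample_ids,
    )


def top_weighted_genes(result: NMFResult, factor: int, n: int) -> list[str]:
    """The ``n`` exemplar genes of a factor: highest ``W`` weight first.

    ``factor`` is 1-based.  Ties are broken lexicographically by gene id
    so the list is deterministic.
    """
    if not (1 <= factor <= result.k):
        raise ValueError(f"factor {factor} out of range 1..{result.k}")
    if result.gene_ids is None:
        gene_ids = [f"g{i}" for i in range(result.W.shape[0])]
    else:
        gene_ids = list(result.gene_ids)
    if n > len(gene_ids):
        raise ValueError(f"requested {n} genes but only {len(gene_ids)} available")
    w = result.W[:, factor - 1]
    order = sorted(range(len(gene_ids)), key=lambda i: (-w[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n]]
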