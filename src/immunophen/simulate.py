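"""Synthetic prostate-cancer cohorts with known immunophenotype ground truth.

The generator emulates the statistical structure the subtyping pipeline
assumes in real bulk expression data: log-scale expression is an additive
mixture of three latent programs (tumor, immune, stroma) plus Gaussian
noise, exponentiated to a non-negative FPKM-like scale.  Immune-class
samples (activated + suppressed) carry an elevated immune-program loading;
immune-suppressed samples additionally carry an elevated stromal-program
loading.  Recurrence-free survival is exponential with subtype-specific
hazards (suppressed worst) under independent uniform censoring, and
somatic mutations are Bernoulli draws with subtype-specific frequencies
(TP53 enriched and SPOP depleted in the suppressed subtype, matching the
frequencies reported for TCGA prostate tumors).

Truth label counts follow deterministic largest-remainder rounding of the
subtype proportions, so tests can assert them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    MutationTable,
    SignatureCollection,
    write_expression,
    write_gene_sets,
)

__all__ = ["CohortParams", "SyntheticCohort", "generate_cohort", "SUBTYPES"]

#: canonical subtype order used throughout: (activated, suppressed, nonimmune)
SUBTYPES = ("activated", "suppressed", "nonimmune")

#: per-subtype nonsynonymous mutation probabilities for the planted driver
#: analogs (activated, suppressed, nonimmune); TP53/SPOP values are the
#: per-subtype frequencies reported for TCGA prostate tumors, the rest are
#: flat background drivers.
DEFAULT_MUTATION_FREQS: dict[str, dict[str, float]] = {
    "TP53": {"activated": 0.054, "suppressed": 0.1905, "nonimmune": 0.0983},
    "SPOP": {"activated": 0.1351, "suppressed": 0.0556, "nonimmune": 0.1322},
    "FOXA1": {"activated": 0.04, "suppressed": 0.04, "nonimmune": 0.04},
    "KMT2D": {"activated": 0.035, "suppressed": 0.035, "nonimmune": 0.035},
    "ATM": {"activated": 0.03, "suppressed": 0.03, "nonimmune": 0.03},
    "BRCA2": {"activated": 0.03, "suppressed": 0.03, "nonimmune": 0.03},
}


@dataclass
class CohortParams:
    """Generative parameters for a synthetic cohort.

    Defaults mirror the training-cohort landscape the subtyping was
    derived from: subtype proportions (0.15, 0.25, 0.60) for (activated,
    suppressed, nonimmune), a 150-gene immune signature, a 50-gene
    activated-stroma signature and recurrence hazard ratios
    (1.0, 2.0, 1.5) so the suppressed subtype recurs fastest.

    ``immune_effect`` / ``stroma_effect`` are natural-log-scale mean
    shifts of the respective program loading in the affected samples;
    ``noise_sd`` is the per-cell log-scale Gaussian noise.
    """

    n_samples: int = 300
    n_genes: int = 1000
    subtype_proportions: tuple[float, float, float] = (0.15, 0.25, 0.60)
    immune_effect: float = 2.0
    stroma_effect: float = 2.0
    noise_sd: float = 0.5
    hazard_ratios: tuple[float, float, float] = (1.0, 2.0, 1.5)
    baseline_hazard: float = np.log(2) / 1825.0  # median 5 y RFS in the activated subtype
    censoring_range: tuple[float, float] = (180.0, 3650.0)  # days
    mutation_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_MUTATION_FREQS.items()}
    )
    n_immune_signature: int = 150
    n_stroma_signature: int = 50
    covered_megabases: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != 3 or (props < 0).any():
            raise ValueError("subtype_proportions must be 3 non-negative values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1 within 1e-9")
        if self.immune_effect <= 0 or self.stroma_effect <= 0 or self.noise_sd <= 0:
            raise ValueError("effects and noise_sd must be positive")
        if self.n_samples < 30:
            raise ValueError("n_samples must be >= 30")
        if self.n_genes < self.n_immune_signature + self.n_stroma_signature:
            raise ValueError("n_genes smaller than combined signature sizes")


@dataclass
class SyntheticCohort:
    """A generated cohort bundling expression, truth labels, clinical data,
    mutations, the signature collection used to plant the programs, and the
    true per-sample latent loadings."""

    expression: ExpressionMatrix
    truth_labels: pd.Series  # sample_id -> {activated, suppressed, nonimmune}
    clinical: ClinicalTable
    mutations: MutationTable
    signatures: SignatureCollection
    latent: pd.DataFrame  # samples x (tumor, immune, stroma) true loadings
    params: CohortParams

    @property
    def stage1_truth(self) -> pd.Series:
        """Two-way truth: immune (activated or suppressed) vs nonimmune."""
        return self.truth_labels.map(
            lambda s: "nonimmune" if s == "nonimmune" else "immune"
        )

    @property
    def three_way_truth(self) -> pd.Series:
        """Truth labels in the pipeline's class vocabulary
        (immune_activated / immune_suppressed / nonimmune)."""
        return self.truth_labels.map(
            {
                "activated": "immune_activated",
                "suppressed": "immune_suppressed",
                "nonimmune": "nonimmune",
            }
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write expression.gct, clinical.tsv, mutations.tsv, signatures.gmt
        and truth_labels.tsv under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": write_expression(self.expression, out / "expression.gct"),
            "signatures": write_gene_sets(self.signatures, out / "signatures.gmt"),
        }
        clin = self.clinical.data.reset_index().rename(columns={"index": "sample_id"})
        clin.to_csv(out / "clinical.tsv", sep="\t", index=False)
        paths["clinical"] = out / "clinical.tsv"
        self.mutations.data.to_csv(out / "mutations.tsv", sep="\t", index=False)
        paths["mutations"] = out / "mutations.tsv"
        truth = self.truth_labels.rename("truth_label").rename_axis("sample_id")
        truth.to_csv(out / "truth_labels.tsv", sep="\t")
        paths["truth_labels"] = out / "truth_labels.tsv"
        return paths


def largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Deterministic integer allocation of ``n`` by largest-remainder rounding."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _signature_collection(immune_genes: list[str], stroma_genes: list[str]) -> SignatureCollection:
    """Immune-cell subset signatures partitioning the immune program genes,
    the pooled immune signature used as the IES, and the activated-stroma
    signature used as the SES / NTP template."""
    n = len(immune_genes)
    cuts = np.linspace(0, n, 5).astype(int)
    subsets = {
        "T_CELL": immune_genes[cuts[0] : cuts[1]],
        "B_CELL": immune_genes[cuts[1] : cuts[2]],
        "NK_CELL": immune_genes[cuts[2] : cuts[3]],
        "MACROPHAGE": immune_genes[cuts[3] : cuts[4]],
    }
    sets = {
        "IMMUNE_SIGNATURE": list(immune_genes),
        **{k: v for k, v in subsets.items() if v},
        "ACTIVATED_STROMA": list(stroma_genes),
    }
    desc = {
        "IMMUNE_SIGNATURE": "pooled immune program genes (IES)",
        "T_CELL": "T cell program genes",
        "B_CELL": "B cell program genes",
        "NK_CELL": "NK cell program genes",
        "MACROPHAGE": "macrophage program genes",
        "ACTIVATED_STROMA": "activated stroma / C-ECM program genes (SES, NTP template)",
    }
    return SignatureCollection(sets, {k: v for k, v in desc.items() if k in sets})


def generate_cohort(params: CohortParams | None = None, **overrides) -> SyntheticCohort:
    """Generate a cohort under ``params`` (keyword overrides accepted).

    The same params (including ``seed``) always produce a byte-identical
    cohort.
    """
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)

    n, g = params.n_samples, params.n_genes
    counts = largest_remainder_counts(n, np.asarray(params.subtype_proportions))
    labels = np.repeat(np.array(SUBTYPES, dtype=object), counts)
    rng.shuffle(labels)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    truth = pd.Series(labels, index=sample_ids, name="truth_label")

    n_imm, n_str = params.n_immune_signature, params.n_stroma_signature
    immune_genes = [f"IMM{i + 1:04d}" for i in range(n_imm)]
    stroma_genes = [f"STR{i + 1:04d}" for i in range(n_str)]
    background_genes = [f"BG{i + 1:05d}" for i in range(g - n_imm - n_str)]
    gene_ids = immune_genes + stroma_genes + background_genes

    is_immune_sample = truth.isin(["activated", "suppressed"]).to_numpy()
    is_suppressed = (truth == "suppressed").to_numpy()

    # per-sample latent loadings (natural-log scale)
    tumor_load = np.clip(rng.normal(1.0, 0.2, n), 0.0, None)
    immune_load = np.where(
        is_immune_sample,
        rng.normal(params.immune_effect, 0.15 * params.immune_effect, n),
        rng.normal(0.15 * params.immune_effect, 0.10 * params.immune_effect, n),
    )
    stroma_load = np.where(
        is_suppressed,
        rng.normal(params.stroma_effect, 0.15 * params.stroma_effect, n),
        rng.normal(0.15 * params.stroma_effect, 0.10 * params.stroma_effect, n),
    )
    immune_load = np.clip(immune_load, 0.0, None)
    stroma_load = np.clip(stroma_load, 0.0, None)
    latent = pd.DataFrame(
        {"tumor": tumor_load, "immune": immune_load, "stroma": stroma_load},
        index=sample_ids,
    )

    # per-gene program weights
    w_tumor = np.zeros(g)
    w_immune = np.zeros(g)
    w_stroma = np.zeros(g)
    w_immune[:n_imm] = rng.uniform(0.7, 1.3, n_imm)
    w_stroma[n_imm : n_imm + n_str] = rng.uniform(0.7, 1.3, n_str)
    w_tumor[n_imm + n_str :] = rng.uniform(0.2, 1.0, g - n_imm - n_str)
    w_tumor[: n_imm + n_str] = 0.2  # signature genes keep a small tumor baseline

    baseline = rng.normal(2.0, 1.0, g)
    log_expr = (
        baseline[:, None]
        + np.outer(w_tumor, tumor_load)
        + np.outer(w_immune, immune_load)
        + np.outer(w_stroma, stroma_load)
        + rng.normal(0.0, params.noise_sd, (g, n))
    )
    values = np.maximum(np.exp(log_expr), 0.0)
    expression = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    # survival: exponential by subtype hazard, independent uniform censoring
    hr = dict(zip(SUBTYPES, params.hazard_ratios))
    lam = np.array([params.baseline_hazard * hr[s] for s in truth])
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(*params.censoring_range, n)
    rfs_time = np.minimum(event_time, censor_time)
    rfs_event = (event_time <= censor_time).astype(int)
    gleason = np.where(is_suppressed, rng.choice([7, 8, 9], n), rng.choice([6, 7, 8], n))
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "rfs_time": np.round(rfs_time, 1),
                "rfs_event": rfs_event,
                "gleason": gleason,
                "t_stage": rng.choice([2, 3], n),
                "age": rng.integers(45, 80, n),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # mutations: Bernoulli per (gene, subtype), plus occasional silent calls
    rows = []
    for gene in sorted(params.mutation_freqs):
        freqs = params.mutation_freqs[gene]
        p = np.array([freqs[s] for s in truth])
        hit = rng.random(n) < p
        for sid in np.array(sample_ids)[hit]:
            rows.append((sid, gene, "missense_mutation"))
    silent_hit = rng.random(n) < 0.10
    for sid in np.array(sample_ids)[silent_hit]:
        rows.append((sid, "SILENTBG1", "silent"))
    mut_df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_classification"])
    mut_df["is_nonsynonymous"] = mut_df["variant_classification"].eq("missense_mutation")
    mut_df["covered_megabases"] = params.covered_megabases
    mutations = MutationTable(mut_df)

    signatures = _signature_collection(immune_genes, stroma_genes)
    return SyntheticCohort(
        expression=expression,
        truth_labels=truth,
        clinical=clinical,
        mutations=mutations,
        signatures=signatures,
        latent=latent,
        params=params,
    )
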