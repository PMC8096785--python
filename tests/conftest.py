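import numpy as np
import pandas as pd
import pytest

from immunophen import CohortParams, ExpressionMatrix, PipelineConfig, generate_cohort


def mini_cohort_params(seed: int = 11, **overrides) -> CohortParams:
    """A scaled-down cohort (120 samples, 400 genes, 80/40-gene signatures).

    Effect sizes are scaled by the square root of the signature-size
    ratio so the per-sample signal-to-noise matches the default study
    conditions (150/50-gene signatures at effect 2.0)."""
    kw = dict(
        n_samples=120,
        n_genes=400,
        n_immune_signature=80,
        n_stroma_signature=40,
        immune_effect=2.0 * np.sqrt(150 / 80),
        stroma_effect=2.0 * np.sqrt(50 / 40),
        seed=seed,
    )
    kw.update(overrides)
    return CohortParams(**kw)


@pytest.fixture(scope="session")
def mini_params() -> CohortParams:
    return mini_cohort_params()


@pytest.fixture(scope="session")
def mini_cohort(mini_params):
    return generate_cohort(mini_params)


@pytest.fixture()
def mini_config() -> PipelineConfig:
    """Pipeline configuration sized for the mini cohort."""
    return PipelineConfig(
        nmf_rank=6,
        nmf_restarts=4,
        nmf_max_iter=400,
        nmf_tol=1e-5,
        consensus_runs=10,
        consensus_max_iter=200,
        ntp_n_perm=200,
        rf_trees=100,
        n_exemplar=80,
        n_classifier_genes=80,
        seed=0,
    )


@pytest.fixture()
def random_expression() -> ExpressionMatrix:
    """Unstructured (exchangeable) lognormal expression, 200 genes x 50 samples."""
    rng = np.random.default_rng(99)
    vals = rng.lognormal(2.0, 1.0, (200, 50))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i:03d}" for i in range(200)],
            columns=[f"S{j:03d}" for j in range(50)],
        )
    )
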