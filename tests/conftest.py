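import numpy as np
import pandas as pd
import pytest

from opcflux import cfi, diffexpr, preprocess, simulate
from opcflux.matrix import ExpressionMatrix


def preprocessed(scenario, seed=None):
    """Simulate + normalize + filter + merge, returning (scenario, gene matrix)."""
    matrix = simulate.generate_expression(scenario, seed_override=seed)
    normed = preprocess.percentile_normalize(matrix)
    filtered, _ = preprocess.low_expression_filter(normed)
    pm = scenario.probe_map()
    merged = preprocess.merge_probes(filtered, {p: pm[p] for p in filtered.feature_ids})
    return merged


@pytest.fixture(scope="session")
def zero_noise_run():
    """Zero-noise default scenario pushed through the whole pipeline."""
    scenario = simulate.default_scenario(noise_sd_log2=0.0, seed=11)
    merged = preprocessed(scenario)
    calls = diffexpr.de_pipeline(merged, scenario.chosen_references)
    results = cfi.cfi_results(calls, cfi.default_pathways())
    return scenario, merged, calls, results


@pytest.fixture()
def toy_matrix():
    """Tiny 3-gene, 3-sample matrix used by the geNorm worked example."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 1.0],
            "s2": [2.0, 4.0, 1.0],
            "s3": [4.0, 8.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    design = pd.Series(["a", "a", "b"], index=["s1", "s2", "s3"])
    return ExpressionMatrix(data, design)


def random_matrix(rng, n_genes=5, n_samples=6, n_groups=2):
    """Random positive matrix with a balanced two-level design."""
    values = np.exp(rng.normal(5.0, 1.0, size=(n_genes, n_samples)))
    samples = [f"s{i}" for i in range(n_samples)]
    conditions = [f"g{i % n_groups}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"gene{i}" for i in range(n_genes)], columns=samples),
        pd.Series(conditions, index=samples),
    )
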