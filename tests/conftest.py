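import pytest
from hypothesis import HealthCheck, settings

from ayamel.expression import (
    differential_expression,
    filter_low_counts,
    median_of_ratios_normalize,
)
from ayamel.synthetic import SimulationConfig, generate_expression_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_cohort():
    """Seeded cohort with a planted resistance program, normalized, plus DE.

    24 resistant + 24 CR (+24 PR) samples, 2,000 genes, 100 planted genes
    with |log2FC| = 1.5 — the parameter-recovery study conditions.
    """
    config = SimulationConfig(
        n_per_group=24, n_genes=2000, n_signature_genes=100, log2_effect=1.5, seed=7
    )
    matrix, truth = generate_expression_cohort(config)
    normed = median_of_ratios_normalize(filter_low_counts(matrix))
    de = differential_expression(
        normed, truth.samples_of("resistant"), truth.samples_of("CR")
    )
    return config, normed, truth, de
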