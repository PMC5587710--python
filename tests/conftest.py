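import numpy as np
import pandas as pd
import pytest

from apobec3kit.sim import (
    ExpressionParams,
    SimConfig,
    build_context_genome,
    build_locus_model,
    simulate_cohort,
    simulate_rnaseq_reads,
)


@pytest.fixture(scope="session")
def locus():
    return build_locus_model()


@pytest.fixture(scope="session")
def small_cohort():
    """A miniature but complete cohort used by several integration tests."""
    cfg = SimConfig(
        n_samples=12,
        n_reads_per_library=600,
        mutations_per_sample=80,
        context_genome_len=25000,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def context_genome():
    return build_context_genome(30000, 5)


@pytest.fixture(scope="session")
def error_free_libraries(locus):
    """Error-free read libraries for one sample of each genotype."""
    genotypes = np.array([0, 1, 2])
    reads, truth = simulate_rnaseq_reads(
        locus,
        genotypes,
        ExpressionParams(),
        read_length=151,
        error_rate=0.0,
        seed=23,
        n_reads=3000,
        tissues=("tumor",),
        sample_ids=["G0", "G1", "G2"],
    )
    return reads, truth, genotypes
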