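import numpy as np
import pytest

from hexmap import pipeline, sim


@pytest.fixture(scope="session")
def small_pop():
    """Two-chromosome hexaploid F1 at modest marker density: fast enough
    for unit tests of clustering, phasing and IBD mechanics."""
    rng = np.random.default_rng(11)
    p1, p2, design = sim.design_population(
        ploidy=6,
        n_chromosomes=2,
        chrom_length_cM=90.0,
        n_simplex_per_homologue=12,
        n_duplex=12,
        n_simplex_simplex=40,
        seed=rng,
    )
    matrix, truth = sim.simulate_f1(
        p1, p2, 300, rng, marker_ids=design.marker_ids
    )
    return matrix, truth, design


@pytest.fixture(scope="session")
def small_run(small_pop):
    matrix, truth, design = small_pop
    result = pipeline.run_pipeline(matrix, pipeline.RunConfig(seed=1))
    return result, truth, design


@pytest.fixture(scope="session")
def dense_pop():
    """The reference study conditions: n=400 F1 of a hexaploid cross,
    two 90 cM chromosomes, 60 simplex markers per homologue plus 40
    duplex and 40 simplex-x-simplex markers per chromosome, 1% missing
    calls."""
    rng = np.random.default_rng(42)
    p1, p2, design = sim.design_population(
        ploidy=6,
        n_chromosomes=2,
        chrom_length_cM=90.0,
        n_simplex_per_homologue=60,
        n_duplex=40,
        n_simplex_simplex=40,
        seed=rng,
    )
    matrix, truth = sim.simulate_f1(
        p1, p2, 400, rng, missing_rate=0.01, marker_ids=design.marker_ids
    )
    return matrix, truth, design


@pytest.fixture(scope="session")
def dense_run(dense_pop):
    matrix, truth, design = dense_pop
    result = pipeline.run_pipeline(matrix, pipeline.RunConfig(seed=1))
    return result, truth, design
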