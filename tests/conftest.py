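"""Shared simulated-study fixtures (session scoped: the pipeline is reused)."""

import pytest

import hepsex as hx


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study: cohort, pool design, arrays (default noise)."""
    matrix = hx.generate_cohort(n_genes=3000, seed=11)
    design = hx.build_pool_design(matrix, seed=12)
    arrays = hx.simulate_arrays(matrix, design, seed=13)
    return matrix, design, arrays


@pytest.fixture(scope="session")
def small_stats(small_study):
    """Normalized ratios and combined probe statistics for the small study."""
    _, _, arrays = small_study
    ratios, amean = hx.lowess_normalize(arrays)
    errors = hx.estimate_replicate_errors(ratios, amean)
    stats = hx.combine_replicates(ratios, errors)
    return ratios, amean, stats
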