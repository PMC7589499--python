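import numpy as np
import pytest

from consensusde import (SimulationConfig, simulate_dataset, filter_low_counts,
                         rle_factors, pseudo_counts, enumerate_combinations,
                         estimate_common_dispersion, estimate_tagwise_dispersions,
                         nb_exact_test_batch, run_8vs8, run_ranef)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default 16-library design with planted effects."""
    cfg = SimulationConfig(n_genes=1000, seed=101)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null draw: no invasion effects, no site variance."""
    cfg = SimulationConfig(n_genes=2000, seed=21, frac_de=0.0, site_sd=0.0)
    return simulate_dataset(cfg)


def first_combination_pvalues(counts, design, prior_df=10.0):
    """Exact-test p-values for the lexicographically first replicate selection."""
    sel = enumerate_combinations(design)[0]
    sub = counts.subset_libraries(list(sel))
    filt = filter_low_counts(sub)
    fac = rle_factors(filt)
    ps = pseudo_counts(filt, fac)
    cat = design.category_of_library()
    labels = np.array([cat[l] for l in filt.library_ids])
    idx_a = np.flatnonzero(labels == "ancient")
    idx_b = np.flatnonzero(labels == "recent")
    common = estimate_common_dispersion(ps, labels)
    est = estimate_tagwise_dispersions(ps, labels, common, prior_df)
    return nb_exact_test_batch(ps, idx_a, idx_b, est.shrunk)[1]


@pytest.fixture(scope="session")
def null_strategy_pvalues(null_dataset):
    """Raw p-values of all three strategies under the global null."""
    counts, design, _ = null_dataset
    return {
        "fourvfour": first_combination_pvalues(counts, design),
        "eightveight": run_8vs8(counts, design)["p_value"].to_numpy(),
        "ranef": run_ranef(counts, design)["p_value"].to_numpy(),
    }
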