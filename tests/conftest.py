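import numpy as np
import pytest

from medipmre.simulate import (
    gen_bin_content,
    gen_counts,
    gen_library_sizes,
    gen_methylome,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One 50 kb chromosome with 5 planted islands, genes, TADs and counts."""
    truth, counts = simulate_dataset(
        seed=7, chrom_len=50_000, n_islands=5, n_genes=3, n_tads=2,
        dmr_frac=0.1, delta=0.5, mean_depth=60.0,
    )
    return truth, counts


def simulate_counts(seed, n_bins=10_000, dmr_frac=0.1, delta=0.5,
                    base_m=0.5, depth=30.0):
    """Sequence-free two-group count simulation used by statistical tests."""
    content = gen_bin_content(n_bins, seed=seed)
    m, dmr_bins = gen_methylome(n_bins, dmr_frac, delta, base_m, seed=seed + 1)
    library_sizes = gen_library_sizes(seed + 2)
    counts = gen_counts(m, content, library_sizes, depth, seed=seed + 3)
    truth = np.zeros(n_bins, dtype=bool)
    truth[list(dmr_bins)] = True
    return counts, truth, m, library_sizes
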