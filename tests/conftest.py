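import numpy as np
import pandas as pd
import pytest

from hybmeth.simulate import (GroundTruth, SimulationConfig,
                              simulate_allelic_counts, simulate_methylomes,
                              simulate_parental_genomes)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down world (one 60 kb chromosome) for fast unit tests."""
    return SimulationConfig(seed=42, n_chromosomes=1, chrom_length=60_000,
                            n_genes=30)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Full in-memory simulated trio for the small world."""
    rng = np.random.default_rng(small_config.seed)
    genomes, variants, genes = simulate_parental_genomes(small_config, rng)
    meth = simulate_methylomes(small_config, genomes, variants, rng)
    depths, gene_truth = simulate_allelic_counts(small_config, variants, genes, rng)
    truth: GroundTruth = meth["truth"]
    truth.genes = gene_truth
    return {"config": small_config, "genomes": genomes, "variants": variants,
            "genes": genes, "depths": depths, **meth}


def make_meth_frame(rows):
    """rows: (chrom, pos, strand, context, mc, total)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context",
                       "mc_count", "total_count"])
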