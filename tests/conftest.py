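import numpy as np
import pytest

from evoltraj import SimConfig, SnpTable, Locus, SampleMeta, simulate_experiment


@pytest.fixture(scope="session")
def sim_default():
    """One moderate paper-mimicking simulation shared across test modules."""
    cfg = SimConfig(n_loci=400, n_selected=60, n_balanced=60, seed=42)
    return simulate_experiment(cfg)


def make_table(minor, coverage, groups=None, generations=None, replicates=None):
    """Small SnpTable builder for hand-constructed cases."""
    minor = np.asarray(minor)
    coverage = np.asarray(coverage)
    n_loci, n_samples = minor.shape
    loci = [Locus("2L", 100 + i, "T", "A") for i in range(n_loci)]
    groups = groups or ["A2C"] * n_samples
    generations = generations if generations is not None else list(range(n_samples))
    replicates = replicates or [1] * n_samples
    samples = [
        SampleMeta(f"s{j}", groups[j], replicates[j], float(generations[j]),
                   timepoint=f"t{j}")
        for j in range(n_samples)
    ]
    return SnpTable(loci, samples, minor, coverage)
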