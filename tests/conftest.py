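import numpy as np
import pandas as pd
import pytest

from hdgwas.genotypes import GenotypeMatrix, CrossDesign
from hdgwas.simulate import SimulationConfig, QtlSpec, simulate_diallel


def make_geno(calls, chrom=None, positions=None, samples=None):
    """Small helper to build a GenotypeMatrix from a call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = chrom if chrom is not None else [1] * m
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    samples = samples if samples is not None else [f"S{i:02d}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"mk{j:03d}" for j in range(m)],
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return GenotypeMatrix(samples, markers, calls)


@pytest.fixture(scope="session")
def default_diallel():
    """Default-parameter simulation (14 maternal x 3x13 paternal, 12
    chromosomes): the study conditions the generator emulates."""
    cfg = SimulationConfig(seed=0, n_replicates=1, qtl_specs=[])
    from hdgwas.simulate import simulate_parents
    from hdgwas.genotypes import combine_f1

    parents, design = simulate_parents(cfg)
    f1 = combine_f1(parents, design)
    return cfg, parents, design, f1


@pytest.fixture(scope="session")
def small_diallel():
    """6 maternal x 2 families x 4 lines = 48 F1s, 3 chromosomes, with one
    additive+dominant QTL; shared across read-only tests."""
    cfg = SimulationConfig(
        n_maternal=6,
        n_paternal_families=2,
        lines_per_family=4,
        n_chromosomes=3,
        markers_per_chromosome=120,
        chrom_length=30_000_000,
        qtl_specs=[QtlSpec(1, 15_000_000, 1.0, 0.5)],
        h2_polygenic=0.2,
        residual_sd=0.5,
        n_replicates=2,
        seed=11,
    )
    parents, design, f1, table, truth = simulate_diallel(cfg)
    return cfg, parents, design, f1, table, truth
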