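import numpy as np
import pytest

from ribocub import SimulationConfig, simulate_footprints, simulate_transcriptome
from ribocub.genetic_code import STANDARD_CODE


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def small_sim():
    """A modest biased simulation shared across tests (50 genes, 20k reads)."""
    config = SimulationConfig(n_genes=50, n_footprints=20_000, seed=7)
    orfs, truth = simulate_transcriptome(config)
    records = simulate_footprints(orfs, truth, config)
    return config, orfs, truth, records


def random_count_table(rng: np.random.Generator, code=STANDARD_CODE):
    """A random codon count table with a few zeroed amino acids."""
    from ribocub.rscu import CodonCountTable, CodonWindow

    counts = {c: int(rng.integers(0, 200)) for c in code.analysis_codons}
    for aa in rng.choice(code.degenerate_aas, size=2, replace=False):
        for c in code.synonyms(aa):
            counts[c] = 0
    return CodonCountTable(counts, CodonWindow())
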