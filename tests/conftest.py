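import numpy as np
import pytest

from damkit import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across test modules."""
    config = SimulationConfig(
        chrom_lengths=(400_000, 200_000),
        n_genes=150,
        gene_length_median=800.0,
        n_peaks=15,
    )
    genomes, genes, fmap, samples, truth = simulate_dataset(config, seed=42)
    return {
        "config": config,
        "genomes": genomes,
        "genes": genes,
        "fmap": fmap,
        "samples": samples,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def bruteforce_gatc_cuts(seq):
    """Independent motif-scan oracle: str.find loop, cut at start + 2."""
    cuts, pos = [], seq.find("GATC")
    while pos != -1:
        cuts.append(pos + 2)
        pos = seq.find("GATC", pos + 1)
    return cuts


def bruteforce_fragments(seq):
    """Fragment intervals + terminal flags from the cut oracle."""
    bounds = [0, *bruteforce_gatc_cuts(seq), len(seq)]
    n = len(bounds) - 1
    return [
        (bounds[i], bounds[i + 1], i == 0 or i == n - 1) for i in range(n)
    ]
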