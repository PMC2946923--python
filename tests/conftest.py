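import warnings

import pytest

from crisprpop.arrays import Spacer, SpacerArray, load_locus_fasta
from crisprpop.simulate import SimConfig, simulate_population


def make_array(strain, seqs, locus="C", end="leader"):
    """Build a SpacerArray from raw spacer sequences."""
    spacers = [
        Spacer(sequence=s, strain=strain, locus=locus, end=end, position=i + 1)
        for i, s in enumerate(seqs)
    ]
    return SpacerArray(strain=strain, locus=locus, end=end, spacers=spacers)


@pytest.fixture(scope="session")
def sim():
    """One full-scale simulated population shared across tests."""
    return simulate_population(seed=42)


@pytest.fixture(scope="session")
def sim_arrays(sim, tmp_path_factory):
    """Arrays extracted back from the simulator's emitted FASTA."""
    path = tmp_path_factory.mktemp("sim") / "crispr.fasta"
    path.write_text(sim.crispr_fasta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = load_locus_fasta(path)
    return result


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast population for brute-force comparisons."""
    cfg = SimConfig(n_strains=10, n_steps=8, end_depth=6, root_array_length=8, n_full=1)
    return simulate_population(cfg, seed=7)
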