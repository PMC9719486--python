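import numpy as np
import pytest
from hypothesis import settings

from hairline import align as al
from hairline import simulate as sim

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ref() -> sim.ReferenceSet:
    """Compact three-compartment reference shared across the suite."""
    return sim.make_reference(
        [("nuc1", 150_000, "nuclear", 0.41), ("nuc2", 150_000, "nuclear", 0.41),
         ("MT", 16_000, "mito", 0.41), ("decoy1", 100_000, "decoy", 0.41)],
        seed=7,
    )


@pytest.fixture(scope="session")
def endo_library(small_ref):
    """50k purely endogenous hair-model reads, truth-aligned."""
    cfg = sim.LibrarySimConfig(n_reads=50_000, endogenous_fraction=1.0,
                               mito_share=0.1, seed=11)
    reads, truth = sim.simulate_library(small_ref, cfg)
    aln = al.alignments_from_truth(reads, truth, small_ref)
    return reads, truth, aln, cfg


def hand_alignments(records, chrom_names):
    return al.Alignments.from_records(records, chrom_names=chrom_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
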