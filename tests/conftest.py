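import numpy as np
import pytest

from svmodes.model import Breakend, ConsensusSV, GenomeRef, SVCall, TADBoundary
from svmodes.simulate import default_config, simulate_cohort, simulate_genome


def make_call(sample="s1", caller="c1", chrom1="chr1", pos1=1000, o1="+",
              chrom2=None, pos2=5000, o2="-", svtype="DEL"):
    return SVCall.create(
        sample, caller, Breakend(chrom1, pos1, o1), Breakend(chrom2 or chrom1, pos2, o2), svtype
    )


def make_consensus(sample="s1", chrom1="chr1", pos1=1000, o1="+",
                   chrom2=None, pos2=5000, o2="-", svtype="DEL", callers=("c1", "c2")):
    b1 = Breakend(chrom1, pos1, o1)
    b2 = Breakend(chrom2 or chrom1, pos2, o2)
    if b1.sort_key() > b2.sort_key():
        b1, b2 = b2, b1
    return ConsensusSV(sample, b1, b2, svtype, frozenset(callers))


@pytest.fixture(scope="session")
def toy_genome():
    lengths = {f"chr{i + 1}": 1_000_000 for i in range(4)}
    return GenomeRef(list(lengths), lengths)


@pytest.fixture(scope="session")
def toy_boundaries():
    bounds = []
    for c in (f"chr{i + 1}" for i in range(4)):
        for i in range(20):
            s = 45_000 * (i + 1)
            bounds.append(TADBoundary(c, s, s + 5_000, f"{c}_b{i}"))
    return bounds


@pytest.fixture(scope="session")
def small_sim():
    """One shared small synthetic cohort (scale 0.1, moderate noise)."""
    config = default_config(scale=0.1)
    scaffold = simulate_genome(config, seed=11)
    cohort = simulate_cohort(config, scaffold, seed=12)
    return config, scaffold, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)
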