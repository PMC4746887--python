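import numpy as np
import pytest

from teleomob.io import LibraryEntry, TEClass
from teleomob.simulate import (
    DivergenceModel,
    InsertionSpec,
    SimulationConfig,
    random_consensus,
    simulate_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hat_consensus():
    """A 400 bp DNA-transposon consensus used across masking tests."""
    rng = np.random.default_rng(42)
    return LibraryEntry(
        name="hAT-1",
        seq=random_consensus(400, rng),
        te_class=TEClass.DNA,
        superfamily="hAT-Ac",
    )


def make_sim(consensus, genome_length=1_000_000, copies=200, divergence=None,
             seed=7, **spec_kw):
    divergence = divergence or DivergenceModel("point", 0.10)
    cfg = SimulationConfig(
        genome_length=genome_length,
        gc_content=0.40,
        insertion_specs=[
            InsertionSpec(consensus, copy_number=copies, divergence=divergence, **spec_kw)
        ],
        seed=seed,
    )
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def point_mass_sim(hat_consensus):
    """1 Mb genome, 200 copies at a 10 % divergence point mass."""
    return make_sim(hat_consensus)


@pytest.fixture(scope="session")
def spread_sim(hat_consensus):
    """1 Mb genome, 200 copies with divergence spread over 0-25 %."""
    return make_sim(
        hat_consensus, divergence=DivergenceModel("uniform", 0.0, 0.25), seed=11
    )


@pytest.fixture(scope="session")
def point_mass_hits(point_mass_sim, hat_consensus):
    from teleomob.masker import mask_genome

    genome, _ = point_mass_sim
    return mask_genome(genome, [hat_consensus])


@pytest.fixture(scope="session")
def spread_hits(spread_sim, hat_consensus):
    from teleomob.masker import mask_genome

    genome, _ = spread_sim
    return mask_genome(genome, [hat_consensus])


def interval_union(intervals):
    """Union of 1-based inclusive intervals as a sorted list."""
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_bp(a, b):
    """Overlap bp between two sorted disjoint interval lists."""
    i = j = tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            tot += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return tot
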