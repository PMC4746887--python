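"""Shared study design for the analysis scripts: four synthetic species
whose genome sizes and TE loads form a gradient like the four teleosts
(largest genome = most TE-rich, smallest = most compact), with
contrasting divergence profiles (an extended-activity species, a
recent-burst species, and a low-activity species).

Sizes are desk-scale stand-ins (0.3-1.2 Mb instead of 0.3-1.4 Gb); copy
numbers scale with genome size so the TE fraction gradient survives.
"""

from pathlib import Path

import numpy as np

from teleomob.io import LibraryEntry, TEClass
from teleomob.simulate import DivergenceModel, InsertionSpec, SimulationConfig
from teleomob.simulate import random_consensus

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

GLOBAL_SEED = 2016


def shared_library() -> list[LibraryEntry]:
    """One consensus per superfamily, shared across species (the same
    ancestral elements invaded each lineage)."""
    rng = np.random.default_rng(GLOBAL_SEED)
    return [
        LibraryEntry("hAT-1", random_consensus(400, rng), TEClass.DNA, "hAT-Ac"),
        LibraryEntry("Tc1-1", random_consensus(350, rng), TEClass.DNA, "TcMar-Tc1"),
        LibraryEntry("L2-1", random_consensus(500, rng), TEClass.LINE, "L2"),
        LibraryEntry("Gypsy-1", random_consensus(450, rng), TEClass.LTR, "Gypsy"),
    ]


def species_configs() -> dict[str, SimulationConfig]:
    """Four species: TE copy numbers grow with genome size; divergence
    profiles differ (broad/old for the large genomes, one sharp recent
    peak for the third, almost nothing for the smallest)."""
    lib = {e.name: e for e in shared_library()}
    old_broad = DivergenceModel("mixture", components=((0.5, 0.05, 0.15), (0.5, 0.15, 0.30)))
    mid = DivergenceModel("uniform", 0.05, 0.20)
    recent = DivergenceModel("point", 0.03)
    designs = {
        "spDr": (1_200_000, [("hAT-1", 260, old_broad), ("Tc1-1", 160, old_broad),
                             ("L2-1", 90, mid), ("Gypsy-1", 110, mid)]),
        "spOl": (700_000, [("hAT-1", 70, mid), ("Tc1-1", 50, mid),
                           ("L2-1", 60, old_broad), ("Gypsy-1", 30, mid)]),
        "spGa": (450_000, [("hAT-1", 25, recent), ("Tc1-1", 15, recent),
                           ("L2-1", 12, recent), ("Gypsy-1", 14, recent)]),
        "spTn": (300_000, [("hAT-1", 6, mid), ("Tc1-1", 4, mid),
                           ("L2-1", 3, mid), ("Gypsy-1", 3, mid)]),
    }
    configs = {}
    for i, (name, (length, specs)) in enumerate(designs.items()):
        configs[name] = SimulationConfig(
            genome_length=length,
            gc_content=0.40,
            insertion_specs=[
                InsertionSpec(lib[n], copies, div, truncation_prob=0.2)
                for n, copies, div in specs
            ],
            seed=GLOBAL_SEED + i,
            genome_id=name,
        )
    return configs
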