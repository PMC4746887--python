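"""Simulate the four synthetic species genomes with planted TE copies.

Writes per-species genome FASTA, truth TSV and the planted library
under results/sim/, and prints the planted TE fraction per species —
the ground truth the rest of the analysis tries to recover.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SIM_DIR, species_configs, shared_library

from teleomob.io import write_fasta, write_library_fasta
from teleomob.simulate import simulate_genome, write_truth_tsv


def main() -> None:
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    write_library_fasta(shared_library(), SIM_DIR / "library.fa")
    print("species  genome_bp  planted_copies  planted_bp  planted_%")
    for name, cfg in species_configs().items():
        genome, truth = simulate_genome(cfg)
        write_fasta([genome], SIM_DIR / f"{name}_genome.fa")
        write_truth_tsv(truth, SIM_DIR / f"{name}_truth.tsv")
        bp = truth.total_bp()
        print(f"{name:7s}  {len(genome.seq):9d}  {len(truth):14d}  {bp:10d}"
              f"  {100 * bp / len(genome.seq):8.2f}")
    print(f"\noutputs in {SIM_DIR}")


if __name__ == "__main__":
    main()
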