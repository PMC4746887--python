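"""Mask each simulated genome against the shared library and build the
per-species coverage tables and JC-corrected divergence landscapes.

Writes hits (.out), coverage TSVs, landscape TSVs and stacked-bar
landscape figures under results/, and prints recovered vs planted TE
fractions — the masking step's headline accuracy.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, species_configs

from teleomob.io import read_fasta, read_library_fasta, write_rm_out
from teleomob.landscape import coverage_table, landscape, landscape_to_frame, plot_landscape
from teleomob.masker import mask_genome, masked_bp
from teleomob.simulate import read_truth_tsv


def main() -> None:
    lib = read_library_fasta(SIM_DIR / "library.fa")
    outdir = RESULTS / "masking"
    outdir.mkdir(parents=True, exist_ok=True)
    print("species  planted_%  masked_%  hits")
    for name in species_configs():
        genome = read_fasta(SIM_DIR / f"{name}_genome.fa")[0]
        truth = read_truth_tsv(SIM_DIR / f"{name}_truth.tsv")
        hits = mask_genome(genome, lib)
        write_rm_out(hits, outdir / f"{name}_hits.out")

        rows = coverage_table(hits, len(genome.seq), "superfamily")
        pd.DataFrame([r.__dict__ for r in rows]).to_csv(
            outdir / f"{name}_coverage.tsv", sep="\t", index=False
        )
        bins, spill = landscape(hits, len(genome.seq), group_by="superfamily")
        landscape_to_frame(bins).to_csv(outdir / f"{name}_landscape.tsv",
                                        sep="\t", index=False)
        plot_landscape(bins, len(genome.seq), outdir / f"{name}_landscape.png",
                       title=f"{name} repeat landscape")

        bp, frac = masked_bp(hits, len(genome.seq))
        planted = 100 * truth.total_bp() / len(genome.seq)
        print(f"{name:7s}  {planted:9.2f}  {100 * frac:8.2f}  {len(hits):5d}")
    print(f"\noutputs in {outdir}")


if __name__ == "__main__":
    main()
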