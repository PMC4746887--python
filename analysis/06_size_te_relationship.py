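"""Cross-species comparison: does TE content track genome size?

Aggregates the per-species masking summaries from step 02 into the
genome-size ~ TE-fraction regression (the planted design makes the true
answer yes), and repeats the regression on the published four-species
coverage table, using the genome sizes implied by each printed
(percent, Mb) pair.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SIM_DIR, species_configs

from teleomob.io import read_fasta, read_rm_out
from teleomob.landscape import SizeTEPoint, size_te_regression
from teleomob.masker import masked_bp

PUBLISHED = {  # total interspersed repeats: (% of genome, Mb masked)
    "zebrafish": (56.49, 773.70),
    "medaka": (33.70, 236.28),
    "stickleback": (14.21, 63.48),
    "tetraodon": (7.13, 21.55),
}


def main() -> None:
    pts = []
    print("species  genome_Mb  TE_%")
    for name in species_configs():
        genome = read_fasta(SIM_DIR / f"{name}_genome.fa")[0]
        hits = read_rm_out(RESULTS / "masking" / f"{name}_hits.out")
        bp, frac = masked_bp(hits, len(genome.seq))
        pts.append(SizeTEPoint(name, len(genome.seq) / 1e6, 100 * frac))
        print(f"{name:7s}  {len(genome.seq) / 1e6:9.3f}  {100 * frac:5.2f}")
    slope, intercept, r = size_te_regression(pts)
    print(f"\nsynthetic species:  TE% = {slope:.2f} * Mb + {intercept:.2f}   r = {r:.3f}")

    pub = [SizeTEPoint(sp, mb / (pct / 100), pct) for sp, (pct, mb) in PUBLISHED.items()]
    slope_p, intercept_p, r_p = size_te_regression(pub)
    print(f"published table:    TE% = {slope_p:.4f} * Mb + {intercept_p:.2f}   r = {r_p:.3f}")

    outdir = RESULTS / "compare"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(p.species, p.genome_size_mb, p.te_fraction_pct) for p in pts + pub],
        columns=["species", "genome_size_mb", "te_fraction_pct"],
    ).to_csv(outdir / "size_te_points.tsv", sep="\t", index=False)
    print(f"\noutputs in {outdir}")


if __name__ == "__main__":
    main()
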