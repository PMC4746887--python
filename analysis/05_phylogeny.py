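"""Bootstrapped neighbor-joining phylogeny of the recovered LINE
families' RT-bearing proteins.

Uses the family representatives from step 04 (truncated to a common
conserved window so the alignment is ungapped), builds the NJ tree from
amino-acid p-distances, attaches 100-replicate bootstrap supports, and
writes the Newick tree.  Families planted within one clade should
cluster together with strong support.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from teleomob.phylo import MultipleAlignment, PhyloParams, bootstrap_support


def main() -> None:
    fam_path = RESULTS / "families" / "families.tsv"
    if not fam_path.exists():
        sys.exit("run 04_autonomous_families.py first")
    outdir = RESULTS / "phylo"
    outdir.mkdir(parents=True, exist_ok=True)

    fams = pd.read_csv(fam_path, sep="\t")
    # one representative element per family: the spDr member when present
    reps = fams.sort_values("species").groupby("family_id").first().reset_index()

    # proteins from step 04 are stored with the elements; re-derive the
    # comparison window from the per-family protein dump
    prot_path = RESULTS / "families" / "family_proteins.tsv"
    if not prot_path.exists():
        sys.exit("family_proteins.tsv missing; re-run 04_autonomous_families.py")
    prots = pd.read_csv(prot_path, sep="\t").set_index("element")["protein"]
    window = min(len(p) for p in prots)
    taxa, rows = [], []
    for _, row in reps.iterrows():
        taxa.append(f"{row.family_id}|{row.clade}")
        rows.append(prots[row.element][:window])

    aln = MultipleAlignment(tuple(taxa), tuple(rows))
    tree, support = bootstrap_support(aln, PhyloParams(bootstrap_replicates=100, seed=3))
    (outdir / "line_families.nwk").write_text(tree.newick() + "\n")
    print(f"{len(taxa)} family representatives, alignment width {window} aa")
    print("internal splits and bootstrap support:")
    for split, sup in sorted(support.items(), key=lambda kv: -kv[1]):
        print(f"  {sup:5.1f}%  {{{', '.join(sorted(split))}}}")
    print(f"\ntree -> {outdir / 'line_families.nwk'}")


if __name__ == "__main__":
    main()
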