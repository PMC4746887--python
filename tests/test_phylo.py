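"""p-distances, neighbor joining and bootstrap support, with independent
oracles: random additive trees (NJ must recover them exactly) and
scikit-bio's NJ implementation as a cross-check."""

import dendropy
import numpy as np
import pytest

from teleomob.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    PhyloParams,
    bootstrap_support,
    nj_tree,
    p_distance,
    tree_splits,
)


# --- random additive trees as generating oracles ---------------------------

def random_additive(n_taxa, rng):
    """Random binary tree topology with positive branch lengths; returns
    (taxon names, distance matrix, set of true internal splits)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: None for t in taxa}  # leaf -> parent edge accumulated later
    # build by random joins, tracking leaf-to-leaf path lengths
    d = np.zeros((n_taxa, n_taxa))
    groups = [[i] for i in range(n_taxa)]
    dist_to_root = np.zeros(n_taxa)
    splits = set()
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        bi, bj = rng.uniform(0.5, 3.0, size=2)
        for a in groups[i]:
            dist_to_root[a] += bi
        for b in groups[j]:
            dist_to_root[b] += bj
        for a in groups[i]:
            for b in groups[j]:
                d[a, b] = d[b, a] = dist_to_root[a] + dist_to_root[b]
        merged = groups[i] + groups[j]
        if 2 <= len(merged) <= n_taxa - 2:
            splits.add(frozenset(taxa[k] for k in merged))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    # canonicalize splits relative to the smallest taxon
    ref = min(taxa)
    canon = set()
    for s in splits:
        canon.add(frozenset(set(taxa) - s) if ref in s else s)
    return taxa, d, canon


def tree_path_lengths(tree):
    """Leaf-to-leaf path length matrix of a TreeNode tree (oracle for
    branch-length correctness on additive inputs)."""
    leaves = sorted(tree.leaves(), key=lambda l: l.name)
    names = [l.name for l in leaves]

    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree, [])
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[names[i]], paths[names[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                k += 1
            length = sum(x.length for x in pi[k:]) + sum(x.length for x in pj[k:])
            d[i, j] = d[j, i] = length
    return names, d


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(("a", "b"), ("MKLV", "MKLV"))
        assert p_distance(aln).d[0, 1] == 0.0

    def test_by_definition(self):
        aln = MultipleAlignment(("a", "b"), ("AAAAACCCCC", "AAAAAGGGGG"))
        assert p_distance(aln).d[0, 1] == 0.5

    def test_all_gap_column_ignored(self):
        a = MultipleAlignment(("a", "b"), ("MKLV", "MKIV"))
        b = MultipleAlignment(("a", "b"), ("MK-LV", "MK-IV"))
        assert p_distance(a).d[0, 1] == p_distance(b).d[0, 1]

    def test_pairwise_vs_complete_deletion(self):
        aln = MultipleAlignment(("a", "b", "c"), ("MKLV", "-KLV", "MKIV"))
        pw = p_distance(aln, "pairwise_deletion")
        cd = p_distance(aln, "complete_deletion")
        assert pw.d[0, 2] == 0.25  # 4 comparable columns for the a-c pair
        assert cd.d[0, 2] == pytest.approx(1 / 3)  # b's gap column dropped for all

    def test_no_comparable_columns_names_pair(self):
        aln = MultipleAlignment(("x", "y"), ("M-", "-M"))
        with pytest.raises(ValueError, match="'x'.*'y'"):
            p_distance(aln)

    def test_symmetry_axioms(self, rng):
        rows = tuple(
            "".join(rng.choice(list("ACDEFGHIKL"), size=30)) for _ in range(5)
        )
        dm = p_distance(MultipleAlignment(tuple("abcde"), rows))
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)


class TestNJ:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.4, 0.6, 0.8
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]))
        tree = nj_tree(dm)
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["A"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["B"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["C"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_cherries_recovered_from_ultrametric(self):
        # two clear pairs (A,B) and (C,D)
        d = np.array(
            [[0, 0.2, 1.0, 1.0],
             [0.2, 0, 1.0, 1.0],
             [1.0, 1.0, 0, 0.2],
             [1.0, 1.0, 0.2, 0]]
        )
        tree = nj_tree(DistanceMatrix(tuple("ABCD"), d))
        assert tree_splits(tree) == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("draw", range(50))
    def test_additive_recovery_exact(self, draw):
        """Topology and branch lengths recovered exactly from additive
        matrices of 4-8 taxa (NJ's consistency guarantee)."""
        rng = np.random.default_rng(500 + draw)
        n = int(rng.integers(4, 9))
        taxa, d, true_splits = random_additive(n, rng)
        tree = nj_tree(DistanceMatrix(tuple(taxa), d))
        assert tree_splits(tree) == true_splits
        names, dhat = tree_path_lengths(tree)
        order = [names.index(t) for t in taxa]
        assert np.allclose(dhat[np.ix_(order, order)], d, atol=1e-9)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        taxa, d, _ = random_additive(6, rng)
        noisy = d + rng.uniform(0, 0.05, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = nj_tree(DistanceMatrix(tuple(taxa), noisy))
        sk = skbio_nj(SkbioDM(noisy, ids=taxa))
        sk_splits = set()
        ref = min(taxa)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(taxa) - 2:
                sk_splits.add(frozenset(set(taxa) - side) if ref in side else side)
        assert tree_splits(ours) == sk_splits

    def test_newick_parses_with_dendropy(self):
        rng = np.random.default_rng(9)
        taxa, d, _ = random_additive(5, rng)
        tree = nj_tree(DistanceMatrix(tuple(taxa), d))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(taxa)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


class TestBootstrap:
    def test_perfect_partition_full_support(self):
        aln = MultipleAlignment(
            ("x1", "x2", "y1", "y2"),
            ("AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"),
        )
        _, support = bootstrap_support(aln, PhyloParams(bootstrap_replicates=50, seed=3))
        assert support == {frozenset({"y1", "y2"}): 100.0}

    def test_supports_bounded_and_reproducible(self, rng):
        rows = tuple("".join(rng.choice(list("ACDE"), size=40)) for _ in range(5))
        aln = MultipleAlignment(tuple("abcde"), rows)
        params = PhyloParams(bootstrap_replicates=30, seed=11)
        _, s1 = bootstrap_support(aln, params)
        _, s2 = bootstrap_support(aln, params)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())

    def test_taxon_order_invariance(self, rng):
        rows = ["".join(rng.choice(list("ACDEFG"), size=60)) for _ in range(6)]
        taxa = [f"t{i}" for i in range(6)]
        aln1 = MultipleAlignment(tuple(taxa), tuple(rows))
        aln2 = MultipleAlignment(tuple(taxa[::-1]), tuple(rows[::-1]))
        p = PhyloParams(bootstrap_replicates=25, seed=5)
        _, s1 = bootstrap_support(aln1, p)
        _, s2 = bootstrap_support(aln2, p)
        assert set(s1) == set(s2)  # same canonical splits on the full tree

    def test_planted_family_clades_high_support(self):
        """4 families at ~50 % between / 5 % within divergence: each
        family clade is recovered with >= 95 % support at 100 reps."""
        rng = np.random.default_rng(99)
        aa = list("ACDEFGHIKLMNPQRSTVWY")

        def mutate(p, prop):
            arr = list(p)
            for s in rng.choice(len(p), size=int(prop * len(p)), replace=False):
                arr[s] = aa[rng.integers(20)]
            return "".join(arr)

        root = "".join(rng.choice(aa, size=200))
        taxa, rows = [], []
        for f in range(4):
            anc = mutate(root, 0.5)
            for m in range(3):
                taxa.append(f"f{f}_m{m}")
                rows.append(mutate(anc, 0.05))
        aln = MultipleAlignment(tuple(taxa), tuple(rows))
        tree, support = bootstrap_support(aln, PhyloParams(bootstrap_replicates=100, seed=13))
        splits = tree_splits(tree)
        for f in range(4):
            clade = frozenset(f"f{f}_m{m}" for m in range(3))
            ref_side = clade if "f0_m0" not in clade else frozenset(set(taxa) - clade)
            assert ref_side in splits
            assert support[ref_side] >= 95.0
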