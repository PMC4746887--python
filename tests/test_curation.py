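"""Library curation: copy collection, consensus building, and the 80-80
redundancy rule, checked against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from Bio import Align

from teleomob.curation import (
    CurationParams,
    InsufficientCopiesError,
    align_with_mafft,
    build_consensus,
    cluster_80_80,
    collect_copies,
    merge_libraries,
    pair_80_80,
    union_find_clusters,
)
from teleomob.io import LibraryEntry, SequenceRecord
from teleomob.simulate import (
    DivergenceModel,
    InsertionSpec,
    SimulationConfig,
    mutate_sequence,
    random_consensus,
    simulate_genome,
)


# --- independent oracle: exhaustive pair matrix + networkx components ------

def _oracle_pair(a: str, b: str, coverage=0.80, identity=0.80) -> bool:
    """Brute-force 80-80 decision from a full local alignment computed
    with an independently configured aligner."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    aln = al.align(a, b)[0]
    c = aln.counts()
    if c.identities + c.mismatches == 0:
        return False
    ident = c.identities / (c.identities + c.mismatches)
    ta, qa = aln.aligned
    if len(ta) == 0:
        return False
    span_a = int(ta[-1][1]) - int(ta[0][0])
    span_b = int(qa[-1][1]) - int(qa[0][0])
    cov = span_a / len(a) if len(a) <= len(b) else span_b / len(b)
    return cov > coverage and ident > identity


def _oracle_clusters(entries):
    g = nx.Graph()
    g.add_nodes_from(range(len(entries)))
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if _oracle_pair(entries[i].seq, entries[j].seq):
                g.add_edge(i, j)
    return {frozenset(entries[i].name for i in comp) for comp in nx.connected_components(g)}


def _random_library(rng, n_seeds=4, max_entries=12):
    """Random mix of unrelated sequences, diverged derivatives and
    fragments — the structures the 80-80 rule must resolve."""
    entries = []
    k = 0
    for s in range(n_seeds):
        base = random_consensus(int(rng.integers(200, 400)), rng)
        entries.append(LibraryEntry(f"e{k:02d}", base))
        k += 1
        for _ in range(int(rng.integers(0, 3))):
            if len(entries) >= max_entries:
                break
            choice = rng.random()
            if choice < 0.4:
                seq, _ = mutate_sequence(base, float(rng.uniform(0.02, 0.15)), rng)
            elif choice < 0.7:
                seq, _ = mutate_sequence(base, float(rng.uniform(0.3, 0.5)), rng)
            else:
                cut = int(rng.integers(len(base) // 4, len(base) // 2))
                seq = base[cut:]
            entries.append(LibraryEntry(f"e{k:02d}", seq))
            k += 1
    return entries


class TestPair8080:
    def test_identical_sequences(self, rng):
        s = random_consensus(1000, rng)
        assert pair_80_80(LibraryEntry("a", s), LibraryEntry("b", s))

    def test_25_percent_substituted_fails_identity(self, rng):
        s = random_consensus(1000, rng)
        mut, _ = mutate_sequence(s, 0.25, rng)
        assert not pair_80_80(LibraryEntry("a", s), LibraryEntry("b", mut))
        assert not _oracle_pair(s, mut)  # oracle agrees

    def test_exact_fragment_fully_covered(self, rng):
        s = random_consensus(1000, rng)
        assert pair_80_80(LibraryEntry("a", s), LibraryEntry("b", s[250:750]))

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            pair_80_80(LibraryEntry("a", ""), LibraryEntry("b", "ACGT"))


class TestCluster8080:
    def test_distinct_sequences_are_singletons(self, rng):
        entries = [LibraryEntry(f"r{i}", random_consensus(300, rng)) for i in range(6)]
        clusters = cluster_80_80(entries)
        assert all(len(c.members) == 1 for c in clusters)
        assert len(clusters) == 6

    def test_single_linkage_chain(self, rng):
        a = random_consensus(800, rng)
        b, _ = mutate_sequence(a, 0.12, rng)
        c, _ = mutate_sequence(b, 0.12, rng)
        entries = [LibraryEntry(n, s) for n, s in zip("ABC", (a, b, c))]
        assert not _oracle_pair(a, c)  # A-C below 80 % identity on its own
        clusters = cluster_80_80(entries)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_known_member_is_representative(self, rng):
        s = random_consensus(500, rng)
        near, _ = mutate_sequence(s, 0.01, rng)
        known = LibraryEntry("RBase-1", s, source="known")
        denovo = LibraryEntry("cons1", near, source="de_novo")
        clusters = cluster_80_80([denovo, known])
        assert len(clusters) == 1
        assert clusters[0].representative.name == "RBase-1"

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        entries = _random_library(rng)
        got = {
            frozenset(m.name for m in c.members) for c in cluster_80_80(entries)
        }
        assert got == _oracle_clusters(entries)

    def test_order_invariance(self, rng):
        entries = _random_library(rng)
        fwd = {frozenset(m.name for m in c.members) for c in cluster_80_80(entries)}
        rev = {frozenset(m.name for m in c.members) for c in cluster_80_80(entries[::-1])}
        assert fwd == rev

    def test_union_find_components(self):
        assert union_find_clusters(5, [(0, 1), (1, 2)]) == [[0, 1, 2], [3], [4]]


class TestMergeLibraries:
    def test_empty_denovo_identity(self, rng):
        known = [LibraryEntry(f"k{i}", random_consensus(300, rng), source="known")
                 for i in range(4)]
        assert merge_libraries(known, []) == known

    def test_known_empty_distinct_denovo(self, rng):
        denovo = [LibraryEntry(f"d{i}", random_consensus(300, rng)) for i in range(5)]
        assert len(merge_libraries([], denovo)) == 5

    def test_redundant_denovo_collapse_onto_known(self, rng):
        base = random_consensus(600, rng)
        known = [LibraryEntry("K", base, source="known")]
        denovo = [
            LibraryEntry(f"d{i}", mutate_sequence(base, 0.05, rng)[0]) for i in range(5)
        ]
        merged = merge_libraries(known, denovo)
        assert [e.name for e in merged] == ["K"]

    def test_output_is_self_nonredundant(self, rng):
        entries = _random_library(rng, n_seeds=3)
        merged = merge_libraries([], entries)
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                assert not pair_80_80(merged[i], merged[j])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(77)
    cons = random_consensus(400, rng)
    cfg = SimulationConfig(
        genome_length=200_000, seed=31,
        insertion_specs=[InsertionSpec(LibraryEntry("TE1", cons), copy_number=20,
                                       divergence=DivergenceModel("point", 0.08))],
    )
    genome, truth = simulate_genome(cfg)
    return cons, genome, truth


class TestCollectCopies:
    def test_recovers_planted_copies(self, planted):
        cons, genome, truth = planted
        recs = collect_copies(genome, SequenceRecord("TE1", cons),
                              rng=np.random.default_rng(2))
        assert len(recs) == 20  # one flanked record per planted copy

    def test_flank_clipped_at_contig_end(self, planted):
        cons, genome, truth = planted
        params = CurationParams(flank_bp=500)
        recs = collect_copies(genome, SequenceRecord("TE1", cons), params,
                              rng=np.random.default_rng(2))
        first = min(truth, key=lambda r: r.start)
        max_len = 400 + 2 * 500
        assert all(len(r.seq) <= max_len for r in recs)

    def test_insufficient_copies_error(self, rng):
        cons = random_consensus(400, rng)
        cfg = SimulationConfig(genome_length=50_000, seed=4,
                               insertion_specs=[InsertionSpec(LibraryEntry("T", cons), 1)])
        genome, _ = simulate_genome(cfg)
        with pytest.raises(InsufficientCopiesError):
            collect_copies(genome, SequenceRecord("T", cons), rng=np.random.default_rng(2))

    def test_top_hits_cap(self, planted):
        cons, genome, _ = planted
        params = CurationParams(top_hits_min=5, top_hits_max=5)
        recs = collect_copies(genome, SequenceRecord("TE1", cons), params,
                              rng=np.random.default_rng(2))
        assert len(recs) == 5


class TestConsensus:
    def test_unanimity(self):
        rows = [SequenceRecord(f"r{i}", "ACGTACGT") for i in range(3)]
        assert build_consensus(rows).seq == "ACGTACGT"

    def test_column_majority_and_gap_drop(self):
        rows = [
            SequenceRecord("r1", "AC-T"),
            SequenceRecord("r2", "AC-T"),
            SequenceRecord("r3", "CCGT"),
        ]
        # col1 {A,A,C}->A; col3 gap-majority dropped
        assert build_consensus(rows).seq == "ACT"

    def test_tie_breaks_by_base_precedence(self):
        rows = [SequenceRecord("r1", "AG"), SequenceRecord("r2", "GA")]
        assert build_consensus(rows).seq == "AA"

    def test_empty_alignment_error(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_rebuilt_consensus_matches_source(self, rng):
        """50 copies at 10 % divergence vote back the true consensus."""
        cons = random_consensus(400, rng)
        copies = [
            SequenceRecord(f"c{i}", mutate_sequence(cons, 0.10, rng)[0])
            for i in range(50)
        ]
        rebuilt = build_consensus(copies)
        identity = np.mean([x == y for x, y in zip(rebuilt.seq, cons)])
        assert identity >= 0.99

    def test_flanked_copies_consensus_via_mafft(self):
        """End-to-end: collect flanked copies, align, trim edges, and
        recover the planted element at full length."""
        rng = np.random.default_rng(55)
        cons = random_consensus(400, rng)
        cfg = SimulationConfig(
            genome_length=150_000, seed=61,
            insertion_specs=[InsertionSpec(LibraryEntry("TE1", cons), copy_number=15,
                                           divergence=DivergenceModel("point", 0.08))],
        )
        genome, _ = simulate_genome(cfg)
        copies = collect_copies(genome, SequenceRecord("TE1", cons),
                                rng=np.random.default_rng(2))
        aligned = align_with_mafft(copies)
        rebuilt = build_consensus(aligned, trim_edges=True)
        assert abs(len(rebuilt.seq) - 400) <= 8
        assert pair_80_80(LibraryEntry("re", rebuilt.seq), LibraryEntry("true", cons))
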