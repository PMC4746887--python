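"""Repeat-library curation.

Collects genomic copies of a query element (with flanking context),
builds majority-rule consensus sequences from their multiple alignment,
filters redundancy with the 80-80 rule (two nucleotide sequences belong
to the same family when a local alignment covers more than 80 % of the
shorter sequence at more than 80 % identity), and merges de novo repeats
with a known library into a non-redundant custom library.

Copy collection mirrors the classical recipe: the top-scoring
non-overlapping hits (at most ``top_hits_max``), each extracted with
``flank_bp`` of flanking genomic sequence.  Hit significance is judged
against a shuffled-sequence null: the query is shuffled a few times,
re-searched, and the best null score (plus a margin) becomes the score
floor — a tool-independent stand-in for a BLAST E-value cutoff.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import (
    LibraryEntry,
    SequenceRecord,
    TEClass,
    read_fasta,
    revcomp,
    write_fasta,
)
from .masker import MaskerParams, mask_genome

__all__ = [
    "CurationParams",
    "FamilyClusterNT",
    "InsufficientCopiesError",
    "collect_copies",
    "align_with_mafft",
    "build_consensus",
    "pair_80_80",
    "cluster_80_80",
    "merge_libraries",
    "union_find_clusters",
]


@dataclass
class CurationParams:
    top_hits_min: int = 10
    top_hits_max: int = 40
    flank_bp: int = 500
    rule_coverage: float = 0.80
    rule_identity: float = 0.80
    coverage_denominator: str = "shorter"  # or "longer"
    null_shuffles: int = 3
    null_margin: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.rule_coverage <= 1 and 0 < self.rule_identity <= 1):
            raise ValueError("coverage and identity must lie in (0, 1]")
        if self.top_hits_min > self.top_hits_max:
            raise ValueError("top_hits_min must be <= top_hits_max")


@dataclass
class FamilyClusterNT:
    """A single-linkage component of the 80-80 pair graph."""

    members: list[LibraryEntry]
    representative: LibraryEntry


class InsufficientCopiesError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Copy collection
# ---------------------------------------------------------------------------

def collect_copies(
    genome: SequenceRecord,
    query: SequenceRecord,
    params: CurationParams | None = None,
    masker_params: MaskerParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Extract the top non-overlapping genomic copies of ``query`` with
    ``flank_bp`` of context on each side (clipped at contig ends).

    Nucleotide queries run through the internal masker; protein queries
    are matched against six-frame translations of the genome.  Copies are
    returned query-oriented ("-" hits reverse-complemented) so they can
    be aligned directly.  Fewer than 2 surviving hits raises
    :class:`InsufficientCopiesError` (a consensus needs at least 2).
    """
    params = params or CurationParams()
    masker_params = masker_params or MaskerParams()
    rng = rng or np.random.default_rng(0)

    if query.alphabet == "aa":
        raw = _protein_hits(genome, query.seq)
        null_floor = _protein_null_floor(genome, query.seq, params, rng)
    else:
        entry = LibraryEntry(name=query.id, seq=query.seq)
        raw = [
            (h.start, h.end, h.strand, h.score)
            for h in mask_genome(genome, [entry], masker_params)
        ]
        null_floor = _nt_null_floor(genome, query.seq, params, masker_params, rng)

    raw = [h for h in raw if h[3] > null_floor]
    raw.sort(key=lambda h: (-h[3], h[0]))
    chosen: list[tuple[int, int, str, float]] = []
    for h in raw:  # greedy non-overlap (protein path; masker output already disjoint)
        if all(h[1] < c[0] or h[0] > c[1] for c in chosen):
            chosen.append(h)
        if len(chosen) >= params.top_hits_max:
            break
    if len(chosen) < 2:
        raise InsufficientCopiesError(
            f"only {len(chosen)} significant copies of '{query.id}' found; need >= 2"
        )

    records = []
    G = len(genome.seq)
    for i, (s, e, strand, score) in enumerate(sorted(chosen), 1):
        lo = max(1, s - params.flank_bp)
        hi = min(G, e + params.flank_bp)
        seq = genome.seq[lo - 1 : hi]
        if strand == "-":
            seq = revcomp(seq)
        records.append(
            SequenceRecord(
                id=f"{query.id}_copy{i}",
                seq=seq,
                description=f"{genome.id}:{lo}-{hi}({strand}) score={score:.0f}",
            )
        )
    return records


def _nt_null_floor(genome, query_seq, params, masker_params, rng) -> float:
    best = 0.0
    arr = list(query_seq)
    for _ in range(params.null_shuffles):
        rng.shuffle(arr)
        entry = LibraryEntry(name="null", seq="".join(arr))
        hits = mask_genome(genome, [entry], masker_params)
        if hits:
            best = max(best, max(h.score for h in hits))
    return best + params.null_margin


def _protein_null_floor(genome, protein, params, rng) -> float:
    best = 0.0
    arr = list(protein)
    for _ in range(params.null_shuffles):
        rng.shuffle(arr)
        hits = _protein_hits(genome, "".join(arr))
        if hits:
            best = max(best, max(h[3] for h in hits))
    return best + 2 * params.null_margin


# --- protein-vs-genome search (six-frame) ----------------------------------

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWYBXZJUO*"
_AA_CODE = np.full(256, len(_AA_ORDER), dtype=np.int64)
for _i, _c in enumerate(_AA_ORDER):
    _AA_CODE[ord(_c)] = _i


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def _aa_seed_diagonals(haystack: str, needle: str, k: int = 4) -> list[list[int]]:
    h = _AA_CODE[np.frombuffer(haystack.encode(), dtype=np.uint8)]
    n = _AA_CODE[np.frombuffer(needle.encode(), dtype=np.uint8)]
    if len(n) < k or len(h) < k:
        return []
    base = len(_AA_ORDER) + 1
    powers = (base ** np.arange(k - 1, -1, -1)).astype(np.int64)
    hv = np.lib.stride_tricks.sliding_window_view(h, k) @ powers
    nv = np.lib.stride_tricks.sliding_window_view(n, k) @ powers
    order = np.argsort(hv, kind="stable")
    hs = hv[order]
    lo = np.searchsorted(hs, nv, "left")
    hi = np.searchsorted(hs, nv, "right")
    diag = set()
    for qi, (l, hgh) in enumerate(zip(lo, hi)):
        if 0 < hgh - l <= 200:
            for p in order[l:hgh]:
                diag.add(int(p) - qi)
    diags = sorted(diag)
    if not diags:
        return []
    clusters = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= 10:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    return clusters


def _protein_hits(genome: SequenceRecord, protein: str) -> list[tuple[int, int, str, float]]:
    """Local BLOSUM62 hits of ``protein`` in all 6 translation frames,
    mapped back to 1-based nucleotide coordinates on the forward strand."""
    aligner = _protein_aligner()
    G = len(genome.seq)
    out: list[tuple[int, int, str, float]] = []
    for strand in "+-":
        nt = genome.seq if strand == "+" else revcomp(genome.seq)
        for frame in range(3):
            usable = (G - frame) // 3 * 3
            if usable < 3:
                continue
            aa = str(Seq(nt[frame : frame + usable]).translate())
            for cluster in _aa_seed_diagonals(aa, protein):
                dlo, dhi = cluster[0], cluster[-1]
                ws = max(0, dlo - 20)
                we = min(len(aa), dhi + len(protein) + 20)
                window = aa[ws:we]
                alns = aligner.align(window, protein)
                if alns.score <= 0:
                    continue
                aln = alns[0]
                tb = aln.aligned[0]
                if len(tb) == 0:
                    continue
                a0 = ws + int(tb[0][0])
                a1 = ws + int(tb[-1][1])
                nt0 = frame + 3 * a0  # 0-based on `nt`
                nt1 = frame + 3 * a1
                if strand == "+":
                    s, e = nt0 + 1, nt1
                else:
                    s, e = G - nt1 + 1, G - nt0
                out.append((s, e, strand, float(aln.score)))
    # deduplicate near-identical windows, keep best score per interval
    best: dict[tuple[int, int, str], float] = {}
    for s, e, st, sc in out:
        key = (s, e, st)
        if key not in best or sc > best[key]:
            best[key] = sc
    return [(s, e, st, sc) for (s, e, st), sc in best.items()]


# ---------------------------------------------------------------------------
# Consensus building
# ---------------------------------------------------------------------------

def align_with_mafft(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Multiple-align nucleotide records with the ``mafft`` binary
    (FFT-NS-2 progressive mode: near-identical element copies do not
    need iterative refinement)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        write_fasta(records, inp)
        proc = subprocess.run(
            ["mafft", "--retree", "2", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(tmp) / "out.fa"
        out.write_text(proc.stdout)
        return read_fasta(out, alphabet="nt-aln")


def build_consensus(
    aligned: Sequence[SequenceRecord],
    name: str = "consensus",
    trim_edges: bool = False,
    edge_agreement: float = 0.6,
    edge_run: int = 10,
) -> SequenceRecord:
    """Majority-rule consensus of an alignment.

    Per column: if non-gap characters form the column majority, emit the
    most frequent non-gap base (ties broken by the fixed precedence
    A > C > G > T); otherwise drop the column.

    With ``trim_edges`` the alignment's flanks are removed first: edge
    columns are discarded until ``edge_run`` consecutive columns show a
    majority-base agreement of at least ``edge_agreement`` among non-gap
    rows.  Unrelated flanking genomic context aligns as low-agreement
    (or gap-dominated) columns, whereas genuine element columns agree at
    roughly one minus the copy divergence, so this recovers the element
    boundaries when copies were extracted with flanks.
    """
    if not aligned:
        raise ValueError("empty alignment")
    ncol = len(aligned[0].seq)
    if any(len(r.seq) != ncol for r in aligned):
        raise ValueError("alignment rows differ in length")
    mat = np.array([list(r.seq.upper()) for r in aligned])

    precedence = "ACGT"

    def column_pick(col) -> tuple[str | None, float]:
        """(majority base or None, agreement among non-gap rows)."""
        nongap = col[(col != "-") & (col != ".")]
        if len(nongap) * 2 <= len(col):
            return None, 0.0
        counts = {b: int((nongap == b).sum()) for b in set(nongap)}
        best = max(counts.values())
        winners = [b for b, c in counts.items() if c == best]
        pick = min(winners, key=lambda b: precedence.index(b) if b in precedence else 99)
        return pick, best / len(nongap)

    picks = [column_pick(col) for col in mat.T]
    lo, hi = 0, ncol
    if trim_edges:
        good = [p is not None and agr >= edge_agreement for p, agr in picks]
        lo = _first_run(good, edge_run)
        hi = ncol - _first_run(good[::-1], edge_run)
        if lo >= hi:
            lo, hi = 0, ncol  # no confident core found; keep everything
    out = [p for p, _ in picks[lo:hi] if p is not None]
    if not out:
        raise ValueError("consensus is empty (all columns gap-dominated)")
    return SequenceRecord(id=name, seq="".join(out))


def _first_run(flags: Sequence[bool], run: int) -> int:
    count = 0
    for i, f in enumerate(flags):
        count = count + 1 if f else 0
        if count >= run:
            return i - run + 1
    return len(flags)


# ---------------------------------------------------------------------------
# 80-80 rule
# ---------------------------------------------------------------------------

def _nt_local_aligner(params: MaskerParams | None = None) -> Align.PairwiseAligner:
    p = params or MaskerParams()
    return p.aligner()


def pair_80_80(
    a: LibraryEntry,
    b: LibraryEntry,
    params: CurationParams | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> bool:
    """True iff a local alignment covers more than ``rule_coverage`` of
    the shorter sequence's length with identity above ``rule_identity``
    over aligned (non-gap) columns."""
    params = params or CurationParams()
    if not a.seq or not b.seq:
        raise ValueError("empty sequence in 80-80 comparison")
    aligner = aligner or _nt_local_aligner()
    alns = aligner.align(a.seq, b.seq)
    if alns.score <= 0:
        return False
    aln = alns[0]
    counts = aln.counts()
    ident_cols = counts.identities + counts.mismatches
    if ident_cols == 0:
        return False
    identity = counts.identities / ident_cols

    tb, qb = aln.aligned
    if len(tb) == 0:
        return False
    span_a = int(tb[-1][1]) - int(tb[0][0])
    span_b = int(qb[-1][1]) - int(qb[0][0])
    if params.coverage_denominator == "shorter":
        if len(a.seq) <= len(b.seq):
            coverage = span_a / len(a.seq)
        else:
            coverage = span_b / len(b.seq)
    else:
        coverage = min(span_a / len(a.seq), span_b / len(b.seq))
    return coverage > params.rule_coverage and identity > params.rule_identity


def union_find_clusters(n: int, edges: Sequence[tuple[int, int]]) -> list[list[int]]:
    """Connected components (single linkage) over ``n`` nodes."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def _representative(members: list[LibraryEntry]) -> LibraryEntry:
    known = [m for m in members if m.source == "known"]
    pool = known if known else members
    return min(pool, key=lambda m: (-len(m.seq), m.name))


def cluster_80_80(
    entries: Sequence[LibraryEntry],
    params: CurationParams | None = None,
) -> list[FamilyClusterNT]:
    """Single-linkage components of the 80-80 pair graph.

    The representative is a known-source member when one exists, else the
    longest member (ties broken by lexicographic name).  Output is
    order-invariant up to cluster set equality.
    """
    params = params or CurationParams()
    entries = list(entries)
    aligner = _nt_local_aligner()
    edges = [
        (i, j)
        for i in range(len(entries))
        for j in range(i + 1, len(entries))
        if pair_80_80(entries[i], entries[j], params, aligner)
    ]
    clusters = []
    for comp in union_find_clusters(len(entries), edges):
        members = sorted((entries[i] for i in comp), key=lambda m: m.name)
        clusters.append(FamilyClusterNT(members=members, representative=_representative(members)))
    clusters.sort(key=lambda c: c.representative.name)
    return clusters


def merge_libraries(
    known: Sequence[LibraryEntry],
    de_novo: Sequence[LibraryEntry],
    params: CurationParams | None = None,
) -> list[LibraryEntry]:
    """Non-redundant union of a known library and de novo repeats.

    Clusters the union under the 80-80 rule and keeps one representative
    per cluster, preferring known entries so their classification is
    preserved; de novo singletons keep class Unknown unless classified
    upstream.
    """
    merged = list(known) + list(de_novo)
    if not merged:
        return []
    clusters = cluster_80_80(merged, params)
    reps = [c.representative for c in clusters]
    order = {id(e): i for i, e in enumerate(merged)}
    reps.sort(key=lambda e: order[id(e)])
    return reps
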