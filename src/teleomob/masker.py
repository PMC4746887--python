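"""Seed-and-extend nucleotide homology search against a repeat library.

Annotates a genome with a TE library and reports per-hit divergence,
making the pipeline self-contained; pre-computed RepeatMasker ``.out``
files remain interchangeable with this masker's output via
:mod:`teleomob.io`.

Algorithm
---------
1. Exact ``seed_length``-mer matches between the genome and each library
   entry (both strands) are located with a sorted k-mer index.
2. Seeds are grouped by (entry, strand, diagonal); nearby diagonals are
   clustered so small indels stay in one candidate.  A fast ungapped
   best-segment score on the dominant diagonal prefilters noise.
3. Each surviving candidate window is refined with a full local
   dynamic-programming alignment (Biopython's C ``PairwiseAligner``)
   under the module's scoring scheme; ``x_drop`` sizes the window pad.
4. Hits below ``min_score`` or ``min_hit_length`` are dropped; the rest
   enter a greedy overlap resolution (descending score, ties by earlier
   start then library name) where lower-scoring overlaps are trimmed to
   their uncovered remainder or discarded.

Divergence ``D`` is 100 x mismatches / (matches + mismatches): gap
columns are excluded, matching the substitution-only model of the
Jukes-Cantor correction.  (RepeatMasker's %div can be CpG-adjusted in
some modes; this masker always reports the raw definition.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .io import LibraryEntry, RepeatHit, SequenceRecord, TEClass, revcomp

__all__ = ["MaskerParams", "AlignmentResult", "mask_genome", "masked_bp", "merge_intervals"]

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

_MAX_SEED_OCC = 1000  # skip pathologically frequent seeds (low complexity)
_DIAG_CLUSTER_GAP = 15  # diagonals closer than this join one candidate


@dataclass
class MaskerParams:
    seed_length: int = 11
    x_drop: int = 20  # window pad around the projected library span, bp
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    min_score: int = 30
    min_hit_length: int = 50

    def __post_init__(self) -> None:
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.min_hit_length <= 0:
            raise ValueError("min_hit_length must be > 0")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


@dataclass
class AlignmentResult:
    """A refined local alignment between a genome window and one entry.

    Invariant: ``matches + mismatches + gap_columns == aligned_columns``
    and ``score`` is consistent with the scoring scheme.
    """

    query_start: int  # genome, 0-based half-open
    query_end: int
    lib_start: int  # position on the (possibly reverse-complemented) entry
    lib_end: int
    strand: str
    aligned_columns: int
    matches: int
    mismatches: int
    gap_columns: int
    score: float
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # each block: (genome 0-based start, end, lib start, end) — ungapped

    @property
    def divergence_D(self) -> float:
        return 100.0 * self.mismatches / (self.matches + self.mismatches)


class _GenomeIndex:
    """Sorted k-mer index of one genome sequence."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        self.codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(seq) < k:
            self.sorted_vals = np.empty(0, dtype=np.int64)
            self.sorted_pos = np.empty(0, dtype=np.int64)
            return
        vals, valid = _kmer_values(self.codes, k)
        pos = np.nonzero(valid)[0]
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")
        self.sorted_vals = vals[order]
        self.sorted_pos = pos[order]

    def seed_matches(self, entry_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (genome positions, entry positions) of exact k-mer matches."""
        if len(entry_codes) < self.k or len(self.sorted_vals) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        vals, valid = _kmer_values(entry_codes, self.k)
        lpos = np.nonzero(valid)[0]
        vals = vals[valid]
        lo = np.searchsorted(self.sorted_vals, vals, side="left")
        hi = np.searchsorted(self.sorted_vals, vals, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= _MAX_SEED_OCC)
        gpos_chunks = [self.sorted_pos[l:h] for l, h in zip(lo[keep], hi[keep])]
        if not gpos_chunks:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        gpos = np.concatenate(gpos_chunks)
        lrep = np.repeat(lpos[keep], counts[keep])
        return gpos, lrep


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ powers
    return vals, valid


def _best_segment_score(eq: np.ndarray, match: int, mismatch: int) -> float:
    """Best-scoring contiguous segment of a +match/-mismatch vector."""
    if eq.size == 0:
        return 0.0
    s = np.where(eq, match, mismatch).cumsum()
    prefix_min = np.minimum.accumulate(np.concatenate(([0], s[:-1])))
    return float((s - prefix_min).max())


def mask_genome(
    genome: SequenceRecord,
    library: Sequence[LibraryEntry],
    params: MaskerParams | None = None,
) -> list[RepeatHit]:
    """Annotate ``genome`` against ``library``; returns resolved hits
    sorted by genome start.

    Raises ``ValueError`` on an empty library; a genome shorter than the
    seed yields an empty result.
    """
    if not library:
        raise ValueError("empty repeat library")
    params = params or MaskerParams()
    if len(genome.seq) < params.seed_length:
        return []

    index = _GenomeIndex(genome.seq, params.seed_length)
    aligner = params.aligner()
    candidates: list[tuple[LibraryEntry, AlignmentResult]] = []

    for entry in library:
        for strand in "+-":
            oriented = entry.seq if strand == "+" else revcomp(entry.seq)
            for res in _search_oriented(index, oriented, strand, params, aligner):
                candidates.append((entry, res))

    hits = _resolve_overlaps(genome, candidates, params)
    hits.sort(key=lambda h: (h.start, h.end, h.library_name))
    for i, h in enumerate(hits, 1):
        h.hit_id = i
    return hits


def _search_oriented(
    index: _GenomeIndex,
    oriented_seq: str,
    strand: str,
    params: MaskerParams,
    aligner: Align.PairwiseAligner,
) -> list[AlignmentResult]:
    ecodes = _CODE[np.frombuffer(oriented_seq.encode(), dtype=np.uint8)]
    gpos, lpos = index.seed_matches(ecodes)
    if gpos.size == 0:
        return []
    diags = np.unique(gpos - lpos)
    L = len(oriented_seq)
    G = len(index.seq)
    pad = max(params.x_drop, 10)
    prefilter = max(10, params.min_score - 10)

    # cluster nearby diagonals into single candidates (tolerates indels)
    clusters: list[list[int]] = [[int(diags[0])]]
    for d in diags[1:]:
        d = int(d)
        if d - clusters[-1][-1] <= _DIAG_CLUSTER_GAP:
            clusters[-1].append(d)
        else:
            clusters.append([d])

    results: dict[tuple[int, int], AlignmentResult] = {}
    for cluster in clusters:
        dlo, dhi = cluster[0], cluster[-1]
        best = 0.0
        for d in cluster:
            ws, we = max(0, d), min(G, d + L)
            if we - ws < params.min_hit_length:
                continue
            gseg = index.codes[ws:we]
            lseg = ecodes[ws - d : we - d]
            best = max(best, _best_segment_score(gseg == lseg, params.match, params.mismatch))
        if best < prefilter:
            continue
        ws = max(0, dlo - pad)
        we = min(G, dhi + L + pad)
        res = _align_window(index.seq, ws, we, oriented_seq, strand, aligner)
        if res is None:
            continue
        key = (res.query_start, res.query_end)
        if key not in results or res.score > results[key].score:
            results[key] = res
    return [r for r in results.values() if r.score >= params.min_score
            and r.query_end - r.query_start >= params.min_hit_length]


def _align_window(
    genome_seq: str,
    ws: int,
    we: int,
    oriented_seq: str,
    strand: str,
    aligner: Align.PairwiseAligner,
) -> AlignmentResult | None:
    window = genome_seq[ws:we]
    alns = aligner.align(window, oriented_seq)
    if alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    tblocks, qblocks = aln.aligned  # target = window, query = entry
    blocks = [
        (ws + int(t0), ws + int(t1), int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks)
    ]
    if not blocks:
        return None
    return AlignmentResult(
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        lib_start=blocks[0][2],
        lib_end=blocks[-1][3],
        strand=strand,
        aligned_columns=identities + mismatches + gaps,
        matches=identities,
        mismatches=mismatches,
        gap_columns=gaps,
        score=float(aln.score),
        blocks=blocks,
    )


def _resolve_overlaps(
    genome: SequenceRecord,
    candidates: list[tuple[LibraryEntry, AlignmentResult]],
    params: MaskerParams,
) -> list[RepeatHit]:
    """Greedy by descending score; overlapped lower-scoring hits are
    trimmed to their longest uncovered piece (stats recomputed over the
    surviving ungapped blocks) or dropped."""
    order = sorted(
        candidates,
        key=lambda c: (-c[1].score, c[1].query_start, c[0].name),
    )
    kept: list[tuple[int, int]] = []  # 0-based half-open, sorted
    gcodes = _CODE[np.frombuffer(genome.seq.encode(), dtype=np.uint8)]
    hits: list[RepeatHit] = []

    for entry, res in order:
        pieces = _subtract(res.query_start, res.query_end, kept)
        if not pieces:
            continue
        a, b = max(pieces, key=lambda p: (p[1] - p[0], -p[0]))
        if b - a < params.min_hit_length:
            continue
        if (a, b) != (res.query_start, res.query_end):
            trimmed = _restrict(res, a, b, gcodes, entry, params)
            if trimmed is None or trimmed.score < params.min_score:
                continue
            res = trimmed
        _insert(kept, res.query_start, res.query_end)
        hits.append(_to_hit(genome, entry, res))
    return hits


def _subtract(s: int, e: int, kept: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = []
    cur = s
    for ks, ke in kept:
        if ke <= cur or ks >= e:
            continue
        if ks > cur:
            pieces.append((cur, ks))
        cur = max(cur, ke)
        if cur >= e:
            break
    if cur < e:
        pieces.append((cur, e))
    return pieces


def _insert(kept: list[tuple[int, int]], s: int, e: int) -> None:
    import bisect

    bisect.insort(kept, (s, e))


def _restrict(
    res: AlignmentResult,
    a: int,
    b: int,
    gcodes: np.ndarray,
    entry: LibraryEntry,
    params: MaskerParams,
) -> AlignmentResult | None:
    """Clip an alignment to genome range [a, b) by intersecting its
    ungapped blocks and recomputing counts from the sequences."""
    oriented = entry.seq if res.strand == "+" else revcomp(entry.seq)
    ecodes = _CODE[np.frombuffer(oriented.encode(), dtype=np.uint8)]
    new_blocks = []
    matches = mismatches = 0
    for g0, g1, q0, q1 in res.blocks:
        s = max(g0, a)
        e = min(g1, b)
        if s >= e:
            continue
        qs = q0 + (s - g0)
        qe = qs + (e - s)
        eq = gcodes[s:e] == ecodes[qs:qe]
        matches += int(eq.sum())
        mismatches += int((~eq).sum())
        new_blocks.append((s, e, qs, qe))
    if not new_blocks or matches + mismatches == 0:
        return None
    # internal gap columns between surviving consecutive blocks
    gap_cols = 0
    for (g0, g1, q0, q1), (h0, h1, r0, r1) in zip(new_blocks, new_blocks[1:]):
        gap_cols += (h0 - g1) + (r0 - q1)
    n_gaps = sum(1 for _ in new_blocks[1:])
    score = (
        matches * params.match
        + mismatches * params.mismatch
        + n_gaps * (params.gap_open - params.gap_extend)
        + gap_cols * params.gap_extend
    )
    return AlignmentResult(
        query_start=new_blocks[0][0],
        query_end=new_blocks[-1][1],
        lib_start=new_blocks[0][2],
        lib_end=new_blocks[-1][3],
        strand=res.strand,
        aligned_columns=matches + mismatches + gap_cols,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gap_cols,
        score=float(score),
        blocks=new_blocks,
    )


def _to_hit(genome: SequenceRecord, entry: LibraryEntry, res: AlignmentResult) -> RepeatHit:
    L = len(entry.seq)
    if res.strand == "+":
        rstart, rend = res.lib_start + 1, res.lib_end
    else:  # positions were on the reverse complement; map back
        rstart, rend = L - res.lib_end + 1, L - res.lib_start
    cols = res.aligned_columns
    qspan = res.query_end - res.query_start
    return RepeatHit(
        query_genome_seq=genome.id,
        start=res.query_start + 1,
        end=res.query_end,
        strand=res.strand,
        library_name=entry.name,
        te_class=entry.te_class,
        superfamily=entry.superfamily,
        family=entry.family,
        divergence_D=res.divergence_D,
        score=res.score,
        pct_del=100.0 * max(0, cols - qspan) / cols,
        pct_ins=100.0 * max(0, cols - (res.lib_end - res.lib_start)) / cols,
        repeat_start=rstart,
        repeat_end=rend,
        repeat_left=L - rend,
        query_left=len(genome.seq) - res.query_end,
    )


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def masked_bp(hits: Sequence[RepeatHit], genome_length: int) -> tuple[int, float]:
    """Union length of hit intervals and its fraction of the genome.

    Overlaps are collapsed; a hit outside genome bounds is an error.
    """
    for h in hits:
        if h.start < 1 or h.end > genome_length:
            raise ValueError(
                f"hit {h.start}-{h.end} outside genome bounds 1-{genome_length}"
            )
    total = sum(e - s + 1 for s, e in merge_intervals([(h.start, h.end) for h in hits]))
    return total, total / genome_length
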