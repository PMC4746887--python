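"""Autonomous-element identification and amino-acid family clustering.

An autonomous LINE carries at least two ORFs with an ORF2 (the
RT-bearing ORF) longer than 700 aa; an autonomous LTR element carries an
ORF longer than 500 aa containing an intact reverse-transcriptase (RT)
domain.  RT intactness is operationalized as a local alignment against a
user-supplied reference RT set covering >= 80 % of the reference at an
identity floor of 25 % (both configurable — there is no universal
definition of "intact").

Families are single-linkage clusters of autonomous elements whose
comparison proteins (ORF2 for LINEs, the RT-bearing ORF for LTRs) align
globally at >= 80 % amino-acid identity, with terminal gaps excluded
from the identity denominator since elements differ in length by
truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .curation import union_find_clusters
from .io import SequenceRecord, revcomp

__all__ = [
    "ORFRecord",
    "AutonomyCriteria",
    "RTProfile",
    "AutonomousElement",
    "FamilyClusterAA",
    "find_orfs",
    "detect_rt",
    "is_autonomous",
    "classify_element",
    "aa_identity",
    "cluster_families_aa",
    "family_diversity_table",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFRecord:
    """An ATG-to-stop open reading frame on one of the 6 frames.

    Coordinates are 1-based inclusive on the parent nucleotide sequence
    and include the stop codon; the protein excludes the stop, so
    ``length_aa == (end - start + 1 - 3) / 3`` for stop-terminated ORFs.
    Negative frames report mirrored (parent-strand) coordinates.
    """

    parent_id: str
    frame: int  # +1..+3, -1..-3
    start: int
    end: int
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class AutonomyCriteria:
    element_kind: str  # "LINE" or "LTR"
    min_orf_aa: int = 0  # 0 -> kind default (LINE 700, LTR 500)
    require_rt: bool = True
    min_orf_count: int = 0  # 0 -> kind default (LINE 2, LTR 1)
    orf_floor_aa: int = 100  # minimum length for counting ORFs at all

    def resolved_min_orf_aa(self) -> int:
        if self.min_orf_aa > 0:
            return self.min_orf_aa
        return 700 if self.element_kind == "LINE" else 500

    def resolved_min_orf_count(self) -> int:
        if self.min_orf_count > 0:
            return self.min_orf_count
        return 2 if self.element_kind == "LINE" else 1


@dataclass(frozen=True)
class RTProfile:
    """Reference RT-domain amino-acid sequences with detection thresholds."""

    references: tuple[SequenceRecord, ...]
    min_coverage: float = 0.80
    min_identity: float = 0.25

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("RT profile needs at least one reference sequence")


@dataclass
class AutonomousElement:
    """An element that passed the autonomy filter, with its comparison
    protein and optional species/clade annotation for diversity tables."""

    id: str
    kind: str  # LINE or LTR
    comparison_protein: str
    species: str | None = None
    clade: str | None = None


@dataclass
class FamilyClusterAA:
    element_kind: str
    members: list[AutonomousElement]
    representative: AutonomousElement
    family_id: str = ""


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def find_orfs(record: SequenceRecord, min_aa: int = 1) -> list[ORFRecord]:
    """All ATG-to-stop ORFs in the 6 frames with length >= ``min_aa``,
    sorted by protein length descending.

    Per frame and stop codon, the outermost ORF (first ATG after the
    previous stop) is reported; nested internal-ATG ORFs are not
    enumerated separately.
    """
    orfs: list[ORFRecord] = []
    L = len(record.seq)
    for strand in (+1, -1):
        seq = record.seq if strand == 1 else revcomp(record.seq)
        for frame in range(3):
            start_codon: int | None = None
            for pos in range(frame, L - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STOPS:
                    if start_codon is not None:
                        prot_nt = seq[start_codon:pos]
                        if len(prot_nt) // 3 >= min_aa:
                            protein = str(Seq(prot_nt).translate())
                            s, e = start_codon, pos + 3  # 0-based half-open incl. stop
                            if strand == 1:
                                gs_, ge_ = s + 1, e
                            else:
                                gs_, ge_ = L - e + 1, L - s
                            orfs.append(
                                ORFRecord(
                                    parent_id=record.id,
                                    frame=strand * (frame + 1),
                                    start=gs_,
                                    end=ge_,
                                    protein=protein,
                                )
                            )
                        start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    orfs.sort(key=lambda o: (-o.length_aa, o.frame, o.start))
    return orfs


# ---------------------------------------------------------------------------
# RT detection
# ---------------------------------------------------------------------------

def _aa_local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def detect_rt(protein: str, profile: RTProfile) -> tuple[bool, float, float]:
    """Best local match of ``protein`` against the reference RT set.

    Returns (detected, coverage of the reference, identity over aligned
    columns); detected iff coverage >= ``min_coverage`` and identity >=
    ``min_identity`` for some reference.
    """
    if not protein:
        return False, 0.0, 0.0
    aligner = _aa_local_aligner()
    best = (False, 0.0, 0.0)
    for ref in profile.references:
        alns = aligner.align(protein, ref.seq)
        if alns.score <= 0:
            continue
        aln = alns[0]
        counts = aln.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols == 0:
            continue
        identity = counts.identities / cols
        qb = aln.aligned[1]  # blocks on the reference
        if len(qb) == 0:
            continue
        coverage = (int(qb[-1][1]) - int(qb[0][0])) / len(ref.seq)
        ok = coverage >= profile.min_coverage and identity >= profile.min_identity
        if (ok, coverage, identity) > best:
            best = (ok, coverage, identity)
    return best


# ---------------------------------------------------------------------------
# Autonomy filter
# ---------------------------------------------------------------------------

def classify_element(
    record: SequenceRecord,
    criteria: AutonomyCriteria,
    profile: RTProfile,
) -> tuple[bool, ORFRecord | None]:
    """Apply the autonomy filter; returns (autonomous, comparison ORF).

    LINE: at least two ORFs (>= ``orf_floor_aa``) must exist and the
    RT-bearing ORF ("ORF2", defined functionally rather than
    positionally, so 5'-truncation of ORF1 cannot mislabel it) must
    exceed the length threshold.  LTR: some ORF above the threshold must
    carry the RT domain.
    """
    orfs = find_orfs(record, min_aa=criteria.orf_floor_aa)
    if not orfs:
        return False, None
    rt_orf = None
    for orf in orfs:
        detected, _, _ = detect_rt(orf.protein, profile)
        if detected:
            rt_orf = orf
            break  # orfs sorted longest-first: take the longest RT-bearing ORF
    if criteria.require_rt and rt_orf is None:
        return False, None
    threshold = criteria.resolved_min_orf_aa()
    candidate = rt_orf if rt_orf is not None else orfs[0]
    if len(orfs) < criteria.resolved_min_orf_count():
        return False, candidate
    if candidate.length_aa <= threshold:
        return False, candidate
    return True, candidate


def is_autonomous(
    record: SequenceRecord,
    criteria: AutonomyCriteria,
    profile: RTProfile,
) -> bool:
    return classify_element(record, criteria, profile)[0]


# ---------------------------------------------------------------------------
# Amino-acid family clustering
# ---------------------------------------------------------------------------

def _aa_semiglobal_aligner() -> Align.PairwiseAligner:
    """Global alignment with free terminal gaps (semi-global)."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    try:
        al.open_end_insertion_score = 0
        al.extend_end_insertion_score = 0
        al.open_end_deletion_score = 0
        al.extend_end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        al.target_end_open_gap_score = 0
        al.target_end_extend_gap_score = 0
        al.query_end_open_gap_score = 0
        al.query_end_extend_gap_score = 0
    return al


def aa_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity of the semi-global alignment of two proteins: matches
    over alignment columns, terminal gap columns excluded.

    The denominator is floored at the shorter protein's length:
    free terminal gaps otherwise let two unrelated proteins overlap on a
    short coincidental stretch and report a spuriously high identity,
    while a genuinely truncated element still aligns over its whole
    length and is unaffected by the floor."""
    if not a or not b:
        raise ValueError("empty protein in identity computation")
    aligner = aligner or _aa_semiglobal_aligner()
    aln = aligner.align(a, b)[0]
    ta, qa = aln.aligned
    if len(ta) == 0:
        return 0.0
    # span of the alignment between first and last aligned columns
    t0, t1 = int(ta[0][0]), int(ta[-1][1])
    q0, q1 = int(qa[0][0]), int(qa[-1][1])
    matches = 0
    inner_cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(ta, qa):
        if prev_t is not None:
            inner_cols += (ts - prev_t) + (qs - prev_q)  # internal gap columns
        seg_t = a[ts:te]
        seg_q = b[qs:qe]
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y)
        inner_cols += te - ts
        prev_t, prev_q = te, qe
    denom = max(inner_cols, min(len(a), len(b)))
    if denom == 0:
        return 0.0
    return matches / denom


def cluster_families_aa(
    elements: Sequence[AutonomousElement],
    threshold: float = 0.80,
) -> list[FamilyClusterAA]:
    """Single-linkage clusters over element pairs of the same kind whose
    comparison proteins reach ``threshold`` identity."""
    elements = list(elements)
    aligner = _aa_semiglobal_aligner()
    edges = []
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            if elements[i].kind != elements[j].kind:
                continue
            ident = aa_identity(
                elements[i].comparison_protein, elements[j].comparison_protein, aligner
            )
            if ident >= threshold:
                edges.append((i, j))
    clusters = []
    for comp in union_find_clusters(len(elements), edges):
        members = sorted((elements[i] for i in comp), key=lambda m: m.id)
        rep = min(members, key=lambda m: (-len(m.comparison_protein), m.id))
        clusters.append(
            FamilyClusterAA(element_kind=members[0].kind, members=members, representative=rep)
        )
    clusters.sort(key=lambda c: c.representative.id)
    for i, c in enumerate(clusters, 1):
        c.family_id = f"{c.element_kind}_fam{i}"
    return clusters


def family_diversity_table(clusters: Sequence[FamilyClusterAA]) -> pd.DataFrame:
    """Family counts per species per clade (Tables 3/4-style).

    A family counts for a species when at least one member was found in
    that species; rows are clades plus a ``Total`` row whose entries are
    the per-species sums over clade rows.
    """
    species = sorted(
        {m.species for c in clusters for m in c.members if m.species is not None}
    )
    clades = sorted(
        {
            (m.clade or "Unassigned")
            for c in clusters
            for m in c.members
        }
    )
    if not species:
        return pd.DataFrame(index=pd.Index([], name="clade"))
    table = pd.DataFrame(0, index=pd.Index(clades, name="clade"), columns=species)
    for c in clusters:
        present: set[tuple[str, str]] = set()
        for m in c.members:
            if m.species is None:
                continue
            present.add(((m.clade or "Unassigned"), m.species))
        for clade, sp in present:
            table.loc[clade, sp] += 1
    table.loc["Total"] = table.sum(axis=0)
    return table
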