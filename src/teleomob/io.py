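"""Readers and writers for the formats the pipeline touches.

FASTA (multi-record, nucleotide or protein), RepeatMasker-style ``.out``
annotation (the 15-column v4 dialect), classification-bearing library
headers (``Name#Class/Superfamily``), and the family sidecar TSV.

Conventions
-----------
* Genome coordinates are 1-based inclusive everywhere, matching the
  RepeatMasker ``.out`` convention.  Any half-open arithmetic is confined
  to private helpers.
* Lowercase (soft-masked) bases are uppercased on read; masking state is
  never inferred from case.
* Every reader/writer pair round-trips losslessly on its own output.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TEClass",
    "SequenceRecord",
    "LibraryEntry",
    "RepeatHit",
    "FastaParseError",
    "RmOutParseError",
    "read_fasta",
    "write_fasta",
    "parse_library_header",
    "format_library_header",
    "read_library_fasta",
    "write_library_fasta",
    "read_family_sidecar",
    "write_family_sidecar",
    "read_rm_out",
    "write_rm_out",
    "revcomp",
]

_IUPAC_NT = set("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


class TEClass(str, enum.Enum):
    """Top-level transposable-element class of a library entry."""

    DNA = "DNA"
    LINE = "LINE"
    SINE = "SINE"
    LTR = "LTR"
    UNKNOWN = "Unknown"

    @classmethod
    def from_token(cls, token: str) -> "TEClass":
        for member in cls:
            if member.value.lower() == token.lower():
                return member
        return cls.UNKNOWN


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``alphabet`` is ``"nt"`` or ``"aa"``."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nt"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LibraryEntry:
    """A repeat-library consensus with its hierarchical classification.

    The two-level ``name#Class/Superfamily`` header convention carries
    class and superfamily; ``family`` travels in a separate sidecar TSV
    because the header has no third level.
    """

    name: str
    seq: str
    te_class: TEClass = TEClass.UNKNOWN
    superfamily: str | None = None
    family: str | None = None
    source: str = "de_novo"  # "known" or "de_novo"

    def header(self) -> str:
        return format_library_header(self.name, self.te_class, self.superfamily)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RepeatHit:
    """One masked genomic interval linked to a library entry.

    ``divergence_D`` is the raw substitution proportion in percent
    (mismatches over matched+mismatched columns; gap columns excluded) —
    the ``D`` that feeds the Jukes-Cantor correction.
    """

    query_genome_seq: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    library_name: str
    te_class: TEClass = TEClass.UNKNOWN
    superfamily: str | None = None
    family: str | None = None
    divergence_D: float = 0.0
    score: float = 0.0
    pct_del: float = 0.0
    pct_ins: float = 0.0
    repeat_start: int = 0
    repeat_end: int = 0
    repeat_left: int = 0
    query_left: int = 0
    hit_id: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"hit on {self.query_genome_seq}: start {self.start} > end {self.end}"
            )
        if self.divergence_D < 0:
            raise ValueError(f"negative divergence {self.divergence_D}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FastaParseError(ValueError):
    pass


class RmOutParseError(ValueError):
    pass


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a multi-FASTA file.

    Order is preserved, whitespace inside sequences is stripped and
    nucleotide sequences are uppercased and checked against IUPAC codes.
    Duplicate ids, empty sequences and malformed headers raise
    :class:`FastaParseError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_seq)
        if not seq:
            raise FastaParseError(f"line {cur_line}: record '{cur_id}' has empty sequence")
        if alphabet in ("nt", "nt-aln"):
            seq = seq.upper()
            allowed = _IUPAC_NT | set("-.") if alphabet == "nt-aln" else _IUPAC_NT
            bad = set(seq) - allowed
            if bad:
                raise FastaParseError(
                    f"record '{cur_id}': non-IUPAC nucleotide code(s) {sorted(bad)}"
                )
        records.append(SequenceRecord(cur_id, seq, cur_desc, alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].strip()
                if not head:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = head.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_line = lineno
                if cur_id in seen:
                    raise FastaParseError(f"line {lineno}: duplicate record id '{cur_id}'")
                seen.add(cur_id)
                cur_seq = []
            else:
                if cur_id is None:
                    raise FastaParseError(f"line {lineno}: sequence data before first header")
                cur_seq.append(re.sub(r"\s+", "", line))
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Library headers and sidecar
# ---------------------------------------------------------------------------

def parse_library_header(header: str) -> tuple[str, TEClass, str | None]:
    """Split a ``name#Class/Superfamily`` header.

    Headers without ``#`` fall back to class ``Unknown`` (no error): de
    novo consensus names are legal library entries before classification.
    """
    header = header.strip()
    if "#" not in header:
        return header, TEClass.UNKNOWN, None
    name, _, rest = header.partition("#")
    cls_token, _, superfamily = rest.partition("/")
    te_class = TEClass.from_token(cls_token) if cls_token else TEClass.UNKNOWN
    return name, te_class, (superfamily or None)


def format_library_header(name: str, te_class: TEClass, superfamily: str | None) -> str:
    if te_class is TEClass.UNKNOWN and superfamily is None:
        return name
    if superfamily:
        return f"{name}#{te_class.value}/{superfamily}"
    return f"{name}#{te_class.value}"


def read_library_fasta(
    path: str | Path,
    sidecar: str | Path | None = None,
    source: str = "known",
) -> list[LibraryEntry]:
    """Read a library FASTA whose ids follow the ``#Class/Superfamily``
    convention, optionally joining family labels from a sidecar TSV."""
    families = read_family_sidecar(sidecar) if sidecar else {}
    entries = []
    for rec in read_fasta(path):
        name, te_class, superfamily = parse_library_header(rec.id)
        entries.append(
            LibraryEntry(
                name=name,
                seq=rec.seq,
                te_class=te_class,
                superfamily=superfamily,
                family=families.get(name),
                source=source,
            )
        )
    return entries


def write_library_fasta(
    entries: Iterable[LibraryEntry],
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    entries = list(entries)
    write_fasta(
        [SequenceRecord(e.header(), e.seq) for e in entries], path
    )
    if sidecar is not None:
        write_family_sidecar(
            {e.name: e.family for e in entries if e.family}, sidecar
        )


def read_family_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, fam = line.split("\t")[:2]
            out[name] = fam
    return out


def write_family_sidecar(families: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(families):
            fh.write(f"{name}\t{families[name]}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query        matching"
    "  repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end        (left)  repeat"
    "         class/family   begin  end    (left)   ID\n"
    "\n"
)


def _class_family_token(hit: RepeatHit) -> str:
    if hit.te_class is TEClass.UNKNOWN and hit.superfamily is None:
        return "Unknown"
    if hit.superfamily:
        return f"{hit.te_class.value}/{hit.superfamily}"
    return hit.te_class.value


def read_rm_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file (v4 15-column dialect).

    Coordinates are kept 1-based inclusive; a ``C`` in the strand column
    maps to strand ``-``; ``%div`` is stored as ``divergence_D``.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("SW", "score", "There were no")):
                continue
            fields = line.split()
            if len(fields) < 14:
                if lineno <= 3:  # header block
                    continue
                raise RmOutParseError(f"line {lineno}: expected >=14 columns, got {len(fields)}")
            try:
                score = float(fields[0])
                div = float(fields[1])
                pdel = float(fields[2])
                pins = float(fields[3])
                query = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                qleft = int(fields[7].strip("()"))
            except ValueError as exc:
                raise RmOutParseError(f"line {lineno}: non-numeric field ({exc})") from None
            strand = "-" if fields[8] in ("C", "-") else "+"
            repeat = fields[9]
            name, te_class, superfamily = parse_library_header(
                f"{repeat}#{fields[10]}" if fields[10] != "Unknown" else repeat
            )
            try:
                if strand == "+":
                    rbegin = int(fields[11])
                    rend = int(fields[12])
                    rleft = int(fields[13].strip("()"))
                else:  # C lines print (left) begin end? -- v4 prints (left) end begin
                    rleft = int(fields[11].strip("()"))
                    rend = int(fields[12])
                    rbegin = int(fields[13])
            except ValueError as exc:
                raise RmOutParseError(f"line {lineno}: non-numeric repeat coordinate ({exc})") from None
            hit_id = int(fields[14]) if len(fields) > 14 and fields[14].isdigit() else 0
            hits.append(
                RepeatHit(
                    query_genome_seq=query,
                    start=begin,
                    end=end,
                    strand=strand,
                    library_name=name,
                    te_class=te_class,
                    superfamily=superfamily,
                    divergence_D=div,
                    score=score,
                    pct_del=pdel,
                    pct_ins=pins,
                    repeat_start=rbegin,
                    repeat_end=rend,
                    repeat_left=rleft,
                    query_left=qleft,
                    hit_id=hit_id,
                )
            )
    return hits


def write_rm_out(hits: Sequence[RepeatHit], path: str | Path) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect (deterministic
    column order; ``-`` strand printed as ``C`` with swapped repeat
    coordinates, as RepeatMasker does)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, 1):
            strand = "+" if h.strand == "+" else "C"
            if h.strand == "+":
                rep_cols = f"{h.repeat_start:>6} {h.repeat_end:>6} ({h.repeat_left})"
            else:
                rep_cols = f"({h.repeat_left}) {h.repeat_end:>6} {h.repeat_start:>6}"
            fh.write(
                f"{h.score:>6.0f} {h.divergence_D:>6.1f} {h.pct_del:>4.1f} {h.pct_ins:>4.1f}  "
                f"{h.query_genome_seq}  {h.start:>8} {h.end:>8} ({h.query_left}) "
                f"{strand}  {h.library_name}  {_class_family_token(h)}  "
                f"{rep_cols} {h.hit_id or i}\n"
            )


def hits_to_dataframe(hits: Sequence[RepeatHit]):
    """Tabular view of hits (one row per hit) for summaries and TSVs."""
    import pandas as pd

    return pd.DataFrame(
        {
            "query": [h.query_genome_seq for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "library_name": [h.library_name for h in hits],
            "te_class": [h.te_class.value for h in hits],
            "superfamily": [h.superfamily for h in hits],
            "family": [h.family for h in hits],
            "divergence_D": [h.divergence_D for h in hits],
            "score": [h.score for h in hits],
        }
    )
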