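"""Synthetic mobilome generator.

Builds genomes with planted transposable-element copies plus a
ground-truth annotation, emulating the statistical structure the
downstream analysis assumes: a random background at a configured GC
content, and per-superfamily insertion programmes with configured copy
numbers, per-copy divergence distributions, 5' truncation and strand
placement.

The mutation model is substitution-only by default, matching the
substitution-only assumption of the one-parameter Jukes-Cantor
correction and keeping every copy's realized divergence exactly
computable by direct string comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import (
    LibraryEntry,
    SequenceRecord,
    TEClass,
    revcomp,
    write_fasta,
    write_library_fasta,
)

__all__ = [
    "DivergenceModel",
    "InsertionSpec",
    "TruthRow",
    "TruthAnnotation",
    "SimulationConfig",
    "simulate_genome",
    "realized_divergence",
    "random_background",
    "random_consensus",
    "mutate_sequence",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DivergenceModel:
    """Distribution of per-copy target substitution proportions.

    ``kind``:
      * ``point``   — every copy at proportion ``a``
      * ``uniform`` — proportion ~ U(a, b)
      * ``mixture`` — list of (weight, a, b) uniform components, e.g. two
        peaks mimicking an old and a recent amplification burst
    """

    kind: str = "point"
    a: float = 0.10
    b: float = 0.0
    components: tuple[tuple[float, float, float], ...] = ()

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.a
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        if self.kind == "mixture":
            w = np.array([c[0] for c in self.components], dtype=float)
            i = rng.choice(len(self.components), p=w / w.sum())
            _, lo, hi = self.components[i]
            return float(rng.uniform(lo, hi))
        raise ValueError(f"unknown divergence model kind {self.kind!r}")

    def cdf(self, x: float) -> float:
        """CDF of the configured distribution (for convergence checks)."""
        if self.kind == "point":
            return 1.0 if x >= self.a else 0.0
        if self.kind == "uniform":
            lo, hi = self.a, self.b
            return min(1.0, max(0.0, (x - lo) / (hi - lo)))
        if self.kind == "mixture":
            w = np.array([c[0] for c in self.components], dtype=float)
            w = w / w.sum()
            total = 0.0
            for wi, (_, lo, hi) in zip(w, self.components):
                total += wi * min(1.0, max(0.0, (x - lo) / (hi - lo)))
            return total
        raise ValueError(self.kind)


@dataclass(frozen=True)
class InsertionSpec:
    """Insertion programme for one library consensus.

    ``truncation_prob`` is the probability a copy is 5'-truncated
    (LINE-like fragmentation); the truncated fraction of the length is
    then drawn U(``truncation_frac_lo``, ``truncation_frac_hi``).
    ``strand_prob_minus`` is the probability of "-" placement.
    """

    consensus: LibraryEntry
    copy_number: int = 0
    divergence: DivergenceModel = field(default_factory=DivergenceModel)
    truncation_prob: float = 0.0
    truncation_frac_lo: float = 0.1
    truncation_frac_hi: float = 0.5
    strand_prob_minus: float = 0.5

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        for p in (self.truncation_prob, self.strand_prob_minus):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRow:
    genome_seq: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    consensus_name: str
    te_class: TEClass
    superfamily: str | None
    realized_divergence: float  # percent
    truncated: bool


class TruthAnnotation(list):
    """List of :class:`TruthRow` — the oracle for recovery tests."""

    def total_bp(self) -> int:
        return sum(r.end - r.start + 1 for r in self)


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    gc_content: float = 0.40
    insertion_specs: list[InsertionSpec] = field(default_factory=list)
    seed: int = 0
    allow_nesting: bool = False
    genome_id: str = "chrSim"
    max_placement_tries: int = 2000


def random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. background as a uint8 ASCII array at the stated GC."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def random_consensus(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    return random_background(length, gc, rng).tobytes().decode()


def mutate_sequence(seq: str, proportion: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute ``round(proportion * len)`` sites, chosen uniformly
    without replacement, each replaced uniformly among the 3 alternative
    bases.  Returns (mutated sequence, substitution count)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_sub = int(round(proportion * len(seq)))
    if n_sub == 0:
        return seq, 0
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for s in sites:
        alternatives = _BASES[_BASES != arr[s]]
        arr[s] = alternatives[rng.integers(3)]
    return arr.tobytes().decode(), n_sub


def realized_divergence(copy_seq: str, consensus: str, strand: str = "+") -> float:
    """Percent mismatches between a planted copy and its source consensus.

    The copy may be a 5'-truncated derivative (it is compared against the
    3' end of the consensus).  "-" copies are reverse-complemented before
    comparison, so the value is strand-symmetric.
    """
    if strand == "-":
        copy_seq = revcomp(copy_seq)
    if len(copy_seq) > len(consensus):
        raise ValueError("copy longer than consensus: not an indel-free derivative")
    ref = consensus[len(consensus) - len(copy_seq):]
    a = np.frombuffer(copy_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(ref.encode(), dtype=np.uint8)
    return 100.0 * float(np.count_nonzero(a != b)) / len(a)


def simulate_genome(config: SimulationConfig) -> tuple[SequenceRecord, TruthAnnotation]:
    """Generate one genome and its truth annotation.

    The background is drawn first, then each copy (mutated / truncated /
    strand-flipped consensus) overwrites a uniformly placed,
    non-overlapping window, so the genome length equals
    ``config.genome_length`` exactly.  A single seeded generator drives
    all draws in a fixed order, making the output byte-identical across
    runs for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    planted = sum(s.copy_number * len(s.consensus.seq) for s in config.insertion_specs)
    if planted > L:
        raise ValueError(f"total planted bp {planted} exceeds genome length {L}")

    genome = random_background(L, config.gc_content, rng)
    occupied: list[tuple[int, int]] = []  # 0-based half-open, kept sorted
    truth = TruthAnnotation()

    def place(length: int) -> int:
        """Uniform non-overlapping placement; bounded retries."""
        for _ in range(config.max_placement_tries):
            pos = int(rng.integers(0, L - length + 1))
            if config.allow_nesting or not _overlaps(occupied, pos, pos + length):
                return pos
        raise RuntimeError(
            f"could not place a {length} bp copy after "
            f"{config.max_placement_tries} tries: genome too crowded"
        )

    for spec in config.insertion_specs:
        cons = spec.consensus.seq
        for _ in range(spec.copy_number):
            seq = cons
            truncated = False
            if spec.truncation_prob > 0 and rng.random() < spec.truncation_prob:
                frac = rng.uniform(spec.truncation_frac_lo, spec.truncation_frac_hi)
                cut = int(frac * len(cons))
                if cut > 0 and len(cons) - cut >= 30:
                    seq = cons[cut:]  # 5' truncation keeps the 3' end
                    truncated = True
            prop = spec.divergence.draw(rng)
            seq, n_sub = mutate_sequence(seq, prop, rng)
            strand = "-" if rng.random() < spec.strand_prob_minus else "+"
            placed_seq = revcomp(seq) if strand == "-" else seq
            pos = place(len(placed_seq))
            genome[pos : pos + len(placed_seq)] = np.frombuffer(
                placed_seq.encode(), dtype=np.uint8
            )
            if not config.allow_nesting:
                _insert_interval(occupied, pos, pos + len(placed_seq))
            truth.append(
                TruthRow(
                    genome_seq=config.genome_id,
                    start=pos + 1,
                    end=pos + len(placed_seq),
                    strand=strand,
                    consensus_name=spec.consensus.name,
                    te_class=spec.consensus.te_class,
                    superfamily=spec.consensus.superfamily,
                    realized_divergence=100.0 * n_sub / len(seq),
                    truncated=truncated,
                )
            )

    truth.sort(key=lambda r: r.start)
    record = SequenceRecord(config.genome_id, genome.tobytes().decode())
    return record, truth


def _overlaps(intervals: list[tuple[int, int]], s: int, e: int) -> bool:
    import bisect

    i = bisect.bisect_left(intervals, (s, s))
    if i < len(intervals) and intervals[i][0] < e:
        return True
    if i > 0 and intervals[i - 1][1] > s:
        return True
    return False


def _insert_interval(intervals: list[tuple[int, int]], s: int, e: int) -> None:
    import bisect

    bisect.insort(intervals, (s, e))


# ---------------------------------------------------------------------------
# Truth TSV I/O (columns mirror RepeatHit)
# ---------------------------------------------------------------------------

_TRUTH_COLS = [
    "genome_seq",
    "start",
    "end",
    "strand",
    "consensus_name",
    "te_class",
    "superfamily",
    "realized_divergence",
    "truncated",
]


def write_truth_tsv(truth: TruthAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for r in truth:
            fh.write(
                f"{r.genome_seq}\t{r.start}\t{r.end}\t{r.strand}\t{r.consensus_name}\t"
                f"{r.te_class.value}\t{r.superfamily or ''}\t"
                f"{r.realized_divergence:.6f}\t{int(r.truncated)}\n"
            )


def read_truth_tsv(path: str | Path) -> TruthAnnotation:
    truth = TruthAnnotation()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == _TRUTH_COLS, "unexpected truth TSV columns"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truth.append(
                TruthRow(
                    genome_seq=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[3],
                    consensus_name=f[4],
                    te_class=TEClass.from_token(f[5]),
                    superfamily=f[6] or None,
                    realized_divergence=float(f[7]),
                    truncated=bool(int(f[8])),
                )
            )
    return truth


# ---------------------------------------------------------------------------
# Config (de)serialisation
# ---------------------------------------------------------------------------

def config_from_dict(d: dict) -> SimulationConfig:
    specs = []
    for s in d.get("insertion_specs", []):
        cons = LibraryEntry(
            name=s["name"],
            seq=s["seq"],
            te_class=TEClass.from_token(s.get("te_class", "Unknown")),
            superfamily=s.get("superfamily"),
        )
        div = s.get("divergence", {})
        model = DivergenceModel(
            kind=div.get("kind", "point"),
            a=div.get("a", 0.10),
            b=div.get("b", 0.0),
            components=tuple(tuple(c) for c in div.get("components", [])),
        )
        specs.append(
            InsertionSpec(
                consensus=cons,
                copy_number=s.get("copy_number", 0),
                divergence=model,
                truncation_prob=s.get("truncation_prob", 0.0),
                truncation_frac_lo=s.get("truncation_frac_lo", 0.1),
                truncation_frac_hi=s.get("truncation_frac_hi", 0.5),
                strand_prob_minus=s.get("strand_prob_minus", 0.5),
            )
        )
    return SimulationConfig(
        genome_length=d.get("genome_length", 1_000_000),
        gc_content=d.get("gc_content", 0.40),
        insertion_specs=specs,
        seed=d.get("seed", 0),
        allow_nesting=d.get("allow_nesting", False),
        genome_id=d.get("genome_id", "chrSim"),
    )


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_outputs(
    config: SimulationConfig,
    outdir: str | Path,
    prefix: str = "sim",
) -> tuple[Path, Path, Path]:
    """Run a simulation and write genome FASTA, truth TSV and the planted
    library FASTA under ``outdir``; returns the three paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record, truth = simulate_genome(config)
    genome_path = outdir / f"{prefix}_genome.fa"
    truth_path = outdir / f"{prefix}_truth.tsv"
    lib_path = outdir / f"{prefix}_library.fa"
    write_fasta([record], genome_path)
    write_truth_tsv(truth, truth_path)
    write_library_fasta([s.consensus for s in config.insertion_specs], lib_path)
    return genome_path, truth_path, lib_path
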