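"""Divergence landscapes, coverage tables and the genome-size~TE
relationship.

The per-hit raw divergence ``D`` (percent of substituted sites against
the consensus) is corrected to an average number of substitutions per
site ``K`` with the one-parameter Jukes-Cantor formula

    K = -300/4 * ln(1 - D * 4/300)      (both in percent units)

i.e. ``K = -75 ln(1 - D/75)``, defined for ``0 <= D < 75``.  Each hit
contributes its masked bp to the ``K`` bin of its classification group;
bin mass divided by genome length gives the genome-fraction landscape
whose shape reads as a proxy for TE activity through time (low K =
recent activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import RepeatHit, TEClass
from .masker import merge_intervals

__all__ = [
    "DivergenceBin",
    "CoverageRow",
    "SizeTEPoint",
    "jc_correct",
    "landscape",
    "landscape_to_frame",
    "coverage_table",
    "rollup_rows",
    "size_te_regression",
    "plot_landscape",
]


@dataclass(frozen=True)
class DivergenceBin:
    """Genome mass in one half-open corrected-divergence bin [k_low, k_high)."""

    group: str
    k_low: float
    k_high: float
    bp: int
    genome_fraction: float


@dataclass(frozen=True)
class CoverageRow:
    """One row of a hierarchical coverage table (Table 1/2 structure)."""

    level: str  # "class", "superfamily" or "family"
    group: str
    count: int
    bp: int
    pct: float


@dataclass(frozen=True)
class SizeTEPoint:
    species: str
    genome_size_mb: float
    te_fraction_pct: float

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0 or self.te_fraction_pct <= 0:
            raise ValueError("genome size and TE fraction must be positive")


def jc_correct(D):
    """Jukes-Cantor correction of a raw divergence (percent -> percent).

    Strictly increasing and convex on [0, 75) with ``jc_correct(D) >= D``
    (equality only at 0); ``D >= 75`` is outside the model's domain (the
    logarithm's argument becomes non-positive) and raises ``ValueError``,
    as does a negative ``D``.  Accepts scalars or arrays.
    """
    arr = np.asarray(D, dtype=float)
    if np.any(arr < 0):
        raise ValueError("divergence D must be >= 0")
    if np.any(arr >= 75.0):
        raise ValueError("divergence D must be < 75 (Jukes-Cantor domain)")
    K = -75.0 * np.log1p(-arr / 75.0)
    return float(K) if np.isscalar(D) or arr.ndim == 0 else K


_GROUPERS = {
    "class": lambda h: h.te_class.value,
    "superfamily": lambda h: h.superfamily or h.te_class.value,
    "family": lambda h: h.family or h.library_name,
    "name": lambda h: h.library_name,
}


def landscape(
    hits: Sequence[RepeatHit],
    genome_length: int,
    bin_width: float = 1.0,
    group_by: str = "superfamily",
    use_correction: bool = True,
) -> tuple[list[DivergenceBin], dict[str, int]]:
    """Bin hit bp by (corrected) divergence per classification group.

    Returns (bins, spill) where ``spill`` maps group -> bp of hits with
    ``D`` outside the Jukes-Cantor domain (D >= 75), which are excluded
    from the landscape but reported so mass is conserved.  With
    ``use_correction=False`` the raw ``D`` is binned instead.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if group_by not in _GROUPERS:
        raise ValueError(f"unknown group_by {group_by!r}")
    key = _GROUPERS[group_by]
    acc: dict[tuple[str, int], int] = {}
    spill: dict[str, int] = {}
    for h in hits:
        g = key(h)
        if h.divergence_D >= 75.0:
            spill[g] = spill.get(g, 0) + h.length
            continue
        k = jc_correct(h.divergence_D) if use_correction else h.divergence_D
        b = int(k // bin_width)
        acc[(g, b)] = acc.get((g, b), 0) + h.length
    bins = [
        DivergenceBin(
            group=g,
            k_low=b * bin_width,
            k_high=(b + 1) * bin_width,
            bp=bp,
            genome_fraction=bp / genome_length,
        )
        for (g, b), bp in sorted(acc.items())
    ]
    return bins, spill


def landscape_to_frame(bins: Sequence[DivergenceBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [b.group for b in bins],
            "k_low": [b.k_low for b in bins],
            "k_high": [b.k_high for b in bins],
            "bp": [b.bp for b in bins],
            "fraction": [b.genome_fraction for b in bins],
        }
    )


def coverage_table(
    hits: Sequence[RepeatHit],
    genome_length: int,
    hierarchy: str = "superfamily",
) -> list[CoverageRow]:
    """Hierarchical coverage rows: per-group fragment count, union-
    collapsed masked bp and percent of genome, with parent rows equal to
    the sum of their children (hits are assumed overlap-resolved, which
    the internal masker guarantees, so sums equal unions).

    ``hierarchy`` is the deepest level to tabulate: "class",
    "superfamily" or "family".
    """
    levels = ["class", "superfamily", "family"]
    if hierarchy not in levels:
        raise ValueError(f"unknown hierarchy level {hierarchy!r}")
    depth = levels.index(hierarchy)
    rows: list[CoverageRow] = []
    for level in levels[: depth + 1]:
        key = _GROUPERS[level]
        groups: dict[str, list[RepeatHit]] = {}
        for h in hits:
            groups.setdefault(key(h), []).append(h)
        for g in sorted(groups):
            hs = groups[g]
            bp = sum(
                e - s + 1 for s, e in merge_intervals([(h.start, h.end) for h in hs])
            )
            rows.append(
                CoverageRow(
                    level=level,
                    group=g,
                    count=len(hs),
                    bp=bp,
                    pct=100.0 * bp / genome_length,
                )
            )
    return rows


def rollup_rows(children: Sequence[CoverageRow], group: str, level: str,
                genome_length: int | None = None) -> CoverageRow:
    """Aggregate component rows into their parent total row (counts and
    bp add exactly; pct recomputed from bp when the genome length is
    known, else summed)."""
    count = sum(r.count for r in children)
    bp = sum(r.bp for r in children)
    if genome_length:
        pct = 100.0 * bp / genome_length
    else:
        pct = sum(r.pct for r in children)
    return CoverageRow(level=level, group=group, count=count, bp=bp, pct=pct)


def size_te_regression(points: Sequence[SizeTEPoint]) -> tuple[float, float, float]:
    """OLS of TE fraction (percent) on genome size (Mb); returns
    (slope, intercept, Pearson r).  Needs >= 3 points with variance."""
    if len(points) < 3:
        raise ValueError("regression needs at least 3 points")
    x = np.array([p.genome_size_mb for p in points])
    y = np.array([p.te_fraction_pct for p in points])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in regression inputs")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def plot_landscape(bins: Sequence[DivergenceBin], genome_length: int, path,
                   title: str = "Repeat divergence landscape") -> None:
    """Stacked-bar landscape figure (percent of genome per K bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = landscape_to_frame(bins)
    if df.empty:
        fig, ax = plt.subplots()
        ax.set_title(title)
        fig.savefig(path)
        plt.close(fig)
        return
    pivot = df.pivot_table(
        index="k_low", columns="group", values="fraction", aggfunc="sum", fill_value=0.0
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(pivot))
    for g in pivot.columns:
        ax.bar(pivot.index, 100 * pivot[g], width=0.9, bottom=bottom, label=g, align="edge")
        bottom += 100 * pivot[g].to_numpy()
    ax.set_xlabel("Jukes-Cantor corrected divergence K (%)")
    ax.set_ylabel("Percent of genome")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
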