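"""Assembly contiguity and composition statistics.

Nx is the length of the sequence at which the cumulative sum of
descending-sorted lengths first reaches x% of the total; Lx is how many
sequences that takes. Percentages and fold-depths are reported half-up at
2 decimals, lengths as integers, matching genome-report table style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import ScaffoldSet
from .util import round_half_up, round_half_up_int

__all__ = [
    "ContiguityStats",
    "contiguity_stats",
    "nx_lx",
    "gap_stats",
    "base_composition",
    "expansion_fraction",
    "summary_report",
]


@dataclass
class ContiguityStats:
    total_length: int
    n_sequences: int
    mean_length: int
    median_length: int
    longest: int
    shortest: int
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float | None = None
    n_count: int | None = None
    gap_lengths: list[int] = field(default_factory=list)

    @property
    def n_gaps(self) -> int:
        return len(self.gap_lengths)


def nx_lx(lengths: list[int], x: float) -> tuple[int, int]:
    """(Nx, Lx) by the first-cumulative-sum >= x% convention."""
    if not lengths:
        raise ValueError("empty length list")
    if any(v <= 0 for v in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    target = x / 100.0 * sum(ordered)
    acc = 0
    for i, v in enumerate(ordered, start=1):
        acc += v
        if acc >= target:
            return v, i
    return ordered[-1], len(ordered)  # unreachable for x <= 100


def contiguity_stats(
    lengths: list[int] | ScaffoldSet, gc_percent: float | None = None
) -> ContiguityStats:
    """Length-based contiguity metrics; medians use the lower-median rule."""
    if isinstance(lengths, ScaffoldSet):
        scaffolds = lengths
        lengths = list(scaffolds.lengths.values())
        seq = "".join(scaffolds.sequences.values())
        comp = base_composition(seq)
        gc_percent = comp["GC"]
        gap_lengths = [
            e - s for name in scaffolds for s, e in scaffolds.gap_runs(name)
        ]
    else:
        gap_lengths = []
    if not lengths:
        raise ValueError("empty length list")
    if any(v <= 0 for v in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    n50, l50 = nx_lx(ordered, 50)
    n90, l90 = nx_lx(ordered, 90)
    median = sorted(lengths)[(len(lengths) - 1) // 2]
    return ContiguityStats(
        total_length=total,
        n_sequences=len(lengths),
        mean_length=round_half_up_int(total / len(lengths)),
        median_length=median,
        longest=ordered[0],
        shortest=ordered[-1],
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        gc_percent=gc_percent,
        n_count=sum(gap_lengths) if gap_lengths else 0,
        gap_lengths=gap_lengths,
    )


def gap_stats(
    scaffolds: ScaffoldSet, min_gap: int = 1
) -> tuple[int, list[int], int]:
    """(number of gaps, gap lengths, total Ns) over maximal N-runs.

    ``min_gap`` filters out short ambiguity-code runs when an assembly uses
    single Ns for ambiguity rather than gaps.
    """
    gap_lengths = [
        e - s
        for name in scaffolds
        for s, e in scaffolds.gap_runs(name)
        if e - s >= min_gap
    ]
    return len(gap_lengths), gap_lengths, sum(gap_lengths)


def base_composition(seq: str) -> dict[str, float]:
    """Percentages of A, C, G, T (over ACGT), N (over all), and GC%."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no ACGT bases")
    out = {b: round_half_up(100.0 * counts[b] / acgt, 2) for b in "ACGT"}
    out["N"] = round_half_up(100.0 * counts["N"] / len(seq), 2)
    out["GC"] = round_half_up(100.0 * (counts["G"] + counts["C"]) / acgt, 2)
    return out


def expansion_fraction(span_bp: int, assembly_length: int) -> float:
    """Percent of the assembly in putative expansion regions (2 dp)."""
    if assembly_length <= 0:
        raise ValueError("assembly length must be positive")
    return round_half_up(100.0 * span_bp / assembly_length, 2)


def summary_report(
    stats: ContiguityStats,
    classes: dict[str, str] | None = None,
    label: str = "assembly",
) -> pd.DataFrame:
    """One-row-per-metric table in a stable order (Table-2-shaped export)."""
    rows = [
        ("assembly_length", stats.total_length),
        ("n_sequences", stats.n_sequences),
        ("gc_percent", stats.gc_percent),
        ("n_count", stats.n_count),
        ("n_gaps", stats.n_gaps),
        ("mean_length", stats.mean_length),
        ("median_length", stats.median_length),
        ("longest", stats.longest),
        ("shortest", stats.shortest),
        ("N50", stats.n50),
        ("N90", stats.n90),
        ("L50", stats.l50),
        ("L90", stats.l90),
    ]
    if classes:
        tally: dict[str, int] = {}
        for cls in classes.values():
            tally[cls] = tally.get(cls, 0) + 1
        rows.extend((f"n_{cls}", tally[cls]) for cls in sorted(tally))
    return pd.DataFrame(rows, columns=["metric", label])
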