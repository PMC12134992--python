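"""De novo tandem-satellite discovery and centromere-candidate calling.

The pipeline finds repetitive candidate regions by k-mer multiplicity
inside fixed windows, infers each array's fundamental monomer period from
the shift-match score

    S(p) = fraction of positions i with seq[i] == seq[i + p],

builds a per-column majority consensus monomer, groups arrays into
families by period and cyclic consensus identity, flags families whose
total span exceeds the centromere-prioritization threshold (100 kb), tests
for higher-order repeat (HOR) structure via monomer-lag identities, and
re-annotates the genome with consensus templates.

Identity between monomer copies is Hamming identity after phase alignment;
the generator plants substitution-only divergence, so indel-free matching
is exact here (an alignment-based mode is the documented upgrade path for
indel-bearing arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import RepeatInterval, ScaffoldSet
from .util import revcomp

__all__ = [
    "SatelliteFamily",
    "HorReport",
    "detect_repetitive_windows",
    "infer_monomer_period",
    "build_consensus_monomer",
    "classify_centromeric",
    "detect_hor",
    "refine_with_templates",
    "discover_satellite_families",
]


@dataclass
class SatelliteFamily:
    family_id: str
    period: int
    consensus: str
    arrays: list[RepeatInterval] = field(default_factory=list)
    centromeric_candidate: bool = False

    @property
    def total_span(self) -> int:
        return sum(iv.span for iv in self.arrays)


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def detect_repetitive_windows(
    seq: str,
    k: int = 12,
    window: int = 2_000,
    min_repetitiveness: float = 0.5,
) -> list[tuple[int, int]]:
    """Windows whose fraction of within-window repeated k-mers is high.

    For each nonoverlapping window, the repetitiveness is the fraction of
    k-mer start positions whose k-mer occurs at least twice inside the
    window. Windows above ``min_repetitiveness`` are kept and adjacent
    candidates merged into maximal regions.
    """
    if k >= window:
        raise ValueError("k must be smaller than window")
    if len(seq) < k + 1:
        return []
    # base-5 integer hash per k-mer start (A,C,G,T,other -> 0..4); exact for
    # k <= 26 in int64, so no collisions at the default k
    table = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    codes = table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    kin = np.convolve(codes, 5 ** np.arange(k, dtype=np.int64), mode="valid")
    flagged = []
    for s in range(0, len(seq), window):
        e = min(s + window, len(seq))
        if e - s < k + 1:
            continue
        vals = kin[s : e - k + 1]
        _, counts = np.unique(vals, return_counts=True)
        repeated = int(counts[counts >= 2].sum())
        if repeated / len(vals) > min_repetitiveness:
            flagged.append((s, e))
    merged: list[tuple[int, int]] = []
    for s, e in flagged:
        if merged and s == merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def shift_match_scores(seq: str, max_period: int = 500) -> np.ndarray:
    """S(p) for p = 1..max_period (index 0 unused)."""
    arr = _to_arr(seq)
    scores = np.zeros(max_period + 1)
    for p in range(1, max_period + 1):
        if len(arr) <= p:
            break
        scores[p] = float(np.mean(arr[:-p] == arr[p:]))
    return scores


def infer_monomer_period(
    seq: str,
    max_period: int = 500,
    min_score: float = 0.6,
    tie_tolerance: float = 0.01,
) -> int:
    """Fundamental monomer period of a tandem array.

    The period maximizing S(p) wins; shifts scoring within ``tie_tolerance``
    (relative) of the maximum are tied and the smallest is returned, so a
    perfect 187-mer array reports 187, not 374. Raises if no shift reaches
    ``min_score`` (the sequence is not usefully tandem).
    """
    if len(seq) < 2 * max_period:
        raise ValueError("array shorter than twice max_period")
    scores = shift_match_scores(seq, max_period)
    best = scores.max()
    if best < min_score:
        raise ValueError("no periodic structure above score threshold")
    tied = np.nonzero(scores >= best * (1 - tie_tolerance))[0]
    return int(tied[tied > 0].min())


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def build_consensus_monomer(seq: str, period: int) -> str:
    """Per-column majority consensus over full monomer copies.

    Phase is anchored at the array start; ties break toward the
    alphabetically first base. Needs at least 3 full copies.
    """
    n_copies = len(seq) // period
    if n_copies < 3:
        raise ValueError("need at least 3 full monomer copies for a consensus")
    arr = _to_arr(seq)[: n_copies * period].reshape(n_copies, period)
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASE_CODES])
    return _BASE_CODES[np.argmax(counts, axis=0)].tobytes().decode("ascii")


def classify_centromeric(
    families: list[SatelliteFamily], min_total_span: int = 100_000
) -> list[SatelliteFamily]:
    """Flag families whose summed array span strictly exceeds the threshold."""
    for fam in families:
        fam.centromeric_candidate = fam.total_span > min_total_span
    return families


@dataclass
class HorReport:
    order: int | None  # None = no higher-order structure
    identities: dict[int, float]  # monomer lag -> mean pairwise identity


def detect_hor(
    seq: str, period: int, max_order: int = 8, margin: float = 0.05
) -> HorReport:
    """Test for higher-order repeats via identity at monomer lags.

    identity(m) is the mean Hamming identity between monomer copies i and
    i+m. An HOR of order m* > 1 is reported when identity(m*) exceeds
    identity(1) by more than ``margin``; a uniform or randomly mutated
    array reports none.
    """
    n_copies = len(seq) // period
    if n_copies < 2 * max_order:
        raise ValueError("array too short for requested max_order")
    arr = _to_arr(seq)[: n_copies * period].reshape(n_copies, period)
    identities = {
        m: float(np.mean(arr[:-m] == arr[m:])) for m in range(1, max_order + 1)
    }
    best_m, best_gain = None, 0.0
    for m in range(2, max_order + 1):
        gain = identities[m] - identities[1]
        if gain > margin and gain > best_gain:
            best_m, best_gain = m, gain
    return HorReport(order=best_m, identities=identities)


def _identity_profile(seq_arr: np.ndarray, tpl_arr: np.ndarray) -> np.ndarray:
    if len(seq_arr) < len(tpl_arr):
        return np.zeros(0)
    win = sliding_window_view(seq_arr, len(tpl_arr))
    return (win == tpl_arr).mean(axis=1)


def refine_with_templates(
    scaffolds: ScaffoldSet,
    templates: dict[str, str],
    min_identity: float = 0.8,
    k: int = 12,
    window: int = 2_000,
    min_copies: int = 3,
) -> list[RepeatInterval]:
    """Template-guided satellite re-annotation.

    Scans repetitive candidate regions for tandem chains of monomer copies
    matching any template (or its reverse complement) at per-copy Hamming
    identity >= ``min_identity``; returns per-family intervals with copy
    counts. Boundaries are exact to within one monomer.
    """
    if not templates:
        raise ValueError("template list must be non-empty")
    out: list[RepeatInterval] = []
    for name, seq in scaffolds.items():
        regions = detect_repetitive_windows(seq, k=k, window=window)
        for r0, r1 in regions:
            for fam, tpl in templates.items():
                p = len(tpl)
                # candidate regions are window-quantized and their edge
                # windows can fall under the repetitiveness cutoff; pad by a
                # window plus a monomer so chains reach the true boundaries
                pad = window + p
                lo, hi = max(0, r0 - pad), min(len(seq), r1 + pad)
                sub = _to_arr(seq[lo:hi])
                for tpl_seq, strand in ((tpl, "+"), (revcomp(tpl), "-")):
                    prof = _identity_profile(sub, _to_arr(tpl_seq))
                    hits = prof >= min_identity
                    if not hits.any():
                        continue
                    i = int(np.argmax(hits))
                    while i < len(prof):
                        if not hits[i]:
                            i += 1
                            continue
                        start, copies, j = i, 0, i
                        while j < len(prof):
                            lo_j = max(0, j - 2)
                            span_hits = hits[lo_j : j + 3]
                            if span_hits.any():
                                j = lo_j + int(np.argmax(span_hits))
                                copies += 1
                                j += p
                            else:
                                break
                        if copies >= min_copies:
                            out.append(
                                RepeatInterval(
                                    scaffold=name,
                                    start=lo + start,
                                    end=min(lo + j, len(seq)),
                                    repeat_class=fam,
                                    motif=fam,
                                    copy_number=copies,
                                    strand=strand,
                                )
                            )
                        i = j + 1
    out.sort(key=lambda iv: (iv.scaffold, iv.start))
    return out


def _cyclic_identity(a: str, b: str) -> float:
    """Best Hamming identity of a vs all rotations of b (equal lengths)."""
    if len(a) != len(b):
        return 0.0
    arr_a = _to_arr(a)
    doubled = _to_arr(b + b)
    win = sliding_window_view(doubled, len(a))[: len(b)]
    return float((win == arr_a).mean(axis=1).max())


def discover_satellite_families(
    scaffolds: ScaffoldSet,
    k: int = 12,
    window: int = 2_000,
    min_repetitiveness: float = 0.5,
    max_period: int = 500,
    min_region: int = 4_000,
    group_identity: float = 0.7,
) -> list[SatelliteFamily]:
    """End-to-end de novo discovery: candidates -> period -> consensus ->
    family grouping (period match within 2 bp and cyclic consensus identity
    >= ``group_identity``). Family ids are SAT<period> with letter suffixes
    for distinct same-period families.
    """
    families: list[SatelliteFamily] = []
    for name, seq in scaffolds.items():
        for r0, r1 in detect_repetitive_windows(
            seq, k=k, window=window, min_repetitiveness=min_repetitiveness
        ):
            if r1 - r0 < min_region:
                continue
            sub = seq[r0:r1]
            eff_max = min(max_period, (r1 - r0) // 2)
            try:
                period = infer_monomer_period(sub, max_period=eff_max)
                consensus = build_consensus_monomer(sub, period)
            except ValueError:
                continue
            iv = RepeatInterval(
                scaffold=name,
                start=r0,
                end=r1,
                repeat_class="satellite",
                motif="",
                copy_number=(r1 - r0) / period,
            )
            home = None
            for fam in families:
                if abs(fam.period - period) <= 2 and (
                    _cyclic_identity(consensus, fam.consensus) >= group_identity
                ):
                    home = fam
                    break
            if home is None:
                siblings = sum(f.period == period for f in families)
                suffix = chr(ord("a") + siblings) if siblings else ""
                home = SatelliteFamily(f"SAT{period}{suffix}", period, consensus)
                families.append(home)
            iv.repeat_class = home.family_id
            iv.motif = home.family_id
            home.arrays.append(iv)
    return classify_centromeric(families)
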