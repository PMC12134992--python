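"""Telomere-array detection, misjoin flagging, and AGP-based splitting.

Telomeres are tandem arrays of the vertebrate motif TTAGGG (CCCTAA on the
minus strand). The caller keeps arrays spanning more than ``min_span`` bases
(600 bp, i.e. >100 motif copies) and labels them terminal when they fall
within ``terminal_dist`` of a scaffold end. An *internal* telomere close to
an assembly gap marks a likely scaffolding misjoin; flagged gaps can be
split, removing the gap Ns and renaming the pieces ``<id>.1``, ``<id>.2``…
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .containers import PlanPart, RepeatInterval, ScaffoldPlan, ScaffoldSet
from .util import revcomp

TELOMERE_MOTIF = "TTAGGG"

__all__ = [
    "scan_motif_runs",
    "call_telomeres",
    "detect_misjoins",
    "split_at_gaps",
]


@dataclass
class _Run:
    start: int
    end: int
    matched: int  # motif bases matched inside [start, end)
    strand: str


def _motif_runs_one_strand(seq: str, motif: str, strand: str) -> list[_Run]:
    """Maximal runs of immediately adjacent motif copies on one strand."""
    pat = re.compile(f"(?:{re.escape(motif)})+")
    return [
        _Run(m.start(), m.end(), m.end() - m.start(), strand) for m in pat.finditer(seq)
    ]


def scan_motif_runs(
    seq: str,
    motif: str = TELOMERE_MOTIF,
    max_interrupt: int = 50,
    min_content: float = 0.9,
) -> list[RepeatInterval]:
    """Find tandem motif arrays on either strand, tolerating interruptions.

    Runs of exact copies (motif on plus, its reverse complement on minus)
    separated by at most ``max_interrupt`` non-motif bases are merged when
    the merged interval keeps >= ``min_content`` motif content. Copy number
    is matched motif bases / motif length, so interruptions do not inflate
    it. Strands are scanned independently and never merged together.
    """
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    out: list[RepeatInterval] = []
    for m, strand in ((motif, "+"), (revcomp(motif), "-")):
        if strand == "-" and m == motif:
            continue  # palindromic motif: one scan suffices
        runs = _motif_runs_one_strand(seq, m, strand)
        merged: list[_Run] = []
        for r in runs:
            if (
                merged
                and r.start - merged[-1].end <= max_interrupt
                and (merged[-1].matched + r.matched) / (r.end - merged[-1].start)
                >= min_content
            ):
                merged[-1] = _Run(
                    merged[-1].start, r.end, merged[-1].matched + r.matched, strand
                )
            else:
                merged.append(r)
        for r in merged:
            out.append(
                RepeatInterval(
                    scaffold="",
                    start=r.start,
                    end=r.end,
                    repeat_class="telomere",
                    motif=motif,
                    copy_number=r.matched / len(motif),
                    strand=strand,
                )
            )
    out.sort(key=lambda iv: iv.start)
    return out


def call_telomeres(
    scaffolds: ScaffoldSet,
    min_span: int = 600,
    terminal_dist: int = 10_000,
    max_interrupt: int = 50,
) -> list[RepeatInterval]:
    """Telomere calls: motif arrays spanning strictly more than ``min_span``.

    Placement is ``terminal`` when the array starts within ``terminal_dist``
    of the scaffold start or ends within ``terminal_dist`` of the scaffold
    end; otherwise ``internal``.
    """
    if min_span <= 0:
        raise ValueError("min_span must be positive")
    calls: list[RepeatInterval] = []
    for name, seq in scaffolds.items():
        L = len(seq)
        for iv in scan_motif_runs(seq, TELOMERE_MOTIF, max_interrupt=max_interrupt):
            if iv.span <= min_span:
                continue
            iv.scaffold = name
            terminal = iv.start < terminal_dist or iv.end > L - terminal_dist
            iv.placement = "terminal" if terminal else "internal"
            calls.append(iv)
    return calls


def detect_misjoins(
    telomeres: list[RepeatInterval],
    plan: ScaffoldPlan,
    near_dist: int = 100_000,
) -> list[tuple[str, int]]:
    """Gaps with an internal telomere within ``near_dist`` of a gap boundary.

    Returns (scaffold, gap index) pairs, each gap reported once, in plan
    order. Gap indices count the gaps of that scaffold from 0.
    """
    internals: dict[str, list[RepeatInterval]] = {}
    for iv in telomeres:
        if iv.placement == "internal":
            if iv.scaffold not in plan.parts:
                raise ValueError(f"telomere on scaffold absent from plan: {iv.scaffold}")
            internals.setdefault(iv.scaffold, []).append(iv)
    flagged: list[tuple[str, int]] = []
    for scaf, telos in internals.items():
        for gi, (gs, ge) in enumerate(plan.gaps(scaf)):
            for t in telos:
                gap_dist = max(gs - t.end, t.start - ge, 0)
                if gap_dist <= near_dist:
                    flagged.append((scaf, gi))
                    break
    return flagged


def split_at_gaps(
    scaffolds: ScaffoldSet,
    plan: ScaffoldPlan,
    gaps_to_split: list[tuple[str, int]],
) -> tuple[ScaffoldSet, ScaffoldPlan]:
    """Split scaffolds at the named gaps, dropping the gap Ns.

    Pieces are named ``<id>.1``, ``<id>.2``… in coordinate order; non-N
    bases are conserved and the plan is rewritten consistently. Requesting
    the same gap twice is an error; scaffolds without splits pass through
    untouched (same ids, same sequences).
    """
    seen = set()
    for key in gaps_to_split:
        if key in seen:
            raise ValueError(f"gap {key} requested twice")
        seen.add(key)
    by_scaffold: dict[str, set[int]] = {}
    for scaf, gi in gaps_to_split:
        if scaf not in plan.parts:
            raise ValueError(f"unknown scaffold in split request: {scaf}")
        n_gaps = len(plan.gaps(scaf))
        if not (0 <= gi < n_gaps):
            raise ValueError(f"gap index {gi} out of range for {scaf}")
        by_scaffold.setdefault(scaf, set()).add(gi)

    out_seqs = ScaffoldSet()
    out_plan = ScaffoldPlan()
    for name, parts in plan.parts.items():
        if name not in by_scaffold:
            out_seqs.add(name, scaffolds[name])
            out_plan.parts[name] = list(parts)
            continue
        split_set = by_scaffold[name]
        seq = scaffolds[name]
        piece_idx, gap_idx = 1, 0
        cur_parts: list[PlanPart] = []
        cur_start = 0

        def flush(end: int):
            nonlocal piece_idx, cur_parts, cur_start
            if end <= cur_start:  # never emit an empty piece
                cur_parts = []
                return
            piece = f"{name}.{piece_idx}"
            out_seqs.add(piece, seq[cur_start:end])
            out_plan.parts[piece] = [
                PlanPart(
                    p.start - cur_start,
                    p.end - cur_start,
                    p.is_gap,
                    component_id=p.component_id,
                    orientation=p.orientation,
                    gap_length=p.gap_length,
                )
                for p in cur_parts
            ]
            piece_idx += 1
            cur_parts = []

        for p in parts:
            if p.is_gap:
                if gap_idx in split_set:
                    flush(p.start)
                    cur_start = p.end
                else:
                    cur_parts.append(p)
                gap_idx += 1
            else:
                cur_parts.append(p)
        flush(len(seq))
    out_plan.validate()
    return out_seqs, out_plan
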