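"""Core containers: scaffold sets, repeat intervals, alignment hits, AGP plans.

Coordinates are 0-based half-open throughout; AGP files are converted to and
from their native 1-based inclusive convention on IO.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import revcomp

_N_RUN = re.compile(r"N+")


class ScaffoldSet:
    """Ordered mapping of scaffold id -> sequence (uppercase string)."""

    def __init__(self, sequences: dict[str, str] | None = None):
        self.sequences: dict[str, str] = dict(sequences or {})

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def items(self):
        return self.sequences.items()

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise ValueError(f"duplicate scaffold id {name!r}")
        self.sequences[name] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(v) for v in self.sequences.values())

    def gap_runs(self, name: str) -> list[tuple[int, int]]:
        """Maximal runs of N in a scaffold as (start, end) intervals."""
        return [(m.start(), m.end()) for m in _N_RUN.finditer(self.sequences[name])]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ScaffoldSet":
        obj = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            obj.add(rec.id, str(rec.seq))
        return obj

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="") for name, s in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass
class RepeatInterval:
    """A located tandem-repeat array (telomere or satellite)."""

    scaffold: str
    start: int
    end: int
    repeat_class: str  # e.g. "telomere", "CEN187"
    motif: str  # motif or monomer id
    copy_number: float
    strand: str = "+"
    placement: str = "internal"  # "terminal" | "internal"

    @property
    def span(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def write_repeat_bed(intervals: Iterable[RepeatInterval], path: str | Path) -> None:
    """BED6 with name = motif:copy_number:placement."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"{iv.motif}:{iv.copy_number:.1f}:{iv.placement}"
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


@dataclass
class AlignmentHit:
    """One tabular alignment hit (PAF/outfmt-6 distilled)."""

    query: str
    target: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    identity: float = 1.0

    def __post_init__(self):
        if self.qend <= self.qstart or self.tend <= self.tstart:
            raise ValueError("hit intervals must be non-empty")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be a fraction")


@dataclass
class PlanPart:
    """One AGP line: a sequence component (W) or a gap (N)."""

    start: int  # on the object scaffold, 0-based
    end: int
    is_gap: bool
    component_id: str | None = None
    orientation: str = "+"
    gap_length: int | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldPlan:
    """AGP-style composition: ordered components and gaps per scaffold."""

    parts: dict[str, list[PlanPart]] = field(default_factory=dict)

    def scaffolds(self) -> list[str]:
        return list(self.parts)

    def gaps(self, scaffold: str) -> list[tuple[int, int]]:
        return [(p.start, p.end) for p in self.parts[scaffold] if p.is_gap]

    def validate(self) -> None:
        for name, plist in self.parts.items():
            pos = 0
            for p in plist:
                if p.start != pos:
                    raise ValueError(f"{name}: parts do not tile (at {p.start})")
                if p.is_gap and (p.gap_length is None or p.gap_length <= 0):
                    raise ValueError(f"{name}: gap with non-positive length")
                pos = p.end

    @classmethod
    def from_scaffolds(cls, scaffolds: ScaffoldSet, min_gap: int = 1) -> "ScaffoldPlan":
        """Derive a plan by treating maximal N-runs (>= min_gap) as gaps."""
        plan = cls()
        for name, seq in scaffolds.items():
            runs = [
                (s, e) for s, e in scaffolds.gap_runs(name) if e - s >= min_gap
            ]
            parts: list[PlanPart] = []
            pos, comp_idx = 0, 0
            for s, e in runs:
                if s > pos:
                    comp_idx += 1
                    parts.append(
                        PlanPart(pos, s, False, component_id=f"{name}_c{comp_idx}")
                    )
                parts.append(PlanPart(s, e, True, gap_length=e - s))
                pos = e
            if pos < len(seq) or not parts:
                comp_idx += 1
                parts.append(
                    PlanPart(pos, len(seq), False, component_id=f"{name}_c{comp_idx}")
                )
            plan.parts[name] = parts
        return plan

    def extract_components(self, scaffolds: ScaffoldSet) -> dict[str, str]:
        comps: dict[str, str] = {}
        for name, plist in self.parts.items():
            seq = scaffolds[name]
            for p in plist:
                if not p.is_gap:
                    sub = seq[p.start : p.end]
                    comps[p.component_id] = revcomp(sub) if p.orientation == "-" else sub
        return comps

    def assemble(self, components: dict[str, str]) -> ScaffoldSet:
        """Rebuild scaffold sequences from component sequences and gap Ns."""
        out = ScaffoldSet()
        for name, plist in self.parts.items():
            chunks = []
            for p in plist:
                if p.is_gap:
                    chunks.append("N" * p.gap_length)
                else:
                    sub = components[p.component_id]
                    chunks.append(revcomp(sub) if p.orientation == "-" else sub)
            out.add(name, "".join(chunks))
        return out

    def to_agp(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##agp-version 2.1\n")
            for name, plist in self.parts.items():
                for i, p in enumerate(plist, 1):
                    if p.is_gap:
                        fh.write(
                            f"{name}\t{p.start + 1}\t{p.end}\t{i}\tN\t"
                            f"{p.gap_length}\tscaffold\tyes\tproximity_ligation\n"
                        )
                    else:
                        fh.write(
                            f"{name}\t{p.start + 1}\t{p.end}\t{i}\tW\t"
                            f"{p.component_id}\t1\t{p.span}\t{p.orientation}\n"
                        )

    @classmethod
    def from_agp(cls, path: str | Path) -> "ScaffoldPlan":
        plan = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                name, beg, end, ctype = f[0], int(f[1]) - 1, int(f[2]), f[4]
                plist = plan.parts.setdefault(name, [])
                if ctype in ("N", "U"):
                    plist.append(PlanPart(beg, end, True, gap_length=int(f[5])))
                else:
                    orient = f[8] if len(f) > 8 else "+"
                    plist.append(
                        PlanPart(beg, end, False, component_id=f[5], orientation=orient)
                    )
        plan.validate()
        return plan
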