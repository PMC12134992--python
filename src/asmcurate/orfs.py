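"""Full-length ORF selection and greedy protein clustering.

Transcripts with a blastx-style best protein hit are extended from the
aligned frame to the nearest in-frame start and stop codons; an ORF is
full-length when it has both and its translated length is between 95% and
105% (inclusive) of the best-hit protein. Transcripts without a hit are
scanned in all six frames for ORFs strictly longer than 50 aa. Amino-acid
sequences are then clustered greedily (longest first) at 80% identity with
the shorter sequence covered over at least 90% of its length, CD-HIT
style, with exhaustive pairwise alignment in place of k-mer screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "TranscriptHit",
    "OrfCall",
    "best_hit",
    "hits_from_table",
    "extract_orf",
    "classify_full_length",
    "find_orfs_unaligned",
    "greedy_cluster",
]

_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass
class TranscriptHit:
    """One blastx-style hit; 1-based inclusive coordinates, qstart > qend
    on the minus strand, as in tabular outfmt 6."""

    transcript: str
    protein: str
    qstart: int
    qend: int
    sstart: int
    send: int
    protein_len: int
    bitscore: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")

    @property
    def minus(self) -> bool:
        return self.qstart > self.qend

    @property
    def alignment_len(self) -> int:
        return self.send - self.sstart + 1


@dataclass
class OrfCall:
    transcript: str
    aa_seq: str
    nt_seq: str
    has_start: bool
    has_stop: bool
    ratio_to_hit: float | None = None
    status: str = "partial"  # full_length | partial | unaligned_orf
    frame: int = 0  # 1..3 plus strand, -1..-3 minus

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


def hits_from_table(table: pd.DataFrame) -> dict[str, list[TranscriptHit]]:
    """Parse an outfmt-6-like DataFrame (needs qseqid, sseqid, qstart, qend,
    sstart, send, bitscore, slen) into per-transcript hit lists."""
    out: dict[str, list[TranscriptHit]] = {}
    for row in table.itertuples(index=False):
        h = TranscriptHit(
            transcript=row.qseqid,
            protein=row.sseqid,
            qstart=int(row.qstart),
            qend=int(row.qend),
            sstart=int(row.sstart),
            send=int(row.send),
            protein_len=int(row.slen),
            bitscore=float(row.bitscore),
        )
        out.setdefault(h.transcript, []).append(h)
    return out


def best_hit(hits: list[TranscriptHit]) -> TranscriptHit:
    """Best hit by bitscore; ties by longer protein alignment, then
    lexicographically smaller protein id (deterministic)."""
    if not hits:
        raise ValueError("no hits")
    return sorted(hits, key=lambda h: (-h.bitscore, -h.alignment_len, h.protein))[0]


def extract_orf(transcript_seq: str, hit: TranscriptHit) -> OrfCall:
    """Extend the aligned reading frame to the nearest in-frame start/stop.

    The aligned region fixes strand and frame. Upstream, the ORF grows
    codon-by-codon to the nearest ATG, never crossing an in-frame stop;
    downstream it runs to the first in-frame stop codon (included in the
    nucleotide ORF, excluded from the translation). An in-frame stop inside
    the aligned region itself demotes the call to partial with a warning.
    """
    seq = transcript_seq.upper()
    if hit.minus:
        seq = str(Seq(seq).reverse_complement())
        a0 = len(seq) - hit.qstart  # 0-based aligned start on the plus copy
        a1 = len(seq) - hit.qend + 1
    else:
        a0, a1 = hit.qstart - 1, hit.qend
    # upstream extension to the nearest in-frame ATG (never across a stop)
    has_start = seq[a0 : a0 + 3] == "ATG"
    pos = a0 - 3
    start = a0
    while pos >= 0 and not has_start:
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            break
        if codon == "ATG":
            has_start = True
            start = pos
        pos -= 3

    # downstream: run to the first in-frame stop (from the aligned start on)
    has_stop = internal_stop = False
    end = a1
    pos = a0
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            has_stop = True
            end = pos + 3
            internal_stop = end <= a1  # stop lies inside the aligned region
            break
        pos += 3
    if not has_stop:
        end = start + ((len(seq) - start) // 3) * 3

    nt = seq[start:end]
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    status = "partial"
    if internal_stop:
        warnings.warn(
            f"{hit.transcript}: in-frame stop inside the aligned region; partial call"
        )
    frame = (start % 3) + 1
    if hit.minus:
        frame = -frame
    call = OrfCall(
        transcript=hit.transcript,
        aa_seq=aa,
        nt_seq=nt,
        has_start=has_start,
        has_stop=has_stop,
        status=status,
        frame=frame,
    )
    if hit.protein_len:
        call.ratio_to_hit = len(aa) / hit.protein_len
    return call


def classify_full_length(call: OrfCall, protein_len: int | None = None) -> str:
    """full_length iff start and stop present and the translated length is
    within 95-105% (inclusive) of the best-hit protein length."""
    if protein_len is not None:
        if protein_len <= 0:
            raise ValueError("protein length must be positive")
        call.ratio_to_hit = call.length_aa / protein_len
    if call.ratio_to_hit is None:
        raise ValueError("no reference protein length available")
    if call.has_start and call.has_stop and 0.95 <= call.ratio_to_hit <= 1.05:
        call.status = "full_length"
    else:
        call.status = "partial"
    return call.status


def find_orfs_unaligned(transcript_seq: str, min_len: int = 50) -> list[OrfCall]:
    """Six-frame ATG-to-stop ORFs strictly longer than ``min_len`` aa.

    Within each frame, ORFs start at the first ATG after the previous stop
    (or sequence start) and run to the next in-frame stop; ORFs without a
    stop codon are not reported.
    """
    seq = transcript_seq.upper()
    calls: list[OrfCall] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            i = off
            orf_start = None
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if orf_start is None and codon == "ATG":
                    orf_start = i
                elif orf_start is not None and codon in _STOPS:
                    nt = s[orf_start : i + 3]
                    aa = str(Seq(nt).translate())[:-1]
                    if len(aa) > min_len:
                        calls.append(
                            OrfCall(
                                transcript="",
                                aa_seq=aa,
                                nt_seq=nt,
                                has_start=True,
                                has_stop=True,
                                status="unaligned_orf",
                                frame=(off + 1) if strand == "+" else -(off + 1),
                            )
                        )
                    orf_start = None
                i += 3
    return calls


@dataclass
class Cluster:
    representative_id: str
    representative_seq: str
    members: list[str] = field(default_factory=list)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -0.5
    return a


def _identity_and_coverage(
    aligner: Align.PairwiseAligner, rep: str, query: str
) -> tuple[float, float]:
    """(identity over alignment columns, aligned fraction of the shorter)."""
    aln = aligner.align(rep, query)
    if len(aln) == 0:
        return 0.0, 0.0
    best = aln[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    short_len = min(len(rep), len(query))
    # aligned span on the shorter sequence
    blocks = best.aligned[0] if len(rep) <= len(query) else best.aligned[1]
    span = sum(e - s for s, e in blocks)
    return identity, span / short_len if short_len else 0.0


def greedy_cluster(
    sequences: dict[str, str],
    min_identity: float = 0.8,
    min_short_coverage: float = 0.9,
) -> list[Cluster]:
    """CD-HIT-style greedy clustering of amino-acid sequences.

    Sequences are sorted by decreasing length; each joins the first cluster
    whose representative it matches at >= ``min_identity`` over at least
    ``min_short_coverage`` of the shorter sequence, else founds a new
    cluster. Representatives are founding (longest) members, so they are
    never shorter than any member.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    aligner = _aligner()
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[Cluster] = []
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cl in clusters:
            ident, cov = _identity_and_coverage(aligner, cl.representative_seq, seq)
            if ident >= min_identity and cov >= min_short_coverage:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, seq, members=[sid]))
    return clusters
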