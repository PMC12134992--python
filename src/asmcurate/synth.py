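"""Truth-labeled synthetic genomes for exercising the curation pipeline.

The generator emulates the structure of a male (XY) skink-like diploid
assembly at desk scale: GC-distinct macro- and microchromosomes, an X at
half male depth with a pseudoautosomal region, fragmented Y scaffolds,
terminal TTAGGG telomere arrays, planted scaffolding misjoins (an internal
telomere abutting a 200-N gap), two centromeric satellite families with
fixed monomer periods spanning >100 kb, rDNA scaffolds carrying 18S/28S-like
segments, a mitochondrial scaffold, and a bimodal (het/hom) k-mer depth
histogram. Every planted feature is enumerated in a :class:`TruthTable`.

Background sequence is i.i.d. with per-scaffold GC targets, so planted
features are the only repeat structure and truth stays unambiguous.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AlignmentHit, ScaffoldSet
from .kmers import KmerHistogram
from .util import mutate_substitutions, random_sequence

TELOMERE_MOTIF = "TTAGGG"

__all__ = [
    "GenomeSpec",
    "TruthFeature",
    "TruthTable",
    "generate_genome",
    "simulate_depth",
    "simulate_kmer_histogram",
    "simulate_reads",
    "simulate_alignments",
    "simulate_transcripts",
    "write_truth",
    "read_truth_bed",
    "toy_18s",
    "toy_28s",
]


# -- toy rDNA subunit seeds -------------------------------------------------

def _fixed_sequence(tag: int, length: int, gc: float) -> str:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=tag))
    return random_sequence(rng, length, gc)


def toy_18s() -> str:
    """Synthetic stand-in for an 18S small-subunit reference (1.8 kb).

    Deterministic pseudo-random sequence; a packaged synthetic fixture, not
    a biological 18S gene.
    """
    return _fixed_sequence(18, 1_800, 0.54)


def toy_28s() -> str:
    """Synthetic stand-in for a 28S large-subunit reference (3.9 kb)."""
    return _fixed_sequence(28, 3_900, 0.57)


# -- spec and truth ---------------------------------------------------------

@dataclass
class GenomeSpec:
    """Parameters of the planted genome; defaults mirror the study structure
    at desk scale (six macrochromosomes, eight GC-elevated microchromosomes,
    187/199-bp centromeric monomer families spanning >100 kb, 200-N gaps)."""

    n_macro: int = 6
    n_micro: int = 8
    macro_len_range: tuple[int, int] = (1_600_000, 2_600_000)
    micro_len_range: tuple[int, int] = (1_000_000, 1_250_000)
    macro_gc: float = 0.42
    micro_gc: float = 0.445
    x_len: int = 1_500_000
    par_len: int = 200_000
    y_fragment_lens: tuple[int, ...] = (250_000, 400_000, 600_000)
    telomere_copies: int = 150
    short_telomere_copies: int = 100  # 600 bp: at the detection boundary
    cen_monomers: tuple[tuple[int, int], ...] = ((187, 112_200), (199, 119_400))
    cen_divergence: float = 0.02
    cen_gc: float = 0.36
    gap_len: int = 200
    misjoin_count: int = 3
    benign_gaps: int = 2
    rdna_scaffolds: int = 2
    sat_only_scaffolds: int = 2
    n_unassigned: int = 2
    mito_len: int = 17_506
    seed: int = 0

    def validate(self) -> None:
        if self.macro_gc >= self.micro_gc:
            raise ValueError("macro_gc must be below micro_gc")
        if self.gap_len <= 0:
            raise ValueError("gap_len must be positive")
        for name in ("x_len", "par_len", "mito_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.x_len > 0 and self.n_macro + self.n_micro == 0:
            raise ValueError(
                "an X without autosomes makes depth normalization impossible"
            )
        if self.misjoin_count > self.n_macro:
            raise ValueError("more misjoins than macro scaffolds")
        if self.par_len >= self.x_len > 0:
            raise ValueError("par_len must be smaller than x_len")


@dataclass
class TruthFeature:
    scaffold: str
    start: int
    end: int
    feature_class: str  # telomere | cen_family_i | misjoin_gap | rdna | par
    payload: dict = field(default_factory=dict)


@dataclass
class TruthTable:
    features: list[TruthFeature] = field(default_factory=list)
    scaffold_classes: dict[str, str] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    planted_monomers: dict[str, str] = field(default_factory=dict)

    def features_of(self, feature_class: str) -> list[TruthFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def validate(self) -> None:
        for f in self.features:
            L = self.scaffold_lengths.get(f.scaffold)
            if L is None:
                raise ValueError(f"feature on unknown scaffold {f.scaffold}")
            if not (0 <= f.start < f.end <= L):
                raise ValueError(f"feature outside scaffold bounds: {f}")


# -- genome construction ----------------------------------------------------

def _telomere_array(copies: int) -> str:
    return TELOMERE_MOTIF * copies


def _cen_array(rng: np.random.Generator, monomer: str, copies: int, divergence: float) -> str:
    return "".join(
        mutate_substitutions(rng, monomer, divergence) for _ in range(copies)
    )


class _Builder:
    """Assembles one scaffold from placed feature blocks over background."""

    def __init__(self, rng, name, length, gc):
        self.rng, self.name, self.gc = rng, name, gc
        self.length = length
        self.blocks: list[tuple[int, str, str, dict]] = []  # (start, seq, class, payload)

    def place(self, start: int, seq: str, feature_class: str | None, **payload):
        self.blocks.append((start, seq, feature_class, payload))

    def build(self, truth: TruthTable):
        self.blocks.sort(key=lambda b: b[0])
        chunks, pos = [], 0
        for start, seq, fclass, payload in self.blocks:
            if start < pos:
                raise ValueError(f"{self.name}: overlapping planted blocks")
            chunks.append(random_sequence(self.rng, start - pos, self.gc))
            if fclass is not None:
                truth.features.append(
                    TruthFeature(self.name, start, start + len(seq), fclass, payload)
                )
            chunks.append(seq)
            pos = start + len(seq)
        chunks.append(random_sequence(self.rng, self.length - pos, self.gc))
        return "".join(chunks)


def generate_genome(spec: GenomeSpec) -> tuple[ScaffoldSet, TruthTable]:
    """Build the planted assembly and its truth table (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scaffolds = ScaffoldSet()
    truth = TruthTable()

    monomers = {}
    for fam_idx, (period, _span) in enumerate(spec.cen_monomers):
        monomers[f"cen_family_{fam_idx}"] = random_sequence(rng, period, spec.cen_gc)
    truth.planted_monomers = monomers

    telo_span = 6 * spec.telomere_copies

    def plant_telomere(b: _Builder, start: int, copies: int, placement: str):
        b.place(
            start,
            _telomere_array(copies),
            "telomere",
            copies=copies,
            span=6 * copies,
            placement=placement,
        )

    # macrochromosomes, longest-first
    macro_lens = sorted(
        (int(rng.integers(*spec.macro_len_range)) for _ in range(spec.n_macro)),
        reverse=True,
    )
    for i, L in enumerate(macro_lens):
        name = f"mac{i + 1}"
        b = _Builder(rng, name, L, spec.macro_gc)
        plant_telomere(b, 0, spec.telomere_copies, "terminal")
        plant_telomere(b, L - telo_span, spec.telomere_copies, "terminal")
        if i < len(spec.cen_monomers):
            fam = f"cen_family_{i}"
            period, span = spec.cen_monomers[i]
            copies = span // period
            arr = _cen_array(rng, monomers[fam], copies, spec.cen_divergence)
            b.place(L // 2, arr, fam, period=period, copies=copies)
        for g in range(spec.benign_gaps):
            b.place(int(L * (0.25 + 0.07 * g)), "N" * spec.gap_len, None)
        if i >= spec.n_macro - spec.misjoin_count:
            # internal telomere immediately followed by a gap: a misjoin
            at = int(L * 0.72)
            plant_telomere(b, at, spec.telomere_copies, "internal")
            gap_start = at + telo_span
            b.place(gap_start, "N" * spec.gap_len, "misjoin_gap")
        scaffolds.add(name, b.build(truth))
        truth.scaffold_classes[name] = "macro"

    # microchromosomes (elevated GC); the first carries boundary-size arrays
    micro_lens = sorted(
        (int(rng.integers(*spec.micro_len_range)) for _ in range(spec.n_micro)),
        reverse=True,
    )
    for i, L in enumerate(micro_lens):
        name = f"mic{i + 1}"
        b = _Builder(rng, name, L, spec.micro_gc)
        copies = spec.short_telomere_copies if i == 0 else spec.telomere_copies
        plant_telomere(b, 0, copies, "terminal")
        plant_telomere(b, L - 6 * copies, copies, "terminal")
        scaffolds.add(name, b.build(truth))
        truth.scaffold_classes[name] = "micro"

    # X with a PAR at its start; one telomere missing (end only)
    if spec.x_len > 0:
        b = _Builder(rng, "chrX", spec.x_len, spec.macro_gc)
        plant_telomere(b, 0, spec.telomere_copies, "terminal")
        seq = b.build(truth)
        truth.features.append(
            TruthFeature("chrX", 0, spec.par_len, "par", {})
        )
        scaffolds.add("chrX", seq)
        truth.scaffold_classes["chrX"] = "X"

    for i, L in enumerate(spec.y_fragment_lens):
        name = f"Yfrag{i + 1}"
        scaffolds.add(name, random_sequence(rng, L, spec.macro_gc))
        truth.scaffold_classes[name] = "Y"

    len18, len28 = len(toy_18s()), len(toy_28s())
    for i in range(spec.rdna_scaffolds):
        name = f"rdna{i + 1}"
        L = 90_000 + 10_000 * i
        b = _Builder(rng, name, L, 0.47)
        pos = 5_000
        for _rep in range(3):  # tandem rDNA cassettes
            s18 = mutate_substitutions(rng, toy_18s(), 0.03)
            b.place(pos, s18, "rdna", subunit="18S")
            pos += len18 + 1_500
            s28 = mutate_substitutions(rng, toy_28s(), 0.03)
            b.place(pos, s28, "rdna", subunit="28S")
            pos += len28 + 4_000
        scaffolds.add(name, b.build(truth))
        truth.scaffold_classes[name] = "rDNA"

    # satellite-only scaffolds: >50% of length is a family-0 array
    if spec.sat_only_scaffolds and spec.cen_monomers:
        period, _ = spec.cen_monomers[0]
        for i in range(spec.sat_only_scaffolds):
            name = f"sat{i + 1}"
            L = 60_000 + 5_000 * i
            copies = int(L * 0.6) // period
            b = _Builder(rng, name, L, spec.macro_gc)
            arr = _cen_array(rng, monomers["cen_family_0"], copies, spec.cen_divergence)
            b.place(10_000, arr, "cen_family_0", period=period, copies=copies)
            scaffolds.add(name, b.build(truth))
            truth.scaffold_classes[name] = "satellite"

    if spec.mito_len > 0:
        scaffolds.add("mito", random_sequence(rng, spec.mito_len, 0.415))
        truth.scaffold_classes["mito"] = "mito"

    for i in range(spec.n_unassigned):
        name = f"una{i + 1}"
        scaffolds.add(name, random_sequence(rng, 80_000 + 7_000 * i, spec.macro_gc))
        truth.scaffold_classes[name] = "unassigned"

    truth.scaffold_lengths = scaffolds.lengths
    truth.validate()
    return scaffolds, truth


# -- depth simulation -------------------------------------------------------

def simulate_depth(
    truth: TruthTable,
    autosomal_mean: float,
    sex: str = "male",
    noise_cv: float = 0.05,
    window: int = 10_000,
    seed: int = 0,
    platform: str = "hifi",
    dip_factor: float = 1.0,
) -> pd.DataFrame:
    """Window-level depth track for one platform and one sex.

    Nominal depth is ``autosomal_mean`` scaled by scaffold class: the X is at
    0.5x in a male and 1.0x in a female; Y fragments at 0.5x in a male and
    0 in a female; PAR windows on the X stay at 1.0x in both sexes. Windows
    overlapping satellite or rDNA features are scaled by ``dip_factor``
    (mapping-difficulty artifact). Noise is normal with coefficient of
    variation ``noise_cv``, truncated at 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if autosomal_mean <= 0:
        raise ValueError("autosomal_mean must be positive")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    rng = np.random.default_rng(seed)

    par_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    dip_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for f in truth.features:
        if f.feature_class == "par":
            par_by_scaffold.setdefault(f.scaffold, []).append((f.start, f.end))
        elif f.feature_class == "rdna" or f.feature_class.startswith("cen_family_"):
            dip_by_scaffold.setdefault(f.scaffold, []).append((f.start, f.end))

    rows = []
    for name, L in truth.scaffold_lengths.items():
        cls = truth.scaffold_classes.get(name, "unassigned")
        if cls == "X":
            base = 0.5 if sex == "male" else 1.0
        elif cls == "Y":
            base = 0.5 if sex == "male" else 0.0
        else:
            base = 1.0
        starts = np.arange(0, L, window)
        for s in starts:
            e = min(s + window, L)
            factor = base
            for ps, pe in par_by_scaffold.get(name, ()):
                if s < pe and e > ps:
                    factor = 1.0
                    break
            for ds, de in dip_by_scaffold.get(name, ()):
                if s < de and e > ds:
                    factor *= dip_factor
                    break
            nominal = autosomal_mean * factor
            if noise_cv > 0 and nominal > 0:
                val = max(0.0, rng.normal(nominal, noise_cv * nominal))
            else:
                val = nominal
            rows.append((name, int(s), int(e), e - s == window, val))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "full", f"depth_{platform}"]
    )


# -- k-mer histogram and read simulation ------------------------------------

def simulate_kmer_histogram(
    genome_size: int,
    het_fraction: float = 0.01,
    homozygous_depth: float = 63.0,
    k: int = 17,
    read_len: int = 241,
    error_rate: float = 0.001,
    seed: int = 0,
) -> KmerHistogram:
    """Mixture k-mer histogram: error tail near multiplicity 1-2, a
    heterozygous peak at half depth, and a homozygous peak at full depth.

    Distinct-k-mer mass is tied to ``genome_size``; the carried total-base
    and read-length statistics are chosen so the k-mer genome-size formula
    recovers ``genome_size`` at the constructed peak.
    """
    if not (0.0 <= het_fraction <= 1.0):
        raise ValueError("het_fraction must be in [0, 1]")
    if homozygous_depth <= 0:
        raise ValueError("homozygous_depth must be positive")
    if k > read_len:
        raise ValueError("k must not exceed the read length")
    rng = np.random.default_rng(seed)
    cap = max(int(homozygous_depth * 3), 20)
    mult = np.arange(cap + 1)

    def poisson_component(n_loci: int, lam: float) -> np.ndarray:
        if n_loci <= 0:
            return np.zeros(cap + 1, dtype=np.int64)
        logpmf = mult * np.log(lam) - lam - np.array(
            [float(np.sum(np.log(np.arange(1, m + 1)))) for m in mult]
        )
        pmf = np.exp(logpmf)
        pmf /= pmf.sum()
        return rng.multinomial(n_loci, pmf)

    n_het = int(round(het_fraction * genome_size))
    n_hom = genome_size - n_het
    hist = poisson_component(n_hom, homozygous_depth)
    hist += poisson_component(2 * n_het, homozygous_depth / 2.0)
    # error k-mers: geometric tail anchored at multiplicity 1
    n_err = int(round(genome_size * error_rate * 10))
    if n_err > 0:
        p = 0.7
        tail = p * (1 - p) ** (mult[1:] - 1)
        tail /= tail.sum()
        hist[1:] += rng.multinomial(n_err, tail)
    counts = {int(m): int(c) for m, c in zip(mult, hist) if m >= 1 and c > 0}
    total_bases = genome_size * homozygous_depth * read_len / (read_len - k + 1)
    return KmerHistogram(
        k=k, counts=counts, total_bases=total_bases, mean_read_len=float(read_len)
    )


def simulate_reads(
    scaffolds: ScaffoldSet | str,
    depth: float,
    read_len: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[str]:
    """Uniform error-optional reads from the genome (k-mer tests only)."""
    if isinstance(scaffolds, str):
        scaffolds = ScaffoldSet({"seq": scaffolds})
    rng = np.random.default_rng(seed)
    names = list(scaffolds)
    lens = np.array([len(scaffolds[n]) for n in names], dtype=float)
    total = lens.sum()
    n_reads = int(round(total * depth / read_len))
    picks = rng.choice(len(names), size=n_reads, p=lens / total)
    reads = []
    for idx in picks:
        seq = scaffolds[names[idx]]
        if len(seq) <= read_len:
            r = seq
        else:
            s = int(rng.integers(0, len(seq) - read_len + 1))
            r = seq[s : s + read_len]
        if error_rate > 0:
            r = mutate_substitutions(rng, r, error_rate)
        reads.append(r)
    return reads


# -- alignment tables -------------------------------------------------------

def simulate_alignments(truth: TruthTable, seed: int = 0) -> dict:
    """Tabular alignment evidence matching the truth: rDNA subunit hits,
    mitochondrial reference hits, and Y-enriched contig mappings (with a
    low-rate background of stray hits on autosomes)."""
    rng = np.random.default_rng(seed)
    len18, len28 = len(toy_18s()), len(toy_28s())
    ref_lengths = {"18S": len18, "28S": len28, "mito_ref": None}

    rdna_hits: list[AlignmentHit] = []
    for f in truth.features_of("rdna"):
        sub = f.payload["subunit"]
        ref_len = len18 if sub == "18S" else len28
        # each cassette copy covers ~85% of the subunit reference
        q0 = int(ref_len * 0.05)
        q1 = q0 + int(ref_len * 0.85)
        rdna_hits.append(
            AlignmentHit(sub, f.scaffold, q0, q1, f.start, f.end, identity=0.96)
        )

    mito_hits: list[AlignmentHit] = []
    for name, cls in truth.scaffold_classes.items():
        if cls == "mito":
            L = truth.scaffold_lengths[name]
            ref_lengths["mito_ref"] = L
            mito_hits.append(
                AlignmentHit("mito_ref", name, 0, L, 0, max(1, int(L * 0.98)), 0.99)
            )

    y_hits: list[AlignmentHit] = []
    density = 20.0  # hits per Mb on true Y fragments
    for name, cls in truth.scaffold_classes.items():
        L = truth.scaffold_lengths[name]
        if cls == "Y":
            n = max(3, int(round(density * L / 1e6)))
        elif cls in ("macro", "micro") and rng.random() < 0.3:
            n = 1  # stray background hit
        else:
            n = 0
        for j in range(n):
            s = int(rng.integers(0, max(1, L - 5_000)))
            y_hits.append(
                AlignmentHit(f"ycontig_{name}_{j}", name, 0, 5_000, s, s + 5_000, 0.98)
            )
    return {
        "rdna": rdna_hits,
        "mito": mito_hits,
        "y_contigs": y_hits,
        "ref_lengths": ref_lengths,
    }


# -- coding transcripts for ORF-selection tests -----------------------------

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
    and a + b + c != "ATG"
]


def simulate_transcripts(
    n: int = 12,
    aa_len_range: tuple[int, int] = (80, 300),
    utr_len_range: tuple[int, int] = (12, 90),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Coding transcripts with UTRs plus a blastx-style best-hit table.

    Returns (transcripts, proteins, hits) where hits carries 1-based
    outfmt-6-like columns plus the subject (protein) full length ``slen``.
    Half the transcripts are reverse-complemented to exercise minus-strand
    frames; the table's coordinates follow blastx conventions
    (qstart > qend on the minus strand).
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    transcripts: dict[str, str] = {}
    proteins: dict[str, str] = {}
    rows = []
    for i in range(n):
        tid, pid = f"tx{i + 1}", f"prot{i + 1}"
        n_aa = int(rng.integers(*aa_len_range))
        cds_codons = ["ATG"] + [
            _CODONS[j] for j in rng.integers(0, len(_CODONS), size=n_aa - 1)
        ]
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        cds = "".join(cds_codons) + stop
        utr5 = random_sequence(rng, int(rng.integers(*utr_len_range)), 0.5)
        utr3 = random_sequence(rng, int(rng.integers(*utr_len_range)), 0.5)
        # keep UTRs free of in-frame ATG/stop interference by construction:
        # the extractor anchors on the aligned frame, so arbitrary UTRs are fine
        plus = utr5 + cds + utr3
        prot = str(Seq(cds[:-3]).translate())
        proteins[pid] = prot
        # alignment covers protein residues [a0, a1) (0-based)
        a0 = int(rng.integers(2, 8))
        a1 = n_aa - int(rng.integers(2, 8))
        q0 = len(utr5) + 3 * a0  # 0-based transcript coord of aligned start
        q1 = len(utr5) + 3 * a1
        minus = bool(i % 2)
        if minus:
            seq = str(Seq(plus).reverse_complement())
            # blastx: coordinates on the submitted (minus) transcript
            qstart = len(seq) - q0  # 1-based
            qend = len(seq) - q1 + 1
        else:
            seq = plus
            qstart, qend = q0 + 1, q1
        transcripts[tid] = seq
        rows.append(
            dict(
                qseqid=tid,
                sseqid=pid,
                pident=100.0,
                length=a1 - a0,
                mismatch=0,
                gapopen=0,
                qstart=qstart,
                qend=qend,
                sstart=a0 + 1,
                send=a1,
                evalue=1e-50,
                bitscore=200.0 + float(rng.integers(0, 100)),
                slen=len(prot),
            )
        )
    return transcripts, proteins, pd.DataFrame(rows)


# -- truth IO ---------------------------------------------------------------

def write_truth(truth: TruthTable, out_prefix: str | Path) -> tuple[Path, Path]:
    """Emit <prefix>.features.bed (BED6, name = feature class) and
    <prefix>.classes.tsv (scaffold, class, length)."""
    prefix = Path(out_prefix)
    bed = prefix.with_suffix(prefix.suffix + ".features.bed")
    tsv = prefix.with_suffix(prefix.suffix + ".classes.tsv")
    with open(bed, "w") as fh:
        fh.write("#scaffold\tstart\tend\tfeature_class\tscore\tstrand\n")
        for f in truth.features:
            fh.write(f"{f.scaffold}\t{f.start}\t{f.end}\t{f.feature_class}\t0\t.\n")
    with open(tsv, "w") as fh:
        fh.write("scaffold\tclass\tlength\n")
        for name, cls in truth.scaffold_classes.items():
            fh.write(f"{name}\t{cls}\t{truth.scaffold_lengths.get(name, 0)}\n")
    return bed, tsv


def read_truth_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3]))
    return out


def spec_from_json(path: str | Path) -> GenomeSpec:
    with open(path) as fh:
        data = json.load(fh)
    if "cen_monomers" in data:
        data["cen_monomers"] = tuple(tuple(x) for x in data["cen_monomers"])
    if "y_fragment_lens" in data:
        data["y_fragment_lens"] = tuple(data["y_fragment_lens"])
    for key in ("macro_len_range", "micro_len_range"):
        if key in data:
            data[key] = tuple(data[key])
    return GenomeSpec(**data)


def spec_to_json(spec: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=1)
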