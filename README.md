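# asmcurate

Genome-assembly curation at desk scale, for the kind of work that turns a
scaffolded long-read assembly of a non-model vertebrate into a curated,
chromosome-labeled reference: k-mer genome-size estimation, windowed GC and
read-depth profiling, telomere calling with misjoin splitting, centromeric
satellite discovery, sex-chromosome and rDNA scaffold classification,
contiguity statistics, and full-length ORF selection for annotation
training. It is aimed at assembly curators and comparative genomicists who
want these steps as tested, scriptable library calls rather than a pile of
one-off scripts.

Every analysis stage can be exercised without any external data: the
`synth` module generates truth-labeled genomes that emulate a male (XY)
skink-like karyotype — GC-distinct macro- and microchromosomes, an X at
half male depth with a pseudoautosomal region (PAR), fragmented Y
scaffolds, terminal TTAGGG arrays, planted misjoins, two centromeric
satellite families (187 and 199 bp monomers), rDNA and mitochondrial
scaffolds — so recovery of every feature can be checked against
construction truth.

## The core computations

**k-mer genome size.** With total sequenced bases *B*, mean read length
*L*, and k-mer length *k*, each read yields *L − k + 1* k-mers, so the
total k-mer count is *B(L − k + 1)/L*. Dividing by the homozygous k-mer
peak depth *d* of the read histogram gives the genome size

  *G = B(L − k + 1)/(L·d)*.

**Windowed profiles.** GC fraction and read depth in nonoverlapping 10-kb
windows (bedcov semantics: summed per-base depth over window span), the
substrate for all depth-based classification.

**Telomeres and misjoins.** Tandem arrays of the vertebrate motif TTAGGG
(or CCCTAA on the minus strand) spanning >600 bp (>100 copies) are called
and labeled terminal or internal. An internal array near an assembly gap
marks a likely scaffolding misjoin; flagged gaps are split AGP-style into
`<id>.1`, `<id>.2` pieces with non-N bases conserved.

**Centromeric satellites.** Repetitive candidate regions are found by
within-window k-mer multiplicity; the fundamental monomer period maximizes
the shift-match score *S(p)* = fraction of positions *i* with
seq[*i*] = seq[*i + p*]; a per-column majority consensus is built; families
whose arrays span >100 kb in total are flagged as centromeric candidates;
higher-order repeat structure is tested via monomer-lag identities; and
consensus templates re-annotate the genome to monomer-exact boundaries.

**Scaffold classification.** Precedence mito > rDNA > satellite-only >
chromosome-scale (macro/micro/X) > Y > unassigned. The X sits at half the
male autosomal depth; rDNA scaffolds cover >50% of an 18S or 28S subunit
reference; Y scaffolds are found among the leftovers by density of
Y-enriched subtraction contigs; the PAR is the run of male/female
depth-ratio ≈ 1 windows anchored at the X's 5' end.

**ORF selection.** Blastx-style best hits anchor a reading frame that is
extended to the nearest in-frame start and stop; calls with both, at
95–105% of the hit protein length, are full length. Unaligned transcripts
are scanned six-frame for ORFs >50 aa. Amino-acid sets are clustered
greedily (longest first) at 80% identity over ≥90% of the shorter
sequence, CD-HIT style.

## Worked example

```python
from asmcurate import synth, telomeres, satellites, classify, windows, stats
from asmcurate.containers import ScaffoldPlan

spec = synth.GenomeSpec(seed=1)                  # desk-scale XY genome
scaffolds, truth = synth.generate_genome(spec)   # 25 scaffolds, 24.8 Mb

cs = stats.contiguity_stats(scaffolds)
print(cs.n50, cs.l50, cs.n_gaps, cs.n_count)     # 1850219 6 15 3000

calls = telomeres.call_telomeres(scaffolds)      # 30 arrays, 3 internal
plan = ScaffoldPlan.from_scaffolds(scaffolds)
flagged = telomeres.detect_misjoins(calls, plan)
print(flagged)                # [('mac4', 2), ('mac5', 2), ('mac6', 2)]
new_seqs, _ = telomeres.split_at_gaps(scaffolds, plan, flagged)
print(len(new_seqs))          # 28  (three misjoins split)

for fam in satellites.discover_satellite_families(scaffolds):
    print(fam.family_id, fam.period, fam.total_span, fam.centromeric_candidate)
# SAT187 187 184000 True
# SAT199 199 118000 True

gc = windows.gc_windows(scaffolds)
male = synth.simulate_depth(truth, 34.49, "male", 0.05, seed=0)
aln = synth.simulate_alignments(truth, seed=2)
report = classify.classify_assembly(
    scaffolds, gc, male,
    satellite_intervals=[iv for f in satellites.discover_satellite_families(scaffolds)
                         if f.centromeric_candidate for iv in f.arrays],
    rdna_hits=aln["rdna"], rdna_ref_lengths=aln["ref_lengths"],
    mito_hits=aln["mito"], y_hits=aln["y_contigs"])
print(report.classes == truth.scaffold_classes)  # True: 25/25 correct
```

The three flagged gaps are exactly the planted misjoins (an internal
telomere abutting a 200-N gap), both satellite families come back with
their planted monomer periods and >100-kb centromeric flags, and every
scaffold class — including the half-depth X, the three Y fragments and the
two unassigned decoys — is recovered from depth, GC and alignment evidence
alone.

The genome-size estimator on a published skink sequencing summary
(B = 110,612,868,725 bp; L = 241.2 bp; k = 17; d = 63):

```python
from asmcurate import kmers
g = kmers.estimate_genome_size(110_612_868_725, 241.2, 17, 63)
print(kmers.format_genome_size_gb(g))   # 1.64  (Gb, 2 dp)
```

A `click` CLI mirrors the library: `asmcurate synth generate`,
`asmcurate kmer genomesize`, `asmcurate profile windows`,
`asmcurate telo call|split`, `asmcurate satellite`, `asmcurate stats run`,
`asmcurate orf select|cluster`.

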