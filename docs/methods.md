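# Methods

## Scope and design

`asmcurate` re-implements, as a tested library, the computations an
assembly curator runs between "scaffolded assembly" and "curated
reference": size/depth arithmetic, windowed profiles, repeat-feature
calling, evidence-based scaffold classification, contiguity statistics and
annotation-training ORF selection. Heavy upstream steps (contig assembly,
HiC scaffolding, base calling, read mapping, repeat classification, gene
prediction) are out of scope; the package consumes their standard outputs
(FASTA, bedGraph-style depth, tabular alignments, AGP) or synthetic
equivalents.

All coordinates are 0-based half-open (BED convention); AGP files are
converted from/to their native 1-based inclusive form on IO. Reported
percentages and fold-depths round half-up to 2 decimals and lengths to
integers, matching genome-report table style.

## k-mer statistics (`kmers`)

Genome size follows *G = B(L − k + 1)/(L·d)*: *B* total bases, *L* mean
read length, *k* k-mer length, *d* homozygous-peak k-mer depth. Each read
of length *L* contributes *L − k + 1* k-mers, so *B(L − k + 1)/L* is the
total k-mer mass and dividing by the per-locus k-mer depth gives the locus
count. The estimator is homogeneous (doubling *B* doubles *G*; doubling
*d* halves it), which the tests assert.

Peak detection smooths the multiplicity histogram with a 3-bin moving
average, takes plateau-aware local maxima above a noise floor
(multiplicity > 5 by default), and reports the rightmost maximum whose
smoothed height reaches 20% of the tallest mode — the homozygous peak of a
diploid histogram, with the heterozygous mode at half depth to its left.
Within a smoothed plateau the mode is located on the raw counts, ties
toward higher multiplicity. The 20% floor keeps sampling bumps in the
high-multiplicity tail from masquerading as the homozygous mode. A
monotone histogram raises an error rather than returning a fabricated
peak.

k-mer counting is exact and in-memory, canonical by default (lexicographic
minimum of k-mer and reverse complement), intended for toy/desk scale
rather than 100-Gb read sets; k-mers containing non-ACGT characters are
skipped. Completeness is the percent of reliable read k-mers (multiplicity
above a noise cutoff) present in the union of assembly sets. Consensus
quality uses E = 1 − (1 − K_err/K_total)^(1/k), QV = −10·log₁₀E, with
K_err the assembly k-mer mass unsupported by reads; K_err = 0 reports
infinity (capped only in display).

Depth-by-division (total platform bases / reference length) divides by the
*assembly* length: that is the convention under which the published
per-platform depth figures that the tests pin down are mutually
consistent.

## Window profiles (`windows`)

GC fraction is (G+C)/(A+C+G+T) per nonoverlapping window (default 10 kb),
with N excluded from the denominator; an all-N window carries a missing
value, never 0, so gap windows cannot drag medians. Depth uses
bedcov-style semantics — summed per-base depth over window span — making
the result invariant to input chunking. The trailing partial window is
kept and flagged (`full=False`); medians use the lower-median rule.
Whether published window medians excluded partial terminal windows is not
stated anywhere we know of; keeping-but-flagging lets callers choose, and
at 10-kb windows on Mb-scale scaffolds the choice moves medians
negligibly.

## Telomeres and misjoins (`telomeres`)

The scanner finds maximal runs of exact TTAGGG copies per strand, merging
runs separated by ≤50 bp of non-motif sequence when the merged interval
keeps ≥90% motif content — an approximation of alignment-scored tandem
repeat detection sufficient for the canonical motif; degenerate variants
(e.g. TTAGGGG) are deliberately not matched. Copy number counts matched
motif bases only, so interruptions never inflate it.

Calls keep arrays spanning strictly more than 600 bp (i.e. >100 copies).
Placement is terminal within 10 kb of a scaffold end — a configurable
default chosen to sit safely below any plausible feature spacing, since no
standard distance exists. Misjoin detection associates internal telomeres
with gaps within 100 kb ("near" is not standardized either; both defaults
are CLI-exposed). Splitting removes the gap's Ns, names pieces
`<id>.1`, `<id>.2`… in coordinate order, conserves non-N bases, never
emits empty pieces, and rewrites the AGP plan consistently.

## Satellites (`satellites`)

Candidate regions are windows (2 kb) whose fraction of within-window
repeated 12-mers exceeds 0.5, merged when adjacent; the k-mer hash is
exact (base-5 integer, collision-free for k ≤ 26). Period inference
maximizes the shift-match score S(p) over p ≤ 500; maxima within 1%
(relative) of the best are tied and the smallest p wins, which returns the
fundamental period rather than a multiple. Consensus is a per-column
majority over full copies, phase-anchored at the array start — so a
consensus from a region whose start is offset into the array is a rotation
of the true monomer, and family grouping therefore compares consensi under
all cyclic rotations (≥0.7 identity, period within 2 bp).

Monomer-copy identity is Hamming after phase alignment. The synthetic
generator plants substitution-only divergence, so indel-free matching is
exact here; indel-bearing natural arrays would need the banded-alignment
upgrade documented as future work, and this is the main caveat when moving
from synthetic to real satellite DNA.

Centromere candidacy is purely span-based: families whose arrays sum to
strictly more than 100 kb. Higher-order repeat (HOR) structure is scored
as mean identity between monomer copies at lag m (m = 1..8); an HOR of
order m\* is reported when identity(m\*) beats identity(1) by more than
0.05 — the margin is this package's own definition of a reportable HOR,
since the negative finding it generalizes was published without a
statistic. Template-guided re-annotation chains per-copy template matches
(identity ≥0.8, either strand) stepping one period at a time with ±2 bp
jitter tolerance, scanning candidate regions padded by a window plus a
period so chains can reach boundaries the window quantization clipped;
recovered boundaries are exact to within one monomer on planted arrays.

## Classification (`classify`)

Label precedence is total and fixed: mito > rDNA > satellite-only >
chromosome-scale (macro/micro/X) > Y > unassigned; input order can never
change labels. Chromosome-scale means ≥1 Mb. The X band is
depth-ratio 0.4–0.6 against the genome median (the principle is "half the
male autosomal depth"; the band half-width is this package's default,
symmetric so that widening it never un-calls an X). Macro/micro is split
by length rank with the expected macro count, GC acting as a cross-check
only (warnings on conflict, rank wins; microchromosomes run GC-richer).
rDNA requires hit-union coverage strictly >50% of an 18S or 28S subunit
reference. A single mitochondrial scaffold is retained (longest aligned
span among scaffolds ≥90% covered by high-identity mito hits); redundant
copies are flagged. Y calls require subtraction-contig density >5 hits/Mb
among still-unlabeled scaffolds — the published principle is "high
density" without a number, so the threshold is exposed and logged in the
report. Satellite-only means >50% of scaffold length under centromeric
family arrays.

PAR detection compares male and female tracks on a shared window grid
(20 kb recommended): windows with male/female depth ratio in 0.8–1.2 are
PAR-class, 0.35–0.65 X-specific; the PAR is the maximal PAR-class run
anchored at a scaffold end (5' preferred) and the boundary is the last PAR
window's end. Hard ratio bands were chosen over a changepoint model:
simpler, parameter-transparent, and sufficient at the noise levels the
generator emulates.

## Contiguity statistics (`stats`)

Nx/Lx use the standard first-cumulative-sum ≥ x% convention on
descending-sorted lengths (cross-checked against seqkit during
development). Medians are lower-median. A gap is any maximal N-run
(≥1 by default; a `min_gap` knob exists for assemblies that use single Ns
as ambiguity codes). Base composition reports A/C/G/T over ACGT with N
separate, so ACGT+N always accounts for every base.

## ORF selection (`orfs`)

Best hits maximize bitscore, ties by longer protein alignment then
lexicographic protein id (fully deterministic). ORF extraction anchors on
the aligned frame: upstream extension walks codon-by-codon to the nearest
in-frame ATG without crossing a stop; downstream runs to the first
in-frame stop (included in the nucleotide ORF, stripped from the
translation). A stop inside the aligned region demotes the call to
partial with a warning — the upstream tool this mirrors does not document
its behavior, so the conservative choice is made and surfaced. Full-length
requires start, stop, and translated length within 95–105% of the hit
protein, bounds inclusive ("between 95% and 105%" read inclusively; the
boundary behavior is pinned by tests). Unaligned transcripts are scanned
in six frames for first-ATG-to-stop ORFs strictly longer than 50 aa.

Clustering is greedy longest-first at ≥80% identity over ≥90% of the
shorter sequence, with exhaustive Smith-Waterman (match 1, mismatch −1,
gap open −2, extend −0.5) in place of k-mer prescreening — exact and
affordable at desk scale. Identity is identities over alignment columns;
coverage is the aligned span on the shorter sequence.

## Synthetic data (`synth`)

The generator emulates the male (XY) skink-like genome structure the
pipeline targets, at desk scale. Defaults: 6 macrochromosomes
(1.6–2.6 Mb, GC 0.42), 8 microchromosomes (1.0–1.25 Mb, GC 0.445), an X of
1.5 Mb with a 200-kb PAR at its 5' end and one missing telomere, 3 Y
fragments (0.25–0.6 Mb), 2 rDNA scaffolds with tandem 18S/28S-like
cassettes, 2 satellite-only scaffolds (>50% family-0 array), a 17,506-bp
mitochondrial scaffold, 2 unassigned decoys, terminal telomeres of 150
copies (900 bp) everywhere except one microchromosome carrying
boundary-size 100-copy (600 bp) negative controls, 3 planted misjoins
(internal telomere + 200-N gap) plus benign 200-N gaps, and two
centromeric families of 187 bp x 600 and 199 bp x 600 copies (>100 kb
each) at 2% per-copy substitution divergence. Scaffold sizes are scaled
down (~25 Mb total) while structural parameters — counts, GC contrast,
monomer periods, gap convention, half-depth X — mirror the study system;
chromosome-sized scaffolds would add runtime, not information, for these
feature-recovery checks.

Background sequence is i.i.d. at per-scaffold GC targets: planted features
are the only repeat structure, keeping truth unambiguous. This is the key
simplification to remember when extrapolating: real genomes carry
interspersed repeats, segmental duplications and indel-bearing satellite
arrays that make candidate detection noisier and identity-based matching
harder than these tests can show. Passing the suite demonstrates
correctness of the decision rules and coordinate bookkeeping, not
robustness to the full repeat landscape of a real assembly.

Depth is simulated at window level: nominal = autosomal mean x class
factor (X 0.5 male / 1.0 female; Y 0.5 male / 0 female; PAR 1.0 both),
with optional dips over satellite/rDNA windows emulating mapping-difficulty
artifacts, and truncated-normal noise of coefficient of variation 0.05 by
default. The k-mer histogram is a Poisson mixture (error tail at
multiplicity ~1–2 as a geometric, heterozygous component at half depth,
homozygous at full depth) sampled by multinomial draws, with carried B and
L chosen so the genome-size formula is self-consistent at the constructed
peak. A uniform read simulator exists solely for k-mer recovery tests.
The 18S/28S seeds are deterministic synthetic stand-ins (not biological
sequences); alignment tables (rDNA subunit hits, mito hits, Y-contig hits
at 20/Mb with sparse autosomal strays) are derived from truth.

Everything is deterministic under a fixed spec seed, byte-identical across
runs.

## Numerical and degenerate-input conventions

Rounding is half-up (`decimal`), matching printed-table style, not
banker's rounding. Empty inputs raise (`contiguity_stats([])`,
`base_composition("")`, clustering with no sequences) rather than
returning sentinels. An X without autosomes is rejected at generation time
(depth normalization would be undefined). Splitting the same gap twice is
an error; zero requested splits is the identity. Genome-median depth of
zero raises. Test problem sizes (25-Mb genomes, 10-kb toys, 20-seed
replicate loops) keep the full suite around twenty seconds on one core.
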