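"""Scaffold classification: macro/micro/X/Y/rDNA/mito/satellite/unassigned.

Evidence rules follow standard XY curation practice: the X sits at half the
male autosomal depth (a female XX carries it at full depth); Y scaffolds
are found by elimination plus density of Y-enriched subtraction contigs;
rDNA scaffolds are those whose hits cover more than half of an 18S or 28S
subunit reference; a single mitochondrial sequence is retained; the
macro/micro split is by length rank with GC as a cross-check
(microchromosomes run GC-richer). Label precedence is total:

    mito > rDNA > satellite-only > chromosome-scale (macro/micro/X) > Y > unassigned

so reordering input scaffolds never changes labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlignmentHit, RepeatInterval, ScaffoldSet
from .windows import median_window_stat

__all__ = [
    "ClassificationReport",
    "classify_size_gc",
    "identify_x",
    "identify_rdna",
    "identify_mito",
    "identify_y",
    "detect_par",
    "assign_chromosome_names",
    "classify_assembly",
]


@dataclass
class ClassificationReport:
    table: pd.DataFrame  # scaffold, class, length, evidence columns
    par_interval: tuple[int, int] | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["scaffold"], self.table["class"]))


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def classify_size_gc(
    stats: pd.DataFrame,
    n_macro_expected: int,
    gc_threshold: float = 0.43,
) -> tuple[dict[str, str], list[str]]:
    """Split chromosome-scale scaffolds into macro and micro by length rank.

    ``stats`` needs columns scaffold, length, median_gc. The
    ``n_macro_expected`` longest scaffolds are macro, the rest micro; a
    scaffold whose GC contradicts its rank (macro with micro-like GC or
    vice versa) is flagged with a warning, but rank wins.
    """
    if len(stats) < n_macro_expected:
        raise ValueError("fewer scaffolds than n_macro_expected")
    ordered = stats.sort_values("length", ascending=False, kind="mergesort")
    labels: dict[str, str] = {}
    warns: list[str] = []
    for rank, row in enumerate(ordered.itertuples(index=False)):
        label = "macro" if rank < n_macro_expected else "micro"
        labels[row.scaffold] = label
        gc = getattr(row, "median_gc", None)
        if gc is not None and not np.isnan(gc):
            if label == "macro" and gc >= gc_threshold:
                warns.append(f"{row.scaffold}: macro by rank but micro-like GC {gc:.3f}")
            elif label == "micro" and gc < gc_threshold:
                warns.append(f"{row.scaffold}: micro by rank but macro-like GC {gc:.3f}")
    return labels, warns


def _depth_cols(track: pd.DataFrame) -> list[str]:
    return [c for c in track.columns if c.startswith("depth_")]


def _scaffold_depth_ratios(
    track: pd.DataFrame, genome_median: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-scaffold median window depth and ratio to the genome median."""
    cols = _depth_cols(track)
    if not cols:
        raise ValueError("track carries no depth_* columns")
    med = track.groupby("scaffold")[cols].median()
    if genome_median is None:
        genome_median = {c: float(track[c].median()) for c in cols}
    for c in cols:
        if genome_median[c] == 0:
            raise ValueError("genome median depth is zero")
        med[f"ratio_{c[6:]}"] = med[c] / genome_median[c]
    return med.reset_index(), genome_median


def identify_x(
    track: pd.DataFrame,
    candidates: list[str] | None = None,
    genome_median: dict[str, float] | None = None,
    band: tuple[float, float] = (0.4, 0.6),
) -> list[str]:
    """Scaffolds at half depth on every available platform (male data).

    A scaffold is X-like when its median-window depth divided by the genome
    median falls inside ``band`` for each depth column in the track.
    """
    med, _ = _scaffold_depth_ratios(track, genome_median)
    ratio_cols = [c for c in med.columns if c.startswith("ratio_")]
    out = []
    for row in med.itertuples(index=False):
        if candidates is not None and row.scaffold not in candidates:
            continue
        ratios = [getattr(row, c) for c in ratio_cols]
        if all(band[0] <= r <= band[1] for r in ratios):
            out.append(row.scaffold)
    return out


def identify_rdna(
    hits: list[AlignmentHit],
    ref_lengths: dict[str, int],
    min_cov: float = 0.5,
) -> dict[str, float]:
    """Scaffolds whose hits cover > min_cov of an 18S or 28S reference.

    Coverage is the union of hit intervals on the reference, per (scaffold,
    reference) pair; the comparison is strict (exactly 50% does not
    qualify). Returns scaffold -> best subunit coverage fraction.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        by_pair.setdefault((h.target, h.query), []).append((h.qstart, h.qend))
    out: dict[str, float] = {}
    for (scaf, ref), ivs in by_pair.items():
        if ref not in ref_lengths:
            continue
        cov = _union_len(ivs) / ref_lengths[ref]
        if cov > min_cov:
            out[scaf] = max(out.get(scaf, 0.0), cov)
    return out


def identify_mito(
    hits: list[AlignmentHit],
    scaffold_lengths: dict[str, int],
    min_identity: float = 0.9,
    min_self_cov: float = 0.9,
) -> tuple[str | None, list[str]]:
    """Retain one mitochondrial scaffold; flag redundant copies for removal.

    Candidates are scaffolds whose high-identity mito-reference hits cover
    at least ``min_self_cov`` of the scaffold's own length; the one with
    the longest aligned span is retained, the rest flagged.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.identity >= min_identity:
            spans.setdefault(h.target, []).append((h.tstart, h.tend))
    candidates = []
    for scaf, ivs in spans.items():
        aligned = _union_len(ivs)
        if scaf in scaffold_lengths and aligned / scaffold_lengths[scaf] >= min_self_cov:
            candidates.append((aligned, scaf))
    if not candidates:
        return None, []
    candidates.sort(reverse=True)
    retained = candidates[0][1]
    flagged = [s for _, s in candidates[1:]]
    return retained, flagged


def identify_y(
    scaffold_lengths: dict[str, int],
    prior_labels: dict[str, str],
    y_hits: list[AlignmentHit],
    min_density: float = 5.0,
) -> dict[str, float]:
    """Y calls among still-unlabeled scaffolds by subtraction-contig density.

    Density is mapped Y-contig hits per Mb of scaffold; scaffolds already
    labeled (rDNA, mito, chromosome-scale, satellite) are never relabeled.
    Returns scaffold -> density for the scaffolds called Y.
    """
    n_hits: dict[str, int] = {}
    for h in y_hits:
        n_hits[h.target] = n_hits.get(h.target, 0) + 1
    out: dict[str, float] = {}
    for scaf, L in scaffold_lengths.items():
        if prior_labels.get(scaf) is not None:
            continue
        density = n_hits.get(scaf, 0) / (L / 1e6)
        if density > min_density:
            out[scaf] = density
    return out


def detect_par(
    male_track: pd.DataFrame,
    female_track: pd.DataFrame,
    x_scaffold: str,
    par_band: tuple[float, float] = (0.8, 1.2),
    x_band: tuple[float, float] = (0.35, 0.65),
) -> tuple[int, int] | None:
    """PAR on the X from male/female window-depth ratios.

    Both tracks must share the window grid on ``x_scaffold``. Windows are
    classed by male/female depth ratio (PAR near 1, X-specific near 0.5);
    the PAR is the maximal run of PAR-class windows anchored at a scaffold
    end (5' end preferred) and the boundary is the last PAR window's end.
    """
    m = male_track[male_track["scaffold"] == x_scaffold].sort_values("start")
    f = female_track[female_track["scaffold"] == x_scaffold].sort_values("start")
    if len(m) == 0 or len(f) == 0:
        raise ValueError(f"tracks do not cover {x_scaffold!r}")
    if not (
        len(m) == len(f)
        and (m["start"].values == f["start"].values).all()
        and (m["end"].values == f["end"].values).all()
    ):
        raise ValueError("male and female tracks use different window grids")
    mcol, fcol = _depth_cols(m)[0], _depth_cols(f)[0]
    male = m[mcol].values.astype(float)
    female = f[fcol].values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(female > 0, male / np.maximum(female, 1e-12), np.inf)
    is_par = (ratio >= par_band[0]) & (ratio <= par_band[1])
    starts, ends = m["start"].values, m["end"].values
    # run anchored at the 5' end
    if is_par[0]:
        i = 0
        while i + 1 < len(is_par) and is_par[i + 1]:
            i += 1
        return int(starts[0]), int(ends[i])
    if is_par[-1]:
        i = len(is_par) - 1
        while i - 1 >= 0 and is_par[i - 1]:
            i -= 1
        return int(starts[i]), int(ends[-1])
    return None


def assign_chromosome_names(
    report: ClassificationReport, prefix: str = "ASM"
) -> dict[str, str]:
    """Notional chromosome names by decreasing length.

    Macro scaffolds take ranks 1..n, micro continue the numbering, the X
    and Y are named explicitly. Output format <prefix>scf<rank>; a split
    suffix (``.2``) on the input id is preserved. Length ties keep input
    order and log a warning.
    """
    t = report.table
    names: dict[str, str] = {}
    autosomes = t[t["class"].isin(["macro", "micro"])]
    ordered = autosomes.sort_values(
        "length", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    dupes = ordered["length"].duplicated(keep=False)
    if dupes.any():
        warnings.warn("duplicate scaffold lengths: rank ties broken by input order")
    for rank, row in enumerate(ordered.itertuples(index=False), start=1):
        base, dot, suffix = row.scaffold.rpartition(".")
        keep = dot and suffix.isdigit()
        names[row.scaffold] = f"{prefix}scf{rank}" + (f".{suffix}" if keep else "")
    n_x = n_y = 0
    for scaf, cls in zip(t["scaffold"], t["class"]):
        if cls == "X":
            n_x += 1
            names[scaf] = f"{prefix}scfX" + (f"_{n_x}" if n_x > 1 else "")
        elif cls == "Y":
            n_y += 1
            names[scaf] = f"{prefix}scfY_{n_y}"
    return names


def classify_assembly(
    scaffolds: ScaffoldSet,
    gc_track: pd.DataFrame,
    depth_track: pd.DataFrame,
    satellite_intervals: list[RepeatInterval] | None = None,
    rdna_hits: list[AlignmentHit] | None = None,
    rdna_ref_lengths: dict[str, int] | None = None,
    mito_hits: list[AlignmentHit] | None = None,
    y_hits: list[AlignmentHit] | None = None,
    n_macro_expected: int = 6,
    chromosome_scale: int = 1_000_000,
    x_band: tuple[float, float] = (0.4, 0.6),
    autosome_band: tuple[float, float] = (0.8, 1.2),
    y_min_density: float = 5.0,
    sat_only_cov: float = 0.5,
    gc_threshold: float = 0.43,
    female_track: pd.DataFrame | None = None,
) -> ClassificationReport:
    """Full evidence-driven classification of a male assembly.

    Applies the documented precedence: mitochondrial and rDNA labels first,
    then satellite-only scaffolds (> ``sat_only_cov`` of length in satellite
    arrays), then chromosome-scale scaffolds (>= ``chromosome_scale`` bp):
    X at half depth, autosomal-depth scaffolds split macro/micro by rank;
    everything left is screened for Y by subtraction-contig density. If a
    female depth track is supplied, the PAR is located on the first X.
    """
    lengths = scaffolds.lengths
    labels: dict[str, str | None] = {s: None for s in lengths}
    warns: list[str] = []

    retained_mito, flagged_mito = (
        identify_mito(mito_hits, lengths) if mito_hits else (None, [])
    )
    if retained_mito:
        labels[retained_mito] = "mito"
    for s in flagged_mito:
        labels[s] = "mito_duplicate"
        warns.append(f"{s}: redundant mitochondrial copy flagged for removal")

    rdna_cov = (
        identify_rdna(rdna_hits, rdna_ref_lengths) if rdna_hits and rdna_ref_lengths else {}
    )
    for s in rdna_cov:
        if labels[s] is None:
            labels[s] = "rDNA"

    sat_cov: dict[str, float] = {}
    if satellite_intervals:
        by_scaf: dict[str, list[tuple[int, int]]] = {}
        for iv in satellite_intervals:
            by_scaf.setdefault(iv.scaffold, []).append((iv.start, iv.end))
        for s, ivs in by_scaf.items():
            if s in lengths:
                sat_cov[s] = _union_len(ivs) / lengths[s]
        for s, cov in sat_cov.items():
            if cov > sat_only_cov and labels[s] is None:
                labels[s] = "satellite"

    med, genome_median = _scaffold_depth_ratios(depth_track)
    ratio_cols = [c for c in med.columns if c.startswith("ratio_")]
    ratios = {
        row.scaffold: [getattr(row, c) for c in ratio_cols]
        for row in med.itertuples(index=False)
    }

    chrom_scale = [
        s for s in lengths if lengths[s] >= chromosome_scale and labels[s] is None
    ]
    x_calls = [
        s
        for s in chrom_scale
        if all(x_band[0] <= r <= x_band[1] for r in ratios.get(s, []))
    ]
    for s in x_calls:
        labels[s] = "X"
    autosomal = [
        s
        for s in chrom_scale
        if s not in x_calls
        and all(autosome_band[0] <= r <= autosome_band[1] for r in ratios.get(s, []))
    ]
    gc_med = {
        s: median_window_stat(gc_track, s, "gc") for s in autosomal
    }
    if autosomal:
        stats = pd.DataFrame(
            {
                "scaffold": autosomal,
                "length": [lengths[s] for s in autosomal],
                "median_gc": [gc_med[s] for s in autosomal],
            }
        )
        size_labels, size_warns = classify_size_gc(stats, n_macro_expected, gc_threshold)
        warns.extend(size_warns)
        for s, lab in size_labels.items():
            labels[s] = lab

    y_density = identify_y(lengths, labels, y_hits or [], y_min_density)
    for s in y_density:
        labels[s] = "Y"

    rows = []
    for s in lengths:
        rows.append(
            {
                "scaffold": s,
                "class": labels[s] or "unassigned",
                "length": lengths[s],
                "median_gc": median_window_stat(gc_track, s, "gc")
                if (gc_track["scaffold"] == s).any()
                else np.nan,
                **{
                    f"depth_ratio_{c[6:]}": ratios.get(s, [np.nan] * len(ratio_cols))[i]
                    for i, c in enumerate(ratio_cols)
                },
                "y_density": y_density.get(s, np.nan),
                "rdna_cov": rdna_cov.get(s, np.nan),
                "sat_cov": sat_cov.get(s, np.nan),
            }
        )
    table = pd.DataFrame(rows)
    report = ClassificationReport(table=table, warnings=warns)
    if female_track is not None and x_calls:
        report.par_interval = detect_par(depth_track, female_track, x_calls[0])
    return report
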