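"""Scaffold classification rules, precedence, PAR detection, naming."""

import numpy as np
import pandas as pd
import pytest

from asmcurate import classify as CL
from asmcurate import synth
from asmcurate.containers import AlignmentHit


def _stats(lengths, gcs):
    return pd.DataFrame(
        {
            "scaffold": [f"s{i}" for i in range(len(lengths))],
            "length": lengths,
            "median_gc": gcs,
        }
    )


class TestSizeGc:
    def test_rank_split_without_warnings(self):
        stats = _stats([300, 280, 260, 240, 220, 200, 90, 80, 70, 60, 50, 40, 30, 20],
                       [0.42] * 6 + [0.45] * 8)
        labels, warns = CL.classify_size_gc(stats, 6)
        assert sum(v == "macro" for v in labels.values()) == 6
        assert sum(v == "micro" for v in labels.values()) == 8
        assert warns == []

    def test_gc_conflict_warns_but_rank_wins(self):
        stats = _stats([300, 200, 100], [0.465, 0.42, 0.45])
        labels, warns = CL.classify_size_gc(stats, 2)
        assert labels["s0"] == "macro"  # rank wins despite micro-like GC
        assert any("s0" in w for w in warns)

    def test_too_few_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            CL.classify_size_gc(_stats([100], [0.42]), 6)


class TestIdentifyX:
    @staticmethod
    def _track(scaffold_depths, n_windows=40):
        rows = []
        for scaf, depth in scaffold_depths.items():
            for i in range(n_windows):
                rows.append((scaf, i * 10_000, (i + 1) * 10_000, True, depth))
        return pd.DataFrame(
            rows, columns=["scaffold", "start", "end", "full", "depth_hifi"]
        )

    def test_half_depth_scaffold_called(self):
        track = self._track({"a": 34.49, "b": 34.49, "c": 34.49, "x": 17.5})
        assert CL.identify_x(track) == ["x"]

    def test_full_depth_not_called(self):
        track = self._track({"a": 34.0, "b": 34.0, "c": 35.0})
        assert CL.identify_x(track) == []

    def test_zero_genome_median_rejected(self):
        track = self._track({"a": 0.0})
        with pytest.raises(ValueError, match="zero"):
            CL.identify_x(track)


class TestIdentifyRdna:
    def test_sixty_percent_coverage_qualifies(self):
        hits = [AlignmentHit("18S", "s", 0, 1_080, 0, 1_080)]
        assert "s" in CL.identify_rdna(hits, {"18S": 1_800})

    def test_forty_percent_fails(self):
        hits = [AlignmentHit("18S", "s", 0, 720, 0, 720)]
        assert CL.identify_rdna(hits, {"18S": 1_800}) == {}

    def test_exactly_half_union_fails_strict_rule(self):
        # 30% + 30% with 10% overlap -> union exactly 50%
        hits = [
            AlignmentHit("18S", "s", 0, 540, 0, 540),
            AlignmentHit("18S", "s", 360, 900, 600, 1_140),
        ]
        assert CL.identify_rdna(hits, {"18S": 1_800}) == {}


class TestIdentifyMito:
    def test_single_full_length_scaffold_retained(self):
        hits = [AlignmentHit("mito_ref", "m", 0, 17_000, 0, 17_200, 0.99)]
        retained, flagged = CL.identify_mito(hits, {"m": 17_506})
        assert retained == "m" and flagged == []

    def test_truncated_copy_flagged(self):
        hits = [
            AlignmentHit("mito_ref", "full", 0, 17_000, 0, 17_200, 0.99),
            AlignmentHit("mito_ref", "trunc", 0, 9_000, 0, 9_000, 0.99),
        ]
        retained, flagged = CL.identify_mito(hits, {"full": 17_506, "trunc": 9_100})
        assert retained == "full" and flagged == ["trunc"]

    def test_no_hits_no_label(self):
        assert CL.identify_mito([], {"s": 100}) == (None, [])


class TestIdentifyY:
    @staticmethod
    def _hits(scaffold, n):
        return [
            AlignmentHit(f"yc{i}", scaffold, 0, 5_000, i * 10, i * 10 + 5_000)
            for i in range(n)
        ]

    def test_high_density_unplaced_scaffold_called(self):
        y = CL.identify_y({"s": 2_000_000}, {"s": None}, self._hits("s", 40))
        assert y == {"s": 20.0}

    def test_prior_label_respected(self):
        y = CL.identify_y({"s": 2_000_000}, {"s": "rDNA"}, self._hits("s", 40))
        assert y == {}

    def test_low_density_not_called(self):
        y = CL.identify_y({"s": 2_000_000}, {"s": None}, self._hits("s", 4))
        assert y == {}


class TestDetectPar:
    @staticmethod
    def _tracks(male_ratios, window=20_000):
        rows_m, rows_f = [], []
        for i, r in enumerate(male_ratios):
            s, e = i * window, (i + 1) * window
            rows_m.append(("x", s, e, True, 34.49 * r))
            rows_f.append(("x", s, e, True, 34.49))
        cols_m = ["scaffold", "start", "end", "full", "depth_hifi"]
        return pd.DataFrame(rows_m, columns=cols_m), pd.DataFrame(
            rows_f, columns=cols_m
        )

    def test_par_run_at_five_prime(self):
        male, female = self._tracks([1.0] * 50 + [0.5] * 50)
        assert CL.detect_par(male, female, "x") == (0, 50 * 20_000)

    def test_no_par_when_half_everywhere(self):
        male, female = self._tracks([0.5] * 60)
        assert CL.detect_par(male, female, "x") is None

    def test_grid_mismatch_rejected(self):
        male, female = self._tracks([1.0] * 10)
        shifted = female.copy()
        shifted["start"] += 1
        with pytest.raises(ValueError, match="grids"):
            CL.detect_par(male, shifted, "x")

    def test_missing_scaffold_rejected(self):
        male, female = self._tracks([1.0] * 10)
        with pytest.raises(ValueError, match="cover"):
            CL.detect_par(male, female, "ghost")

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_par_boundary_within_two_windows(self, genome, seed):
        spec, _, truth = genome
        window = 20_000
        male = synth.simulate_depth(
            truth, 34.49, "male", 0.05, window, seed=seed, platform="hifi"
        )
        female = synth.simulate_depth(
            truth, 34.49, "female", 0.05, window, seed=1_000 + seed, platform="hifi"
        )
        par = CL.detect_par(male, female, "chrX")
        assert par is not None
        assert par[0] == 0
        assert abs(par[1] - spec.par_len) <= 2 * window


class TestAssignNames:
    @staticmethod
    def _report(rows):
        return CL.ClassificationReport(
            table=pd.DataFrame(rows, columns=["scaffold", "class", "length"])
        )

    def test_rank_by_decreasing_length(self):
        rep = self._report(
            [("b", "macro", 200), ("a", "macro", 300), ("c", "micro", 100)]
        )
        names = CL.assign_chromosome_names(rep, prefix="T")
        assert names == {"a": "Tscf1", "b": "Tscf2", "c": "Tscf3"}

    def test_x_and_y_named_explicitly(self):
        rep = self._report(
            [("a", "macro", 300), ("x", "X", 250), ("y1", "Y", 50), ("y2", "Y", 40)]
        )
        names = CL.assign_chromosome_names(rep, prefix="T")
        assert names["x"] == "TscfX"
        assert names["y1"] == "TscfY_1" and names["y2"] == "TscfY_2"
        assert names["a"] == "Tscf1"  # X excluded from autosome numbering

    def test_split_suffix_preserved(self):
        rep = self._report([("a.2", "macro", 300), ("b", "macro", 200)])
        names = CL.assign_chromosome_names(rep, prefix="T")
        assert names["a.2"] == "Tscf1.2"

    def test_stable_under_permutation(self):
        rows = [("a", "macro", 300), ("b", "macro", 200), ("c", "micro", 100)]
        n1 = CL.assign_chromosome_names(self._report(rows))
        n2 = CL.assign_chromosome_names(self._report(rows[::-1]))
        assert n1 == n2


@pytest.fixture(scope="module")
def inputs(genome, gc_track, satellite_families, alignments):
    _, scaffolds, truth = genome
    sat_ivs = [
        iv
        for fam in satellite_families
        if fam.centromeric_candidate
        for iv in fam.arrays
    ]
    return scaffolds, truth, gc_track, sat_ivs, alignments


class TestEndToEnd:
    @pytest.mark.parametrize("seed", range(20))
    def test_full_truth_recovery_across_noise_seeds(self, inputs, seed):
        scaffolds, truth, gc_track, sat_ivs, aln = inputs
        male = synth.simulate_depth(truth, 34.49, "male", 0.05, seed=seed)
        report = CL.classify_assembly(
            scaffolds,
            gc_track,
            male,
            satellite_intervals=sat_ivs,
            rdna_hits=aln["rdna"],
            rdna_ref_lengths=aln["ref_lengths"],
            mito_hits=aln["mito"],
            y_hits=aln["y_contigs"],
        )
        assert report.classes == truth.scaffold_classes

    def test_input_order_does_not_change_labels(self, inputs):
        scaffolds, truth, gc_track, sat_ivs, aln = inputs
        male = synth.simulate_depth(truth, 34.49, "male", 0.05, seed=0)
        kwargs = dict(
            satellite_intervals=sat_ivs,
            rdna_hits=aln["rdna"],
            rdna_ref_lengths=aln["ref_lengths"],
            mito_hits=aln["mito"],
            y_hits=aln["y_contigs"],
        )
        rep1 = CL.classify_assembly(scaffolds, gc_track, male, **kwargs)
        reordered = type(scaffolds)(dict(reversed(list(scaffolds.items()))))
        rep2 = CL.classify_assembly(reordered, gc_track, male, **kwargs)
        assert rep1.classes == rep2.classes

    def test_widening_x_band_keeps_x_calls(self, inputs):
        scaffolds, truth, gc_track, sat_ivs, aln = inputs
        male = synth.simulate_depth(truth, 34.49, "male", 0.05, seed=1)
        narrow = CL.identify_x(male)
        wide = CL.identify_x(male, band=(0.3, 0.7))
        assert set(narrow) <= set(wide)

    def test_par_located_with_female_track(self, inputs):
        scaffolds, truth, gc_track, sat_ivs, aln = inputs
        male = synth.simulate_depth(truth, 34.49, "male", 0.05, seed=2)
        female = synth.simulate_depth(truth, 34.49, "female", 0.05, seed=3)
        report = CL.classify_assembly(
            scaffolds,
            gc_track,
            male,
            satellite_intervals=sat_ivs,
            rdna_hits=aln["rdna"],
            rdna_ref_lengths=aln["ref_lengths"],
            mito_hits=aln["mito"],
            y_hits=aln["y_contigs"],
            female_track=female,
        )
        assert report.par_interval is not None
        assert report.par_interval[0] == 0
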