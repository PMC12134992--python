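"""Satellite discovery: periods, consensus, centromere flags, HOR, templates."""

import numpy as np
import pytest

from asmcurate import satellites as S
from asmcurate.containers import RepeatInterval, ScaffoldSet
from asmcurate.util import mutate_substitutions, random_sequence


def _array(period, copies, divergence=0.0, seed=0, gc=0.36):
    rng = np.random.default_rng(seed)
    mono = random_sequence(rng, period, gc)
    return mono, "".join(
        mutate_substitutions(rng, mono, divergence) for _ in range(copies)
    )


class TestDetectRepetitiveWindows:
    def test_random_sequence_has_no_candidates(self):
        rng = np.random.default_rng(0)
        assert S.detect_repetitive_windows(random_sequence(rng, 10_000)) == []

    def test_perfect_array_fully_flagged(self):
        _, arr = _array(187, 100)
        regions = S.detect_repetitive_windows(arr)
        assert len(regions) == 1
        assert regions[0] == (0, len(arr))

    def test_matches_kmer_multiplicity_oracle(self):
        rng = np.random.default_rng(1)
        _, arr = _array(187, 40, seed=2)
        seq = random_sequence(rng, 6_000) + arr + random_sequence(rng, 6_000)
        k, window = 12, 2_000
        regions = S.detect_repetitive_windows(seq, k=k, window=window)
        flagged = set()
        for s, e in regions:
            flagged.update(range(s, e, window))
        for ws in range(0, len(seq), window):
            sub = seq[ws : ws + window]
            if len(sub) < k + 1:
                continue
            counts = {}
            for i in range(len(sub) - k + 1):
                counts[sub[i : i + k]] = counts.get(sub[i : i + k], 0) + 1
            repeated = sum(c for c in counts.values() if c >= 2)
            expect = repeated / (len(sub) - k + 1) > 0.5
            assert (ws in flagged) == expect

    def test_k_must_be_below_window(self):
        with pytest.raises(ValueError):
            S.detect_repetitive_windows("ACGT" * 100, k=50, window=40)


class TestInferMonomerPeriod:
    @pytest.mark.parametrize("period", [187, 199])
    def test_perfect_array_fundamental_period(self, period):
        _, arr = _array(period, 600)
        assert S.infer_monomer_period(arr) == period  # not 2x the period

    @pytest.mark.parametrize("period", [187, 199])
    @pytest.mark.parametrize("seed", range(20))
    def test_mutated_arrays_across_seeds(self, period, seed):
        _, arr = _array(period, 600, divergence=0.02, seed=seed + 1000 * period)
        assert S.infer_monomer_period(arr) == period

    def test_agrees_with_bruteforce_shift_scores(self):
        _, arr = _array(151, 30, divergence=0.02, seed=9)
        scores = np.zeros(501)
        for p in range(1, 501):
            matches = sum(a == b for a, b in zip(arr, arr[p:]))
            scores[p] = matches / (len(arr) - p)
        best = scores.max()
        tied = [p for p in range(1, 501) if scores[p] >= best * 0.99]
        assert S.infer_monomer_period(arr) == min(tied)

    def test_random_sequence_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="periodic"):
            S.infer_monomer_period(random_sequence(rng, 5_000))

    def test_short_array_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            S.infer_monomer_period("ACGT" * 100, max_period=500)


class TestConsensusMonomer:
    def test_perfect_array(self):
        mono, arr = _array(187, 10)
        assert S.build_consensus_monomer(arr, 187) == mono

    def test_mutated_array_majority_wins(self):
        mono, arr = _array(187, 600, divergence=0.02, seed=3)
        assert S.build_consensus_monomer(arr, 187) == mono

    def test_consensus_length_is_period(self):
        _, arr = _array(100, 5, seed=6)
        assert len(S.build_consensus_monomer(arr, 100)) == 100

    def test_too_few_copies_rejected(self):
        with pytest.raises(ValueError, match="3 full"):
            S.build_consensus_monomer("ACGT" * 50, 100)


class TestClassifyCentromeric:
    @staticmethod
    def _family(span):
        iv = RepeatInterval("s", 0, span, "SAT187", "SAT187", span / 187)
        return S.SatelliteFamily("SAT187", 187, "A" * 187, arrays=[iv])

    def test_above_threshold_flagged(self):
        (fam,) = S.classify_centromeric([self._family(112_200)])
        assert fam.centromeric_candidate

    def test_at_threshold_not_flagged(self):
        (fam,) = S.classify_centromeric([self._family(99_999)])
        assert not fam.centromeric_candidate
        (fam,) = S.classify_centromeric([self._family(100_000)])
        assert not fam.centromeric_candidate  # strictly greater than

    def test_planted_families_flagged_no_others(self, satellite_families):
        flagged = {f.period for f in satellite_families if f.centromeric_candidate}
        assert flagged == {187, 199}


class TestDetectHor:
    def test_uniform_array_reports_none(self):
        _, arr = _array(187, 40)
        assert S.detect_hor(arr, 187).order is None

    def test_dimeric_alternation_reports_order_two(self):
        rng = np.random.default_rng(8)
        a = random_sequence(rng, 187, 0.36)
        b = mutate_substitutions(rng, a, 0.10)
        rep = S.detect_hor((a + b) * 40, 187)
        assert rep.order == 2
        assert rep.identities[2] > rep.identities[1] + 0.05

    @pytest.mark.parametrize("seed", range(20))
    def test_randomly_mutated_array_reports_none(self, seed):
        _, arr = _array(187, 40, divergence=0.02, seed=seed)
        assert S.detect_hor(arr, 187).order is None

    def test_identity_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        a = random_sequence(rng, 150, 0.4)
        b = mutate_substitutions(rng, a, 0.08)
        arr = (a + b) * 20
        rep = S.detect_hor(arr, 150, max_order=4)
        copies = [arr[i * 150 : (i + 1) * 150] for i in range(len(arr) // 150)]
        for m in range(1, 5):
            pairs = [
                sum(x == y for x, y in zip(copies[i], copies[i + m])) / 150
                for i in range(len(copies) - m)
            ]
            assert rep.identities[m] == pytest.approx(float(np.mean(pairs)))

    def test_short_array_rejected(self):
        with pytest.raises(ValueError):
            S.detect_hor("ACGT" * 100, 100, max_order=8)


class TestRefineWithTemplates:
    def test_empty_templates_rejected(self, genome):
        _, scaffolds, _ = genome
        with pytest.raises(ValueError, match="non-empty"):
            S.refine_with_templates(scaffolds, {})

    def test_planted_arrays_recovered_within_one_period(self, genome):
        _, scaffolds, truth = genome
        calls = S.refine_with_templates(scaffolds, truth.planted_monomers)
        for f in truth.features:
            if not f.feature_class.startswith("cen_family_"):
                continue
            p = f.payload["period"]
            match = [
                iv
                for iv in calls
                if iv.scaffold == f.scaffold
                and iv.repeat_class == f.feature_class
                and abs(iv.start - f.start) <= p
                and abs(iv.end - f.end) <= p
            ]
            assert len(match) == 1, f

    def test_only_matching_family_reported(self):
        mono, arr = _array(187, 600, divergence=0.02, seed=13)
        rng = np.random.default_rng(14)
        other = random_sequence(rng, 199, 0.36)
        scaf = ScaffoldSet(
            {"s": random_sequence(rng, 5_000) + arr + random_sequence(rng, 5_000)}
        )
        calls = S.refine_with_templates(scaf, {"fam187": mono, "fam199": other})
        assert calls and all(iv.repeat_class == "fam187" for iv in calls)


class TestDiscovery:
    def test_both_planted_families_found(self, genome, satellite_families):
        _, _, truth = genome
        by_period = {f.period: f for f in satellite_families}
        assert set(by_period) >= {187, 199}
        for fam_name, mono in truth.planted_monomers.items():
            period = len(mono)
            fam = by_period[period]
            assert S._cyclic_identity(fam.consensus, mono) > 0.95

    def test_template_refinement_covers_de_novo_calls(self, genome, satellite_families):
        _, scaffolds, truth = genome
        refined = S.refine_with_templates(scaffolds, truth.planted_monomers)
        spans = {}
        for iv in refined:
            spans[iv.scaffold] = spans.get(iv.scaffold, 0) + iv.span
        for fam in satellite_families:
            if not fam.centromeric_candidate:
                continue
            for iv in fam.arrays:
                # every de novo array sits inside a refined call's scaffold span
                assert spans.get(iv.scaffold, 0) >= 0.9 * iv.span
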