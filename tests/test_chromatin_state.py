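from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from bivalscan.chromatin_state import (
    ConsensusClass,
    SampleState,
    StateMatrix,
    build_state_matrix,
    call_sample_state,
    collapse_to_gene,
    consensus_classify,
    consensus_threshold,
    detection_curve,
    mark_colocation_fraction,
    sample_qc,
    top_signal_overlap,
)
from bivalscan.genomic_io import (
    GenomicInterval,
    PeakSet,
    TssRecord,
    promoter_window,
)
from bivalscan import synthetic_data as sd


def random_matrix(rng, n_promoters, n_samples):
    return StateMatrix(
        promoter_ids=[f"p{i}" for i in range(n_promoters)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        states=rng.integers(0, 4, size=(n_promoters, n_samples)),
    )


class TestCallSampleState:
    @pytest.mark.parametrize(
        "k4,k27,expected",
        [
            (True, True, SampleState.BIVALENT),
            (True, False, SampleState.ACTIVE),
            (False, True, SampleState.REPRESSED),
            (False, False, SampleState.LATENT),
        ],
    )
    def test_truth_table(self, k4, k27, expected):
        assert call_sample_state(k4, k27) == expected


class TestConsensusThreshold:
    def test_printed_cutoffs(self):
        assert consensus_threshold(11) == 8
        assert consensus_threshold(8) == 6

    def test_strict_inequality_at_exact_fraction(self):
        # 7/10 is not strictly > 0.7
        assert consensus_threshold(10) == 8

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            consensus_threshold(10, fraction=0.0)
        with pytest.raises(ValueError):
            consensus_threshold(10, fraction=1.0)

    @pytest.mark.parametrize("fraction", [0.5, 0.6, 0.7, 0.75, 0.8, 0.9])
    @pytest.mark.parametrize("n", range(1, 31))
    def test_against_exact_rational_oracle(self, n, fraction):
        exact = Fraction(str(fraction))
        k = 1
        while Fraction(k, n) <= exact:
            k += 1
        assert consensus_threshold(n, fraction) == k


class TestConsensusClassify:
    def test_paper_rule_example(self):
        states = np.full((1, 11), int(SampleState.ACTIVE))
        states[0, :8] = int(SampleState.BIVALENT)
        m = StateMatrix(["p"], [f"s{j}" for j in range(11)], states)
        assert consensus_classify(m)["p"] == ConsensusClass.HC_BIVALENT

    def test_below_threshold_unclassified(self):
        states = np.full((1, 11), int(SampleState.ACTIVE))
        states[0, :7] = int(SampleState.BIVALENT)
        m = StateMatrix(["p"], [f"s{j}" for j in range(11)], states)
        assert consensus_classify(m)["p"] == ConsensusClass.UNCLASSIFIED

    def test_matches_brute_force_oracle(self, rng):
        m = random_matrix(rng, 1000, 12)
        k = consensus_threshold(12)
        got = consensus_classify(m)
        for i, pid in enumerate(m.promoter_ids):
            counts = Counter(int(v) for v in m.states[i])
            expected = ConsensusClass.UNCLASSIFIED
            for state in SampleState:
                if counts.get(int(state), 0) >= k:
                    from bivalscan.chromatin_state import STATE_TO_HC

                    expected = STATE_TO_HC[state]
            assert got[pid] == expected

    def test_uniqueness_on_random_matrices(self, rng):
        # with fraction >= 0.5 at most one state can reach the threshold
        for _ in range(20):
            m = random_matrix(rng, 50, int(rng.integers(2, 13)))
            k = consensus_threshold(m.n_samples, 0.5)
            for i in range(m.n_promoters):
                counts = Counter(int(v) for v in m.states[i])
                assert sum(1 for c in counts.values() if c >= k) <= 1

    def test_monotone_in_state_count(self, rng):
        m = random_matrix(rng, 100, 8)
        classes = consensus_classify(m)
        target = int(SampleState.BIVALENT)
        flipped = m.states.copy()
        i, j = int(rng.integers(100)), int(rng.integers(8))
        flipped[i, j] = target
        m2 = StateMatrix(m.promoter_ids, m.sample_ids, flipped)
        classes2 = consensus_classify(m2)
        pid = m.promoter_ids[i]
        if classes[pid] == ConsensusClass.HC_BIVALENT:
            assert classes2[pid] == ConsensusClass.HC_BIVALENT

    def test_noiseless_recovery(self):
        truth = sd.simulate_truth(300, seed=21)
        chip = sd.simulate_chip_samples(
            truth,
            n_samples=5,
            k4_detect_p=1.0,
            k27_detect_p=1.0,
            false_positive_rate=0.0,
            seed=22,
        )
        matrix = build_state_matrix(truth.promoter_regions(), chip.sample_pairs())
        classes = consensus_classify(matrix)
        expected = truth.hc_classes()
        assert all(str(classes[p]) == expected[p] for p in expected)


class TestDetectionCurve:
    def test_hand_counted_toy(self):
        # bivalent-counts per promoter: 3, 2, 1, 0
        B, A = int(SampleState.BIVALENT), int(SampleState.ACTIVE)
        states = np.array(
            [[B, B, B], [B, B, A], [B, A, A], [A, A, A]], dtype=np.int8
        )
        m = StateMatrix(list("wxyz"), list("abc"), states)
        assert detection_curve(m, SampleState.BIVALENT).tolist() == [3, 2, 1]

    def test_constant_when_all_bivalent(self):
        states = np.full((5, 4), int(SampleState.BIVALENT))
        m = StateMatrix([f"p{i}" for i in range(5)], list("abcd"), states)
        assert detection_curve(m, SampleState.BIVALENT).tolist() == [5, 5, 5, 5]

    def test_non_increasing_and_matches_recount(self, rng):
        m = random_matrix(rng, 500, 10)
        for state in SampleState:
            curve = detection_curve(m, state)
            assert all(curve[i] >= curve[i + 1] for i in range(len(curve) - 1))
            for n in range(1, 11):
                brute = sum(
                    1
                    for i in range(500)
                    if sum(int(v) == int(state) for v in m.states[i]) >= n
                )
                assert curve[n - 1] == brute


class TestTopSignalOverlap:
    def test_perfect_ranking(self):
        scores = {"a": 9.0, "b": 8.0, "c": 1.0, "d": 0.5}
        assert top_signal_overlap(scores, {"a", "b"}) == 1.0

    def test_half_overlap(self):
        scores = {"a": 9.0, "c": 8.0, "b": 1.0, "d": 0.5}
        assert top_signal_overlap(scores, {"a", "b"}) == 0.5

    def test_tie_break_by_id(self):
        scores = {"a": 1.0, "b": 1.0, "c": 1.0}
        # all tied: top-1 is 'a' by ascending id
        assert top_signal_overlap(scores, {"a"}) == 1.0
        assert top_signal_overlap(scores, {"c"}) == 0.0

    def test_empty_hc_set_rejected(self):
        with pytest.raises(ValueError):
            top_signal_overlap({"a": 1.0}, set())

    def test_noisy_scores_miss_part_of_hc_set(self):
        # per-sample score noise keeps the top-k from recovering the HC set
        truth = sd.simulate_truth(500, seed=31)
        chip = sd.simulate_chip_samples(truth, n_samples=6, seed=32)
        proms = truth.promoter_regions()
        from bivalscan.chromatin_state import promoter_signal_scores

        matrix = build_state_matrix(proms, chip.sample_pairs())
        classes = consensus_classify(matrix)
        hc_biv = {p for p, c in classes.items() if c == ConsensusClass.HC_BIVALENT}
        fractions = []
        for sample in chip.samples:
            scores = promoter_signal_scores(proms, sample.k27_peaks)
            fractions.append(top_signal_overlap(scores, hc_biv))
        assert all(f < 1.0 for f in fractions)
        assert np.mean(fractions) > 0.2  # still informative


class TestMarkColocation:
    def _prom(self, pid, pos):
        return promoter_window(TssRecord(pid, pid, "chr1", pos, "+"))

    def test_overlapping_peaks_colocated(self):
        prom = self._prom("p", 1000)
        k4 = PeakSet("s", "H3K4me3", [GenomicInterval("chr1", 100, 200)])
        k27 = PeakSet("s", "H3K27me3", [GenomicInterval("chr1", 150, 400)])
        assert mark_colocation_fraction(k4, k27, [prom]) == 1.0

    def test_disjoint_peaks_not_colocated(self):
        prom = self._prom("p", 1000)
        k4 = PeakSet("s", "H3K4me3", [GenomicInterval("chr1", 100, 200)])
        k27 = PeakSet("s", "H3K27me3", [GenomicInterval("chr1", 300, 400)])
        assert mark_colocation_fraction(k4, k27, [prom]) == 0.0

    def test_three_of_four(self):
        proms = [self._prom(f"p{i}", 10000 + 20000 * i) for i in range(4)]
        k4_ivs, k27_ivs = [], []
        for i, prom in enumerate(proms):
            pos = prom.tss.position
            k4_ivs.append(GenomicInterval("chr1", pos, pos + 100))
            if i < 3:
                k27_ivs.append(GenomicInterval("chr1", pos + 50, pos + 200))
            else:
                k27_ivs.append(GenomicInterval("chr1", pos + 500, pos + 700))
        k4 = PeakSet("s", "H3K4me3", k4_ivs)
        k27 = PeakSet("s", "H3K27me3", k27_ivs)
        assert mark_colocation_fraction(k4, k27, proms) == 0.75


class TestSampleQc:
    def test_hand_arithmetic(self):
        A = int(SampleState.ACTIVE)
        L = int(SampleState.LATENT)
        states = np.zeros((19000, 2), dtype=np.int8)
        states[:18000, 0] = A
        states[:19000, 1] = A
        states[18000:, 0] = L
        m = StateMatrix(
            [f"p{i}" for i in range(19000)], ["s1", "s2"], states
        )
        qc = sample_qc(m)
        row = qc.summary.loc["ACTIVE"]
        assert row["mean"] == pytest.approx(18500.0)
        assert row["sd"] == pytest.approx(707.10678, abs=1e-4)
        assert row["relative_sd_pct"] == pytest.approx(3.8222, abs=1e-3)

    def test_identical_counts_zero_rel_sd(self, rng):
        states = rng.integers(0, 4, size=(100, 1))
        states = np.repeat(states, 3, axis=1)
        m = StateMatrix([f"p{i}" for i in range(100)], list("abc"), states)
        qc = sample_qc(m)
        nonzero = qc.summary["mean"] > 0
        assert (qc.summary.loc[nonzero, "relative_sd_pct"] == 0).all()

    def test_depths_proportional_to_counts(self):
        A = int(SampleState.ACTIVE)
        states = np.zeros((100, 3), dtype=np.int8)
        states[:10, 0] = A
        states[:20, 1] = A
        states[:40, 2] = A
        m = StateMatrix([f"p{i}" for i in range(100)], list("abc"), states)
        qc = sample_qc(m, read_depths=[100, 200, 400])
        assert qc.depth_correlation["ACTIVE"] == pytest.approx(1.0)

    def test_needs_two_samples(self):
        m = StateMatrix(["p"], ["s"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            sample_qc(m)


class TestCollapseToGene:
    def test_bivalent_takes_priority(self):
        classes = {
            "t1": ConsensusClass.HC_ACTIVE,
            "t2": ConsensusClass.HC_BIVALENT,
            "t3": ConsensusClass.UNCLASSIFIED,
        }
        mapping = {"t1": "g", "t2": "g", "t3": "g"}
        assert collapse_to_gene(classes, mapping) == {
            "g": ConsensusClass.HC_BIVALENT
        }
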