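import numpy as np
import pandas as pd
import pytest

from cnapipe.aberration import (AMPLIFICATION, GAIN, HOMOZYGOUS_DELETION, LOSS,
                                NEUTRAL, CallerConfig, amplification_grade,
                                classify_track, frequency_track, genes_in_calls,
                                most_overlapping_section, read_calls, write_calls)
from cnapipe.io import GeneModel

from _oracles import oracle_most_overlapping


class TestClassify:
    @pytest.mark.parametrize("cn,psi,expected", [
        (3, 2.0, GAIN),            # log2(1.5) = 0.585 > 0.377
        (4, 2.0, AMPLIFICATION),   # log2(2.0) = 1.0 > 0.811
        (1, 2.0, LOSS),            # log2(0.5) = -1.0 < -0.377
        (2, 2.0, NEUTRAL),
        (0, 2.0, HOMOZYGOUS_DELETION),
        (4, 3.0, GAIN),            # log2(4/3) = 0.415
        (5, 3.0, GAIN),            # log2(5/3) = 0.737 still gain
        (6, 3.0, AMPLIFICATION),   # log2(2) = 1.0
    ])
    def test_threshold_classes(self, cn, psi, expected):
        track = -8.0 if cn == 0 else np.log2(cn / psi)
        got = classify_track(np.array([cn]), np.array([track]), CallerConfig())
        assert got[0] == expected

    def test_hd_wins_regardless_of_track(self):
        got = classify_track(np.array([0]), np.array([0.9]), CallerConfig())
        assert got[0] == HOMOZYGOUS_DELETION

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CallerConfig(gain_loss_threshold=0.9, amplification_threshold=0.5)

    def test_amplification_grades(self):
        assert amplification_grade(0.5) == 0
        assert amplification_grade(0.9) == 1
        assert amplification_grade(1.5) == 2
        assert amplification_grade(1.9) == 3
        assert amplification_grade(2.5) == 4


class TestFrequencyTrack:
    def test_fraction_counts(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(5, 10)], AMPLIFICATION, sample_id=f"s{k}")
                 for k in range(11)]
        calls += [unit_probe_calls(20, [], AMPLIFICATION, sample_id=f"n{k}")
                  for k in range(4)]
        freq = frequency_track(calls)
        assert freq["f_amp"].iloc[7] == pytest.approx(11 / 15)
        assert freq["f_amp"].iloc[0] == 0.0

    def test_class_fractions_partition_unity(self, small_cohort):
        calls = [s["call"] for s in small_cohort]
        freq = frequency_track(calls)
        stacked = np.stack([c.classes for c in calls])
        f_neutral = (stacked == NEUTRAL).sum(axis=0) / len(calls)
        total = freq[["f_amp", "f_gain", "f_loss", "f_hd"]].sum(axis=1) + f_neutral
        assert np.allclose(total, 1.0)

    def test_sample_order_irrelevant(self, small_cohort):
        calls = [s["call"] for s in small_cohort]
        a = frequency_track(calls)
        b = frequency_track(calls[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_grids_rejected(self, unit_probe_calls):
        a = unit_probe_calls(10, [], GAIN)
        b = unit_probe_calls(12, [], GAIN)
        with pytest.raises(ValueError, match="grid"):
            frequency_track([a, b])


class TestMostOverlappingSection:
    def test_three_interval_example(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(0, 10)], GAIN, sample_id="a"),
                 unit_probe_calls(20, [(5, 15)], GAIN, sample_id="b"),
                 unit_probe_calls(20, [(8, 12)], GAIN, sample_id="c")]
        reg = most_overlapping_section(calls, "chr1", GAIN)
        assert (reg.start, reg.end, reg.support) == (8, 10, 3)

    def test_single_sample_run(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(3, 7)], LOSS)]
        reg = most_overlapping_section(calls, "chr1", LOSS)
        assert (reg.start, reg.end, reg.support) == (3, 7, 1)

    def test_disjoint_tie_longest_then_leftmost(self, unit_probe_calls):
        calls = [unit_probe_calls(30, [(2, 5)], HOMOZYGOUS_DELETION, sample_id="a"),
                 unit_probe_calls(30, [(10, 20)], HOMOZYGOUS_DELETION, sample_id="b")]
        reg = most_overlapping_section(calls, "chr1", HOMOZYGOUS_DELETION)
        assert (reg.start, reg.end, reg.support) == (10, 20, 1)

    def test_absent_class_rejected(self, unit_probe_calls):
        calls = [unit_probe_calls(10, [], GAIN)]
        with pytest.raises(ValueError, match="absent"):
            most_overlapping_section(calls, "chr1", GAIN)

    def test_matches_brute_force_on_random_instances(self, unit_probe_calls):
        rng = np.random.default_rng(17)
        for trial in range(15):
            n = int(rng.integers(10, 60))
            calls = []
            for s in range(int(rng.integers(1, 6))):
                spans = []
                for _ in range(int(rng.integers(0, 4))):
                    a = int(rng.integers(0, n - 1))
                    b = int(rng.integers(a + 1, n + 1))
                    spans.append((a, b))
                calls.append(unit_probe_calls(n, spans, GAIN, sample_id=f"s{s}"))
            hits = np.stack([c.classes == GAIN for c in calls])
            if not hits.any():
                continue
            starts = np.arange(n)
            ends = starts + 1
            expected = oracle_most_overlapping(starts, ends, hits)
            reg = most_overlapping_section(calls, "chr1", GAIN)
            assert (reg.start, reg.end, reg.support) == expected


class TestGenesInCalls:
    def test_fully_deleted_gene_counted(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(4, 9)], HOMOZYGOUS_DELETION,
                                  sample_id=f"s{k}") for k in range(3)]
        genes = [GeneModel("g1", "chr1", 5, 8)]
        assert genes_in_calls(calls, genes, HOMOZYGOUS_DELETION, 2) == [("g1", 3)]

    def test_partial_deletion_does_not_count_for_hd(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(4, 6)], HOMOZYGOUS_DELETION)]
        genes = [GeneModel("g1", "chr1", 5, 8)]  # probes 6,7 not deleted
        assert genes_in_calls(calls, genes, HOMOZYGOUS_DELETION, 1) == []

    def test_single_amplified_probe_counts_for_amplification(self, unit_probe_calls):
        calls = [unit_probe_calls(20, [(6, 7)], AMPLIFICATION)]
        genes = [GeneModel("g1", "chr1", 5, 9)]
        assert genes_in_calls(calls, genes, AMPLIFICATION, 1) == [("g1", 1)]

    def test_gene_without_probes_warned_and_skipped(self, unit_probe_calls):
        calls = [unit_probe_calls(10, [(0, 10)], AMPLIFICATION)]
        genes = [GeneModel("far", "chr9", 0, 100)]
        with pytest.warns(UserWarning, match="no overlapping probes"):
            assert genes_in_calls(calls, genes, AMPLIFICATION, 1) == []

    def test_counts_match_exhaustive_overlap_check(self, unit_probe_calls):
        rng = np.random.default_rng(23)
        n = 40
        calls = []
        for s in range(4):
            spans = [(int(a), int(a) + int(rng.integers(1, 6)))
                     for a in rng.integers(0, n - 6, size=3)]
            calls.append(unit_probe_calls(n, spans, HOMOZYGOUS_DELETION,
                                          sample_id=f"s{s}"))
        genes = [GeneModel(f"g{k}", "chr1", int(a), int(a) + 4)
                 for k, a in enumerate(rng.integers(0, n - 4, size=8))]
        got = dict(genes_in_calls(calls, genes, HOMOZYGOUS_DELETION, 1))
        hits = np.stack([c.classes == HOMOZYGOUS_DELETION for c in calls])
        for g in genes:
            probes = [i for i in range(n) if i < g.end and i + 1 > g.start]
            expected = sum(all(hits[s, p] for p in probes) for s in range(4))
            assert got.get(g.gene_id, 0) == expected

    def test_calls_tsv_round_trip(self, small_cohort, tmp_path):
        call = small_cohort[0]["call"]
        path = tmp_path / "calls.tsv"
        write_calls(call, path)
        back = read_calls(path)
        assert back.sample_id == call.sample_id
        assert np.array_equal(back.classes, call.classes)
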