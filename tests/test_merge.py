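"""Overlap arithmetic, CNP normal-state inference, and consensus merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famcnv.errors import ValidationError
from famcnv.intervals import (
    GenomicInterval,
    overlap_fraction,
    union_coverage_fraction,
)
from famcnv.io import CnvCall
from famcnv.merge import canary_normal_state, merge_two_callers, rare_cnv_delta


def iv(start, end, chrom="8"):
    return GenomicInterval(chrom, start, end)


def call(start, end, cn=3, sample="S1", probes=10, conf=20.0, caller="A", chrom="8"):
    state = "loss" if cn < 2 else "gain" if cn > 2 else "normal"
    return CnvCall(sample, "F1", iv(start, end, chrom), cn, state, probes, conf, caller)


def brute_force_overlap(a, b, mode):
    """Oracle: enumerate covered bases on a scaled copy of the intervals."""
    set_a = set(range(a.start, a.end + 1)) if a.chrom == b.chrom else set()
    set_b = set(range(b.start, b.end + 1))
    shared = len(set_a & set_b)
    if shared == 0:
        return 0.0
    if mode == "of_a":
        return shared / a.length
    return min(shared / a.length, shared / b.length)


class TestOverlapFraction:
    def test_identical_intervals_give_one(self):
        a = iv(100, 199)
        assert overlap_fraction(a, a, "of_a") == 1.0
        assert overlap_fraction(a, a, "reciprocal") == 1.0

    def test_half_overlap_directional(self):
        a, b = iv(1, 100_000), iv(50_001, 150_000)
        assert overlap_fraction(a, b, "of_a") == pytest.approx(0.5)

    def test_different_chromosomes_do_not_overlap(self):
        assert overlap_fraction(iv(1, 100, "8"), iv(1, 100, "9")) == 0.0

    @given(
        st.integers(1, 300), st.integers(0, 300),
        st.integers(1, 300), st.integers(0, 300),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_base_enumeration_oracle(self, a1, alen, b1, blen):
        a, b = iv(a1, a1 + alen), iv(b1 + 1, b1 + 1 + blen)
        for mode in ("of_a", "reciprocal"):
            assert overlap_fraction(a, b, mode) == pytest.approx(
                brute_force_overlap(a, b, mode)
            )

    @given(st.integers(1, 300), st.integers(0, 300), st.integers(1, 300),
           st.integers(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_is_symmetric_and_bounded(self, a1, alen, b1, blen):
        a, b = iv(a1, a1 + alen), iv(b1, b1 + blen)
        r = overlap_fraction(a, b, "reciprocal")
        assert r == overlap_fraction(b, a, "reciprocal")
        assert 0.0 <= r <= min(
            overlap_fraction(a, b, "of_a"), overlap_fraction(b, a, "of_a")
        ) + 1e-12


class TestUnionCoverage:
    def test_overlapping_records_not_double_counted(self):
        target = iv(1, 1000)
        cover = [iv(1, 300), iv(201, 600)]
        assert union_coverage_fraction(target, cover) == pytest.approx(0.6)

    def test_adjacent_records_merge(self):
        target = iv(1, 10)
        assert union_coverage_fraction(target, [iv(1, 5), iv(6, 10)]) == 1.0


class TestCanaryNormalState:
    def test_mean_rounds_to_population_normal(self):
        normal, deltas = canary_normal_state({"a": 2, "b": 2, "c": 2, "d": 3})
        assert normal == 2
        assert deltas == {"a": "normal", "b": "normal", "c": "normal", "d": "gain"}

    def test_population_normal_may_exceed_two(self):
        normal, deltas = canary_normal_state({"a": 3, "b": 3, "c": 3})
        assert normal == 3
        assert set(deltas.values()) == {"normal"}

    def test_half_mean_rounds_away_from_zero(self):
        normal, deltas = canary_normal_state({"a": 2, "b": 3})
        assert normal == 3
        assert deltas["a"] == "loss" and deltas["b"] == "normal"

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            canary_normal_state({})


class TestRareCnvDelta:
    @pytest.mark.parametrize(
        "cn, chrom, sex, expected",
        [
            (0, "1", "unknown", "loss"),
            (3, "1", "unknown", "gain"),
            (2, "1", "unknown", "normal"),
            (2, "X", "male", "gain"),
            (1, "X", "male", "normal"),
            (1, "X", "female", "loss"),
            (0, "Y", "female", "normal"),
            (1, "Y", "male", "normal"),
        ],
    )
    def test_sex_aware_reference(self, cn, chrom, sex, expected):
        assert rare_cnv_delta(cn, chrom, sex) == expected


class TestMergeTwoCallers:
    def test_half_overlap_merges_to_outer_envelope(self):
        a = call(100_001, 200_000, caller="A", probes=8)
        b = call(150_001, 260_000, caller="B")
        (m,) = merge_two_callers([a], [b])
        assert (m.interval.start, m.interval.end) == (100_001, 260_000)
        assert m.overlap_fraction == pytest.approx(0.5)
        assert m.n_probes == 10  # max of the two sources

    def test_insufficient_overlap_yields_no_merge(self):
        a = call(100_001, 200_000, caller="A")
        b = call(180_001, 400_000, caller="B")
        assert merge_two_callers([a], [b]) == []

    def test_single_caller_evidence_is_never_emitted(self):
        assert merge_two_callers([call(1, 100_000)], []) == []

    def test_opposite_states_do_not_merge(self):
        a = call(100_001, 200_000, cn=3, caller="A")
        b = call(100_001, 200_000, cn=1, caller="B")
        assert merge_two_callers([a], [b]) == []

    def test_small_or_sparse_merges_dropped(self):
        a = call(100_001, 115_000, caller="A")  # envelope < 20 kb
        b = call(100_001, 115_000, caller="B")
        assert merge_two_callers([a], [b]) == []
        a = call(100_001, 200_000, probes=4, caller="A")
        b = call(100_001, 200_000, probes=4, caller="B")
        assert merge_two_callers([a], [b]) == []

    def test_low_confidence_caller_b_prefiltered(self):
        a = call(100_001, 200_000, caller="A")
        b = call(100_001, 200_000, caller="B", conf=5.0)
        assert merge_two_callers([a], [b]) == []

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValidationError, match="single sample"):
            merge_two_callers([call(1, 30_000, sample="S1")],
                              [call(1, 30_000, sample="S2")])

    def test_envelope_contains_both_sources(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s1, s2 = rng.integers(1, 500_000, size=2)
            a = call(s1, s1 + int(rng.integers(20_000, 200_000)), caller="A")
            b = call(s2, s2 + int(rng.integers(20_000, 200_000)), caller="B")
            for m in merge_two_callers([a], [b]):
                assert m.interval.contains(a.interval)
                assert m.interval.contains(b.interval)

    def test_output_count_bounded_by_smaller_input(self):
        rng = np.random.default_rng(11)
        calls_a = [call(int(s), int(s) + 50_000, caller="A")
                   for s in rng.integers(1, 2_000_000, size=8)]
        calls_b = [call(int(s), int(s) + 50_000, caller="B")
                   for s in rng.integers(1, 2_000_000, size=5)]
        merged = merge_two_callers(calls_a, calls_b)
        assert len(merged) <= 5

    def test_greedy_matches_exhaustive_on_small_instances(self):
        """Greedy one-to-one matching equals exhaustive max-total-overlap search."""

        def exhaustive(calls_a, calls_b, min_overlap=0.5):
            pairs = {}
            for i, a in enumerate(calls_a):
                for j, b in enumerate(calls_b):
                    f = overlap_fraction(a.interval, b.interval, "of_a")
                    if f >= min_overlap:
                        pairs[(i, j)] = f
            best, best_total = frozenset(), -1.0
            ids_a = {i for i, _ in pairs}
            for r in range(len(ids_a), -1, -1):
                for chosen_a in itertools.combinations(sorted(ids_a), r):
                    for chosen_b in itertools.permutations(
                        sorted({j for _, j in pairs}), r
                    ):
                        m = list(zip(chosen_a, chosen_b))
                        if any(p not in pairs for p in m):
                            continue
                        total = sum(pairs[p] for p in m)
                        if total > best_total:
                            best_total, best = total, frozenset(m)
            return best, best_total

        rng = np.random.default_rng(3)
        agree = 0
        n_instances = 40
        for _ in range(n_instances):
            calls_a = [call(int(s), int(s) + int(rng.integers(30_000, 120_000)), caller="A")
                       for s in rng.integers(1, 600_000, size=4)]
            calls_b = [call(int(s), int(s) + int(rng.integers(30_000, 120_000)), caller="B")
                       for s in rng.integers(1, 600_000, size=4)]
            merged = merge_two_callers(calls_a, calls_b, min_probes=1, min_size=1)
            greedy_total = sum(m.overlap_fraction for m in merged)
            _, best_total = exhaustive(calls_a, calls_b)
            if abs(greedy_total - max(best_total, 0.0)) <= 1e-9:
                agree += 1
        assert agree >= 0.95 * n_instances
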