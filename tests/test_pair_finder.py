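"""Twin-peak detection: worked examples, equivalence with the exhaustive
reference, tolerance semantics, and natural-isotope decoy rejection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopair import (ELEMENTS, PeakTable, TolerancePolicy, brute_force_pairs,
                     deduplicate_hits, find_labeled_pairs, intensity_rel_diff)

C13_C12 = ELEMENTS["C13"] - ELEMENTS["C12"]


class TestWorkedExamples:
    def test_clean_twin_pair_detected(self, twin_pair_table):
        hits = find_labeled_pairs(twin_pair_table)
        assert len(hits) == 1
        hit = hits.hits.iloc[0]
        assert hit["n_tags"] == 1
        assert abs(hit["ppm_error"]) < 0.1
        assert hit["heavy_mz"] > hit["light_mz"]

    @pytest.mark.parametrize("heavy_rt,heavy_int,expect", [
        (10.01, 0.9e5, 1),   # within all three tolerances
        (10.01, 0.5e5, 0),   # 50 % intensity difference
        (10.20, 0.9e5, 0),   # 0.19 min RT gap
    ])
    def test_each_filter_rejects(self, heavy_rt, heavy_int, expect):
        table = PeakTable("t", peaks=pd.DataFrame({
            "peak_id": [0, 1], "mz": [500.0, 503.0101],
            "rt": [10.0, heavy_rt], "intensity": [1.0e5, heavy_int]}))
        assert len(find_labeled_pairs(table)) == expect

    def test_empty_and_singleton_tables(self):
        empty = PeakTable("e", peaks=pd.DataFrame(
            columns=["peak_id", "mz", "rt", "intensity"]))
        assert len(find_labeled_pairs(empty)) == 0
        assert len(brute_force_pairs(empty)) == 0
        one = PeakTable("o", peaks=pd.DataFrame({
            "peak_id": [0], "mz": [500.0], "rt": [1.0], "intensity": [1.0]}))
        assert len(find_labeled_pairs(one)) == 0
        assert len(brute_force_pairs(one)) == 0


class TestPolicyValidation:
    @pytest.mark.parametrize("kwargs", [
        {"mz_ppm": 0}, {"rt_window": -1}, {"intensity_max_rel_diff": 0},
        {"intensity_max_rel_diff": 1.5}, {"n_tags_searched": frozenset()},
        {"n_tags_searched": frozenset({0})}, {"charge": 0},
    ])
    def test_invalid_policy_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TolerancePolicy(**kwargs)


def test_intensity_rel_diff_symmetric_and_bounded():
    assert intensity_rel_diff(100.0, 67.0) == pytest.approx(0.33)
    assert intensity_rel_diff(67.0, 100.0) == pytest.approx(0.33)
    assert intensity_rel_diff(0.0, 0.0) == 0.0
    assert intensity_rel_diff(0.0, 5.0) == 1.0


POLICIES = [
    TolerancePolicy(),
    TolerancePolicy(mz_ppm=10, rt_window=0.5, intensity_max_rel_diff=0.9),
    TolerancePolicy(mz_ppm=1, rt_window=0.01, intensity_max_rel_diff=0.1),
    TolerancePolicy(n_tags_searched=frozenset({1, 2})),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("policy", POLICIES)
    def test_fast_join_equals_exhaustive(self, policy, random_table_factory):
        for seed in range(12):
            table = random_table_factory(seed, n_background=250, n_pairs=25,
                                         jitter_ppm=3.0, rt_jitter=0.05)
            fast = find_labeled_pairs(table, policy=policy)
            slow = brute_force_pairs(table, policy=policy)
            assert fast.pair_keys() == slow.pair_keys()

    def test_hit_metrics_identical_not_just_keys(self, random_table_factory):
        table = random_table_factory(99)
        fast = find_labeled_pairs(table).hits
        slow = brute_force_pairs(table).hits
        pd.testing.assert_frame_equal(fast, slow)


class TestInvariants:
    def test_hits_satisfy_their_policy(self, random_table_factory):
        policy = TolerancePolicy()
        hits = find_labeled_pairs(random_table_factory(4), policy=policy).hits
        assert len(hits) > 0
        assert (hits["ppm_error"].abs() <= policy.mz_ppm).all()
        assert (hits["rt_delta"].abs() <= policy.rt_window).all()
        assert (hits["intensity_rel_diff"] <= policy.intensity_max_rel_diff).all()
        assert (hits["heavy_mz"] > hits["light_mz"]).all()
        assert not hits.duplicated(["light_id", "heavy_id", "n_tags"]).any()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        from conftest import make_random_table
        table = make_random_table(seed % 50, n_background=120, n_pairs=15)
        rng = np.random.default_rng(seed)
        shuffled = PeakTable(
            table.sample_label,
            peaks=table.peaks.sample(frac=1, random_state=rng.integers(2**31))
            .reset_index(drop=True))
        assert (find_labeled_pairs(shuffled).pair_keys()
                == find_labeled_pairs(table).pair_keys())

    @pytest.mark.parametrize("field,loose,tight", [
        ("mz_ppm", 6.0, 1.5),
        ("rt_window", 0.1, 0.02),
        ("intensity_max_rel_diff", 0.66, 0.15),
    ])
    def test_tolerance_monotonicity(self, field, loose, tight,
                                    random_table_factory):
        table = random_table_factory(21, n_background=200, n_pairs=40,
                                     jitter_ppm=3.0, rt_jitter=0.05)
        base = find_labeled_pairs(table).pair_keys()
        wider = find_labeled_pairs(table, policy=TolerancePolicy(
            **{field: loose})).pair_keys()
        narrower = find_labeled_pairs(table, policy=TolerancePolicy(
            **{field: tight})).pair_keys()
        assert base <= wider
        assert narrower <= base
        assert len(narrower) < len(wider)  # the table straddles the defaults


class TestDecoyRejection:
    def test_natural_isotope_envelope_yields_no_pairs(self):
        """An untagged compound's M+0..M+3 envelope must not look like a
        twin pair: the M+3 satellite sits at the right m/z spacing but at
        ~1 % of the monoisotopic intensity, far beyond the 33 % filter."""
        mz0 = 500.0
        table = PeakTable("envelope", peaks=pd.DataFrame({
            "peak_id": list(range(4)),
            "mz": [mz0 + k * C13_C12 for k in range(4)],
            "rt": [15.0] * 4,
            "intensity": [100.0, 30.0, 6.0, 1.0],
        }))
        assert len(find_labeled_pairs(table)) == 0

    def test_equal_intensity_m3_would_pass(self):
        # control for the control: intensity is the discriminating filter
        table = PeakTable("ctrl", peaks=pd.DataFrame({
            "peak_id": [0, 1],
            "mz": [500.0, 500.0 + 3 * C13_C12],
            "rt": [15.0, 15.0],
            "intensity": [100.0, 100.0]}))
        assert len(find_labeled_pairs(table)) == 1


class TestDeduplicate:
    def _competing_hits(self):
        # one light peak matched by two heavies at ~0.1 and ~2.9 ppm
        delta = 3.0100645
        table = PeakTable("d", peaks=pd.DataFrame({
            "peak_id": ["L", "H1", "H2"],
            "mz": [500.0, (500.0 + delta) * (1 + 0.1e-6),
                   (500.0 + delta) * (1 + 2.9e-6)],
            "rt": [10.0, 10.0, 10.0],
            "intensity": [1.0e5, 1.0e5, 1.0e5]}))
        return find_labeled_pairs(table)

    def test_keep_all_is_identity(self):
        hits = self._competing_hits()
        assert deduplicate_hits(hits, "keep_all") is hits
        assert len(hits) == 2

    def test_best_ppm_keeps_smallest_error(self):
        kept = deduplicate_hits(self._competing_hits(), "best_ppm")
        assert len(kept) == 1
        assert kept.hits.iloc[0]["heavy_id"] == "H1"

    def test_ppm_tie_broken_by_rt(self):
        delta = 3.0100645
        table = PeakTable("tie", peaks=pd.DataFrame({
            "peak_id": ["L", "H1", "H2"],
            "mz": [500.0, 500.0 + delta, 500.0 + delta],
            "rt": [10.0, 10.04, 10.00],
            "intensity": [1.0e5, 1.0e5, 1.0e5]}))
        kept = deduplicate_hits(find_labeled_pairs(table), "best_ppm")
        assert len(kept) == 1
        assert kept.hits.iloc[0]["rt_delta"] == 0.0

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            deduplicate_hits(self._competing_hits(), "magic")


def test_multi_tag_search_finds_doubly_tagged_pair():
    delta = 3.0100645
    table = PeakTable("m", peaks=pd.DataFrame({
        "peak_id": [0, 1], "mz": [500.0, 500.0 + 2 * delta],
        "rt": [5.0, 5.0], "intensity": [1.0, 1.0]}))
    assert len(find_labeled_pairs(table)) == 0  # default searches n=1 only
    hits = find_labeled_pairs(table, policy=TolerancePolicy(
        n_tags_searched=frozenset({1, 2})))
    assert len(hits) == 1 and hits.hits.iloc[0]["n_tags"] == 2
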