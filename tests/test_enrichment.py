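"""Tests of interval-region overlap counting, randomization and coverage."""

import numpy as np
import pandas as pd
import pytest

from ltrscape import enrichment
from ltrscape.enrichment import RegionSet
from ltrscape.errors import CapacityError, ParameterError


def regions_from(records):
    return RegionSet(pd.DataFrame(records, columns=["scaffold", "start", "end", "cls"]))


def brute_overlap_count(intervals, regions_df, cls):
    sub = regions_df[regions_df["cls"] == cls]
    n = 0
    for iv in intervals.itertuples():
        for r in sub.itertuples():
            if r.scaffold == iv.scaffold and iv.start < r.end and r.start < iv.end:
                n += 1
                break
    return n


class TestOverlapCount:
    def test_partial_overlap_counts(self):
        regs = regions_from([("s1", 150, 250, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [100], "end": [200]})
        assert enrichment.overlap_count(ivs, regs, "SPE") == 1

    def test_half_open_abutment_does_not_count(self):
        regs = regions_from([("s1", 200, 300, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [100], "end": [200]})
        assert enrichment.overlap_count(ivs, regs, "SPE") == 0

    def test_unknown_class_rejected(self):
        regs = regions_from([("s1", 0, 100, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [10]})
        with pytest.raises(ParameterError):
            enrichment.overlap_count(ivs, regs, "NOPE")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 19_000, size=50)
        ivs = pd.DataFrame(
            {"scaffold": "s1", "start": starts, "end": starts + rng.integers(50, 900, 50)}
        )
        r_starts = np.sort(rng.choice(np.arange(0, 20_000, 600), 12, replace=False))
        regs_df = pd.DataFrame(
            {"scaffold": "s1", "start": r_starts, "end": r_starts + 400,
             "cls": rng.choice(["SPE", "SYN"], 12)}
        )
        regs = RegionSet(regs_df)
        for cls in ("SPE", "SYN"):
            assert enrichment.overlap_count(ivs, regs, cls) == brute_overlap_count(
                ivs, regs_df, cls
            )

    def test_additive_over_disjoint_classes(self):
        """For intervals hitting exactly one class, per-class counts sum to
        the count against the union."""
        regs_df = pd.DataFrame(
            {"scaffold": "s1", "start": [0, 5_000], "end": [1_000, 6_000],
             "cls": ["SPE", "SYN"]}
        )
        union_df = regs_df.assign(cls="ALL")
        ivs = pd.DataFrame(
            {"scaffold": "s1", "start": [100, 5_100, 9_000], "end": [200, 5_200, 9_100]}
        )
        per = sum(
            enrichment.overlap_count(ivs, RegionSet(regs_df), c) for c in ("SPE", "SYN")
        )
        assert per == enrichment.overlap_count(ivs, RegionSet(union_df), "ALL")


class TestRandomizeIntervals:
    def setup_method(self):
        self.lengths = {"s1": 10_000, "s2": 30_000}
        self.ivs = pd.DataFrame(
            {"scaffold": ["s1"] * 5, "start": [0, 100, 200, 300, 400],
             "end": [100, 350, 400, 800, 450]}
        )

    def test_seed_reproducible(self):
        a = enrichment.randomize_intervals(self.ivs, self.lengths, 5)
        b = enrichment.randomize_intervals(self.ivs, self.lengths, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_length_multiset_preserved(self):
        out = enrichment.randomize_intervals(self.ivs, self.lengths, 1)
        assert sorted(out["end"] - out["start"]) == sorted(
            self.ivs["end"] - self.ivs["start"]
        )

    def test_placements_stay_inside_scaffolds(self):
        out = enrichment.randomize_intervals(self.ivs, self.lengths, 2)
        for r in out.itertuples():
            assert 0 <= r.start and r.end <= self.lengths[r.scaffold]

    def test_scaffold_choice_proportional_to_length(self):
        one = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [100]})
        rng = np.random.default_rng(3)
        n2 = 0
        draws = 2_000
        for _ in range(draws):
            out = enrichment.randomize_intervals(one, self.lengths, rng)
            n2 += out.iloc[0]["scaffold"] == "s2"
        p = 0.75
        sd = np.sqrt(draws * p * (1 - p))
        assert abs(n2 - draws * p) <= 3 * sd

    def test_oversized_interval_rejected(self):
        big = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [50_000]})
        with pytest.raises(CapacityError):
            enrichment.randomize_intervals(big, self.lengths, 0)


class TestPermutationEnrichment:
    def test_blanket_regions_give_p_one(self):
        lengths = {"s1": 10_000}
        regs = regions_from([("s1", 0, 10_000, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"] * 4, "start": [0, 10, 20, 30],
                            "end": [5, 15, 25, 35]})
        t = enrichment.permutation_enrichment(ivs, regs, "SPE", lengths,
                                              n_perm=99, seed=0)
        assert t.observed == 4
        assert t.p_enrich == 1.0
        assert t.z_score is None  # degenerate null

    def test_null_reproducible(self):
        lengths = {"s1": 50_000}
        regs = regions_from([("s1", 0, 10_000, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"] * 10,
                            "start": np.arange(10) * 3_000,
                            "end": np.arange(10) * 3_000 + 500})
        t1 = enrichment.permutation_enrichment(ivs, regs, "SPE", lengths, 99, seed=7)
        t2 = enrichment.permutation_enrichment(ivs, regs, "SPE", lengths, 99, seed=7)
        assert (t1.null_samples == t2.null_samples).all()

    def test_too_few_permutations_rejected(self):
        regs = regions_from([("s1", 0, 100, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [10]})
        with pytest.raises(ParameterError):
            enrichment.permutation_enrichment(ivs, regs, "SPE", {"s1": 1_000}, n_perm=10)


class TestClassCoverage:
    def test_simple_fraction(self):
        regs = regions_from([("s1", 0, 1_000, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [100], "end": [200]})
        cov = enrichment.class_coverage(regs, ivs)
        assert cov.iloc[0]["percent"] == 10.0

    def test_overlapping_ltrs_do_not_double_count(self):
        regs = regions_from([("s1", 0, 1_000, "SPE")])
        ivs = pd.DataFrame({"scaffold": ["s1", "s1"], "start": [100, 150],
                            "end": [200, 200]})
        cov = enrichment.class_coverage(regs, ivs)
        assert cov.iloc[0]["percent"] == 10.0

    def test_empty_class_is_nan(self):
        regs = regions_from([("s1", 0, 1_000, "SPE"), ("s1", 2_000, 2_000, "SYN")])
        ivs = pd.DataFrame({"scaffold": ["s1"], "start": [0], "end": [10]})
        cov = enrichment.class_coverage(regs, ivs)
        row = cov[cov["cls"] == "SYN"].iloc[0]
        assert np.isnan(row["percent"])

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 20_000
        r_starts = np.sort(rng.choice(np.arange(0, L, 500), 10, replace=False))
        regs_df = pd.DataFrame({"scaffold": "s1", "start": r_starts,
                                "end": r_starts + 300, "cls": "SPE"})
        starts = rng.integers(0, L - 400, 40)
        ivs = pd.DataFrame({"scaffold": "s1", "start": starts,
                            "end": starts + rng.integers(50, 400, 40)})
        covered = np.zeros(L, dtype=bool)
        for r in ivs.itertuples():
            covered[r.start : r.end] = True
        in_class = np.zeros(L, dtype=bool)
        for r in regs_df.itertuples():
            in_class[r.start : r.end] = True
        expected = 100.0 * (covered & in_class).sum() / in_class.sum()
        cov = enrichment.class_coverage(RegionSet(regs_df), ivs)
        assert cov.iloc[0]["percent"] == pytest.approx(expected, abs=5e-4)


class TestRegionSetNormalization:
    def test_within_class_overlaps_merged(self):
        regs = regions_from([("s1", 0, 100, "SPE"), ("s1", 50, 150, "SPE")])
        assert regs.class_bases("SPE") == 150

    def test_cross_class_overlaps_preserved(self):
        regs = regions_from([("s1", 0, 100, "SPE"), ("s1", 50, 150, "SYN")])
        assert regs.class_bases("SPE") == 100
        assert regs.class_bases("SYN") == 100
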