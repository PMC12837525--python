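"""Tests of homology search, status classification and census statistics."""

import numpy as np
import pytest

from conftest import match_truth, smith_waterman_present
from ltrscape import census, simulate
from ltrscape._seq import random_seq, revcomp
from ltrscape.census import (
    CensusTable,
    FamilySummary,
    LtrLocus,
    SearchParams,
    format_ratio,
)
from ltrscape.errors import ParameterError


def make_locus(i, status, family="famA", scaffold="s1", start=None):
    start = 100 * i if start is None else start
    return LtrLocus(
        element_id=f"e{i}", scaffold=scaffold, start=start, end=start + 50,
        strand="+", family=family, status=status,
    )


class TestSearchHomology:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.scaffold = random_seq(5_000, rng)
        self.query = self.scaffold[1_200:1_700]

    def test_exact_substring_found_at_coordinates(self):
        hits = census.search_homology(self.query, {"s1": self.scaffold})
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert (h.start, h.end) == (1_200, 1_700)
        assert h.identity == 1.0

    def test_reverse_complement_found_on_minus_strand(self):
        hits = census.search_homology(revcomp(self.query), {"s1": self.scaffold})
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (1_200, 1_700)

    def test_heavily_mutated_query_rejected(self):
        rng = np.random.default_rng(3)
        q = simulate.mutate_sequence(self.query, 0.2, 0.2, rng)  # 40% diverged
        hits = census.search_homology(
            q, {"s1": self.scaffold}, SearchParams(min_identity=0.8)
        )
        assert hits == []

    def test_empty_subject_is_empty_result(self):
        assert census.search_homology(self.query, {}) == []

    def test_degenerate_params_rejected(self):
        with pytest.raises(ParameterError):
            census.search_homology(self.query, {"s1": self.scaffold},
                                   SearchParams(min_identity=0.0))
        with pytest.raises(ParameterError):
            census.search_homology("ACGT", {"s1": self.scaffold})

    def test_diverged_copy_found_above_identity_floor(self):
        rng = np.random.default_rng(5)
        copy = simulate.mutate_sequence(self.query, 0.05, 0.02, rng)
        subject = self.scaffold[:3_000] + copy + self.scaffold[3_000:]
        hits = census.search_homology(self.query, {"s1": subject})
        spans = {(h.start, h.end) for h in hits}
        assert any(s <= 3_000 + 10 and e >= 3_500 - 10 for s, e in spans)


class TestClassifyLocus:
    def _setup(self, seed=23):
        rng = np.random.default_rng(seed)
        internal = random_seq(2_000, rng)
        ltr = random_seq(300, rng)
        return rng, ltr, internal

    def test_solo_no_internal_neighbourhood(self):
        rng, ltr, internal = self._setup()
        scaffold = random_seq(4_000, rng) + ltr + random_seq(4_000, rng)
        hit = census.HomologyHit("q", "s1", 4_000, 4_300, "+", 1.0, 300)
        assert census.classify_locus(hit, internal, {"s1": scaffold}) == "solo"

    def test_truncated_internal_on_one_side(self):
        rng, ltr, internal = self._setup()
        scaffold = random_seq(4_000, rng) + ltr + internal[:800] + random_seq(4_000, rng)
        hit = census.HomologyHit("q", "s1", 4_000, 4_300, "+", 1.0, 300)
        assert census.classify_locus(hit, internal, {"s1": scaffold}) == "truncated"

    def test_hit_inside_internal_is_intact_overlap(self):
        rng, ltr, internal = self._setup()
        scaffold = random_seq(2_000, rng) + internal + random_seq(2_000, rng)
        # a (mis)hit in the middle of the internal region: internal homology
        # on both flanks
        hit = census.HomologyHit("q", "s1", 2_900, 3_100, "+", 1.0, 200)
        assert census.classify_locus(hit, internal, {"s1": scaffold}) == "intact-overlap"

    def test_flank_clipped_at_scaffold_edge(self):
        rng, ltr, internal = self._setup()
        scaffold = ltr + random_seq(4_000, rng)
        hit = census.HomologyHit("q", "s1", 0, 300, "+", 1.0, 300)
        assert census.classify_locus(hit, internal, {"s1": scaffold}) == "solo"


class TestClassifyGenome:
    def test_truth_recovery_on_small_bundle(self, small_bundle, small_loci):
        truth = small_bundle.truth.elements
        assert match_truth(truth, small_loci) == len(truth)

    def test_conservation_of_classified_loci(self, small_loci):
        table = census.run_census(small_loci)
        assert table.STI == len(small_loci)

    def test_oracle_agreement_on_small_genome(self, small_bundle, small_loci):
        """Every non-intact call agrees with an exhaustive Smith-Waterman
        oracle applied to the locus flanks."""
        intact = small_bundle.intact_annotation()
        refs = {}
        for fam, grp in intact.groupby("family"):
            first = grp[grp["element_id"] == grp["element_id"].iloc[0]]
            by_part = {r.part: r for r in first.itertuples()}
            refs[fam] = small_bundle.part_sequence(by_part["internal"])
        window = census.default_flank_window(2_000)
        for locus in small_loci:
            if locus.status == "intact":
                continue
            seq = small_bundle.scaffolds[locus.scaffold]
            up = seq[max(0, locus.start - window) : locus.start]
            down = seq[locus.end : locus.end + window]
            sides = sum(
                smith_waterman_present(refs[locus.family], flank)
                for flank in (up, down)
            )
            expected = {0: "solo", 1: "truncated", 2: "intact-overlap"}[sides]
            assert locus.status == expected


class TestRunCensus:
    @pytest.mark.parametrize(
        "I,S,T,s_i,t_i,st_i",
        [
            (2_394, 8_806, 1_565, "3.68", "0.65", "4.33"),
            (2_474, 19_238, 2_308, "7.78", "0.93", "8.71"),
            (3_230, 25_930, 3_748, "8.03", "1.16", "9.19"),
        ],
    )
    def test_ratio_arithmetic(self, I, S, T, s_i, t_i, st_i):
        loci = (
            [make_locus(i, "intact") for i in range(I)]
            + [make_locus(I + i, "solo") for i in range(S)]
            + [make_locus(I + S + i, "truncated") for i in range(T)]
        )
        table = census.run_census(loci)
        assert table.STI == I + S + T
        assert format_ratio(table.S_over_I) == s_i
        assert format_ratio(table.T_over_I) == t_i
        assert format_ratio(table.ST_over_I) == st_i

    def test_zero_solo_truncated(self):
        loci = [make_locus(i, "intact") for i in range(10)]
        t = census.run_census(loci)
        assert (t.S_over_I, t.T_over_I, t.ST_over_I) == (0, 0, 0)
        assert t.STI == 10

    def test_undefined_ratios_when_no_intact(self):
        loci = [make_locus(i, "solo") for i in range(5)]
        t = census.run_census(loci)
        assert not t.ratios_defined
        assert np.isnan(t.S_over_I)

    def test_scaffold_length_filter_monotone(self, small_loci, small_bundle):
        lengths = small_bundle.scaffold_lengths
        prev = None
        for thr in sorted([0] + list(lengths.values())):
            t = census.run_census(small_loci, thr, lengths)
            f = t.filtered()
            if prev is not None:
                assert f.I <= prev.I and f.S <= prev.S and f.T <= prev.T
            prev = f


class TestFamilyCensus:
    @pytest.mark.parametrize(
        "n_high,n_fam,expected",
        [(202, 401, "50.37"), (232, 474, "48.94"), (149, 378, "39.41"),
         (172, 389, "44.21"), (198, 407, "48.64")],
    )
    def test_proportion_formatting(self, n_high, n_fam, expected):
        assert FamilySummary(n_families=n_fam, n_high=n_high).proportion_high_str == expected

    def test_family_ratios_and_flags(self):
        loci = (
            [make_locus(i, "intact", "famA") for i in range(2)]
            + [make_locus(10 + i, "solo", "famA") for i in range(7)]  # 3.5 > 3
            + [make_locus(20 + i, "intact", "famB") for i in range(3)]
            + [make_locus(30 + i, "solo", "famB") for i in range(9)]  # exactly 3
            + [make_locus(40 + i, "solo", "famC") for i in range(2)]  # I = 0
        )
        fams, summary = census.family_census(loci)
        by_id = {f.family_id: f for f in fams}
        assert by_id["famA"].high_elimination
        assert not by_id["famB"].high_elimination  # strict > 3
        assert by_id["famC"].high_elimination  # complete elimination
        assert summary.n_families == 3 and summary.n_high == 2

    def test_all_low_elimination(self):
        loci = [make_locus(i, "intact", "famA") for i in range(4)] + [
            make_locus(9, "solo", "famA")
        ]
        _, summary = census.family_census(loci)
        assert summary.proportion_high == 0.0

    def test_empty_input(self):
        fams, summary = census.family_census([])
        assert fams == [] and summary.n_families == 0


class TestStabilityScan:
    def test_small_scaffolds_with_solo_excess(self):
        """Small scaffolds carrying only solos inflate S:I; the scan picks a
        threshold above them and the filtered ratio drops."""
        lengths = {f"small_{i}": 5_000 for i in range(10)}
        lengths.update({f"mid_{i}": 50_000 for i in range(3)})
        lengths.update({f"big_{i}": 500_000 for i in range(3)})
        loci = []
        k = 0
        for i in range(10):
            for _ in range(6):
                loci.append(make_locus(k, "solo", scaffold=f"small_{i}")); k += 1
        for group in ("mid", "big"):
            for i in range(3):
                for _ in range(10):
                    loci.append(make_locus(k, "intact", scaffold=f"{group}_{i}")); k += 1
                for _ in range(10):
                    loci.append(make_locus(k, "solo", scaffold=f"{group}_{i}")); k += 1
        scan = census.stability_scan(loci, lengths, grid=[0, 10_000, 60_000, 400_000])
        assert scan.stable
        assert scan.selected_threshold > 5_000
        unfiltered = census.run_census(loci)
        filtered = census.run_census(loci, scan.selected_threshold, lengths).filtered()
        assert filtered.S_over_I < unfiltered.S_over_I
        # direct recomputation at each grid point matches the scan
        for thr, ratio in zip(scan.thresholds, scan.ratio_at_threshold):
            t = census.run_census(loci, max(thr, 1), lengths).filtered()
            assert t.S_over_I == pytest.approx(ratio)

    def test_single_scaffold_constant_ratio(self):
        lengths = {"s1": 100_000}
        loci = [make_locus(i, s) for i, s in enumerate(["intact"] * 5 + ["solo"] * 5)]
        scan = census.stability_scan(loci, lengths, grid=[0, 10, 20, 30])
        assert scan.stable and scan.selected_threshold == 0

    def test_single_point_grid(self):
        loci = [make_locus(0, "intact")]
        scan = census.stability_scan(loci, {"s1": 1_000}, grid=[0])
        assert scan.selected_threshold == 0 and scan.stable

    def test_truncated_when_intacts_vanish(self):
        lengths = {"s1": 1_000, "s2": 50_000}
        loci = [make_locus(0, "intact", scaffold="s1"),
                make_locus(1, "solo", scaffold="s2")]
        scan = census.stability_scan(loci, lengths, grid=[0, 2_000])
        assert scan.truncated_at == 2_000

    def test_bad_grid_rejected(self):
        with pytest.raises(ParameterError):
            census.stability_scan([], {"s1": 10}, grid=[5, 10])


class TestCensusTableFromCounts:
    def test_invariants(self):
        t = CensusTable.from_counts(10, 20, 5)
        assert t.STI == 35
        assert t.ST_over_I == pytest.approx(2.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            CensusTable.from_counts(-1, 0, 0)
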