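import numpy as np
import pytest

from karyograph.breakpoint_stats import (
    RecombWindow,
    association_test,
    chromnum_correlation,
    flag_ebr_windows,
    reuse_report,
    reuse_report_from_counts,
    tally_segment_end_usage,
    window_recombination_rates,
)
from karyograph.genome_io import (
    GeneticMapMarker,
    KaryotypeInfo,
    ValidationError,
    packaged_karyotype,
)
from karyograph.rearrangement import EventRecord
from karyograph.synteny import EBRecord


def _event(lineage_step, ends):
    return EventRecord("branch", "inversion", frozenset(ends), step=lineage_step)


class TestUsageTally:
    def test_empty_scenarios_give_zero_counts(self):
        usage = tally_segment_end_usage({"L1": []}, {1, 2})
        assert len(usage) == 4
        assert all(counts == {} for counts in usage.values())

    def test_single_inversion_counts_its_ends(self):
        ev = _event(1, {(1, "h"), (2, "t")})
        usage = tally_segment_end_usage({"L1": [ev]}, {1, 2})
        assert usage[(1, "h")] == {"L1": 1}
        assert usage[(2, "t")] == {"L1": 1}
        assert usage[(1, "t")] == {}

    def test_two_lineages_sharing_an_end(self):
        ev = _event(1, {(1, "h")})
        usage = tally_segment_end_usage({"L1": [ev], "L2": [ev]}, {1})
        assert usage[(1, "h")] == {"L1": 1, "L2": 1}

    def test_unknown_extremity_rejected(self):
        with pytest.raises(ValidationError):
            tally_segment_end_usage({"L1": [_event(1, {(9, "h")})]}, {1})


class TestReuseReport:
    def test_published_tally_group_one(self):
        # chromosomes 1-5 group: 620 ends, 421 involved
        rep = reuse_report_from_counts("chr1-5", 620, 421, 100, 214)
        assert rep.pct_across == 23.8
        assert rep.pct_any == 50.8

    def test_published_tally_group_two(self):
        # chromosomes 4p + 6-28 + Z group: 560 ends, 428 involved
        rep = reuse_report_from_counts("chr4p-6-28-Z", 560, 428, 109, 210)
        assert rep.pct_across == 25.5
        assert rep.pct_any == 49.1

    def test_single_use_everywhere_means_no_reuse(self):
        usage = {
            (1, "t"): {"L1": 1},
            (1, "h"): {"L2": 1},
            (2, "t"): {},
            (2, "h"): {},
        }
        rep = reuse_report(usage)
        assert rep.total_segment_ends == 4
        assert rep.ends_involved == 2
        assert rep.reused_any == 0 and rep.reused_across_lineages == 0

    def test_within_lineage_and_across_lineage_reuse(self):
        usage = {
            (1, "t"): {"L1": 2},  # reused within one lineage
            (1, "h"): {"L1": 1, "L2": 1},  # reused across lineages
            (2, "t"): {"L1": 1},
            (2, "h"): {},
        }
        rep = reuse_report(usage)
        assert rep.ends_involved == 3
        assert rep.reused_across_lineages == 1
        assert rep.reused_any == 2
        assert rep.pct_across == round(100 / 3, 1)

    def test_monotonicity_chain_enforced(self):
        with pytest.raises(ValidationError):
            reuse_report_from_counts("g", 10, 5, 6, 6)

    def test_no_involved_ends_gives_null_percentages(self):
        rep = reuse_report({(1, "t"): {}, (1, "h"): {}})
        assert rep.pct_across is None and rep.pct_any is None


class TestRecombWindows:
    def test_uniform_map_gives_uniform_rates(self):
        markers = [
            GeneticMapMarker("gg", "chr1", 0, 0.0),
            GeneticMapMarker("gg", "chr1", 2_000_000, 4.0),
        ]
        wins = window_recombination_rates(markers, {"chr1": 2_000_000})
        assert [w.rate for w in wins] == [pytest.approx(2.0)] * 2

    def test_single_marker_chromosome_has_no_rates(self):
        markers = [GeneticMapMarker("gg", "chr1", 500_000, 1.0)]
        wins = window_recombination_rates(markers, {"chr1": 2_000_000})
        assert all(w.rate is None for w in wins)

    def test_piecewise_map_interpolated_per_window(self):
        markers = [
            GeneticMapMarker("gg", "chr1", 0, 0.0),
            GeneticMapMarker("gg", "chr1", 1_000_000, 1.0),
            GeneticMapMarker("gg", "chr1", 2_000_000, 5.0),
        ]
        wins = window_recombination_rates(markers, {"chr1": 2_000_000})
        assert [w.rate for w in wins] == [pytest.approx(1.0), pytest.approx(4.0)]

    def test_windows_tile_the_chromosome(self):
        markers = [
            GeneticMapMarker("gg", "chr1", 0, 0.0),
            GeneticMapMarker("gg", "chr1", 3_500_000, 7.0),
        ]
        wins = window_recombination_rates(markers, {"chr1": 3_500_000})
        assert sum(w.end - w.start for w in wins) == 3_500_000
        assert wins[-1].end - wins[-1].start == 500_000  # terminal remainder

    def test_nonmonotone_map_clamped_with_warning(self):
        markers = [
            GeneticMapMarker("gg", "chr1", 0, 0.0),
            GeneticMapMarker("gg", "chr1", 1_000_000, 3.0),
            GeneticMapMarker("gg", "chr1", 2_000_000, 2.0),
        ]
        with pytest.warns(UserWarning, match="non-monotone"):
            wins = window_recombination_rates(markers, {"chr1": 2_000_000})
        assert wins[1].rate == pytest.approx(0.0)


class TestFlagging:
    def _win(self, i):
        return RecombWindow("chr1", i * 10**6, (i + 1) * 10**6, 1.0)

    def test_interior_ebr_flags_single_window_under_both_rules(self):
        wins = [self._win(0), self._win(1)]
        ebr = EBRecord("gg", "chr1", 400_000, 600_000, "intrachromosomal")
        for rule in ("midpoint", "any_overlap"):
            flagged = flag_ebr_windows(wins, [ebr], rule)
            assert [w.has_ebr for w in flagged] == [True, False]

    def test_boundary_spanning_ebr_differs_by_rule(self):
        wins = [self._win(0), self._win(1)]
        ebr = EBRecord("gg", "chr1", 900_000, 1_100_000, "intrachromosomal")
        # midpoint = 1.0 Mb belongs to [1,2) under the half-open convention
        assert [w.has_ebr for w in flag_ebr_windows(wins, [ebr], "midpoint")] == [
            False, True,
        ]
        assert [w.has_ebr for w in flag_ebr_windows(wins, [ebr], "any_overlap")] == [
            True, True,
        ]

    def test_no_ebrs_no_flags(self):
        wins = [self._win(0)]
        assert not any(w.has_ebr for w in flag_ebr_windows(wins, [], "midpoint"))


class TestAssociation:
    def _windows(self, with_rates, without_rates):
        wins = [
            RecombWindow("c", i * 10**6, (i + 1) * 10**6, float(r), True)
            for i, r in enumerate(with_rates)
        ]
        wins += [
            RecombWindow("c", (100 + i) * 10**6, (101 + i) * 10**6, float(r), False)
            for i, r in enumerate(without_rates)
        ]
        return wins

    def test_wilcoxon_matches_R_reference(self):
        # frozen from R: wilcox.test(x, y, correct=TRUE, exact=FALSE)
        x = [4.547, 6.178, 4.823, 1.671, 1.355, 2.811, 4.182, 3.506, 6.72,
             3.957, 3.743, 1.886]
        y = [1.279, 4.675, 2.281, 3.339, 1.118, 1.789, 1.167, 1.51, 3.496,
             1.062, 1.704, 2.415, 1.593, 1.962, 1.992, 2.743, 1.794, 2.55,
             2.29, 2.752, 2.49, 5.098, 1.597, 4.054, 1.82, 1.379, 4.078,
             1.786, 1.833, 1.111]
        res = association_test(self._windows(x, y), n_iter=100, seed=1)
        assert res.wilcoxon_W == 276
        assert res.wilcoxon_p == pytest.approx(0.00783869512374, rel=1e-9)

    def test_identical_classes_give_null_difference(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = association_test(self._windows(vals, vals), n_iter=500, seed=3)
        assert res.perm_diff == pytest.approx(0.0)
        assert res.perm_p > 0.4

    def test_extreme_separation_gives_minimal_perm_p(self):
        res = association_test(
            self._windows([100.0] * 5, [1.0] * 50), n_iter=1000, seed=4
        )
        assert res.perm_p <= 1 / 1000

    def test_seeded_runs_are_bit_reproducible(self):
        rng = np.random.default_rng(8)
        wins = self._windows(rng.random(10) + 1, rng.random(60))
        r1 = association_test(wins, n_iter=400, seed=77)
        r2 = association_test(wins, n_iter=400, seed=77)
        assert r1 == r2
        assert r1.perm_p * 400 == round(r1.perm_p * 400)  # resolution 1/n_iter

    def test_empty_class_rejected(self):
        wins = self._windows([], [1.0, 2.0])
        with pytest.raises(ValidationError):
            association_test(wins, n_iter=10, seed=0)


class TestChromnumCorrelation:
    def test_published_table_reproduces_reported_r_squared(self):
        karyo = packaged_karyotype()
        res = chromnum_correlation(karyo)
        assert res.n == 15
        assert round(res.r_squared, 1) == 0.3
        assert res.p_value == pytest.approx(0.03, abs=0.005)

    def test_ostrich_exclusion_strengthens_fit(self):
        karyo = packaged_karyotype()
        res = chromnum_correlation(karyo, exclude=["ostrich"])
        assert res.n == 14
        assert round(res.r_squared, 1) == 0.7
        assert res.p_value == pytest.approx(0.0002, abs=0.0002)

    def test_perfect_linearity(self):
        karyo = [
            KaryotypeInfo(f"s{i}", 40 + i, total_interchrom=3 * i) for i in range(5)
        ]
        res = chromnum_correlation(karyo)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(12)
        karyo = []
        xs, ys = [], []
        for i in range(10):
            n = int(rng.integers(25, 50))
            y = int(rng.integers(0, 12))
            karyo.append(KaryotypeInfo(f"s{i}", n, total_interchrom=y))
            xs.append(abs(n - 40))
            ys.append(y)
        res = chromnum_correlation(karyo)
        x, y = np.array(xs, float), np.array(ys, float)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r_squared == pytest.approx(r**2)

    def test_species_without_published_number_excluded(self):
        karyo = packaged_karyotype()
        res = chromnum_correlation(karyo)
        assert res.n == 15  # 6 of 21 lack a published haploid number

    def test_fewer_than_three_points_rejected(self):
        karyo = [KaryotypeInfo("a", 40), KaryotypeInfo("b", 30)]
        with pytest.raises(ValidationError):
            chromnum_correlation(karyo)
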