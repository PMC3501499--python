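import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from rodiso import (
    SpecimenRecord,
    flag_outliers,
    intra_jaw_ranges,
    kruskal_wallis,
    one_way_anova,
    paired_tissue_offsets,
    round_half_away,
    summarize,
    tukey_hsd,
)
from rodiso.errors import (
    DegenerateVarianceError,
    EmptySelectionError,
    InvalidInputError,
)

# tenth-per-mil grid keeps within-group variances away from float noise
values_strategy = st.lists(
    st.integers(min_value=-300, max_value=300).map(lambda i: i / 10.0),
    min_size=2, max_size=15,
)


class TestSummarize:
    def test_table3_incisor_column(self, table3_records):
        groups = summarize(table3_records, "tissue", "d18O_co3")
        by_tissue = {g.group_key[0]: g for g in groups}
        inc = by_tissue["incisor"]
        assert round_half_away(inc.mean) == 26.5
        assert round_half_away(inc.sd) == 1.2
        m1 = by_tissue["M1"]
        assert round_half_away(m1.mean) == 25.8
        assert round_half_away(m1.sd) == 1.1

    def test_constant_group(self):
        recs = [SpecimenRecord(f"S{i}", "sp", "other", "bone", d18O_co3=25.0)
                for i in range(4)]
        (g,) = summarize(recs, "species", "d18O_co3")
        assert g.sd == 0.0
        assert g.range_width == 0.0

    def test_unknown_variable(self, table3_records):
        with pytest.raises(InvalidInputError):
            summarize(table3_records, "tissue", "d18O_hydroxyl")

    def test_min_mean_max_ordering_and_permutation_invariance(self, table3_records):
        fwd = summarize(table3_records, ("species", "tissue"), "d18O_po4")
        rev = summarize(list(reversed(table3_records)), ("species", "tissue"),
                        "d18O_po4")
        assert len(fwd) == len(rev) > 0
        for a, b in zip(fwd, rev):
            assert a.group_key == b.group_key and a.n == b.n
            assert a.mean == pytest.approx(b.mean, abs=1e-12)
            assert a.sd == pytest.approx(b.sd, abs=1e-12)
            assert a.min <= a.mean <= a.max

    def test_missing_values_excluded(self):
        recs = [
            SpecimenRecord("S1", "sp", "other", "bone", d18O_co3=25.0),
            SpecimenRecord("S2", "sp", "other", "bone", d13C=-17.0),
        ]
        (g,) = summarize(recs, "species", "d18O_co3")
        assert g.n == 1


class TestPairedTissueOffsets:
    def test_table3_specimen01(self, table3_records):
        report = paired_tissue_offsets(table3_records, "incisor", "bone")
        by_specimen = {p[0]: p[3] for p in report.pairs}
        assert by_specimen["AT01"] == pytest.approx(28.4 - 27.7)

    def test_all_arvicola_incisors_higher(self, table3_records):
        # sign check on the five incisor-bone pairs: 0.7, 0.1, 1.2, 2.1, 0.2
        report = paired_tissue_offsets(table3_records, "incisor", "bone")
        assert len(report.pairs) == 5
        assert report.n_positive == 5
        assert report.proportion_positive == 1.0

    def test_same_tissue_all_zero(self, table3_records):
        report = paired_tissue_offsets(table3_records, "bone", "bone")
        assert all(p[3] == 0.0 for p in report.pairs)

    def test_species_sd(self, table3_records):
        report = paired_tissue_offsets(table3_records, "incisor", "bone")
        offs = [p[3] for p in report.pairs]
        mean = sum(offs) / len(offs)
        expected = math.sqrt(sum((o - mean) ** 2 for o in offs) / (len(offs) - 1))
        assert report.offset_sd_by_species["Arvicola terrestris"] == pytest.approx(expected)

    def test_no_pairs(self):
        recs = [SpecimenRecord("S1", "sp", "other", "incisor", d18O_co3=26.0)]
        with pytest.raises(EmptySelectionError):
            paired_tissue_offsets(recs, "incisor", "bone")


class TestIntraJawRanges:
    def _jaw(self, sid, teeth):
        return [SpecimenRecord(sid, "sp", "other", t, d18O_co3=v)
                for t, v in teeth.items()]

    def test_two_teeth(self):
        recs = self._jaw("S1", {"incisor": 26.6, "M1": 26.1})
        (r,) = intra_jaw_ranges(recs)
        assert r.overall_range == pytest.approx(0.5)
        assert r.molar_range is None

    def test_synthetic_jaw(self):
        recs = self._jaw("S1", {"incisor": 27.0, "M1": 26.2, "M2": 26.2, "M3": 26.2})
        (r,) = intra_jaw_ranges(recs)
        assert r.overall_range == pytest.approx(0.8)
        assert r.molar_range == pytest.approx(0.0)

    def test_molar_range_bounded_by_overall(self, table3_records, rng):
        recs = []
        for i in range(5):
            teeth = {t: float(rng.uniform(24, 29))
                     for t in ("incisor", "M1", "M2", "M3")}
            recs.extend(self._jaw(f"S{i}", teeth))
        for r in intra_jaw_ranges(recs):
            assert r.molar_range <= r.overall_range

    def test_single_tooth_skipped(self):
        recs = self._jaw("S1", {"incisor": 26.0})
        assert intra_jaw_ranges(recs) == []


class TestOneWayAnova:
    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [2, 1, 3]])
        assert res.f_statistic == pytest.approx(0.0)

    def test_hand_decomposition(self):
        # SSB = 1.5, SSW = 4, df = (1, 4), MSW = 1 -> F = 1.5
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.f_statistic == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_cross_implementation_oracle(self, seeded_normal_groups):
        res = one_way_anova(seeded_normal_groups)
        ref = sps.f_oneway(*seeded_normal_groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_within_variance(self):
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    @given(values_strategy, values_strategy,
           st.floats(min_value=0.1, max_value=10, allow_nan=False),
           st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_location_scale_invariance(self, g1, g2, scale, shift):
        try:
            base = one_way_anova([g1, g2])
            moved = one_way_anova([[scale * x + shift for x in g] for g in (g1, g2)])
        except DegenerateVarianceError:
            return
        assert moved.f_statistic == pytest.approx(base.f_statistic, rel=1e-6, abs=1e-9)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        pairs = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 30.0]])
        first = next(p for p in pairs if (p.group_i, p.group_j) == (0, 1))
        assert first.p_adjusted == pytest.approx(1.0, abs=1e-9)

    def test_shifted_group_flagged(self):
        groups = [[1.0, 2.0, 3.0], [1.1, 2.1, 3.1], [101.0, 102.0, 103.0]]
        pairs = {(p.group_i, p.group_j): p for p in tukey_hsd(groups)}
        assert pairs[(0, 2)].significant(0.01)
        assert pairs[(1, 2)].significant(0.01)
        assert not pairs[(0, 1)].significant(0.05)

    def test_cross_implementation_oracle(self, seeded_normal_groups):
        pairs = {(p.group_i, p.group_j): p for p in tukey_hsd(seeded_normal_groups)}
        ref = sps.tukey_hsd(*seeded_normal_groups)
        for (i, j), pair in pairs.items():
            assert pair.p_adjusted == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_conservative_vs_unadjusted_t(self, seeded_normal_groups):
        pairs = tukey_hsd(seeded_normal_groups)
        for p in pairs:
            gi = seeded_normal_groups[p.group_i]
            gj = seeded_normal_groups[p.group_j]
            t_p = sps.ttest_ind(gi, gj).pvalue
            assert p.p_adjusted >= t_p - 1e-9


class TestKruskalWallis:
    def test_hand_rank_computation(self):
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.h_statistic == pytest.approx(2.4)

    def test_within_group_reordering_invariant(self):
        a = kruskal_wallis([[3, 1, 2], [5, 4, 6]])
        b = kruskal_wallis([[1, 2, 3], [6, 5, 4]])
        assert a.h_statistic == pytest.approx(b.h_statistic)

    def test_cross_implementation_oracle(self, seeded_normal_groups):
        res = kruskal_wallis(seeded_normal_groups)
        ref = sps.kruskal(*seeded_normal_groups)
        assert res.h_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_corrected_against_reference(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4], [1, 4, 4, 4]]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.h_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.tie_correction < 1.0

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            kruskal_wallis([[5, 5], [5, 5]])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                    max_size=8, unique=True),
           st.lists(st.integers(min_value=51, max_value=100), min_size=2,
                    max_size=8, unique=True))
    def test_monotone_transform_invariance(self, g1, g2):
        base = kruskal_wallis([g1, g2])
        transformed = kruskal_wallis([
            [math.exp(x / 20.0) for x in g1],
            [math.exp(x / 20.0) for x in g2],
        ])
        assert transformed.h_statistic == pytest.approx(base.h_statistic, abs=1e-9)


class TestFlagOutliers:
    def test_extreme_value_flagged(self):
        values = [24.7, 25.5, 26.0, 26.5, 27.0, 27.2, 27.5, 27.8, 28.2, 31.4]
        flags = flag_outliers(values)
        assert flags[values.index(31.4)]
        assert sum(flags) == 1

    def test_tight_cluster_unflagged(self):
        assert not any(flag_outliers([26.0, 26.1, 26.2, 25.9, 26.05]))

    def test_infinite_k_disables(self):
        values = [24.7, 25.5, 26.0, 26.5, 27.0, 27.2, 27.5, 27.8, 28.2, 31.4]
        assert not any(flag_outliers(values, k=math.inf))

    def test_flags_only_never_deletes(self):
        values = [1.0, 1.1, 1.2, 9.0]
        flags = flag_outliers(values)
        assert len(flags) == len(values)

    def test_needs_three_values(self):
        with pytest.raises(InvalidInputError):
            flag_outliers([1.0, 2.0])
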