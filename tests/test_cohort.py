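"""Cohort statistics: type census, survival, exact association, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capfuse import cohort, io
from capfuse.rearrange import HG19_MODEL


class TestTypeCensus:
    def test_fixture_reproduces_published_counts(self, junction_table):
        assert cohort.count_types(junction_table) == {
            "a": 0, "b": 1, "c": 23, "d": 16}

    def test_thirteen_patients_carry_both_c_and_d(self, junction_table):
        by = cohort.patients_by_type(junction_table)
        assert len(by["c"] & by["d"]) == 13

    def test_counts_are_row_order_invariant(self, junction_table):
        shuffled = junction_table.sample(frac=1, random_state=3)
        assert cohort.count_types(shuffled) == cohort.count_types(junction_table)

    def test_patient_counts_bounded_by_cohort(self, junction_table):
        n_patients = junction_table["Sample"].nunique()
        assert all(v <= n_patients
                   for v in cohort.count_types(junction_table).values())

    def test_empty_table_all_zero(self, junction_table):
        empty = junction_table.iloc[0:0]
        assert cohort.count_types(empty) == {"a": 0, "b": 0, "c": 0, "d": 0}


class TestThreeWay:
    def test_five_patients_with_expected_partners(self, junction_table):
        tw = cohort.find_three_way(junction_table)
        assert {pid: sorted(p) for pid, p in tw.items()} == {
            "SCMC-000206": ["chr5"], "SCMC-000863": ["chr5"],
            "SCMC-000966": ["chr6"], "SCMC-001245": ["chr8"],
            "SCMC-001579": ["chr15"]}

    def test_far_primary_pair_breakend_is_not_three_way(self, junction_table):
        # one patient's reciprocal breakpoint lies megabases outside the
        # capture region but still on chr12: not a third chromosome
        assert "SCMC-001213" not in cohort.find_three_way(junction_table)

    def test_c_only_table_is_empty(self, junction_table):
        c_only = junction_table[junction_table["Mode"] == "c"]
        assert cohort.find_three_way(c_only) == {}


class TestRegionStats:
    def test_capture_region_arithmetic(self):
        stats = cohort.region_stats(HG19_MODEL.target_regions)
        by_chrom = {r["chrom"]: r for r in stats["regions"]}
        assert by_chrom["chr21"]["length_bp"] == 166_256
        assert stats["total_bp"] == 181_030
        assert stats["total_kbp"] == 181

    def test_degenerate_interval(self):
        stats = cohort.region_stats([("chr1", 5, 5)])
        assert stats["total_bp"] == 1

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            cohort.region_stats([("chr1", 10, 5)])


class TestBreakpointOffsets:
    def test_known_offset(self, junction_table):
        df = cohort.breakpoint_offsets(junction_table, HG19_MODEL.target_regions)
        row = df[(df["sample"] == "SCMC-000864") & (df["chrom"] == "chr12")]
        assert int(row["offset"].iloc[0]) == 12_508

    def test_region_start_is_offset_one(self):
        table = pd.DataFrame([{
            "Sample": "S", "Left_chr": "chr12", "Left_str": "F",
            "Left_breakpoint": "12022748", "Gene_left": "", "Right_chr": "chr21",
            "Right_str": "R", "Right_breakpoint": "36259140", "Gene_right": "",
            "Mode": "c"}])
        df = cohort.breakpoint_offsets(table, HG19_MODEL.target_regions)
        assert set(df["offset"]) == {1}

    def test_out_of_region_flagged_not_dropped(self, junction_table):
        df = cohort.breakpoint_offsets(junction_table, HG19_MODEL.target_regions)
        row = df[(df["sample"] == "SCMC-000926") & (df["pos"] == 37_500_446)]
        assert len(row) == 1
        assert not bool(row["in_region"].iloc[0])


def _groups(patient_table, junction_table):
    tw = cohort.find_three_way(junction_table)
    return {pid: ("three_way" if pid in tw else "two_way")
            for pid in patient_table["POND_id"]}


class TestLogrank:
    def test_hand_computed_oracle(self, patient_table, junction_table):
        # risk sets at the four event times (428, 546, 1297, 1319), worked
        # by hand from the fixture: O1 = 4 events all in the 5-patient
        # three-way group
        E1 = 4 / 20 + 3 / 16 + 2 / 9 + 1 / 7
        V = (1 * 19 * 4 * 16 / (20**2 * 19) + 1 * 15 * 3 * 13 / (16**2 * 15)
             + 1 * 8 * 2 * 7 / (9**2 * 8) + 1 * 6 * 1 * 6 / (7**2 * 6))
        chi2 = (4 - E1) ** 2 / V
        res = cohort.logrank_test(patient_table, _groups(patient_table,
                                                         junction_table))
        assert res.observed["three_way"] == 4.0
        assert res.expected["three_way"] == pytest.approx(E1)
        assert res.chi_square == pytest.approx(chi2)

    def test_meets_published_significance_bound(self, patient_table,
                                                junction_table):
        res = cohort.logrank_test(patient_table, _groups(patient_table,
                                                         junction_table))
        assert res.p_value < 1e-4

    def test_agrees_with_lifelines(self, patient_table, junction_table):
        lifelines = pytest.importorskip("lifelines.statistics")
        groups = _groups(patient_table, junction_table)
        g = patient_table["POND_id"].map(groups) == "three_way"
        t = patient_table["Remission_days"]
        e = patient_table["Outcome"] == "Relapse"
        ref = lifelines.logrank_test(t[g], t[~g], e[g], e[~g])
        res = cohort.logrank_test(patient_table, groups)
        assert res.chi_square == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_invariant_under_label_swap(self, patient_table, junction_table):
        groups = _groups(patient_table, junction_table)
        flipped = {k: ("A" if v == "three_way" else "B")
                   for k, v in groups.items()}
        a = cohort.logrank_test(patient_table, groups)
        b = cohort.logrank_test(patient_table, flipped)
        assert a.chi_square == pytest.approx(b.chi_square)
        assert a.p_value == pytest.approx(b.p_value)

    def test_early_censored_patient_changes_nothing(self, patient_table,
                                                    junction_table):
        # a patient censored before the first event never enters a risk set
        groups = _groups(patient_table, junction_table)
        extra = pd.concat([patient_table, pd.DataFrame([{
            "POND_id": "EXTRA", "Gender": "Male", "Age_years": 5,
            "Outcome": "Alive", "Remission_days": 100}])], ignore_index=True)
        groups["EXTRA"] = "two_way"
        a = cohort.logrank_test(patient_table, groups)
        b = cohort.logrank_test(extra, groups)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_km_curves_are_valid_survival_functions(self, patient_table,
                                                    junction_table):
        res = cohort.logrank_test(patient_table,
                                  _groups(patient_table, junction_table))
        for times, surv in res.km_curves.values():
            assert surv[0] == 1.0
            assert np.all(np.diff(surv) <= 0)
            assert np.all((surv >= 0) & (surv <= 1))

    def test_no_events_is_degenerate(self, patient_table):
        alive = patient_table.copy()
        alive["Outcome"] = "Alive"
        groups = {pid: ("A" if i % 2 else "B")
                  for i, pid in enumerate(alive["POND_id"])}
        with pytest.raises(ValueError, match="no events"):
            cohort.logrank_test(alive, groups)

    def test_empty_group_rejected(self, patient_table):
        groups = {pid: "A" for pid in patient_table["POND_id"]}
        with pytest.raises(ValueError):
            cohort.logrank_test(patient_table, groups)


def _brute_force_tail(n_total, n_group, n_events, n_obs):
    hits = total = 0
    for subset in itertools.combinations(range(n_total), n_events):
        total += 1
        if sum(1 for x in subset if x < n_group) >= n_obs:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_cohort_value_exact_fraction(self):
        p = cohort.hypergeom_association(26, 5, 4, 4)
        assert p == pytest.approx(5 / 14_950, abs=0, rel=1e-12)

    def test_certain_outcome(self):
        assert cohort.hypergeom_association(10, 10, 4, 4) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cohort.hypergeom_association(10, 3, 4, 5)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(2, 12), st.data())
    def test_matches_brute_force_enumeration(self, n_total, data):
        n_group = data.draw(st.integers(1, n_total))
        n_events = data.draw(st.integers(1, n_total))
        n_obs = data.draw(st.integers(0, min(n_group, n_events)))
        p = cohort.hypergeom_association(n_total, n_group, n_events, n_obs)
        assert p == pytest.approx(
            _brute_force_tail(n_total, n_group, n_events, n_obs))


class TestCohortSummary:
    def test_fixture_summary(self, patient_table):
        s = cohort.cohort_summary(patient_table)
        assert (s["n"], s["mean_age_years"], s["boys"], s["girls"]) == (
            26, 5.1, 20, 6)
        assert s["relapses"] == 4

    def test_single_row(self):
        df = pd.DataFrame([{"POND_id": "X", "Gender": "Male", "Age_years": 7,
                            "Outcome": "Alive", "Remission_days": 100}])
        assert cohort.cohort_summary(df)["mean_age_years"] == 7.0

    def test_missing_age_excluded_with_warning_count(self, patient_table):
        df = patient_table.copy()
        df.loc[0, "Age_years"] = np.nan
        s = cohort.cohort_summary(df)
        assert s["rows_excluded_missing_age"] == 1


class TestRelapseComparison:
    def test_table_verdicts(self, relapse_table):
        out = cohort.compare_relapse_patterns(relapse_table)
        assert {k: v.relation for k, v in out.items()} == {
            "SCMC-000206": "identical", "SCMC-000863": "identical",
            "SCMC-000966": "identical", "SCMC-001245": "shared_subset"}
        lost = sorted(j.chrom_pair() for j in out["SCMC-001245"].lost)
        assert lost == [("chr8", "chr12"), ("chr8", "chr21")]
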