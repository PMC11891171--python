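"""Deduplication rule, target-name matching and indication exclusion."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faersig import CohortConfig, deduplicate
from faersig.cohort import (build_cohort, exclude_indications, match_target,
                            normalize_name)

from conftest import frames_to_tables, tables_from_rows


def _demo(rows):
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    df["event_dt"] = ""
    df["age_yr"] = float("nan")
    df["sex"] = pd.NA
    df["wt_kg"] = float("nan")
    df["occp_cod"] = pd.NA
    df["reporter_country"] = pd.NA
    return df


CONFIG = CohortConfig(target_names=("trintellix", "vortioxetine"))


class TestDeduplicate:
    def test_most_recent_fda_dt_wins(self):
        res = deduplicate(_demo([("1", "X", "20230101"), ("2", "X", "20230301")]))
        assert list(res.survivors["primaryid"]) == ["2"]

    def test_highest_primaryid_breaks_date_ties(self):
        res = deduplicate(_demo([("5", "X", "20230301"), ("9", "X", "20230301")]))
        assert list(res.survivors["primaryid"]) == ["9"]

    def test_primaryid_compared_numerically_not_lexically(self):
        res = deduplicate(_demo([("9", "X", "20230301"), ("10", "X", "20230301")]))
        assert list(res.survivors["primaryid"]) == ["10"]

    def test_distinct_caseids_pass_through(self):
        demo = _demo([("1", "A", "20230101"), ("2", "B", "20230201")])
        res = deduplicate(demo)
        assert set(res.survivors["primaryid"]) == {"1", "2"}
        assert res.n_dropped_versions == 0

    def test_unparseable_fda_dt_excluded_and_counted(self):
        res = deduplicate(_demo([("1", "A", "garbage"), ("2", "B", "20230201")]))
        assert set(res.survivors["primaryid"]) == {"2"}
        assert res.n_excluded_unparseable == 1

    def test_partial_date_outranked_by_full_date_sibling(self):
        # the partial imputes to 20231231, but a fully dated sibling exists
        res = deduplicate(_demo([("3", "Y", "2023"), ("4", "Y", "20230115")]))
        assert list(res.survivors["primaryid"]) == ["4"]

    def test_partial_only_case_ordered_by_period_end(self):
        res = deduplicate(_demo([("7", "Z", "202302"), ("8", "Z", "2023")]))
        assert list(res.survivors["primaryid"]) == ["8"]  # 20231231 > 20230228

    def test_idempotent(self, base_frames):
        frames, _ = base_frames
        once = deduplicate(frames["demo"])
        twice = deduplicate(once.survivors)
        assert set(twice.survivors["primaryid"]) == set(once.survivors["primaryid"])
        assert twice.n_dropped_versions == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 30),            # caseid pool
                  st.integers(1, 99),            # primaryid
                  st.integers(0, 400)),          # day offset
        min_size=1, max_size=60))
    def test_one_survivor_per_case_maximizing_date_then_id(self, rows):
        seen = set()
        recs = []
        for case, pid, day in rows:
            if pid in seen:  # primaryids are globally unique in FAERS
                continue
            seen.add(pid)
            date = (pd.Timestamp("2022-01-01")
                    + pd.Timedelta(days=day)).strftime("%Y%m%d")
            recs.append((str(pid), f"C{case}", date))
        res = deduplicate(_demo(recs))
        by_case = {}
        for pid, case, date in recs:  # brute-force oracle
            key = (date, int(pid))
            if case not in by_case or key > by_case[case]:
                by_case[case] = key
        expected = {str(key[1]) for key in by_case.values()}
        assert set(res.survivors["primaryid"]) == expected


class TestMatchTarget:
    def _drug(self, drugname, prod_ai, role):
        return pd.DataFrame({
            "primaryid": ["1"], "caseid": ["c"], "drug_seq": [1],
            "role_cod": [role], "drugname": [drugname], "prod_ai": [prod_ai]})

    def test_generic_name_primary_suspect_matches(self):
        assert match_target(self._drug("TRINTELLIX", "", "PS"), CONFIG).all()

    def test_role_filter_excludes_secondary_suspect(self):
        assert not match_target(
            self._drug("x", "vortioxetine", "SS"), CONFIG).any()

    def test_substring_containment_catches_salt_forms(self):
        assert match_target(
            self._drug("vortioxetine hydrobromide", "", "PS"), CONFIG).all()
        assert match_target(
            self._drug("VORTIOXETINE HYDROBROMIDE 10MG", "", "PS"), CONFIG).all()

    def test_whitespace_and_case_normalized(self):
        assert normalize_name("  Trintellix   10 MG ") == "trintellix 10 mg"
        assert match_target(self._drug(" TRINTELLIX  ", "", "PS"), CONFIG).all()

    def test_unrelated_drug_does_not_match(self):
        assert not match_target(self._drug("SERTRALINE", "", "PS"), CONFIG).any()


class TestExcludeIndications:
    def _reac(self, pairs):
        return pd.DataFrame(pairs, columns=["primaryid", "pt"])

    def test_named_pt_removed_but_report_retained(self):
        cfg = CohortConfig(target_names=("x",),
                           indication_exclusion_pts=("depression",))
        res = exclude_indications(
            self._reac([("1", "nausea"), ("1", "Depression")]), cfg)
        assert list(res.reactions["pt"]) == ["nausea"]
        assert res.n_pairs_removed == 1 and res.n_reports_emptied == 0

    def test_empty_exclusion_list_is_identity(self):
        cfg = CohortConfig(target_names=("x",), indication_exclusion_pts=())
        reac = self._reac([("1", "nausea")])
        res = exclude_indications(reac, cfg)
        pd.testing.assert_frame_equal(res.reactions, reac)

    def test_fully_excluded_report_counted_and_counts_reconcile(self):
        cfg = CohortConfig(target_names=("x",),
                           indication_exclusion_pts=("depression",))
        reac = self._reac([("1", "depression"), ("2", "nausea"),
                           ("2", "depression")])
        res = exclude_indications(reac, cfg)
        assert res.n_reports_emptied == 1
        assert len(res.reactions) + res.n_pairs_removed == len(reac)
        assert res.removed_per_pt == {"depression": 2}


class TestBuildCohort:
    def test_filters_are_monotone_non_increasing(self, base_frames, base_config):
        frames, _ = base_frames
        cohort = build_cohort(frames_to_tables(frames), CohortConfig(
            target_names=base_config.target_drug_names))
        assert cohort.dedup.n_cases <= len(frames["demo"])
        assert cohort.size <= cohort.dedup.n_cases
        assert cohort.demo["caseid"].is_unique

    def test_bystander_roles_stay_out_of_cohort(self):
        tables = tables_from_rows(
            demo=[{"primaryid": "1", "caseid": "A", "fda_dt": "20230101"},
                  {"primaryid": "2", "caseid": "B", "fda_dt": "20230101"}],
            drug=[{"primaryid": "1", "caseid": "A", "drug_seq": 1,
                   "role_cod": "PS", "drugname": "TRINTELLIX", "prod_ai": ""},
                  {"primaryid": "2", "caseid": "B", "drug_seq": 1,
                   "role_cod": "C", "drugname": "TRINTELLIX", "prod_ai": ""}],
            reac=[{"primaryid": "1", "caseid": "A", "pt": "nausea"},
                  {"primaryid": "2", "caseid": "B", "pt": "nausea"}],
        )
        cohort = build_cohort(tables, CONFIG)
        assert list(cohort.demo["primaryid"]) == ["1"]
        assert list(cohort.comparator_reactions["primaryid"]) == ["2"]
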