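"""Deduplication, PT case selection, PS exposure, name/ATC/age handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faerspv as f
from faerspv.cli import packaged_table
from _oracles import dedup_oracle


def demo_frame(rows):
    """rows: (primaryid, caseid, fda_dt) with None allowed."""
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    for c in df.columns:
        df[c] = pd.array(df[c], dtype="Int64")
    return df


class TestDeduplicate:
    def test_single_record_retained(self):
        assert f.deduplicate(demo_frame([(1, 9, 20230101)])) == {1}

    def test_latest_date_then_highest_primaryid(self):
        retained = f.deduplicate(demo_frame([
            (1111, 111, 20230101), (1112, 111, 20230201), (1113, 111, 20230201)]))
        assert retained == {1113}

    def test_distinct_caseids_both_retained(self):
        assert f.deduplicate(demo_frame([(1, 9, 20230101), (2, 8, 20230101)])) == {1, 2}

    def test_dated_version_beats_undated(self):
        assert f.deduplicate(demo_frame([(5, 9, None), (4, 9, 20200101)])) == {4}

    def test_missing_caseid_is_singleton(self):
        assert f.deduplicate(demo_frame([(1, None, 20230101),
                                         (2, None, 20230101)])) == {1, 2}

    def test_idempotent_and_unique_on_random_clusters(self, rng):
        rows = self._random_rows(rng, 800)
        df = demo_frame(rows)
        retained = f.deduplicate(df)
        again = f.deduplicate(df[df["primaryid"].isin(retained)])
        assert again == retained
        kept = df[df["primaryid"].isin(retained)]
        with_case = kept[kept["caseid"].notna()]
        assert with_case["caseid"].is_unique
        assert len(retained) <= len(df)

    def test_agrees_with_brute_force_oracle(self, rng):
        for trial in range(20):
            rows = self._random_rows(rng, 120)
            got = f.deduplicate(demo_frame(rows))
            want = dedup_oracle([(p, c, t) for p, c, t in rows])
            assert got == want

    @staticmethod
    def _random_rows(rng, n):
        rows, pid = [], 1000
        while len(rows) < n:
            cid = int(rng.integers(1, n // 3 + 2))
            cid_val = None if rng.random() < 0.05 else cid
            dt = None if rng.random() < 0.1 else int(20200000 + rng.integers(1, 9999))
            pid += int(rng.integers(1, 5))
            rows.append((pid, cid_val, dt))
        return rows


class TestSelectCases:
    REAC = pd.DataFrame({
        "primaryid": [1, 1, 2, 3],
        "pt_name": ["Vitiligo", "Vitiligo", "Rash", "VITILIGO "],
        "pt_code": pd.array([10047642, 10047642, 10037844, None], dtype="Int64"),
    })

    def test_code_match(self):
        assert f.select_cases(self.REAC, {1, 2}, target_code=10047642) == {1}

    def test_repeated_pt_counts_once(self):
        got = f.select_cases(self.REAC, {1}, target_code=10047642)
        assert got == {1} and len(got) == 1

    def test_name_fallback_case_insensitive(self):
        got = f.select_cases(self.REAC, {1, 2, 3}, target_name="vitiligo")
        assert got == {1, 3}

    def test_empty_target_raises(self):
        with pytest.raises(ValueError):
            f.select_cases(self.REAC, {1}, None, None)

    def test_matches_linear_scan_oracle(self, rng):
        n = 500
        reac = pd.DataFrame({
            "primaryid": rng.integers(1, 200, n),
            "pt_name": rng.choice(["Vitiligo", "Rash", "Nausea"], n),
            "pt_code": pd.array(rng.choice([10047642, 10037844, 10028813], n),
                                dtype="Int64"),
        })
        retained = set(range(1, 150))
        got = f.select_cases(reac, retained, target_code=10047642)
        want = {int(p) for p, code in zip(reac["primaryid"], reac["pt_code"])
                if code == 10047642 and int(p) in retained}
        assert got == want


class TestPrimarySuspectExposures:
    def test_only_ps_rows_contribute(self):
        drug = pd.DataFrame({"primaryid": [1, 1, 1],
                             "role_cod": ["PS", "SS", "C"],
                             "drugname": ["A", "B", "C"]})
        assert f.primary_suspect_exposures(drug, {1}) == {1: ["A"]}

    def test_report_without_ps_maps_to_empty(self):
        drug = pd.DataFrame({"primaryid": [1], "role_cod": ["SS"], "drugname": ["B"]})
        assert f.primary_suspect_exposures(drug, {1, 2}) == {1: [], 2: []}

    def test_identical_ps_names_collapse(self):
        drug = pd.DataFrame({"primaryid": [1, 1], "role_cod": ["PS", "PS"],
                             "drugname": ["A", "A"]})
        assert f.primary_suspect_exposures(drug, {1}) == {1: ["A"]}

    def test_matches_filter_oracle(self, rng):
        n = 400
        drug = pd.DataFrame({
            "primaryid": rng.integers(1, 100, n),
            "role_cod": rng.choice(["PS", "SS", "C", "I"], n),
            "drugname": rng.choice(["A", "B", "C", "D"], n),
        })
        retained = set(range(1, 80))
        got = f.primary_suspect_exposures(drug, retained)
        assert set(got) == retained
        for pid in retained:
            want = []
            for p, r, d in zip(drug["primaryid"], drug["role_cod"], drug["drugname"]):
                if int(p) == pid and r == "PS" and d not in want:
                    want.append(d)
            assert got[pid] == want


class TestNormalizeNames:
    @pytest.fixture()
    def synmap(self):
        return f.SynonymMap({"OPDIVO": "nivolumab", "NIVOLUMAB": "nivolumab"})

    @pytest.mark.parametrize("verbatim, expected, mapped", [
        ("OPDIVO", "nivolumab", True),
        ("nivolumab", "nivolumab", True),          # generic is a fixed point
        ("  opdivo  40 MG ", "nivolumab", True),    # dose tokens stripped
        ("OPDIVO (INJECTION)", "nivolumab", True),  # trailing parenthetical
        ("UNKNOWNDRUG123", "UNKNOWNDRUG123", False),
    ])
    def test_lookup(self, synmap, verbatim, expected, mapped):
        assert f.normalize_name(verbatim, synmap) == (expected, mapped)

    def test_never_increases_distinct_names(self, synmap, rng):
        pool = ["OPDIVO", "Opdivo", "NIVOLUMAB 40 MG", "ASPIRIN", "aspirin "]
        names = list(rng.choice(pool, 50))
        out = [g for g, _ in f.normalize_names(names, synmap)]
        assert len(set(out)) <= len(set(names))


class TestAssignAtc:
    @pytest.fixture()
    def atcmap(self):
        return f.AtcMap.from_file(packaged_table("atc.tsv"))

    def test_nivolumab_is_antineoplastic(self, atcmap):
        group, code = f.assign_atc("nivolumab", atcmap)
        assert group == "Antineoplastic and immunomodulating agents"
        assert code.startswith("L")

    def test_imiquimod_is_dermatological(self, atcmap):
        assert f.assign_atc("imiquimod", atcmap)[0] == "Dermatologicals"

    def test_absent_name_is_unclassified(self, atcmap):
        assert f.assign_atc("notadrug", atcmap) == ("Unclassified", None)


class TestNormalizeAge:
    @pytest.mark.parametrize("age, unit, expected", [
        (5, "DEC", 50.0),
        (18, "MON", 1.5),
        (200, "YR", None),       # implausible -> unknown
        (54, None, 54.0),        # missing unit assumed years
        (2, "WK", 2 / 52.1775),
        (730.5, "DY", 2.0),
        (None, "YR", None),
    ])
    def test_units(self, age, unit, expected):
        got = f.normalize_age(age, unit)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestPipelineComposition:
    def test_dedup_before_or_after_selection_same_caseset(self, planted_bundle):
        """Duplicate versions repeat reactions, so the composition order of
        dedup and PT selection cannot change the final case set (up to the
        retained version identifier's case)."""
        retained = f.deduplicate(planted_bundle.demo)
        cases_a = f.select_cases(planted_bundle.reac, retained,
                                 target_code=10047642)
        all_pids = set(planted_bundle.demo["primaryid"].tolist())
        hits = f.select_cases(planted_bundle.reac, all_pids,
                              target_code=10047642)
        demo_hits = planted_bundle.demo[
            planted_bundle.demo["primaryid"].isin(hits)]
        cases_b = f.deduplicate(demo_hits)
        case_of = dict(zip(planted_bundle.demo["primaryid"],
                           planted_bundle.demo["caseid"]))
        assert {case_of[p] for p in cases_a} == {case_of[p] for p in cases_b}

    def test_flow_accounting_is_monotone(self, planted_bundle, planted_synmap):
        _, _, flow = f.build_caseset(planted_bundle, planted_synmap)
        assert (flow["cases_selected"] <= flow["reports_deduplicated"]
                <= flow["reports_parsed"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 50),            # caseid
                          st.integers(0, 30),            # date offset
                          st.booleans()),                # dated?
                min_size=1, max_size=40))
def test_dedup_oracle_property(entries):
    """Property: implementation equals brute-force (fda_dt, primaryid)-max."""
    rows = []
    for i, (cid, off, dated) in enumerate(entries):
        rows.append((1000 + i, cid, 20200101 + off if dated else None))
    assert f.deduplicate(demo_frame(rows)) == dedup_oracle(rows)
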