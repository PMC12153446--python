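"""Cohort screening: parsing, exclusion cascade, scoring, descriptives."""

import json

import numpy as np
import pandas as pd
import pytest

from symptomnet.screening import (
    ColumnMapError,
    ParticipantRecord,
    apply_exclusions,
    descriptives,
    flag_prevalences,
    parse_roster,
    score_scales,
)


def _record(id="r1", age=80.0, sex="female", living=2,
            gad=None, cesd=None):
    return ParticipantRecord(
        id=id, age=age, sex=sex, residence="rural",
        living_arrangement=living,
        gad_items=np.zeros(7) if gad is None else np.array(gad, float),
        cesd_items=np.zeros(10) if cesd is None else np.array(cesd, float),
    )


def _roster_csv(tmp_path, rows, name="roster.csv"):
    cols = (["id", "age", "sex", "residence", "living"]
            + [f"gad{i}" for i in range(1, 8)]
            + [f"cesd{i}" for i in range(1, 11)])
    path = tmp_path / name
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


class TestParseRoster:
    def test_well_formed_rows_parse_without_missing(self, tmp_path):
        rows = [[f"r{k}", 70 + k, "female", "rural", 2] + [1] * 17
                for k in range(3)]
        records = parse_roster(_roster_csv(tmp_path, rows))
        assert len(records) == 3
        assert all(r.n_items_missing == 0 for r in records)

    def test_out_of_range_code_becomes_missing_record_kept(self, tmp_path):
        row = ["r1", 70, "female", "rural", 2] + [1] * 17
        row[5] = 9  # gad1 out of range
        records = parse_roster(_roster_csv(tmp_path, [row]))
        assert len(records) == 1
        assert np.isnan(records[0].gad_items[0])
        assert records[0].n_items_missing == 1

    @pytest.mark.parametrize("sentinel", ["", "NA", ".", "-", "nan"])
    def test_sentinels_map_to_missing(self, tmp_path, sentinel):
        row = ["r1", 70, "female", "rural", 2] + [1] * 17
        row[6] = sentinel
        records = parse_roster(_roster_csv(tmp_path, [row]))
        assert np.isnan(records[0].gad_items[1])

    def test_missing_mandatory_column_raises_naming_it(self, tmp_path):
        cols = ["id", "age", "sex", "residence"] + \
            [f"gad{i}" for i in range(1, 8)] + [f"cesd{i}" for i in range(1, 11)]
        path = tmp_path / "bad.csv"
        pd.DataFrame([["r1", 70, "f", "rural"] + [1] * 17],
                     columns=cols).to_csv(path, index=False)
        with pytest.raises(ColumnMapError, match="living"):
            parse_roster(path)


class TestApplyExclusions:
    def test_complete_records_all_retained(self):
        records = [_record(id=f"r{k}") for k in range(10)]
        retained, report = apply_exclusions(records)
        assert len(retained) == 10
        assert report.n_final == 10
        assert report.n_excluded_demographic_or_incomplete == 0
        assert report.n_excluded_missing_gad == 0
        assert report.n_excluded_missing_cesd == 0

    def test_six_of_seventeen_missing_fails_stage1(self):
        gad = [np.nan] * 6 + [1]
        r = _record(gad=gad)
        retained, report = apply_exclusions([r])
        assert not retained
        assert report.n_excluded_demographic_or_incomplete == 1

    def test_five_missing_gad_items_fails_stage2_not_stage1(self):
        # 5/17 < 1/3 so stage 1 passes; missing GAD items reject at stage 2
        gad = [np.nan] * 5 + [1, 1]
        _, report = apply_exclusions([_record(gad=gad)])
        assert report.n_excluded_demographic_or_incomplete == 0
        assert report.n_excluded_missing_gad == 1

    def test_missing_cesd_only_fails_stage3(self):
        cesd = [np.nan] + [1] * 9
        _, report = apply_exclusions([_record(cesd=cesd)])
        assert report.n_excluded_missing_cesd == 1

    def test_stage_attribution_goes_to_first_rejecting_stage(self):
        # missing demographics AND missing GAD: counted at stage 1 only
        r = _record(age=float("nan"), gad=[np.nan] + [1] * 6)
        _, report = apply_exclusions([r])
        assert report.n_excluded_demographic_or_incomplete == 1
        assert report.n_excluded_missing_gad == 0

    def test_conservation_and_disjointness(self):
        rng = np.random.default_rng(3)
        records = []
        for k in range(200):
            gad = np.where(rng.random(7) < 0.2, np.nan, 1.0)
            cesd = np.where(rng.random(10) < 0.2, np.nan, 1.0)
            age = float("nan") if rng.random() < 0.1 else 80.0
            records.append(_record(id=f"r{k}", age=age, gad=gad, cesd=cesd))
        retained, rep = apply_exclusions(records)
        total = (rep.n_final + rep.n_excluded_demographic_or_incomplete
                 + rep.n_excluded_missing_gad + rep.n_excluded_missing_cesd)
        assert total == rep.n_initial == len(records)

    def test_idempotent_on_retained_set(self):
        rng = np.random.default_rng(4)
        records = [
            _record(id=f"r{k}",
                    gad=np.where(rng.random(7) < 0.3, np.nan, 1.0))
            for k in range(50)
        ]
        retained, _ = apply_exclusions(records)
        again, rep2 = apply_exclusions(retained)
        assert len(again) == len(retained)
        assert rep2.n_final == rep2.n_initial

    def test_non_alone_records_filtered_outside_stage_counts(self):
        records = [_record(id="a", living=2), _record(id="b", living=1)]
        retained, rep = apply_exclusions(records)
        assert rep.n_initial == 1
        assert [r.id for r in retained] == ["a"]
        assert rep.excluded_ids_by_stage["not_alone"] == ["b"]

    def test_empty_input_gives_zero_report(self):
        retained, rep = apply_exclusions([])
        assert retained == []
        assert rep.n_initial == rep.n_final == 0


class TestScoreScales:
    def test_maximum_totals(self):
        r = _record(gad=[3] * 7, cesd=[3] * 10)
        s = score_scales(r)
        assert s.gad_total == 21
        assert s.cesd_total == 30
        assert s.anxiety_flag and s.depressive_flag

    def test_minimum_totals_no_flags(self):
        s = score_scales(_record())
        assert s.gad_total == 0 and s.cesd_total == 0
        assert not s.anxiety_flag and not s.depressive_flag

    def test_gad_cutoff_boundary_at_five(self):
        s = score_scales(_record(gad=[1, 1, 1, 1, 1, 0, 0]))
        assert s.gad_total == 5
        assert s.anxiety_flag

    def test_cesd_cutoff_boundary(self):
        assert score_scales(_record(cesd=[1] * 10)).depressive_flag
        assert not score_scales(_record(cesd=[1] * 9 + [0])).depressive_flag

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            score_scales(_record(gad=[np.nan] + [1] * 6))

    def test_score_bounds_property(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            r = _record(gad=rng.integers(0, 4, 7),
                        cesd=rng.integers(0, 4, 10))
            s = score_scales(r)
            assert 0 <= s.gad_total <= 21
            assert 0 <= s.cesd_total <= 30


class TestDescriptives:
    def test_constant_item(self):
        recs = [_record(id=f"r{k}", gad=[2] * 7) for k in range(5)]
        d = descriptives(recs)
        assert d.loc["GAD1", "M"] == 2.0
        assert d.loc["GAD1", "SD"] == 0.0

    def test_two_value_sd_uses_n_minus_1(self):
        recs = [_record(id="a", gad=[0] * 7), _record(id="b", gad=[2] * 7)]
        d = descriptives(recs)
        assert d.loc["GAD1", "M"] == pytest.approx(1.0)
        assert d.loc["GAD1", "SD"] == pytest.approx(1.4142, abs=1e-4)

    def test_prevalence_percentage(self):
        # 263 anxiety-flagged of 1952 -> 13.47%
        flagged = [_record(id=f"f{k}", gad=[1, 1, 1, 1, 1, 0, 0])
                   for k in range(263)]
        rest = [_record(id=f"n{k}") for k in range(1952 - 263)]
        prev = flag_prevalences(flagged + rest)
        assert prev["anxiety_pct"] == pytest.approx(13.47, abs=0.005)
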