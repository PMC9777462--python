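"""Ingestion: long-format parsing, matrix building, ICD-10 labelling,
cohort filtering."""

import numpy as np
import pytest

from labsieve.records import (
    CohortLabels,
    LabRecord,
    SchemaError,
    UnitConflictError,
    build_matrix,
    filter_troponin_cohort,
    label_cases,
    parse_records,
    read_matrix,
    write_matrix,
)

HEADER = "case_id\tanalyte_id\tanalyte_name\tvalue\tunit\ttimestamp\n"


def _write(tmp_path, body, name="records.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestParseRecords:
    def test_toy_file_maps_fields(self, tmp_path):
        path = _write(
            tmp_path,
            "a\ttnt\tTroponin T\t12.5\tng/L\t1\n"
            "a\tk\tPotassium\t4.2\tmmol/L\t2\n"
            "b\ttnt\tTroponin T\t30\tng/L\t1\n",
        )
        recs = parse_records(path)
        assert len(recs) == 3
        assert recs[0] == LabRecord("a", "tnt", "Troponin T", 12.5, "ng/L", 1.0)
        assert recs[2].case_id == "b" and recs[2].value == 30.0

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert parse_records(path) == []

    def test_unparseable_numeric_value_is_skipped(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            "a\ttnt\tTroponin T\t12.5\tng/L\t1\n"
            "b\ttnt\tTroponin T\tabc\tng/L\t1\n",
        )
        with caplog.at_level("WARNING"):
            recs = parse_records(path)
        assert [r.case_id for r in recs] == ["a"]
        assert any("abc" in m for m in caplog.messages)

    def test_categorical_analyte_keeps_tokens(self, tmp_path):
        path = _write(
            tmp_path,
            "a\tcoll\tCollection\tarterial\t\t1\n"
            "b\tcoll\tCollection\tvenous\t\t1\n",
        )
        recs = parse_records(path)
        assert {r.value for r in recs} == {"arterial", "venous"}

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("case_id,analyte_id,value\na,tnt,1\n")
        with pytest.raises(SchemaError):
            parse_records(path)

    def test_comma_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "case_id,analyte_id,analyte_name,value,unit\na,tnt,TnT,5.5,ng/L\n"
        )
        recs = parse_records(path)
        assert recs[0].value == 5.5


class TestBuildMatrix:
    def _records(self):
        return [
            LabRecord("a", "tnt", "TnT", 12.0, "ng/L", timestamp=5.0),
            LabRecord("a", "tnt", "TnT", 99.0, "ng/L", timestamp=9.0),
            LabRecord("a", "k", "K", 4.0, "mmol/L", timestamp=1.0),
            LabRecord("b", "k", "K", 4.4, "mmol/L", timestamp=1.0),
            LabRecord("b", "crea", "Crea", 80.0, "µmol/L", timestamp=1.0),
        ]

    def test_first_by_timestamp_keeps_earlier_value(self):
        m = build_matrix(self._records(), dedup="first_by_timestamp")
        assert m.values[m.cases.index("a"), m.analytes.index("tnt")] == 12.0

    def test_last_and_mean_policies(self):
        recs = self._records()
        assert build_matrix(recs, dedup="last").column("tnt")[0] == 99.0
        assert build_matrix(recs, dedup="mean").column("tnt")[0] == pytest.approx(55.5)

    def test_missing_cells_masked(self):
        m = build_matrix(self._records())
        assert not m.observed_mask[m.cases.index("a"), m.analytes.index("crea")]
        assert np.isnan(m.values[m.cases.index("a"), m.analytes.index("crea")])

    def test_complete_records_give_full_mask(self):
        recs = [
            LabRecord(c, a, a, 1.0, "u", timestamp=1.0)
            for c in "ab" for a in ("x", "y")
        ]
        assert build_matrix(recs).observed_mask.all()

    def test_collection_tokens_encoded_binary(self):
        recs = [
            LabRecord("a", "coll", "Coll", "arterial", ""),
            LabRecord("b", "coll", "Coll", "venous", ""),
        ]
        m = build_matrix(recs)
        assert m.encoding_map["coll"] == {"arterial": 1, "venous": 0}
        assert m.column("coll").tolist() == [1.0, 0.0]

    def test_three_level_categorical_rejected(self):
        recs = [
            LabRecord(c, "coll", "Coll", tok, "")
            for c, tok in zip("abc", ("arterial", "venous", "capillary"))
        ]
        with pytest.raises(ValueError, match="levels"):
            build_matrix(recs)

    def test_conflicting_units_error_names_offender(self):
        recs = [
            LabRecord("a", "k", "K", 4.0, "mmol/L"),
            LabRecord("b", "k", "K", 4.0, "mEq/L"),
        ]
        with pytest.raises(UnitConflictError, match="k"):
            build_matrix(recs)

    def test_flattening_back_reproduces_retained_values(self):
        recs = self._records()
        m = build_matrix(recs)
        kept = {("a", "tnt"): 12.0, ("a", "k"): 4.0, ("b", "k"): 4.4, ("b", "crea"): 80.0}
        for (cid, aid), v in kept.items():
            assert m.values[m.cases.index(cid), m.analytes.index(aid)] == v


class TestLabelCases:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            (["I21.4", "E11.9"], 1),
            (["I25.90"], 1),  # upper boundary inclusive
            (["I20.0"], 1),  # lower boundary
            (["J18.9"], 0),
            ([], 0),
            ([" i21.4 "], 1),  # normalization: case and whitespace
        ],
    )
    def test_range_membership(self, codes, expected):
        labels = label_cases({"a": codes})
        assert labels.labels["a"] == expected

    def test_malformed_code_warns_and_does_not_match(self, caplog):
        with caplog.at_level("WARNING"):
            labels = label_cases({"a": ["2199", "I21.4"], "b": ["???"]})
        assert labels.labels == {"a": 1, "b": 0}
        assert any("malformed" in m for m in caplog.messages)

    def test_idempotent_and_order_insensitive(self):
        codes = ["E11.9", "I21.4", "j18.9"]
        first = label_cases({"a": codes}).labels
        assert first == label_cases({"a": codes[::-1]}).labels
        assert first == label_cases({"a": [c.upper() for c in codes]}).labels


class TestTroponinCohort:
    def test_keeps_exactly_observed_cases(self, toy_matrix, toy_labels):
        sub, sub_labels = filter_troponin_cohort(toy_matrix, toy_labels, "tnt")
        assert sub.cases == ["c0", "c2", "c4"]
        assert set(sub_labels.labels) == {"c0", "c2", "c4"}
        j = sub.analytes.index("tnt")
        assert sub.observed_mask[:, j].all()

    def test_fully_observed_is_identity(self, toy_matrix, toy_labels):
        sub, _ = filter_troponin_cohort(toy_matrix, toy_labels, "crea")
        assert sub.cases == toy_matrix.cases

    def test_no_observed_case_gives_empty_with_warning(self, toy_labels, caplog):
        import labsieve.records as R

        m = R.LabMatrix(
            values=np.full((2, 1), np.nan),
            observed_mask=np.zeros((2, 1), dtype=bool),
            cases=["c0", "c1"],
            analytes=["tnt"],
        )
        labels = CohortLabels({"c0": 0, "c1": 1})
        with caplog.at_level("WARNING"):
            sub, _ = filter_troponin_cohort(m, labels, "tnt")
        assert sub.n_cases == 0

    def test_absent_troponin_id_errors(self, toy_matrix, toy_labels):
        with pytest.raises(KeyError):
            filter_troponin_cohort(toy_matrix, toy_labels, "nope")


def test_matrix_round_trip_through_wide_file(tmp_path, toy_matrix):
    path = tmp_path / "matrix.tsv"
    write_matrix(toy_matrix, path)
    back = read_matrix(path)
    assert back.cases == toy_matrix.cases
    assert back.analytes == toy_matrix.analytes
    assert np.array_equal(back.observed_mask, toy_matrix.observed_mask)
    np.testing.assert_array_equal(
        back.values[back.observed_mask], toy_matrix.values[toy_matrix.observed_mask]
    )
    assert back.units == toy_matrix.units
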