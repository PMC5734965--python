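"""Canonicalization, pair-table I/O, the packaged table, and the sweep."""

import hashlib
from importlib import resources

import pytest

from lasamatch import (
    MatchParams,
    PairRecord,
    ValidationError,
    canonicalize,
    load_formulary,
    load_pairs,
    reference_pairs,
    reproduce_reference,
    write_pairs,
)
from lasamatch.dataset import REFERENCE_SHA256, convention_id


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("TINYPHEN®", "TINYPHEN"),
            ("ARY-TAC®", "ARYTAC"),
            ("OVUSTOP-H®", "OVUSTOPH"),
            ("Depo-Testosterone", "DEPOTESTOSTERONE"),
            ("A-VIGEL®", "AVIGEL"),
            ("B12 Plus", "BPLUS"),
        ],
    )
    def test_stripping_rules(self, raw, canonical):
        assert canonicalize(raw).text == canonical

    def test_idempotent(self):
        once = canonicalize("ARY-TAC®")
        assert canonicalize(once.text).text == once.text

    def test_raw_label_is_kept(self):
        assert canonicalize("ARY-TAC®").raw_label == "ARY-TAC®"

    @pytest.mark.parametrize("bad", ["", "1234", "®-/"])
    def test_letterless_labels_rejected(self, bad):
        with pytest.raises(ValidationError):
            canonicalize(bad)


class TestPairTableIO:
    def _records(self):
        return [
            PairRecord(1, "GEN A", "LOCAL-1®", "WORLD, ONE", "gen x", 70, "high"),
            PairRecord(2, "GEN B", "LOCAL2®", "WORLDTWO", "", None, "high"),
        ]

    @pytest.mark.parametrize("delimiter", [",", "\t"])
    def test_round_trip_is_lossless(self, tmp_path, delimiter):
        ext = "tsv" if delimiter == "\t" else "csv"
        path = tmp_path / f"pairs.{ext}"
        write_pairs(path, self._records(), delimiter=delimiter,
                    header_comments=["written by a test"])
        assert load_pairs(path) == self._records()

    def test_blank_match_cell_is_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "row_id,local_proprietary,overseas_similar,match_percent\n1,A,B,\n",
            encoding="utf-8",
        )
        (rec,) = load_pairs(path)
        assert rec.printed_match_percent is None

    def test_unparseable_match_cites_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "row_id,local_proprietary,overseas_similar,match_percent\n"
            "1,A,B,70\n2,C,D,abc\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="row 3"):
            load_pairs(path)

    def test_missing_required_columns(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("row_id,generic_name\n1,A\n", encoding="utf-8")
        with pytest.raises(ValidationError, match="overseas_similar"):
            load_pairs(path)

    def test_duplicate_row_ids_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "row_id,local_proprietary,overseas_similar\n1,A,B\n1,C,D\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_pairs(path)

    def test_formulary_with_comments(self, tmp_path):
        path = tmp_path / "formulary.txt"
        path.write_text("# header\nLOPROX\n\nAXAR  # inline note\n", encoding="utf-8")
        assert load_formulary(path) == ["LOPROX", "AXAR"]

    def test_empty_formulary_is_an_error(self, tmp_path):
        path = tmp_path / "formulary.txt"
        path.write_text("# only a comment\n", encoding="utf-8")
        with pytest.raises(ValidationError):
            load_formulary(path)


class TestReferenceTable:
    def test_has_100_records(self, reference):
        assert len(reference) == 100
        assert [r.row_id for r in reference] == list(range(1, 101))

    def test_known_row(self, reference):
        rec = reference[1]
        assert rec.local_proprietary == "TINYPHEN®"
        assert rec.overseas_similar == "SINIPHEN"
        assert rec.printed_match_percent == 70
        assert rec.printed_risk == "high"

    def test_exactly_one_row_without_a_value(self, reference):
        missing = [r for r in reference if r.printed_match_percent is None]
        assert len(missing) == 1
        assert missing[0].row_id == 1
        assert missing[0].printed_risk == "high"

    def test_checksum_pinned(self):
        data = resources.files("lasamatch").joinpath("data", "reference_pairs.tsv").read_bytes()
        assert hashlib.sha256(data).hexdigest() == REFERENCE_SHA256
        reference_pairs(verify_checksum=True)

    def test_every_name_canonicalizes(self, reference):
        for rec in reference:
            a, b = rec.names
            assert a.length >= 3 and b.length >= 3


class TestReproductionSweep:
    def test_report_covers_rows_times_conventions(self, reference):
        grid = [MatchParams(), MatchParams(end_markers=False)]
        report = reproduce_reference(grid, records=reference[:10])
        scored_rows = sum(1 for r in reference[:10] if r.printed_match_percent is not None)
        assert len(report.scores) == scored_rows * len(grid)
        assert set(report.convention_summary["convention"]) == {
            convention_id(g) for g in grid
        }

    def test_calibrated_convention_hits_known_row_exactly(self, reference):
        report = reproduce_reference([MatchParams()], records=reference[:5])
        row = report.scores[report.scores.row_id == 2].iloc[0]
        assert row.printed == 70
        assert row.abs_deviation == 0

    def test_identity_control_scores_100_under_any_convention(self):
        control = PairRecord(1, "CTRL", "LOPRAX", "LOPRAX", "", 100, "high")
        grid = [
            MatchParams(),
            MatchParams(end_markers=False, denominator_mode="mean"),
            MatchParams(word_role="second_name", binding_mode="optimal"),
        ]
        report = reproduce_reference(grid, records=[control])
        assert (report.scores.computed_percent == 100.0).all()
        assert (report.scores.abs_deviation == 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            reproduce_reference([])
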