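"""Unit tests for position encoding, binding, peak finding and match values."""

import math

import pytest

from lasamatch import (
    CanonicalName,
    MatchParams,
    ValidationError,
    bind_letters,
    encode,
    find_peak,
    match_value,
)

from oracles import grid_peak


def name(text: str) -> CanonicalName:
    return CanonicalName.from_text(text)


class TestEncode:
    @pytest.mark.parametrize(
        "text, series, values",
        [
            ("CAT", "descending_unit", [3.0, 2.0, 1.0]),
            ("A", "descending_unit", [1.0]),
            ("AA", "descending_unit", [2.0, 1.0]),
            ("CAT", "ascending_unit", [-1.0, -2.0, -3.0]),
        ],
    )
    def test_series_values(self, text, series, values):
        code = encode(name(text), series)
        assert [t.value for t in code.tokens] == values

    def test_occurrence_indexing(self):
        code = encode(name("AA"))
        assert [(t.token.letter, t.token.occurrence) for t in code.tokens] == [
            ("A", 1),
            ("A", 2),
        ]

    def test_one_token_per_letter_and_descending(self):
        code = encode(name("SINIPHEN"))
        assert code.length == 8
        vals = [t.value for t in code.tokens]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError, match="BAD-LABEL"):
            CanonicalName.from_text("", raw_label="BAD-LABEL")

    def test_unknown_series_rejected(self):
        with pytest.raises(ValidationError):
            encode(name("CAT"), "unit_descending")


class TestBindLetters:
    def test_identity_all_zero(self):
        code = encode(name("ABC"))
        res = bind_letters(code, encode(name("ABC")), end_markers=False)
        assert [p.d for p in res.bound] == [0.0, 0.0, 0.0]
        assert res.unbound_word_tokens == ()
        assert res.l_i == 3

    def test_shared_suffix_constant_offset(self):
        # CIPLEX vs IPLEX: the five suffix letters align at a constant
        # ordinal offset, so all bound differences are identical
        res = bind_letters(encode(name("CIPLEX")), encode(name("IPLEX")), end_markers=False)
        assert [p.letter for p in res.bound] == ["I", "P", "L", "E", "X"]
        ds = {p.d for p in res.bound}
        assert len(ds) == 1
        assert [t.letter for t in res.unbound_word_tokens] == ["C"]
        assert res.l_i == 6

    def test_repeated_letter_in_order(self):
        # word SINIPHEN has two Is; input TINYPHEN has one: the second I
        # and the S stay unbound, six tokens bind at d = 0
        res = bind_letters(encode(name("SINIPHEN")), encode(name("TINYPHEN")), end_markers=False)
        assert [p.letter for p in res.bound] == ["I", "N", "P", "H", "E", "N"]
        assert all(p.d == 0.0 for p in res.bound)
        assert {(t.letter, t.occurrence) for t in res.unbound_word_tokens} == {
            ("S", 1),
            ("I", 2),
        }

    def test_end_markers_add_channels_and_count(self):
        res = bind_letters(encode(name("TINYPHEN")), encode(name("SINIPHEN")), end_markers=True)
        # first letters differ, last letters agree: one marker channel
        assert res.marker_differences == (0.0,)
        assert res.l_i == 10

    def test_no_input_token_bound_twice(self):
        res = bind_letters(encode(name("AABA")), encode(name("ABAA")), mode="optimal")
        seen = [p.input_position for p in res.bound]
        assert len(seen) == len(set(seen))

    def test_optimal_no_worse_than_in_order(self):
        word, inp = encode(name("ABCABC")), encode(name("CABCAB"))
        for markers in (True, False):
            res_in = bind_letters(word, inp, "in_order", markers)
            res_opt = bind_letters(word, inp, "optimal", markers)
            f_in = find_peak(res_in.centers, 3.0)[1]
            f_opt = find_peak(res_opt.centers, 3.0)[1]
            assert f_opt >= f_in - 1e-9


class TestFindPeak:
    def test_single_gaussian_peaks_at_center(self):
        assert find_peak([0.0], 3.0) == (0.0, 1.0)
        x, f = find_peak([2.5], 0.7)
        assert (x, f) == (2.5, 1.0)

    def test_two_centers_symmetric(self):
        x, f = find_peak([0.0, 1.0], 3.0)
        assert x == pytest.approx(0.5, abs=1e-6)
        assert f == pytest.approx(2 * math.exp(-1 / 12), abs=1e-9)

    def test_weighted_cluster(self):
        x, f = find_peak([0, 0, 0, 1, 1, 1, 1], 3.0)
        assert f == pytest.approx(6.4534, abs=1e-4)
        _, f_oracle = grid_peak([0, 0, 0, 1, 1, 1, 1], 3.0)
        assert f == pytest.approx(f_oracle, abs=1e-6)

    def test_empty_centers(self):
        assert find_peak([], 3.0) == (0.0, 0.0)

    def test_invalid_sigma(self):
        for sigma in (0.0, -1.0, math.nan):
            with pytest.raises(ValidationError):
                find_peak([0.0], sigma)

    def test_tie_breaks_to_smallest_x(self):
        # two well-separated equal Gaussians: two equal maxima, report the left
        x, _ = find_peak([0.0, 10.0], 0.5)
        assert x == pytest.approx(0.0, abs=1e-6)


class TestMatchValue:
    def test_identity_is_exactly_one(self):
        n = name("LOPRAX")
        for markers in (True, False):
            for mode in ("word", "input", "longer", "shorter", "mean"):
                params = MatchParams(end_markers=markers, denominator_mode=mode)
                assert match_value(n, n, params).value == 1.0

    def test_one_substitution_markers_off(self, markers_off):
        score = match_value(name("ABC"), name("ABD"), markers_off)
        assert score.value == pytest.approx(2 / 3, abs=1e-12)

    def test_calibrated_reference_row_is_exact(self):
        # TINYPHEN vs SINIPHEN: six letters and the final-letter channel all
        # at d = 0, peak 7, denominator 8 + 2
        score = match_value(name("TINYPHEN"), name("SINIPHEN"))
        assert score.percent == pytest.approx(70.0, abs=1e-9)
        assert score.profile.f_star == pytest.approx(7.0, abs=1e-9)
        assert score.l_i == 10

    def test_word_role_selects_the_stored_word(self):
        a, b = name("FARALEX"), name("FARMALEX")
        first = match_value(a, b, MatchParams(word_role="first_name"))
        second = match_value(a, b, MatchParams(word_role="second_name"))
        swapped = match_value(b, a, MatchParams(word_role="first_name"))
        assert second.value == pytest.approx(swapped.value, abs=1e-12)
        assert first.value != pytest.approx(second.value, abs=1e-6)

    def test_denominator_modes(self):
        a, b = name("FARALEX"), name("FARMALEX")  # lengths 7 and 8
        peak = match_value(a, b).profile.f_star
        expect = {"word": 9.0, "input": 10.0, "longer": 10.0, "shorter": 9.0, "mean": 9.5}
        for mode, denom in expect.items():
            s = match_value(a, b, MatchParams(denominator_mode=mode))
            assert s.value == pytest.approx(peak / denom, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            MatchParams(sigma=-3)
        with pytest.raises(ValidationError):
            MatchParams(denominator_mode="both")
        with pytest.raises(ValidationError):
            MatchParams(word_role="left")
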