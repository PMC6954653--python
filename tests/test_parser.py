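"""ISCN parsing: tokenization, event grammar, base inference, round-trips."""

import pytest

from karyokit import EventKind, canonical_iscn, parse
from karyokit.model import Level, chromosome_count
from karyokit.parser import (
    ConsistencyError,
    ParseError,
    StructureError,
    UnsupportedEventError,
    ValidationError,
    parse_event,
    tokenize,
)


class TestTokenize:
    def test_splits_on_top_level_commas_only(self):
        p = tokenize("46,XY,del(15)(q11q12)")
        assert (p.declared_total, p.sex_field) == (46, "XY")
        assert p.raw_event_fields == ("del(15)(q11q12)",)

    def test_embedded_whitespace_is_insignificant(self):
        p = tokenize("45, X,-Y")
        assert (p.declared_total, p.sex_field, p.raw_event_fields) == (45, "X", ("-Y",))

    def test_commas_inside_parentheses_belong_to_the_group(self):
        # hypothetical dialect with comma-separated groups stays one field
        p = tokenize("46,XX,t(2;5)(q21;q31)")
        assert len(p.raw_event_fields) == 1

    @pytest.mark.parametrize("bad", ["abc", "", "  ", "46", "xy,XX", "46,ZZ"])
    def test_malformed_designations_raise(self, bad):
        with pytest.raises(ParseError):
            tokenize(bad)

    @pytest.mark.parametrize("bad", ["46,XX/47,XX,+21", "46,XX,?del(1)(p31)", "45~48,XY"])
    def test_unsupported_dialect_is_rejected_not_guessed(self, bad):
        with pytest.raises(ParseError, match="unsupported|not an integer"):
            tokenize(bad)


class TestParseEvent:
    def test_interstitial_deletion(self, band_map):
        e = parse_event("del(15)(q11q12)", band_map)
        assert e.kind is EventKind.DELETION and e.level is Level.BAND
        assert [str(b) for b in e.breakpoints] == ["15q11", "15q12"]

    def test_whole_chromosome_loss(self, band_map):
        e = parse_event("-Y", band_map)
        assert e.kind is EventKind.DELETION and e.level is Level.CHROMOSOME
        assert e.delta == -1 and str(e.chromosomes[0]) == "Y"

    def test_translocation_breakpoints_map_to_their_chromosomes(self, band_map):
        e = parse_event("t(2;5)(q21;q31)", band_map)
        assert {str(b) for b in e.breakpoints} == {"2q21", "5q31"}

    def test_nonexistent_band_is_a_validation_error(self, band_map):
        with pytest.raises(ValidationError):
            parse_event("del(15)(q99q12)", band_map)

    def test_unknown_abbreviation(self, band_map):
        with pytest.raises(UnsupportedEventError):
            parse_event("foo(1)(p31)", band_map)

    def test_arity_mismatch(self, band_map):
        with pytest.raises(StructureError):
            parse_event("t(2)(q21)", band_map)

    def test_derivative_holds_constituents(self, band_map):
        e = parse_event("der(1)t(1;3)(p22;q13)", band_map)
        assert e.kind is EventKind.DERIVATIVE
        assert len(e.constituents) == 1
        assert e.constituents[0].kind is EventKind.TRANSLOCATION

    ALL_KINDS = {
        EventKind.ADDITION: "add(1)(p31)",
        EventKind.DELETION: "del(1)(p31p21)",
        EventKind.DERIVATIVE: "der(1)t(1;3)(p22;q13)",
        EventKind.DICENTRIC: "dic(13;15)(q11;q11)",
        EventKind.DUPLICATION: "dup(1)(q21q31)",
        EventKind.FISSION: "fis(1)(q11)",
        EventKind.FRAGILE_SITE: "fra(X)(q27)",
        EventKind.HSR: "hsr(1)(p31)",
        EventKind.INSERTION: "ins(5)(q13q21q23)",
        EventKind.INVERSION: "inv(3)(p21q21)",
        EventKind.ISOCHROMOSOME: "i(17)(q11)",
        EventKind.MARKER: "+mar",
        EventKind.NEOCENTROMERE: "neo(1)(q32)",
        EventKind.QUADRUPLICATION: "qdp(1)(q21q31)",
        EventKind.RING: "r(1)(p36q44)",
        EventKind.TELOMERIC_ASSOCIATION: "tas(12;14)(q24;q32)",
        EventKind.TRANSLOCATION: "t(2;5)(q21;q31)",
        EventKind.TRICENTRIC: "trc(2;3;4)(q21;q21;q21)",
        EventKind.TRIPLICATION: "trp(1)(q21q31)",
    }

    @pytest.mark.parametrize("kind", list(EventKind), ids=lambda k: k.abbreviation)
    def test_every_event_kind_is_parsable(self, band_map, kind):
        e = parse_event(self.ALL_KINDS[kind], band_map)
        assert e.kind is kind

    def test_no_parse_result_references_a_nonexistent_band(self, band_map):
        for spec in self.ALL_KINDS.values():
            e = parse_event(spec, band_map)
            assert all(band_map.band_exists(str(b)) for b in e.breakpoints)


class TestParse:
    def test_normal_male_has_no_events(self, band_map):
        k = parse("46,XY", band_map)
        assert (k.base.ploidy, k.base.sex_complement, k.events) == (2, "XY", ())

    def test_loss_of_y_derives_from_male_base(self, band_map):
        k = parse("45,X,-Y", band_map)
        assert k.base.sex_complement == "XY"
        assert len(k.events) == 1 and chromosome_count(k) == 45

    def test_trisomy_21_derives_from_female_base(self, band_map):
        k = parse("47,XX,+21", band_map)
        assert k.base.sex_complement == "XX"
        assert chromosome_count(k) == 47

    def test_unknown_sex_base_is_accepted(self, band_map):
        k = parse("46,XN", band_map)
        assert k.base.sex_complement == "XN"

    def test_count_mismatch_is_a_consistency_error(self, band_map):
        with pytest.raises(ConsistencyError):
            parse("46,XY,-5", band_map)

    def test_repeated_identical_fields_accumulate(self, band_map):
        k = parse("48,XX,+21,+21", band_map)
        assert len(k.events) == 1 and k.events[0].multiplicity == 2
        assert chromosome_count(k) == 48


class TestCanonical:
    @pytest.mark.parametrize(
        "text,canon",
        [
            ("45, X,-Y", "45,X,-Y"),
            ("46,XY", "46,XY"),
            ("48 , XX, +21,+21", "48,XX,+21,+21"),
            ("45,X", "45,X"),
        ],
    )
    def test_normalization(self, band_map, text, canon):
        assert canonical_iscn(parse(text, band_map)) == canon

    def test_parse_canonical_parse_is_idempotent(self, band_map, sample_karyotypes):
        for k in sample_karyotypes:
            s = canonical_iscn(k)
            k2 = parse(s, band_map)
            assert canonical_iscn(k2) == s
            assert k2 == k
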