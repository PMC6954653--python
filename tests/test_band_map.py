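"""Band partonomy: existence, containment, ordering and interval queries."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from karyokit.band_map import (
    BandLabel,
    BandMapError,
    DomainError,
    UnknownBandError,
    load_band_map,
)

HEADER = "chromosome\tarm\tband\tparent\tresolutions\n"


def minimal_table(rows):
    body = "".join("\t".join(r) + "\n" for r in rows)
    return HEADER + body


class TestLoading:
    def test_packaged_map_covers_all_24_chromosome_types(self, band_map):
        assert len(band_map.chromosomes) == 24
        labels = {c.label for c in band_map.chromosomes}
        assert labels == {str(i) for i in range(1, 23)} | {"X", "Y"}

    def test_every_chromosome_has_p_and_q_bands(self, band_map):
        for c in band_map.chromosomes:
            arms = {e.label.arm for e in band_map.bands_of(c)}
            assert arms == {"p", "q"}, c

    def test_duplicate_band_rejected(self):
        text = minimal_table(
            [("1", "p", "36", "", "300"), ("1", "p", "36", "", "300"),
             ("1", "q", "11", "", "300")]
        )
        with pytest.raises(BandMapError, match="duplicate"):
            load_band_map(text)

    def test_child_before_parent_rejected(self):
        text = minimal_table(
            [("1", "p", "36.1", "36", "550"), ("1", "p", "36", "", "300"),
             ("1", "q", "11", "", "300")]
        )
        with pytest.raises(BandMapError, match="before parent"):
            load_band_map(text)

    def test_missing_arm_rejected(self):
        text = minimal_table([("1", "p", "36", "", "300")])
        with pytest.raises(BandMapError, match="p and q"):
            load_band_map(text)


class TestExistence:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("1p35", True),        # the partonomy's worked example band
            ("1p99", False),
            ("17q21.1", True),     # dotted sub-band
            ("17q21.31", True),
            ("X", True),           # bare chromosome
            ("15q", True),         # bare arm
            ("25p11", False),
            ("garbage", False),
            ("", False),
        ],
    )
    def test_band_exists(self, band_map, label, expected):
        assert band_map.band_exists(label) is expected


class TestPartonomy:
    def test_17q21_sub_bands_are_prefixed_and_ordered(self, band_map):
        subs = band_map.sub_bands("17q21")
        assert len(subs) >= 2
        assert all(str(s).startswith("17q21.") for s in subs)
        assert all(band_map.band_exists(str(s)) for s in subs)
        idx = [band_map.entry(s).order_index for s in subs]
        assert idx == sorted(idx)

    def test_leaf_band_has_no_sub_bands(self, band_map):
        assert band_map.sub_bands("1p36") == []

    def test_unknown_band_raises(self, band_map):
        with pytest.raises(UnknownBandError):
            band_map.sub_bands("1p99")


class TestResolution:
    @pytest.mark.parametrize(
        "band,res,expected",
        [
            ("1p36", 300, True),
            ("1p36", 850, True),     # visibility is cumulative toward finer levels
            ("17q21.31", 300, False),
            ("17q21.31", 550, True),
            ("17q21.31", 850, True),
        ],
    )
    def test_seen_at_resolution(self, band_map, band, res, expected):
        assert band_map.seen_at_resolution(band, res) is expected


class TestOrdering:
    def test_chr1_p_arm_order_pter_to_cen(self, band_map):
        expected = ["1p36", "1p35", "1p34", "1p33", "1p32", "1p31",
                    "1p22", "1p21", "1p13", "1p12", "1p11"]
        assert [str(e.label) for e in band_map.bands_of("1", "p")] == expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("1p31", "1p21", -1),  # p numbers decrease toward the centromere
            ("1p22", "1p22", 0),
            ("15q11", "15q12", -1),
            ("15q12", "15q11", 1),
            ("1p11", "1q11", -1),  # p-arm precedes q-arm across the centromere
        ],
    )
    def test_compare_bands(self, band_map, a, b, expected):
        assert band_map.compare_bands(a, b) == expected

    def test_compare_across_chromosomes_is_a_domain_error(self, band_map):
        with pytest.raises(DomainError):
            band_map.compare_bands("1p31", "2p21")

    def test_compare_is_a_strict_total_order_per_chromosome(self, band_map):
        for chrom in ("1", "17"):
            seq = band_map.traversal(chrom)
            for a, b in itertools.combinations(seq, 2):
                assert band_map.compare_bands(a, b) == -band_map.compare_bands(b, a)
            for a, b, c in itertools.combinations(seq, 3):
                if band_map.compare_bands(a, b) < 0 and band_map.compare_bands(b, c) < 0:
                    assert band_map.compare_bands(a, c) < 0


class TestIntervals:
    def test_exactly_1p22_lies_between_1p31_and_1p21(self, band_map):
        assert [str(x) for x in band_map.bands_between("1p31", "1p21")] == [
            "1p31", "1p22", "1p21"
        ]

    def test_1p34_to_1p32_covers_1p33(self, band_map):
        assert [str(x) for x in band_map.bands_between("1p34", "1p32")] == [
            "1p34", "1p33", "1p32"
        ]

    def test_degenerate_interval(self, band_map):
        assert [str(x) for x in band_map.bands_between("1p22", "1p22")] == ["1p22"]

    def test_interval_may_span_the_centromere(self, band_map):
        bands = [str(x) for x in band_map.bands_between("3p21", "3q21")]
        assert bands[0] == "3p21" and bands[-1] == "3q21"
        assert "3p11" in bands and "3q11" in bands

    def test_symmetric_in_endpoints_exhaustively(self, band_map):
        for chrom in ("1", "15", "17", "21", "X", "Y"):
            seq = band_map.traversal(chrom)
            for a, b in itertools.combinations(seq, 2):
                assert band_map.bands_between(a, b) == band_map.bands_between(b, a)

    def test_adjacent_pairs_have_two_element_intervals(self, band_map):
        for chrom in ("1", "15", "17"):
            seq = band_map.traversal(chrom)
            for a, b in zip(seq, seq[1:]):
                assert len(band_map.bands_between(a, b)) == 2

    def test_parent_endpoint_expands_to_visible_descendants(self, band_map):
        bands = [str(x) for x in band_map.bands_between("17q21", "17q22")]
        assert bands == ["17q21.1", "17q21.2", "17q21.31", "17q21.32",
                         "17q21.33", "17q22"]

    def test_coarse_resolution_keeps_parent_band(self, band_map):
        bands = [str(x) for x in band_map.bands_between("17q21", "17q22", res=300)]
        assert bands == ["17q21", "17q22"]

    def test_different_chromosomes_is_a_domain_error(self, band_map):
        with pytest.raises(DomainError):
            band_map.bands_between("1p31", "2p21")


@settings(deadline=None, derandomize=True, max_examples=200)
@given(data=st.data())
def test_interval_properties_on_random_band_pairs(band_map, data):
    """For any same-chromosome pair: the interval is symmetric, includes both
    endpoints, and its length matches their order distance."""
    chrom = data.draw(st.sampled_from([c.label for c in band_map.chromosomes]))
    seq = band_map.traversal(chrom)
    a = data.draw(st.sampled_from(seq))
    b = data.draw(st.sampled_from(seq))
    interval = band_map.bands_between(a, b)
    assert interval == band_map.bands_between(b, a)
    assert a in interval and b in interval
    assert len(interval) == abs(seq.index(a) - seq.index(b)) + 1


def test_band_label_parsing_roundtrip():
    lbl = BandLabel.parse("17q21.31")
    assert (str(lbl.chromosome), lbl.arm, lbl.designation) == ("17", "q", "21.31")
    assert str(lbl) == "17q21.31"
    assert lbl.parent_designation == "21"
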