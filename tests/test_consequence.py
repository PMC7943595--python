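"""Frame-aware SNV classification: categories, enumerations, strand symmetry."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uorfsel.consequence import (
    classify_orf_snv,
    classify_start_snv,
    classify_variants,
    csc_direction,
    exclude_cds_overlap,
    find_potential_stop_positions,
    find_start_disrupting_positions,
    find_utr_stop_creating_positions,
    stop_strength,
)
from uorfsel.genomic_model import (
    RNA_STOPS,
    SENSE_CODONS,
    CscTable,
    UtrAnnotation,
    translate_codon,
)

from conftest import make_orf, variant_for


def oracle_category(ref_codon: str, alt_codon: str, codon_index: int) -> str:
    """Brute-force category from the genetic code and the stop hierarchy only."""
    strength = {"UGA": 1, "UAG": 2, "UAA": 3}
    nug = {"AUG", "CUG", "GUG", "UUG"}
    if codon_index == 0:
        return "start_maintain" if alt_codon in nug else "start_disrupt"
    if ref_codon in strength and alt_codon in strength:
        return (
            "stop_strengthen"
            if strength[alt_codon] > strength[ref_codon]
            else "stop_weaken"
        )
    if ref_codon in strength:
        return "stop_loss"
    if alt_codon in strength:
        return "stop_gain"
    aa = lambda c: translate_codon(c)  # noqa: E731
    return "synonymous" if aa(ref_codon) == aa(alt_codon) else "missense"


def all_substitutions(codon):
    for off in range(3):
        for b in "ACGU":
            if b != codon[off]:
                yield off, b, codon[:off] + b + codon[off + 1 :]


class TestStopStrength:
    def test_hierarchy(self):
        assert stop_strength("UAA") == 3  # strongest terminator
        assert stop_strength("UAG") == 2
        assert stop_strength("UGA") == 1  # weakest, read-through prone
        assert stop_strength("UAG") > stop_strength("UGA")

    def test_sense_codon_rejected(self):
        with pytest.raises(ValueError, match="not a stop"):
            stop_strength("UGG")


class TestCodonChangeExamples:
    """The canonical single-codon substitutions, checked end to end."""

    @pytest.mark.parametrize(
        "ref_codon, tidx_in_codon, alt, category, new_stop",
        [
            ("UGG", 1, "A", "stop_gain", "UAG"),  # Trp -> amber UTC
            ("UGA", 1, "A", "stop_strengthen", "UAA"),  # opal -> ochre
            ("UAG", 2, "A", "stop_strengthen", "UAA"),  # amber -> ochre
            ("CAA", 0, "U", "stop_gain", "UAA"),  # Gln -> ochre UTC
            ("UAC", 2, "A", "stop_gain", "UAA"),  # Tyr -> ochre UTC
            ("AAA", 2, "G", "synonymous", None),  # Lys -> Lys
            ("AAA", 0, "G", "missense", None),  # Lys -> Glu
            ("UAA", 1, "G", "stop_weaken", None),  # ochre -> opal
            ("UAA", 0, "C", "stop_loss", None),  # ochre -> Gln
        ],
    )
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_middle_codon_substitutions(
        self, ref_codon, tidx_in_codon, alt, category, new_stop, strand
    ):
        orf = make_orf("AUG" + ref_codon + "UAA", strand=strand, orf_class="lncRNA")
        v = variant_for(orf, 3 + tidx_in_codon, alt)
        call = classify_orf_snv(orf, v)
        assert call.category == category
        assert call.new_stop == new_stop
        assert call.codon_index == 1
        assert call.codon_offset == tidx_in_codon
        assert call.ref_codon == ref_codon

    def test_terminal_stop_strengthen(self):
        """A UGA-terminated uORF strengthened to UAA at its own stop codon."""
        orf = make_orf("AUGAAAUGA")
        call = classify_orf_snv(orf, variant_for(orf, 7, "A"))
        assert call.category == "stop_strengthen"
        assert call.new_stop == "UAA"

    def test_indel_rejected(self):
        orf = make_orf("AUGAAAUAA")
        v = variant_for(orf, 3, "A")
        v.ref = "AT"
        with pytest.raises(ValueError, match="SNV only"):
            classify_orf_snv(orf, v)


class TestStartCodonRules:
    @pytest.mark.parametrize(
        "start, tidx, alt, expected",
        [
            ("CUG", 0, "A", "start_maintain"),  # CUG -> AUG keeps NUG
            ("AUG", 1, "C", "start_disrupt"),  # AUG -> ACG
            ("GUG", 2, "A", "start_disrupt"),  # GUG -> GUA
            ("AUG", 0, "U", "start_maintain"),  # AUG -> UUG
        ],
    )
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_nug_rules(self, start, tidx, alt, expected, strand):
        orf = make_orf(start + "AAAUAA", strand=strand)
        assert classify_start_snv(orf, variant_for(orf, tidx, alt)) == expected

    def test_non_first_codon_rejected(self):
        orf = make_orf("AUGAAAUAA")
        with pytest.raises(ValueError, match="first codon"):
            classify_start_snv(orf, variant_for(orf, 4, "C"))

    def test_every_uorf_has_two_in_frame_disrupting_positions(self):
        orf = make_orf("CUGCCAAAAUAA", cds_start_distance=7)
        pos = find_start_disrupting_positions(orf, in_frame=True)
        assert len(pos) == 2
        gpos = orf.genomic_positions()
        assert {p.pos for p in pos} == {int(gpos[1]), int(gpos[2])}

    def test_out_of_frame_nug_control_set(self):
        # internal AUG at transcript index 4 (out of frame)
        orf = make_orf("CUGCAUGAAUAA")
        ctrl = find_start_disrupting_positions(orf, in_frame=False)
        gpos = orf.genomic_positions()
        assert {p.pos for p in ctrl} == {int(gpos[5]), int(gpos[6])}

    def test_no_internal_nug_empty_control(self):
        orf = make_orf("CUGCCCAAAUAA")
        assert find_start_disrupting_positions(orf, in_frame=False) == []


@pytest.fixture(scope="module")
def table():
    csc = {c: 0.0 for c in SENSE_CODONS}
    csc["AAA"], csc["AAG"] = 0.1, -0.2
    return CscTable(csc)


class TestCscDirection:

    def test_decreasing(self, table):
        assert csc_direction("AAA", "AAG", table) == "decreasing"

    def test_increasing(self, table):
        assert csc_direction("AAG", "AAA", table) == "increasing"

    def test_neutral_and_na(self, table):
        assert csc_direction("CCC", "CCA", table) == "neutral"
        assert csc_direction("UGG", "UGA", table) == "n/a"
        assert csc_direction("UAA", "CAA", table) == "n/a"


class TestOracleEquivalence:
    def test_all_64x9_substitutions_match_oracle(self):
        """Category assignment agrees with the brute-force oracle everywhere."""
        codons = ["".join(c) for c in itertools.product("UCAG", repeat=3)]
        assert len(codons) == 64
        checked = 0
        for codon in codons:
            orf = make_orf("AUG" + codon + "UAA", orf_class="lncRNA")
            for off, b, alt_codon in all_substitutions(codon):
                call = classify_orf_snv(orf, variant_for(orf, 3 + off, b))
                assert call.category == oracle_category(codon, alt_codon, 1), (
                    codon,
                    alt_codon,
                )
                checked += 1
        assert checked == 64 * 9

    def test_first_codon_oracle(self):
        for start in ("AUG", "CUG", "GUG", "UUG"):
            orf = make_orf(start + "AAAUAA")
            for off, b, alt_codon in all_substitutions(start):
                call = classify_orf_snv(orf, variant_for(orf, off, b))
                assert call.category == oracle_category(start, alt_codon, 0)

    @settings(max_examples=40, deadline=None)
    @given(
        body=st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=6),
        start=st.sampled_from(["AUG", "CUG", "GUG", "UUG"]),
        stop=st.sampled_from(list(RNA_STOPS)),
        data=st.data(),
    )
    def test_strand_mirror_invariance(self, body, start, stop, data):
        """A minus-strand variant classifies as its plus-strand mirror."""
        seq = start + "".join(body) + stop
        tidx = data.draw(st.integers(0, len(seq) - 1))
        alt = data.draw(st.sampled_from([b for b in "ACGU" if b != seq[tidx]]))
        plus = make_orf(seq, strand="+")
        minus = make_orf(seq, strand="-")
        call_p = classify_orf_snv(plus, variant_for(plus, tidx, alt))
        call_m = classify_orf_snv(minus, variant_for(minus, tidx, alt))
        assert call_p.category == call_m.category
        assert call_p.alt_codon == call_m.alt_codon
        assert call_p.codon_index == call_m.codon_index

    def test_categories_partition_all_possible_snvs(self):
        """Every one of the 9L possible SNVs gets exactly one category."""
        orf = make_orf("CUGUGGAAAUCAUGA")
        n_calls = 0
        for tidx in range(orf.length):
            for b in "ACGU":
                if b == orf.spliced_sequence[tidx]:
                    continue
                call = classify_orf_snv(orf, variant_for(orf, tidx, b))
                assert call.category in {
                    "stop_gain",
                    "stop_strengthen",
                    "stop_weaken",
                    "stop_loss",
                    "start_disrupt",
                    "start_maintain",
                    "missense",
                    "synonymous",
                }
                n_calls += 1
        assert n_calls == 9 * orf.n_codons


class TestPotentialStopPositions:
    def brute_force(self, orf):
        """Positions where classify_orf_snv emits stop_gain for some alt."""
        hits = {}
        for tidx in range(orf.length):
            for b in "ACGU":
                if b == orf.spliced_sequence[tidx]:
                    continue
                call = classify_orf_snv(orf, variant_for(orf, tidx, b))
                if call.category == "stop_gain":
                    gpos = int(orf.genomic_positions()[tidx])
                    hits.setdefault(gpos, set()).add(call.alt_codon)
        return hits

    @pytest.mark.parametrize(
        "codon, expected",
        [
            ("UGG", {1: {"UAG"}, 2: {"UGA"}}),
            ("AAA", {0: {"UAA"}}),
            ("UCA", {1: {"UGA", "UAA"}}),  # multi-stop position
        ],
    )
    def test_known_codons(self, codon, expected):
        orf = make_orf("AUG" + codon + "UAA", orf_class="lncRNA")
        found = {
            p.pos: set(p.achievable_stops)
            for p in find_potential_stop_positions(orf)
            if 3 <= orf.transcript_index(p.pos) < 6
        }
        gpos = orf.genomic_positions()
        assert found == {int(gpos[3 + off]): stops for off, stops in expected.items()}

    def test_multi_flag(self):
        orf = make_orf("AUGUCAUAA", orf_class="lncRNA")
        multi = [p for p in find_potential_stop_positions(orf) if p.is_multi]
        assert len(multi) == 1
        assert multi[0].achievable_stops == {"UGA", "UAA"}

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_classifier_cross_module(self, strand):
        """Enumeration equals the classifier's stop_gain positions exactly."""
        orf = make_orf("CUGUGGAGCAAAUAUUUGUGA", strand=strand)
        enumerated = {
            p.pos: set(p.achievable_stops) for p in find_potential_stop_positions(orf)
        }
        assert enumerated == self.brute_force(orf)

    def test_terminal_stop_excluded(self):
        orf = make_orf("AUGUAA", orf_class="lncRNA")  # single sense codon + stop
        positions = find_potential_stop_positions(orf)
        gpos = orf.genomic_positions()
        assert all(orf.transcript_index(p.pos) < 3 for p in positions)

    def test_distance_windows(self):
        orf = make_orf("AUGAAAUAA", cds_start_distance=25)
        by_tidx = {
            orf.transcript_index(p.pos): p for p in find_potential_stop_positions(orf)
        }
        # base at transcript index 3 is length-1-3 = 5 nt from the 3' end
        assert by_tidx[3].distance_to_cds == 25 + 5
        assert by_tidx[3].distance_window == 3


class TestCdsOverlapExclusion:
    def _calls(self):
        orf = make_orf("AUGAAAUAA", start=100)
        return [classify_orf_snv(orf, variant_for(orf, i, "C")) for i in (3, 4)]

    def test_no_overlap_identity(self):
        calls = self._calls()
        assert exclude_cds_overlap(calls, [("chr1", 500, 600)]) == calls

    def test_overlap_removed(self):
        calls = self._calls()  # variants at genomic 103, 104
        kept = exclude_cds_overlap(calls, [("chr1", 103, 104)])
        assert [c.variant.pos0 for c in kept] == [104]

    def test_half_open_boundary_retained(self):
        calls = self._calls()
        kept = exclude_cds_overlap(calls, [("chr1", 100, 103)])  # end == 103
        assert [c.variant.pos0 for c in kept] == [103, 104]


class TestUtrControlEnumeration:
    def test_any_frame_scan_matches_naive(self):
        seq = "CCUGACCUAAGGUAGCC"
        utr = UtrAnnotation("tx", "chr1", "+", [(0, len(seq))], seq)
        found = {p.pos for p in find_utr_stop_creating_positions(utr)}
        naive = set()
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            for off in range(3):
                for b in "ACGU":
                    if b == tri[off]:
                        continue
                    if tri[:off] + b + tri[off + 1 :] in RNA_STOPS:
                        naive.add(i + off)
        assert found == naive

    def test_orf_positions_excluded(self):
        seq = "CCUGACCUAAGG"
        utr = UtrAnnotation("tx", "chr1", "+", [(0, len(seq))], seq)
        all_pos = {p.pos for p in find_utr_stop_creating_positions(utr)}
        masked = {
            p.pos
            for p in find_utr_stop_creating_positions(
                utr, exclude_orf_positions=all_pos
            )
        }
        assert masked == set()


def test_dedup_keeps_most_severe_call():
    """A variant inside two overlapping ORFs is counted once, at max severity."""
    # same genomic interval carries two frames: orf_b shifted by 3
    orf_a = make_orf("AUGUGGAAAUAA", start=100, orf_id="a")
    orf_b = make_orf("UGGAAAUAAUAA", start=103, orf_id="b", orf_class="lncRNA")
    v = variant_for(orf_a, 4, "A")  # UGG->UAG stop_gain in a; same base in b
    calls = classify_variants([orf_a, orf_b], [v], dedup=True)
    assert len(calls) == 1
    assert calls[0].category == "stop_gain"
    undup = classify_variants([orf_a, orf_b], [v], dedup=False)
    assert len(undup) == 2
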