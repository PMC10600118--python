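"""Cut-site geometry and allele construction."""

import pytest
from hypothesis import given, settings, strategies as st

from delinver import (
    CutSite,
    GuideTarget,
    apply_deletion,
    apply_indel,
    apply_inversion,
    build_diploid,
    compute_cut_site,
    genotype_label,
    map_inverted_coordinate,
    reverse_complement,
    wildtype_allele,
)
from delinver.errors import GeometryError, ParameterError

TOY = "AAAATGCCGGGG"

dna = st.text(alphabet="ACGT", min_size=30, max_size=120)


def _guide(proto="A" * 20, strand="+", start=100, nuclease="SpCas9"):
    pam = "AGG" if nuclease == "SpCas9" else "TTTA"
    if nuclease == "LbCpf1":
        proto = "A" * 23
    return GuideTarget("g", proto, pam, strand, start, nuclease)


class TestCutSites:
    def test_spcas9_plus_strand_cuts_3bp_from_pam(self):
        # protospacer [100,120), PAM [120,123): blunt cut at 117
        cs = compute_cut_site(_guide(strand="+", start=100))
        assert cs == CutSite(117, 117) and cs.blunt

    def test_spcas9_minus_strand_mirrors_the_rule(self):
        # PAM [100,103), protospacer [103,123) on the - strand: cut at 106
        cs = compute_cut_site(_guide(strand="-", start=103))
        assert cs == CutSite(106, 106)

    def test_minus_strand_equals_revcomp_oracle(self):
        # oracle: reverse-complement the axis, apply the + strand rule, mirror back
        n = 500
        start = 103
        cs = compute_cut_site(_guide(strand="-", start=start))
        mirrored_start = n - (start + 20)  # protospacer start on the rc axis
        plus_cut = mirrored_start + 17
        assert cs.top_cut == n - plus_cut

    @pytest.mark.parametrize("overhang", [4, 5])
    def test_lbcpf1_staggered_overhang(self, overhang):
        cs = compute_cut_site(_guide(nuclease="LbCpf1"), overhang=overhang)
        assert cs.overhang == overhang and not cs.blunt
        # 5' overhang distal to the TTTV PAM: nicks after positions 18 / 18+overhang
        assert cs.top_cut == 100 + 18
        assert cs.bottom_cut == 100 + 18 + overhang

    def test_lbcpf1_minus_strand_mirrors(self):
        cs = compute_cut_site(_guide(nuclease="LbCpf1", strand="-"), overhang=5)
        assert cs.overhang == 5
        assert cs.bottom_cut == 100 + 23 - 18

    def test_bad_overhang_and_nuclease(self):
        with pytest.raises(ParameterError):
            compute_cut_site(_guide(nuclease="LbCpf1"), overhang=3)
        with pytest.raises(ParameterError):
            GuideTarget("g", "A" * 20, "AGG", "+", 0, "Cas13")


class TestDeletionInversion:
    def test_blunt_deletion_joins_flanks(self):
        allele = apply_deletion(TOY, CutSite(4, 4), CutSite(8, 8))
        assert allele.sequence == "AAAAGGGG"
        assert allele.allele_class == "DELETION"
        assert allele.breakpoints == (4, 8)

    def test_blunt_inversion_reverse_complements_segment(self):
        allele = apply_inversion(TOY, CutSite(4, 4), CutSite(8, 8))
        assert allele.sequence == "AAAAGGCAGGGG"  # revcomp("TGCC") == "GGCA"
        assert len(allele.sequence) == len(TOY)

    def test_inversion_is_an_involution(self):
        c1, c2 = CutSite(4, 4), CutSite(8, 8)
        once = apply_inversion(TOY, c1, c2)
        twice = apply_inversion(once.sequence, c1, c2)
        assert twice.sequence == TOY

    def test_deletion_length_identity_at_reported_scale(self, demo_assay):
        c1, c2 = demo_assay["cuts"]
        ref = demo_assay["locus"].sequence
        assert c2.top_cut - c1.top_cut == 5500
        allele = apply_deletion(ref, c1, c2)
        assert len(allele.sequence) == len(ref) - 5500

    def test_deletion_and_inversion_share_left_flank(self, demo_assay):
        c1, c2 = demo_assay["cuts"]
        ref = demo_assay["locus"].sequence
        d = apply_deletion(ref, c1, c2)
        v = apply_inversion(ref, c1, c2)
        assert d.sequence[: c1.top_cut] == v.sequence[: c1.top_cut] == ref[: c1.top_cut]

    def test_staggered_fill_in_vs_trim_differ_by_total_overhang(self):
        ref = "ACGTAC" * 5  # 30 bp
        c1, c2 = CutSite(5, 10), CutSite(18, 23)  # two 5-nt overhangs
        # a deletion has one junction (10 nt difference); an inversion has two
        filled = apply_deletion(ref, c1, c2, mode="fill_in")
        trimmed = apply_deletion(ref, c1, c2, mode="trim")
        assert len(filled.sequence) - len(trimmed.sequence) == 10
        filled = apply_inversion(ref, c1, c2, mode="fill_in")
        trimmed = apply_inversion(ref, c1, c2, mode="trim")
        assert len(filled.sequence) - len(trimmed.sequence) == 20

    def test_perfect_mode_requires_blunt_cuts(self):
        with pytest.raises(ParameterError):
            apply_deletion("A" * 40, CutSite(5, 10), CutSite(20, 25), mode="perfect")

    def test_overlapping_cut_windows_rejected(self):
        with pytest.raises(GeometryError):
            apply_deletion(TOY, CutSite(6, 6), CutSite(4, 4))

    def test_inverted_coordinate_map_reflects_through_segment(self):
        c1, c2 = CutSite(4, 4), CutSite(8, 8)
        assert map_inverted_coordinate(5, c1, c2) == 7
        assert map_inverted_coordinate(6, c1, c2) == 6
        with pytest.raises(GeometryError):
            map_inverted_coordinate(20, c1, c2)

    def test_junctions_recorded_at_breakpoints(self):
        allele = apply_inversion(TOY, CutSite(4, 4), CutSite(8, 8))
        positions = [p for p, _ in allele.junctions]
        assert positions == [4, 8]


@settings(max_examples=50, deadline=None)
@given(dna, st.data())
def test_inversion_involution_property(seq, data):
    c1 = data.draw(st.integers(1, len(seq) // 2 - 1))
    c2 = data.draw(st.integers(c1 + 1, len(seq) - 1))
    once = apply_inversion(seq, CutSite(c1, c1), CutSite(c2, c2))
    assert len(once.sequence) == len(seq)
    twice = apply_inversion(once.sequence, CutSite(c1, c1), CutSite(c2, c2))
    assert twice.sequence == seq


@settings(max_examples=50, deadline=None)
@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


class TestIndelsAndDiploids:
    def test_insertion_and_deletion_change_length(self):
        cut = CutSite(6, 6)
        plus1 = apply_indel(TOY, cut, +1, "T")
        assert len(plus1.sequence) == len(TOY) + 1
        minus2 = apply_indel(TOY, cut, -2)
        assert len(minus2.sequence) == len(TOY) - 2
        assert plus1.allele_class == minus2.allele_class == "INDEL"

    def test_zero_indel_returns_wildtype(self):
        allele = apply_indel(TOY, CutSite(6, 6), 0)
        assert allele.allele_class == "WT" and allele.sequence == TOY

    def test_indel_bounds(self):
        with pytest.raises(ParameterError):
            apply_indel(TOY, CutSite(6, 6), 30)
        with pytest.raises(GeometryError):
            apply_indel(TOY, CutSite(10, 10), -5)
        with pytest.raises(ParameterError):
            apply_indel(TOY, CutSite(6, 6), +2, "A")

    def test_diploid_labels_and_symmetry(self, demo_assay):
        a = demo_assay["alleles"]
        assert build_diploid(a["D"], a["V"]).class_label == "DV"
        assert build_diploid(a["V"], a["D"]).class_label == "DV"
        assert build_diploid(a["D"], a["D"]).class_label == "DD"
        indel = apply_indel(demo_assay["locus"].sequence, demo_assay["cuts"][0], 1, "A")
        assert build_diploid(indel, a["W"]).class_label == "WW"  # indels class as W

    def test_genotype_label_ordering(self):
        assert genotype_label("V", "W") == "WV"
        assert genotype_label("D", "W") == "WD"
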