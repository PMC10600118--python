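"""Primer scheme design and in-silico PCR."""

import pytest
from hypothesis import given, settings, strategies as st

from delinver import (
    Primer,
    SimLocusConfig,
    apply_deletion,
    apply_inversion,
    build_diploid,
    cut_pair,
    design_tier_scheme,
    generate_locus,
    insilico_pcr,
    place_guide_pair,
    predict_band_pattern,
    reverse_complement,
    wildtype_allele,
)
from delinver.errors import DesignInfeasibleError


def brute_force_pcr(template, primer_a, primer_b, max_len):
    """Independent oracle: enumerate every substring position of both primers
    on both strands and test every site pair for convergence."""
    spans = []
    for p in (primer_a, primer_b):
        for i in range(len(template) - len(p) + 1):
            window = template[i : i + len(p)]
            if window == p.sequence:
                spans.append((i, "fwd", len(p)))
            if reverse_complement(window) == p.sequence:
                spans.append((i, "rev", len(p)))
    amplicons = set()
    for fi, fdir, flen in spans:
        for ri, rdir, rlen in spans:
            if fdir != "fwd" or rdir != "rev":
                continue
            if fi <= ri and (ri + rlen) - fi <= max_len:
                amplicons.add((fi, ri + rlen))
    return amplicons


class TestDesign:
    def test_scheme_exists_for_18kb_segment(self):
        cfg = SimLocusConfig(n_genes=6, gene_length=2500, intergenic_length=1200,
                             flank_length=2000, seed=21)
        locus = generate_locus(cfg)
        locus, gl, gr = place_guide_pair(locus, 1700, 1700 + 18200, seed=21)
        c1, c2 = cut_pair(gl, gr)
        scheme = design_tier_scheme(locus, c1, c2, max_amplicon_len=3000)
        assert scheme.fw1.ref_start + 20 <= c1.left_end - 50
        assert scheme.rev1.ref_start >= c2.right_end + 50
        assert c1.right_end + 50 <= scheme.rev2.ref_start

    def test_short_segment_is_infeasible(self):
        cfg = SimLocusConfig(n_genes=1, gene_length=1000, flank_length=3000, seed=22)
        locus = generate_locus(cfg)
        locus, gl, gr = place_guide_pair(locus, 2500, 4500, seed=22)
        c1, c2 = cut_pair(gl, gr)
        with pytest.raises(DesignInfeasibleError):
            design_tier_scheme(locus, c1, c2, max_amplicon_len=3000)

    def test_rev2_flips_to_face_rev1_on_inversion(self, demo_assay):
        scheme = demo_assay["scheme"]
        wt = demo_assay["alleles"]["W"]
        inv = demo_assay["alleles"]["V"]
        assert scheme.rev2.orientation == "reverse"
        assert insilico_pcr(wt, scheme.rev1, scheme.rev2, scheme.max_amplicon_len) == []
        amps = insilico_pcr(inv, scheme.rev1, scheme.rev2, scheme.max_amplicon_len)
        assert len(amps) == 1


class TestInsilicoPCR:
    def test_deletion_amplicon_size_by_coordinate_arithmetic(self, demo_assay):
        scheme = demo_assay["scheme"]
        c1, c2 = demo_assay["cuts"]
        deln = demo_assay["alleles"]["D"]
        amps = insilico_pcr(deln, scheme.fw1, scheme.rev1, scheme.max_amplicon_len)
        assert len(amps) == 1
        expected = (c1.top_cut - scheme.fw1.ref_start) + (scheme.rev1.ref_start + 20 - c2.top_cut)
        assert amps[0].length == expected

    def test_matches_brute_force_oracle_on_all_alleles(self, demo_assay):
        scheme = demo_assay["scheme"]
        pairs = list(scheme.tiers.values())
        for allele in demo_assay["alleles"].values():
            for pa, pb in pairs:
                got = {(a.start, a.end) for a in
                       insilico_pcr(allele, pa, pb, scheme.max_amplicon_len)}
                want = brute_force_pcr(allele.sequence, pa, pb, scheme.max_amplicon_len)
                assert got == want

    def test_diploid_template_pools_both_alleles(self, demo_assay):
        scheme = demo_assay["scheme"]
        a = demo_assay["alleles"]
        dv = build_diploid(a["D"], a["V"])
        amps = insilico_pcr(dv, scheme.fw1, scheme.rev1, scheme.max_amplicon_len)
        assert len(amps) == 1  # only the deletion allele yields a tier-1 product

    def test_revcomp_template_mirrors_amplicons(self, demo_assay):
        scheme = demo_assay["scheme"]
        deln = demo_assay["alleles"]["D"].sequence
        fwd = insilico_pcr(deln, scheme.fw1, scheme.rev1, scheme.max_amplicon_len)
        rc = insilico_pcr(reverse_complement(deln), scheme.fw1, scheme.rev1,
                          scheme.max_amplicon_len)
        n = len(deln)
        assert {(n - a.end, n - a.start) for a in rc} == {(a.start, a.end) for a in fwd}
        assert {a.sequence for a in rc} == {reverse_complement(a.sequence) for a in fwd}


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet="ACGT", min_size=60, max_size=200), st.data())
def test_pcr_oracle_equivalence_on_random_templates(seq, data):
    """Exhaustive-oracle agreement on arbitrary templates with implanted sites."""
    i = data.draw(st.integers(0, len(seq) - 40))
    j = data.draw(st.integers(i + 10, len(seq) - 10))
    pa = Primer("a", seq[i : i + 10], i, "forward")
    pb = Primer("b", reverse_complement(seq[j : j + 10]), j, "reverse")
    for max_len in (30, len(seq)):
        got = {(a.start, a.end) for a in insilico_pcr(seq, pa, pb, max_len)}
        assert got == brute_force_pcr(seq, pa, pb, max_len)


class TestBandPatterns:
    def test_published_truth_table_rows(self, demo_assay):
        """WT (-,+,-); het deletion (+,+,-); hom deletion (+,-,-); delinver (+,-,+)."""
        scheme = demo_assay["scheme"]
        a = demo_assay["alleles"]
        expected = {
            ("W", "W"): (False, True, False),
            ("W", "D"): (True, True, False),
            ("D", "D"): (True, False, False),
            ("D", "V"): (True, False, True),
        }
        for (x, y), tiers in expected.items():
            bp = predict_band_pattern([a[x], a[y]], scheme)
            assert bp.tiers == tiers, (x, y)

    def test_all_six_diploid_classes_have_distinct_patterns(self, demo_assay):
        scheme = demo_assay["scheme"]
        a = demo_assay["alleles"]
        patterns = {}
        for label in ("WW", "WD", "WV", "DD", "DV", "VV"):
            bp = predict_band_pattern([a[label[0]], a[label[1]]], scheme)
            patterns[label] = bp.tiers
        assert len(set(patterns.values())) == 6
        # tiers 1-2 only: the collapse that causes delinver misidentification
        two_tier = {label: t[:2] for label, t in patterns.items()}
        assert two_tier["WW"] == two_tier["WV"]
        assert two_tier["DD"] == two_tier["DV"]

    def test_staggered_cut_delinver_detected_under_both_chemistries(self):
        """An LbCpf1 (staggered-break) assay still resolves the delinver
        bi-allele, whichever junction chemistry produced it."""
        from delinver import SimLocusConfig, apply_deletion, apply_inversion
        from delinver import call_genotype, generate_locus, place_guide_pair
        cfg = SimLocusConfig(n_genes=3, gene_length=1500, intergenic_length=600,
                             flank_length=2000, seed=51)
        locus = generate_locus(cfg)
        locus, gl, gr = place_guide_pair(locus, 1700, 7200, nuclease="LbCpf1", seed=51)
        c1, c2 = cut_pair(gl, gr)
        assert c1.overhang == 5 and c2.overhang == 5
        scheme = design_tier_scheme(locus, c1, c2)
        ref = locus.sequence
        for mode in ("trim", "fill_in"):
            d = apply_deletion(ref, c1, c2, mode)
            v = apply_inversion(ref, c1, c2, mode)
            bp = predict_band_pattern([d, v], scheme)
            assert bp.tiers == (True, False, True)
            assert call_genotype(bp).calls == {"DV"}

    def test_amplicons_respect_length_ceiling(self, demo_assay):
        scheme = demo_assay["scheme"]
        for allele in demo_assay["alleles"].values():
            bp = predict_band_pattern([allele, allele], scheme)
            for sizes in bp.amplicon_sizes:
                assert all(s <= scheme.max_amplicon_len for s in sizes)
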