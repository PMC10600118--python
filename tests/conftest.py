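import pytest

from delinver import (
    SimLocusConfig,
    apply_deletion,
    apply_inversion,
    cut_pair,
    design_tier_scheme,
    generate_locus,
    place_guide_pair,
    wildtype_allele,
)


@pytest.fixture(scope="session")
def demo_assay():
    """A 9.7-kb synthetic 3-gene locus with a 5.5-kb excisable segment, its
    guide pair, cut sites, designed tier scheme, and one allele per class."""
    cfg = SimLocusConfig(n_genes=3, gene_length=1500, intergenic_length=600,
                         flank_length=2000, seed=11, name="demo")
    locus = generate_locus(cfg)
    locus, g_left, g_right = place_guide_pair(locus, 1700, 7200, seed=11)
    cut1, cut2 = cut_pair(g_left, g_right)
    scheme = design_tier_scheme(locus, cut1, cut2)
    ref = locus.sequence
    alleles = {
        "W": wildtype_allele(ref),
        "D": apply_deletion(ref, cut1, cut2),
        "V": apply_inversion(ref, cut1, cut2),
    }
    return {
        "locus": locus,
        "guides": (g_left, g_right),
        "cuts": (cut1, cut2),
        "scheme": scheme,
        "alleles": alleles,
    }
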