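"""Three-tier genotyping primer design and orientation-aware in-silico PCR.

The scheme distinguishes a homozygous segment deletion from a
deletion-inversion bi-allele with three reactions:

* tier 1 (Fw1 + Rev1): primers flanking the segment; a product appears only
  when the segment is gone (the wild-type distance exceeds what the
  polymerase can amplify).
* tier 2 (Fw1 + Rev2): Rev2 sits inside the segment near the left cut; a
  product reports an intact, correctly oriented left end.
* tier 3 (Rev1 + Rev2): two co-aligned primers that both point leftward on
  the wild-type map. They can never amplify the wild-type arrangement, but an
  inversion carries Rev2's site to the right cut in flipped orientation,
  where it faces Rev1 and yields a short product.

Primer binding is exact-match (no mismatch or thermodynamic model): scheme
validity is positional. All primers keep an ``indel_margin`` distance from
the cut sites, which documents the scheme's deliberate blindness to small
repair indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .editing import (
    Allele,
    CutSite,
    DiploidGenotype,
    apply_deletion,
    apply_inversion,
    wildtype_allele,
)
from .errors import DesignError, DesignInfeasibleError, ParameterError
from .locus import Locus
from .seqio import reverse_complement

DEFAULT_PRIMER_LEN = 20
#: stands in for the extension-time ceiling of a genotyping polymerase
DEFAULT_MAX_AMPLICON = 3000
DEFAULT_INDEL_MARGIN = 50
DEFAULT_SEARCH_WINDOW = 500


@dataclass(frozen=True)
class Primer:
    """A genotyping primer anchored on the reference + strand.

    ``forward`` primers equal the + strand at ``[ref_start, ref_start+len)``
    and extend rightward; ``reverse`` primers are the reverse complement of
    that window and extend leftward.
    """

    name: str
    sequence: str
    ref_start: int
    orientation: Literal["forward", "reverse"]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    sequence: str
    primer_pair: tuple[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BandPattern:
    """Presence/absence of a product in each tier, with observed sizes."""

    tier1: bool
    tier2: bool
    tier3: bool
    amplicon_sizes: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]] = ((), (), ())

    @property
    def tiers(self) -> tuple[bool, bool, bool]:
        return (self.tier1, self.tier2, self.tier3)


@dataclass(frozen=True)
class TierScheme:
    """The named primers and amplicon-length contract of the three-tier assay."""

    fw1: Primer
    rev1: Primer
    rev2: Primer
    fw2: Primer | None
    max_amplicon_len: int
    cut1: CutSite
    cut2: CutSite

    @property
    def tiers(self) -> dict[int, tuple[Primer, Primer]]:
        return {1: (self.fw1, self.rev1), 2: (self.fw1, self.rev2), 3: (self.rev1, self.rev2)}

    def primer_table(self):
        prims = [self.fw1, self.rev1, self.rev2] + ([self.fw2] if self.fw2 else [])
        return [(p.name, p.sequence, p.ref_start, p.orientation) for p in prims]


def _count_occurrences(haystack: str, needle: str) -> int:
    count = pos = 0
    while (pos := haystack.find(needle, pos)) != -1:
        count += 1
        pos += 1
    return count


def _unique_in(sequence: str, window_seq: str) -> bool:
    """A primer is unique if its footprint occurs once across both strands."""
    n = _count_occurrences(sequence, window_seq)
    rc = reverse_complement(window_seq)
    n += _count_occurrences(sequence, rc)
    if window_seq == rc:  # palindromic footprint counted twice
        n //= 2
    return n == 1


def _scan(sequence: str, starts: Iterable[int], primer_len: int) -> int:
    for s in starts:
        if s < 0 or s + primer_len > len(sequence):
            continue
        if _unique_in(sequence, sequence[s : s + primer_len]):
            return s
    raise DesignError("no unique primer footprint in search window")


def _make_primer(name: str, sequence: str, start: int, primer_len: int,
                 orientation: str) -> Primer:
    window = sequence[start : start + primer_len]
    seq = window if orientation == "forward" else reverse_complement(window)
    return Primer(name, seq, start, orientation)  # type: ignore[arg-type]


def design_tier_scheme(
    locus: Locus,
    cut1: CutSite,
    cut2: CutSite,
    primer_len: int = DEFAULT_PRIMER_LEN,
    max_amplicon_len: int = DEFAULT_MAX_AMPLICON,
    indel_margin: int = DEFAULT_INDEL_MARGIN,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    with_fw2: bool = True,
) -> TierScheme:
    """Design Fw1/Rev1/Rev2 (and optionally Fw2) for a cut-site pair.

    Each primer is placed at the position nearest its constraint boundary
    (Fw1 just left of cut1, Rev2 just right of it, Rev1 just right of cut2,
    Fw2 just left of cut2), scanning outward deterministically and keeping
    the first position whose footprint is unique in the locus. The finished
    scheme is verified against constructed deletion, inversion and wild-type
    alleles before being returned.
    """
    seq = locus.sequence
    if cut2.left_end - cut1.right_end <= max_amplicon_len:
        raise DesignInfeasibleError(
            "cut-to-cut distance must exceed max_amplicon_len, otherwise the "
            "wild-type arrangement amplifies in tier 1"
        )
    L = primer_len
    fw1_anchor = cut1.left_end - indel_margin - L
    fw1_start = _scan(seq, range(fw1_anchor, fw1_anchor - search_window, -1), L)
    rev2_anchor = cut1.right_end + indel_margin
    rev2_start = _scan(seq, range(rev2_anchor, rev2_anchor + search_window), L)
    rev1_anchor = cut2.right_end + indel_margin
    rev1_start = _scan(seq, range(rev1_anchor, rev1_anchor + search_window), L)
    fw1 = _make_primer("Fw1", seq, fw1_start, L, "forward")
    rev2 = _make_primer("Rev2", seq, rev2_start, L, "reverse")
    rev1 = _make_primer("Rev1", seq, rev1_start, L, "reverse")
    fw2 = None
    if with_fw2:
        fw2_anchor = cut2.left_end - indel_margin - L
        fw2_start = _scan(seq, range(fw2_anchor, fw2_anchor - search_window, -1), L)
        if fw2_start < cut1.right_end + indel_margin:
            raise DesignError("segment too short to host Fw2 inside the margins")
        fw2 = _make_primer("Fw2", seq, fw2_start, L, "forward")

    scheme = TierScheme(fw1, rev1, rev2, fw2, max_amplicon_len, cut1, cut2)
    _verify_scheme(locus, scheme)
    return scheme


def _verify_scheme(locus: Locus, scheme: TierScheme) -> None:
    """Diagnostic contract: deletion amplifies in tier 1, WT in tier 2, the
    inversion in tier 3, and WT never in tiers 1 or 3."""
    mode = "perfect" if (scheme.cut1.blunt and scheme.cut2.blunt) else "trim"
    wt = wildtype_allele(locus.sequence)
    deln = apply_deletion(locus.sequence, scheme.cut1, scheme.cut2, mode)
    inv = apply_inversion(locus.sequence, scheme.cut1, scheme.cut2, mode)
    checks = [
        (deln, scheme.tiers[1], True, "deletion allele must amplify in tier 1"),
        (wt, scheme.tiers[2], True, "WT allele must amplify in tier 2"),
        (inv, scheme.tiers[3], True, "inversion allele must amplify in tier 3"),
        (wt, scheme.tiers[1], False, "WT allele must not amplify in tier 1"),
        (wt, scheme.tiers[3], False, "co-aligned primers must not amplify WT"),
    ]
    for template, (pa, pb), expect, msg in checks:
        amps = insilico_pcr(template, pa, pb, scheme.max_amplicon_len)
        if bool(amps) is not expect:
            raise DesignError(msg)


def _binding_sites(template: str, primer: Primer) -> tuple[list[int], list[int]]:
    """Forward (extends rightward) and reverse (extends leftward) binding
    start positions of a primer on a template, both strands considered."""
    fwd, rev = [], []
    pos = -1
    while (pos := template.find(primer.sequence, pos + 1)) != -1:
        fwd.append(pos)
    rc = reverse_complement(primer.sequence)
    pos = -1
    while (pos := template.find(rc, pos + 1)) != -1:
        rev.append(pos)
    return fwd, rev


def insilico_pcr(
    template: str | Allele | DiploidGenotype | Sequence[str | Allele],
    primer_a: Primer,
    primer_b: Primer,
    max_amplicon_len: int = DEFAULT_MAX_AMPLICON,
) -> list[Amplicon]:
    """Predict every amplicon a primer pair yields on the template(s).

    Finds all exact binding sites of both primers on both strands of each
    template and emits one amplicon per convergent pair (a rightward-extending
    site left of a leftward-extending site) whose span is at most
    ``max_amplicon_len``. Co-aligned or divergent site pairs yield nothing.
    Diploid templates are processed per allele and pooled. An empty list is a
    valid result.
    """
    templates: list[str] = []
    for t in _as_template_list(template):
        templates.append(t.sequence if isinstance(t, Allele) else t)

    out: list[Amplicon] = []
    for tpl in templates:
        bindings_fwd: list[tuple[int, str, int]] = []
        bindings_rev: list[tuple[int, str, int]] = []
        for p in (primer_a, primer_b):
            fwd, rev = _binding_sites(tpl, p)
            bindings_fwd += [(i, p.name, len(p)) for i in fwd]
            bindings_rev += [(i, p.name, len(p)) for i in rev]
        for fi, fname, flen in bindings_fwd:
            for ri, rname, rlen in bindings_rev:
                if fi > ri:
                    continue  # divergent: 3' ends point away from each other
                end = ri + rlen
                if end - fi > max_amplicon_len:
                    continue
                out.append(Amplicon(fi, end, tpl[fi:end], (fname, rname)))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def _as_template_list(template) -> list:
    if isinstance(template, DiploidGenotype):
        return [template.allele_a, template.allele_b]
    if isinstance(template, (str, Allele)):
        return [template]
    return list(template)


def predict_band_pattern(genotype: DiploidGenotype | Sequence[Allele], scheme: TierScheme) -> BandPattern:
    """Run all three tiers on both alleles of a diploid and pool the bands."""
    alleles = _as_template_list(genotype)
    sizes = []
    for tier in (1, 2, 3):
        pa, pb = scheme.tiers[tier]
        amps = insilico_pcr(alleles, pa, pb, scheme.max_amplicon_len)
        sizes.append(tuple(a.length for a in amps))
    return BandPattern(
        tier1=bool(sizes[0]), tier2=bool(sizes[1]), tier3=bool(sizes[2]),
        amplicon_sizes=(sizes[0], sizes[1], sizes[2]),
    )
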