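"""Nuclease cut-site geometry and allele construction.

Models the editing outcomes of a paired-guide CRISPR experiment at a single
locus: SpCas9 makes a blunt double-strand break 3 bp 5' of the NGG PAM
(between protospacer positions 17|18 of 20); LbCpf1 cuts distal to its 5'
TTTV PAM with a staggered break leaving a 4-5 nt 5' overhang (default nicks
after protospacer positions 18 and 23). Two concurrent breaks can excise the
intervening segment (deletion) or re-insert it in reverse orientation
(inversion); single breaks can heal with small indels. A diploid genotype is
an unordered pair of alleles; the deletion/inversion pair is the "delinver"
bi-allele.

Coordinates are 0-based half-open on the + strand; cut positions are
inter-base integers (the number of bases to their left).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, TYPE_CHECKING

from .errors import (
    AmbiguousTargetError,
    GeometryError,
    ParameterError,
    TargetNotFoundError,
)
from .seqio import reverse_complement

if TYPE_CHECKING:  # pragma: no cover
    from .locus import Locus

Nuclease = Literal["SpCas9", "LbCpf1"]
AlleleClass = Literal["WT", "INDEL", "DELETION", "INVERSION"]

#: protospacer lengths by nuclease
PROTOSPACER_LEN = {"SpCas9": 20, "LbCpf1": 23}
#: SpCas9 blunt cut: 3 bp 5' of the PAM, i.e. after protospacer position 17 of 20
SPCAS9_CUT_OFFSET = 17
#: LbCpf1 nick on the protospacer-bearing (non-target) strand, after position 18
LBCPF1_NONTARGET_NICK = 18
JUNCTION_FLANK = 15
INDEL_CAP = 25

# genotyping shorthand: WT and small indels are invisible to the tier scheme
CLASS_TO_LETTER = {"WT": "W", "INDEL": "W", "DELETION": "D", "INVERSION": "V"}
_LETTER_ORDER = {"W": 0, "D": 1, "V": 2}


@dataclass(frozen=True)
class GuideTarget:
    """A protospacer+PAM site on a locus.

    ``start`` is the 0-based + strand position of the protospacer footprint.
    For a ``-`` strand guide the protospacer string is the reverse complement
    of the + strand at ``[start, start+len)``. The PAM sits 3' of the
    protospacer for SpCas9 and 5' for LbCpf1, in guide orientation.
    """

    id: str
    protospacer: str
    pam: str
    strand: Literal["+", "-"]
    start: int
    nuclease: Nuclease = "SpCas9"

    def __post_init__(self):
        if self.nuclease not in PROTOSPACER_LEN:
            raise ParameterError(f"unknown nuclease {self.nuclease!r}")
        want = PROTOSPACER_LEN[self.nuclease]
        if len(self.protospacer) != want:
            raise ParameterError(
                f"{self.nuclease} protospacer must be {want} nt, got {len(self.protospacer)}"
            )
        if self.strand not in "+-":
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class CutSite:
    """A double-strand break as two inter-base nick positions on the + strand.

    ``top_cut`` is the nick on the + strand, ``bottom_cut`` the nick on the
    - strand (both expressed in + strand coordinates). Equal positions mean a
    blunt break; LbCpf1 leaves ``|top - bottom|`` of 4-5 (a 5' overhang).
    """

    top_cut: int
    bottom_cut: int

    @property
    def blunt(self) -> bool:
        return self.top_cut == self.bottom_cut

    @property
    def left_end(self) -> int:
        return min(self.top_cut, self.bottom_cut)

    @property
    def right_end(self) -> int:
        return max(self.top_cut, self.bottom_cut)

    @property
    def overhang(self) -> int:
        return abs(self.top_cut - self.bottom_cut)


@dataclass(frozen=True)
class Allele:
    """One haplotype at the locus, with its breakpoints and junction context.

    ``breakpoints`` are the reference coordinates (a, b) such that the allele
    was assembled from ``ref[:a]`` and ``ref[b:]`` (deletion) or with the
    reverse-complemented segment between them (inversion); absent for WT.
    ``junctions`` lists (position_on_allele, +/-15 bp of sequence context).
    """

    allele_class: AlleleClass
    sequence: str
    breakpoints: tuple[int, int] | None = None
    edit_detail: str = ""
    junctions: tuple[tuple[int, str], ...] = ()

    @property
    def letter(self) -> str:
        """Genotyping letter: W (WT or indel), D (deletion), V (inversion)."""
        return CLASS_TO_LETTER[self.allele_class]

    def fasta_header(self) -> str:
        bp = f" breakpoints={self.breakpoints[0]}-{self.breakpoints[1]}" if self.breakpoints else ""
        detail = f" detail={self.edit_detail!r}" if self.edit_detail else ""
        return f"class={self.allele_class}{bp}{detail}"


@dataclass(frozen=True)
class DiploidGenotype:
    """Unordered pair of alleles with a two-letter class label (WW..VV)."""

    allele_a: Allele
    allele_b: Allele

    @property
    def class_label(self) -> str:
        return genotype_label(self.allele_a.letter, self.allele_b.letter)


def genotype_label(letter_a: str, letter_b: str) -> str:
    """Order-independent two-letter label; W sorts before D before V."""
    pair = sorted((letter_a, letter_b), key=_LETTER_ORDER.__getitem__)
    return "".join(pair)


def _pam_matches(pam_pattern: str, observed: str) -> bool:
    iupac = {"N": "ACGT", "V": "ACG", "A": "A", "C": "C", "G": "G", "T": "T"}
    return len(pam_pattern) == len(observed) and all(
        o in iupac[p] for p, o in zip(pam_pattern, observed)
    )


def _pam_pattern(nuclease: Nuclease) -> str:
    return "NGG" if nuclease == "SpCas9" else "TTTV"


def _scan_guide_sites(sequence: str, guide: GuideTarget) -> list[tuple[int, str]]:
    """All (+ strand start, strand) positions where protospacer+PAM match exactly."""
    hits = []
    proto = guide.protospacer.upper()
    pam_pat = _pam_pattern(guide.nuclease)
    plen, pamlen = len(proto), len(pam_pat)
    rc_proto = reverse_complement(proto)
    n = len(sequence)
    for strand, needle in (("+", proto), ("-", rc_proto)):
        pos = sequence.find(needle)
        while pos != -1:
            if guide.nuclease == "SpCas9":
                # PAM 3' of protospacer in guide orientation
                if strand == "+":
                    window = sequence[pos + plen : pos + plen + pamlen]
                else:
                    window = reverse_complement(sequence[pos - pamlen : pos]) if pos >= pamlen else ""
            else:
                # PAM 5' of protospacer in guide orientation
                if strand == "+":
                    window = sequence[pos - pamlen : pos] if pos >= pamlen else ""
                else:
                    window = reverse_complement(sequence[pos + plen : pos + plen + pamlen])
            if _pam_matches(pam_pat, window):
                hits.append((pos, strand))
            pos = sequence.find(needle, pos + 1)
    return hits


def locate_protospacer(locus: "Locus", guide: GuideTarget) -> GuideTarget:
    """Verify a guide has exactly one exact protospacer+PAM match in the locus.

    Returns the guide with its coordinates set to the verified hit. Zero hits
    raise :class:`TargetNotFoundError`; more than one raise
    :class:`AmbiguousTargetError` (a duplicated target is unsafe for
    multiplex editing).
    """
    sequence = locus.sequence.upper()
    hits = _scan_guide_sites(sequence, guide)
    if not hits:
        raise TargetNotFoundError(f"guide {guide.id}: no exact protospacer+PAM match")
    if len(hits) > 1:
        raise AmbiguousTargetError(f"guide {guide.id}: {len(hits)} matches at {hits}")
    pos, strand = hits[0]
    pam_pat = _pam_pattern(guide.nuclease)
    plen, pamlen = len(guide.protospacer), len(pam_pat)
    if guide.nuclease == "SpCas9":
        span = (pos + plen, pos + plen + pamlen) if strand == "+" else (pos - pamlen, pos)
    else:
        span = (pos - pamlen, pos) if strand == "+" else (pos + plen, pos + plen + pamlen)
    observed_pam = sequence[span[0] : span[1]]
    if strand == "-":
        observed_pam = reverse_complement(observed_pam)
    return GuideTarget(
        id=guide.id,
        protospacer=guide.protospacer.upper(),
        pam=observed_pam,
        strand=strand,
        start=pos,
        nuclease=guide.nuclease,
    )


def compute_cut_site(guide: GuideTarget, overhang: int = 5) -> CutSite:
    """Cut-site coordinates implied by a verified guide.

    SpCas9: blunt break 3 bp 5' of the PAM. LbCpf1: staggered break with the
    non-target-strand nick after protospacer position 18 and the
    target-strand nick ``overhang`` (4 or 5) bases further, giving a 5'
    overhang. Minus-strand guides mirror the same rules onto + strand
    coordinates.
    """
    if guide.nuclease == "SpCas9":
        plen = PROTOSPACER_LEN["SpCas9"]
        if guide.strand == "+":
            c = guide.start + SPCAS9_CUT_OFFSET
        else:
            c = guide.start + (plen - SPCAS9_CUT_OFFSET)
        return CutSite(c, c)
    if guide.nuclease == "LbCpf1":
        if overhang not in (4, 5):
            raise ParameterError(f"LbCpf1 overhang must be 4 or 5, got {overhang}")
        plen = PROTOSPACER_LEN["LbCpf1"]
        if guide.strand == "+":
            top = guide.start + LBCPF1_NONTARGET_NICK
            bottom = top + overhang
        else:
            bottom = guide.start + (plen - LBCPF1_NONTARGET_NICK)
            top = bottom - overhang
        return CutSite(top, bottom)
    raise ParameterError(f"unknown nuclease {guide.nuclease!r}")


def _junction(sequence: str, pos: int) -> tuple[int, str]:
    lo = max(0, pos - JUNCTION_FLANK)
    return pos, sequence[lo : pos + JUNCTION_FLANK]


def _resolve_mode(cut1: CutSite, cut2: CutSite, mode: str) -> tuple[int, int, int, int]:
    """Junction coordinates (a1, b1, a2, b2): the allele keeps ref[:a1] on the
    left, ref[b2:] on the right, and (for inversions) the segment ref[b1:a2]...

    Returned as (left_keep_end, seg_start, seg_end, right_keep_start).
    """
    if mode not in ("perfect", "fill_in", "trim"):
        raise ParameterError(f"unknown ligation mode {mode!r}")
    if mode == "perfect":
        if not (cut1.blunt and cut2.blunt):
            raise ParameterError("'perfect' ligation is defined for blunt cuts only; "
                                 "use 'fill_in' or 'trim' for staggered cuts")
        return cut1.top_cut, cut1.top_cut, cut2.top_cut, cut2.top_cut
    if mode == "trim":
        # 5' overhangs chewed back: every end becomes blunt at its recessed side
        return cut1.left_end, cut1.right_end, cut2.left_end, cut2.right_end
    # fill_in: recessed 3' ends extended, duplicating the overhang bases
    return cut1.right_end, cut1.left_end, cut2.right_end, cut2.left_end


def apply_deletion(reference: str, cut1: CutSite, cut2: CutSite, mode: str = "perfect") -> Allele:
    """Excise the segment between two cuts and re-ligate the flanks.

    ``perfect`` (blunt cuts) joins the flanks exactly at the cut positions;
    for staggered cuts ``fill_in`` duplicates the overhang bases at the
    junction and ``trim`` removes them. Deterministic in every mode.
    """
    _check_geometry(reference, cut1, cut2)
    a1, _, _, b2 = _resolve_mode(cut1, cut2, mode)
    sequence = reference[:a1] + reference[b2:]
    return Allele(
        allele_class="DELETION",
        sequence=sequence,
        breakpoints=(a1, b2),
        edit_detail=f"{mode} deletion junction {a1}|{b2}",
        junctions=(_junction(sequence, a1),),
    )


def apply_inversion(reference: str, cut1: CutSite, cut2: CutSite, mode: str = "perfect") -> Allele:
    """Re-insert the excised segment in reverse orientation between the cuts.

    Under perfect blunt ligation the allele has the reference length and the
    operation is an involution. A reference coordinate x inside the segment
    maps to ``cut1 + cut2 - x`` on the allele (see
    :func:`map_inverted_coordinate`).
    """
    _check_geometry(reference, cut1, cut2)
    a1, b1, a2, b2 = _resolve_mode(cut1, cut2, mode)
    segment = reverse_complement(reference[b1:a2])
    sequence = reference[:a1] + segment + reference[b2:]
    j2 = a1 + len(segment)
    return Allele(
        allele_class="INVERSION",
        sequence=sequence,
        breakpoints=(a1, b2),
        edit_detail=f"{mode} inversion of [{b1},{a2})",
        junctions=(_junction(sequence, a1), _junction(sequence, j2)),
    )


def map_inverted_coordinate(x: int, cut1: CutSite, cut2: CutSite) -> int:
    """Map a reference coordinate inside a perfectly inverted segment onto the
    inversion allele: positions reflect through the segment midpoint."""
    c1, c2 = cut1.top_cut, cut2.top_cut
    if not (c1 <= x <= c2):
        raise GeometryError(f"coordinate {x} outside inverted segment [{c1}, {c2}]")
    return c1 + c2 - x


def apply_indel(
    reference: str,
    cut: CutSite,
    indel: int,
    inserted_bases: str = "",
    cap: int = INDEL_CAP,
) -> Allele:
    """Small insertion (+n) or deletion (-n) at a single repaired cut.

    Insertions place ``inserted_bases`` at the cut; deletions remove bases to
    the right of the cut. ``indel == 0`` returns the unchanged WT allele.
    """
    if abs(indel) > cap:
        raise ParameterError(f"|indel| exceeds cap {cap}")
    c = cut.top_cut
    if indel == 0:
        return Allele(allele_class="WT", sequence=reference, edit_detail="no edit")
    if indel > 0:
        if len(inserted_bases) != indel:
            raise ParameterError(f"+{indel} bp insertion needs {indel} inserted bases")
        sequence = reference[:c] + inserted_bases.upper() + reference[c:]
        detail = f"+{indel} bp at cut"
    else:
        if c + (-indel) > len(reference):
            raise GeometryError("deletion extends past sequence end")
        sequence = reference[:c] + reference[c - indel :]
        detail = f"{indel} bp at cut"
    return Allele(
        allele_class="INDEL",
        sequence=sequence,
        breakpoints=(c, c),
        edit_detail=detail,
        junctions=(_junction(sequence, c),),
    )


def wildtype_allele(reference: str) -> Allele:
    return Allele(allele_class="WT", sequence=reference, edit_detail="wild type")


def build_diploid(allele_a: Allele, allele_b: Allele) -> DiploidGenotype:
    """Pair two alleles of the same reference into an unordered diploid genotype."""
    return DiploidGenotype(allele_a, allele_b)


def _check_geometry(reference: str, cut1: CutSite, cut2: CutSite) -> None:
    if cut1.right_end > cut2.left_end:
        raise GeometryError(
            f"cut windows overlap or are out of order: {cut1} vs {cut2}"
        )
    if cut1.left_end < 0 or cut2.right_end > len(reference):
        raise GeometryError("cut site outside reference")
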