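"""Synthetic tandem-gene loci and guide-pair placement.

Generates reference sequences shaped like the tandem arrays this toolkit is
aimed at: a row of 3-6 paralog-sized gene features separated by short
intergenic spacers, with enough flanking sequence to place genotyping
primers, and a pair of guide target sites bracketing the array. Excisable
segment sizes of roughly 5-32 kb are reachable by choosing gene/intergenic
lengths. The generator is fully deterministic for a fixed seed and may
overwrite a few bases to write a valid PAM at each requested guide position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .editing import (
    CutSite,
    GuideTarget,
    PROTOSPACER_LEN,
    compute_cut_site,
    locate_protospacer,
)
from .errors import ParameterError, PlacementError
from .seqio import read_bed6, read_fasta, reverse_complement, write_bed6, write_fasta

Feature = tuple[str, int, int, str]  # (gene_name, start, end, strand)

#: Arabidopsis-like genomic base composition; not biologically load-bearing.
DEFAULT_GC = 0.36


@dataclass(frozen=True)
class Locus:
    """A reference sequence with gene features and guide target sites.

    Features are (name, start, end, strand) in 0-based half-open coordinates,
    non-overlapping and ordered by start. ``guide_sites`` carries the ids of
    guides placed on this locus.
    """

    name: str
    sequence: str
    features: tuple[Feature, ...] = ()
    guide_sites: tuple[str, ...] = ()

    def __post_init__(self):
        seq = self.sequence
        if set(seq) - set("ACGT"):
            raise ParameterError("locus sequence must contain only A/C/G/T")
        last_end = -1
        for name, start, end, strand in self.features:
            if not (0 <= start < end <= len(seq)):
                raise ParameterError(f"feature {name} outside [0, {len(seq)})")
            if start < last_end:
                raise ParameterError("gene features must be non-overlapping and ordered")
            last_end = end

    def __len__(self) -> int:
        return len(self.sequence)

    def to_files(self, fasta_path: str | Path, bed_path: str | Path,
                 guides: list[GuideTarget] | None = None) -> None:
        """Write the sequence as FASTA and features (+ guide intervals) as BED6."""
        write_fasta(fasta_path, [(self.name, self.sequence)])
        rows = [(self.name, s, e, n, 0, st) for n, s, e, st in self.features]
        for g in guides or []:
            rows.append((self.name, g.start, g.start + len(g.protospacer), g.id, 0, g.strand))
        write_bed6(bed_path, sorted(rows, key=lambda r: r[1]))


def locus_from_files(fasta_path: str | Path, bed_path: str | Path,
                     guide_ids: set[str] | None = None) -> Locus:
    """Rebuild a Locus from FASTA+BED6; BED rows named in ``guide_ids`` become
    guide sites, everything else gene features."""
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ParameterError(f"expected a single-record FASTA, found {len(seqs)}")
    name, sequence = next(iter(seqs.items()))
    features, guide_sites = [], []
    for chrom, start, end, feat_name, _score, strand in read_bed6(bed_path):
        if chrom != name:
            raise ParameterError(f"BED chrom {chrom!r} does not match FASTA record {name!r}")
        if guide_ids and feat_name in guide_ids:
            guide_sites.append(feat_name)
        else:
            features.append((feat_name, start, end, strand))
    return Locus(name, sequence, tuple(features), tuple(guide_sites))


@dataclass(frozen=True)
class SimLocusConfig:
    """Parameters of a synthetic tandem-array locus.

    Defaults give a 3-gene array whose guide-bracketed segment can be sized
    to the 5-20 kb range typical of the deletions this assay targets.
    """

    n_genes: int = 3
    gene_length: int = 1000
    intergenic_length: int = 500
    flank_length: int = 2000
    gc_fraction: float = DEFAULT_GC
    seed: int = 0
    name: str = "synthetic_locus"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if min(self.gene_length, self.intergenic_length, self.flank_length) <= 0:
            raise ParameterError("lengths must be positive")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ParameterError("gc_fraction must be in (0, 1)")


def generate_locus(config: SimLocusConfig) -> Locus:
    """Sample a locus per the config: evenly spaced gene features flanked by
    ``flank_length`` on each side, bases i.i.d. with the stated GC fraction."""
    total = (
        2 * config.flank_length
        + config.n_genes * config.gene_length
        + (config.n_genes - 1) * config.intergenic_length
    )
    rng = np.random.default_rng(config.seed)
    g = config.gc_fraction / 2.0
    a = (1.0 - config.gc_fraction) / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=total, p=[a, g, g, a])
    sequence = "".join(bases)
    features = []
    pos = config.flank_length
    for i in range(config.n_genes):
        features.append((f"gene{i + 1}", pos, pos + config.gene_length, "+"))
        pos += config.gene_length + config.intergenic_length
    return Locus(config.name, sequence, tuple(features))


def _write_pam(sequence: str, guide_start: int, strand: str, nuclease: str,
               rng: np.random.Generator) -> tuple[str, tuple[int, int]]:
    """Overwrite bases adjacent to the protospacer to create a valid PAM.

    Returns the edited sequence and the + strand PAM span. Deterministic for
    a fixed rng state; faster than rejection-sampling a PAM-bearing locus.
    """
    plen = PROTOSPACER_LEN[nuclease]
    n = rng.choice(list("ACGT"))
    v = rng.choice(list("ACG"))
    if nuclease == "SpCas9":
        pam_fwd = n + "GG"  # NGG 3' of protospacer
        span = (guide_start + plen, guide_start + plen + 3) if strand == "+" else (guide_start - 3, guide_start)
    else:
        pam_fwd = "TTT" + v  # TTTV 5' of protospacer
        span = (guide_start - 4, guide_start) if strand == "+" else (guide_start + plen, guide_start + plen + 4)
    if span[0] < 0 or span[1] > len(sequence):
        raise PlacementError("guide too close to locus end to fit protospacer+PAM")
    pam_plus = pam_fwd if strand == "+" else reverse_complement(pam_fwd)
    return sequence[: span[0]] + pam_plus + sequence[span[1] :], span


def place_guide_pair(
    locus: Locus,
    left_offset: int,
    right_offset: int,
    nuclease: str = "SpCas9",
    seed: int = 0,
    strands: tuple[str, str] = ("+", "+"),
) -> tuple[Locus, GuideTarget, GuideTarget]:
    """Write a guide pair onto the locus at the given protospacer start offsets.

    Returns the PAM-edited locus together with the two verified guides, whose
    computed cut sites bracket the segment between them. Each protospacer must
    be unique within the locus (checked on both strands) or a
    :class:`PlacementError` is raised.
    """
    if nuclease not in PROTOSPACER_LEN:
        raise ParameterError(f"unknown nuclease {nuclease!r}")
    if left_offset >= right_offset:
        raise ParameterError("left_offset must be < right_offset")
    plen = PROTOSPACER_LEN[nuclease]
    if left_offset < 0 or right_offset + plen > len(locus.sequence):
        raise PlacementError("guide offsets too close to locus ends")

    rng = np.random.default_rng(seed)
    sequence = locus.sequence
    guides = []
    for gid, start, strand in (
        (f"{locus.name}_gL", left_offset, strands[0]),
        (f"{locus.name}_gR", right_offset, strands[1]),
    ):
        sequence, _span = _write_pam(sequence, start, strand, nuclease, rng)
        proto_plus = sequence[start : start + plen]
        proto = proto_plus if strand == "+" else reverse_complement(proto_plus)
        guides.append(GuideTarget(gid, proto, _pam_of(nuclease), strand, start, nuclease))

    edited = replace(locus, sequence=sequence,
                     guide_sites=locus.guide_sites + tuple(g.id for g in guides))
    for g in guides:
        # protospacer must be unique as a raw substring (either strand),
        # independent of PAM context: multiplex-safety requirement
        n_hits = sequence.count(g.protospacer) + sequence.count(
            reverse_complement(g.protospacer))
        if n_hits != 1:
            raise PlacementError(
                f"guide {g.id}: protospacer occurs {n_hits} times in the locus")
    verified = []
    for g in guides:
        try:
            vg = locate_protospacer(edited, g)
        except Exception as exc:
            raise PlacementError(f"guide {g.id} not uniquely placeable: {exc}") from exc
        if vg.start != g.start:
            raise PlacementError(f"guide {g.id} matched elsewhere ({vg.start} != {g.start})")
        verified.append(vg)
    left, right = verified
    cl, cr = compute_cut_site(left), compute_cut_site(right)
    if cl.right_end >= cr.left_end:
        raise PlacementError("guide cut sites do not bracket a segment")
    return edited, left, right


def _pam_of(nuclease: str) -> str:
    return "NGG" if nuclease == "SpCas9" else "TTTV"


def cut_pair(left: GuideTarget, right: GuideTarget, overhang: int = 5) -> tuple[CutSite, CutSite]:
    """Convenience: cut sites of a verified guide pair, ordered left to right."""
    c1, c2 = compute_cut_site(left, overhang), compute_cut_site(right, overhang)
    return (c1, c2) if c1.left_end <= c2.left_end else (c2, c1)
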