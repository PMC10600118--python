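# Methods

## Coordinate conventions

All sequences are over {A,C,G,T}; all intervals are 0-based half-open on the
+ strand (BED convention). Cut positions are inter-base integers — the
number of bases to their left — so junction arithmetic needs no ±1
adjustments: a blunt deletion is `ref[:c1] + ref[c2:]`, a blunt inversion
`ref[:c1] + revcomp(ref[c1:c2]) + ref[c2:]`.

## Nuclease cut model

SpCas9 leaves a blunt break 3 bp 5′ of its NGG PAM, i.e. between
protospacer positions 17|18 of 20. LbCpf1 cuts distal to its 5′ TTTV PAM
with a staggered break: the nick on the protospacer-bearing (non-target)
strand falls after protospacer position 18 and the target-strand nick 4–5 nt
further, leaving a 5′ overhang (default 5, configurable to 4). These exact
offsets come from the nuclease literature, not from any screen this package
reproduces, and both are parameters with these defaults. Minus-strand guides
mirror the same rules onto + strand coordinates; the mirroring is tested
against an independent oracle (reverse-complement the axis, apply the
+ strand rule, reflect back).

## Junction chemistry

Default ligation is *perfect* — flanks rejoin exactly at the breaks with no
indels, matching the cleanest observed junction sequences. Perfect ligation
is only defined for blunt breaks. For staggered breaks two deterministic
chemistries are provided: `fill_in` (recessed 3′ ends extended before blunt
ligation, duplicating the overhang bases at each junction) and `trim`
(overhangs chewed back). A deletion has one junction, so fill-in and trim
alleles differ by the sum of the two overhangs (10 bp for two 5-nt
overhangs); an inversion has two junctions and differs by twice that. No
claim is made about which chemistry dominates in vivo; published junction
data for staggered-cut inversions is too sparse to pick a default.
Junction-indel noise is deliberately out of the core model: the assay is
designed to be insensitive to it (below).

## Assay design

The three-tier scheme places Fw1 just left of cut 1, Rev2 just inside the
segment right of cut 1, Rev1 just right of cut 2, and (optionally) Fw2 just
inside left of cut 2. Placement scans deterministically outward from each
constraint boundary and keeps the first footprint that is unique in the
locus across both strands; ties cannot arise, and the scan is bounded by
`search_window` (default 500 bp). Every footprint keeps `indel_margin`
(default 50 bp) clear of the cut sites, which makes the assay blind to small
repair indels *by construction* — indel alleles genotype as W, and every
batch report carries that caveat.

`max_amplicon_len` (default 3000 bp) stands in for the extension-time
ceiling of a genotyping polymerase; the design precondition
`cut2 − cut1 > max_amplicon_len` guarantees the wild-type arrangement is
tier-1-negative. The ceiling is a free parameter, not fit to any gel.

In-silico PCR is exact-match and positional: all binding sites of both
primers on both strands, one amplicon per convergent site pair within the
ceiling; co-aligned or divergent pairs yield nothing; mismatch tolerance,
melting temperature and dimer screening are out of scope. The implementation
is checked against a brute-force all-substring-pairs oracle on loci up to
20 kb and on random templates with implanted sites.

## Genotype calling

A single allele is positive in exactly one tier (W → tier 2, D → tier 1,
V → tier 3) and a diploid's pattern is the OR of its alleles, so the six
unordered diploid classes give six distinct three-tier patterns and calling
is table inversion. The published table lists four genotypes; the WV and VV
rows follow from the same amplification logic and are labelled extensions.
Two-tier mode returns the ambiguity sets {WW, WV} and {DD, DV} — the
collapse that motivates the third tier. Patterns no genotype can produce
(e.g. all-negative) return an empty call set flagged uninterpretable.

## Population models

**Empirical per-homolog model.** Each homolog independently carries the
deletion (p_del), the inversion (p_inv), or stays W. Expected DV fraction is
2·p_del·p_inv; expected tier-1-positive ("plants with deletions") fraction
is 1 − (1 − p_del)². This is a summary of observed per-guide-pair outcome
frequencies, not a mechanism.

**Five-fate re-ligation model.** A mechanistic hypothesis, clearly labelled
speculative: with probability `cut_prob` a homolog's segment is excised;
each free segment then takes one of five fates — re-ligation in wild-type or
inverted orientation into its own gap or into the other homolog's gap, or
loss. Cross-homolog fates require the other homolog to have a gap, so with a
single excision they are disabled and the remaining weights renormalised
over (own-WT, own-inverted, lost). A gap receiving two segments is a
*complex* chromosome: tallied in `attrs['n_complex']` and excluded from
W/D/V counts, never silently dropped. No fate weights are published; the
default is uniform (0.2 each). With cross-homolog weights at zero the model
reduces to an empirical model with p_del = c·w_lost′ and
p_inv = c·w_own_inv′ (renormalised weights), checked numerically.

T1 individuals are modelled as single diploids, not mosaics, matching how
such screens genotype them. `simulate_t1` returns per-homolog class letters
in a DataFrame rather than sequence-bearing allele objects; operational
scoring still runs through the real assay: a reference locus/scheme is built
once, each class's band pattern is computed by in-silico PCR on constructed
alleles, and populations are then scored and called from those patterns — so
simulated frequencies are comparable to PCR-based counts (tier-1-positive %
and called-DV %), not to true classes.

**Selfing.** Gametes are drawn uniformly from the parent's two alleles and
united at random; a DV parent segregates DD : DV : VV = 1 : 2 : 1.

**Efficiency sweep.** A per-cut efficiency e excises a homolog with
probability e² (both cuts must fire); an excised homolog becomes an
inversion with probability `inversion_bias` (default 0.35) and a deletion
otherwise. This coupling makes delinver frequency track deletion frequency
across an efficiency grid, the qualitative pattern the correlation
statistics quantify. Default grid sizes (12 points × 500 individuals) keep
the sweep in seconds; the correlation at those sizes exceeds 0.9 but is
stochastic.

## Summary statistics

Per-guide-pair rows carry raw counts; derived percentages
(100·n_deletion/n_transgenic, 100·n_delinver/n_transgenic,
100·n_delinver/n_deletion) are kept at full precision internally and
displayed rounded half-up to one decimal. A ratio with zero deletion
carriers is *undefined* (excluded from medians), not zero. Pearson r/R² uses
the standard product-moment formula (scipy); correlations over a table block
include every guide pair of the block, zero-deletion pairs too — this
convention reproduces the published block R² values from raw counts and from
printed percentages alike (both within ±0.005). Chi-square goodness of fit
is Pearson's statistic with df = k−1.

The shipped count tables are re-entered from the published screen summaries
as plain TSV. Recomputing every derived cell from its counts matches the
printed value within 0.1 (one rounding unit); one rice cell (12/303 printed
as 3.9, recomputed 3.96) appears truncated rather than rounded, and the
±0.1 tolerance covers it rather than adopting truncation globally.

## Synthetic data: what it does and does not emulate

Generated loci have i.i.d. bases at a configurable GC fraction (default
0.36, Arabidopsis-like, not load-bearing), evenly spaced featureless genes,
and PAMs written in place at the requested guide positions (deterministic,
rather than rejection-sampling a PAM-bearing sequence). They emulate the
*structural* properties the analysis depends on — array geometry, excisable
segment sizes from ~5 to ~32 kb, unique primer and protospacer sites — and
none of the sequence biology (exon structure, repeats, chromatin,
sequence-dependent cutting). Passing tests therefore validate the assay
logic, the truth table, and the statistics; they say nothing about cutting
efficiencies or repair outcomes in real plants, which enter only through the
re-entered count tables.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (numpy default_rng) and is
bit-reproducible. Test and acceptance runs use: 10⁵ individuals for
parameter-recovery checks (3-standard-error bands), 10⁴ replicate selfings
of 96 offspring for the segregation range check (central 99% interval),
12 × 500 for the efficiency sweep, and ≤20-kb loci for oracle equivalence —
sizes at which every closed-form expectation is resolvable in seconds.

## Known limitations

- No off-target cutting, translocations, microhomology-mediated junction
  prediction, or somatic mosaicism.
- Primer binding has no mismatch or thermodynamic model; a real assay needs
  Tm and specificity checks this package does not attempt.
- The five-fate model's weights are unconstrained by data; it is a tool for
  exploring the hypothesis, not an estimate of it.
- Small indels at cut sites are invisible to the assay by design; W calls
  conflate wild-type and indel alleles.
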