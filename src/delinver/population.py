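"""Transgenic population and selfing-segregation simulators.

Two generative models for first-generation (T1) transgenic individuals:

* **Empirical per-homolog model** — each homolog independently ends up
  carrying the segment deletion (probability ``p_del``), the inverted
  segment (``p_inv``), or remains wild-type-like (the rest). This is the
  minimal model that summarises the observed per-guide-pair frequencies;
  under it the expected delinver (DV) fraction is ``2 * p_del * p_inv``.

* **Five-fate re-ligation model** — a mechanistic hypothesis: when both
  homologs are cut and their segments excised simultaneously, each free
  segment has five fates — re-ligation in wild-type or inverted orientation
  back into its own chromosome or into the other homolog's gap, or loss.
  When only one homolog is excised the cross-homolog fates are disabled and
  the remaining weights renormalised. A gap that receives two segments is a
  "complex" outcome: tallied and excluded from W/D/V counts, never silently
  dropped. All five weights are free parameters with a uniform default; the
  mechanism is speculative and so labelled.

Selfing segregation draws each offspring's two alleles uniformly from the
parent's pair, so a DV parent segregates DD:DV:VV = 1:2:1.

Operational frequencies (what a PCR screen would report) are computed by
pushing simulated classes through the real assay pipeline: band patterns are
predicted by in-silico PCR on constructed alleles of a reference assay, then
inverted by the truth-table caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import design_tier_scheme, predict_band_pattern
from .calling import call_genotype
from .editing import (
    apply_deletion,
    apply_inversion,
    genotype_label,
    wildtype_allele,
)
from .errors import ParameterError
from .locus import SimLocusConfig, cut_pair, generate_locus, place_guide_pair

_LETTERS = np.array(["W", "D", "V"])


@dataclass(frozen=True)
class EmpiricalModel:
    """Independent per-homolog multinomial over (WT-like, deletion, inversion)."""

    p_del: float
    p_inv: float

    def __post_init__(self):
        if self.p_del < 0 or self.p_inv < 0 or self.p_del + self.p_inv > 1:
            raise ParameterError("need p_del, p_inv >= 0 and p_del + p_inv <= 1")

    @property
    def p_w(self) -> float:
        return 1.0 - self.p_del - self.p_inv

    @property
    def expected_dv_fraction(self) -> float:
        return 2.0 * self.p_del * self.p_inv

    @property
    def expected_deletion_carrier_fraction(self) -> float:
        """Expected fraction of individuals with at least one D allele
        (the operational 'plants with deletions' a tier-1 screen reports)."""
        return 1.0 - (1.0 - self.p_del) ** 2


FATE_NAMES = ("own_wt", "own_inv", "other_wt", "other_inv", "lost")


@dataclass(frozen=True)
class FiveFateModel:
    """Excision probability plus re-ligation fate weights (speculative)."""

    cut_prob: float
    weights: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self):
        if not 0.0 <= self.cut_prob <= 1.0:
            raise ParameterError("cut_prob must be in [0, 1]")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ParameterError("fate weights must be 5 non-negative numbers summing to 1")

    @property
    def single_cut_weights(self) -> np.ndarray:
        """Own-chromosome fates renormalised when the other homolog is intact."""
        w = np.asarray(self.weights, dtype=float)
        own = np.array([w[0], w[1], w[4]])
        total = own.sum()
        if total == 0:
            raise ParameterError("own_wt, own_inv and lost weights cannot all be zero")
        return own / total


@dataclass(frozen=True)
class PopulationConfig:
    n_individuals: int
    model: EmpiricalModel | FiveFateModel
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ParameterError("n_individuals must be >= 0")


def simulate_t1(config: PopulationConfig) -> pd.DataFrame:
    """Draw a T1 population of diploid genotypes.

    Returns a DataFrame with per-homolog allele classes (``allele_a``,
    ``allele_b`` in {W, D, V, C}) and the unordered ``class_label``
    ('complex' when either homolog is a two-segment chromosome).
    ``df.attrs['n_complex']`` tallies complex outcomes. Bit-reproducible for
    a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    model = config.model
    if isinstance(model, EmpiricalModel):
        draws = rng.choice(3, size=(n, 2), p=[model.p_w, model.p_del, model.p_inv])
        a, b = _LETTERS[draws[:, 0]], _LETTERS[draws[:, 1]]
        n_complex = 0
    elif isinstance(model, FiveFateModel):
        a, b, n_complex = _simulate_five_fate(model, n, rng)
    else:
        raise ParameterError(f"unknown model type {type(model).__name__}")
    labels = [
        "complex" if "C" in (x, y) else genotype_label(x, y) for x, y in zip(a, b)
    ]
    df = pd.DataFrame({"allele_a": a, "allele_b": b, "class_label": labels})
    df.attrs["n_complex"] = int(n_complex)
    df.attrs["seed"] = config.seed
    return df


def _simulate_five_fate(model: FiveFateModel, n: int, rng: np.random.Generator):
    excised = rng.random((n, 2)) < model.cut_prob
    w5 = np.asarray(model.weights)
    w3 = None  # renormalised single-cut weights, built only if ever needed
    alleles = np.empty((n, 2), dtype="<U1")
    n_complex = 0
    for i in range(n):
        landed: list[list[str]] = [[], []]  # orientations landing in each gap
        for h in range(2):
            if not excised[i, h]:
                continue
            other = 1 - h
            if excised[i, other]:
                fate = FATE_NAMES[rng.choice(5, p=w5)]
            else:
                if w3 is None:
                    w3 = model.single_cut_weights
                fate = ("own_wt", "own_inv", "lost")[rng.choice(3, p=w3)]
            if fate == "own_wt":
                landed[h].append("wt")
            elif fate == "own_inv":
                landed[h].append("inv")
            elif fate == "other_wt":
                landed[other].append("wt")
            elif fate == "other_inv":
                landed[other].append("inv")
            # 'lost': segment re-ligated nowhere
        for h in range(2):
            if not excised[i, h]:
                alleles[i, h] = "W"
            elif len(landed[h]) == 0:
                alleles[i, h] = "D"
            elif len(landed[h]) == 1:
                alleles[i, h] = "W" if landed[h][0] == "wt" else "V"
            else:
                alleles[i, h] = "C"
                n_complex += 1
    return alleles[:, 0], alleles[:, 1], n_complex


def simulate_selfing(parent_class: str, n: int, seed: int = 0) -> dict[str, int]:
    """Self a parent of the given diploid class and count offspring classes.

    Gametes are drawn uniformly from the parent's two alleles and united at
    random, so a DV parent segregates DD : DV : VV in 1 : 2 : 1 expectation.
    """
    if len(parent_class) != 2 or any(c not in "WDV" for c in parent_class):
        raise ParameterError(f"parent class must be two of W/D/V, got {parent_class!r}")
    rng = np.random.default_rng(seed)
    parent = np.array(list(parent_class))
    gametes = parent[rng.integers(0, 2, size=(n, 2))]
    counts: dict[str, int] = {}
    for a, b in gametes:
        label = genotype_label(a, b)
        counts[label] = counts.get(label, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Operational scoring through the assay pipeline


@dataclass(frozen=True)
class ReferenceAssay:
    """A designed scheme plus the band pattern of each allele class, computed
    once by in-silico PCR on constructed alleles of a synthetic locus."""

    patterns: dict[str, tuple[bool, bool, bool]]

    @classmethod
    def build(cls, seed: int = 0) -> "ReferenceAssay":
        cfg = SimLocusConfig(n_genes=3, gene_length=1200, intergenic_length=600,
                             flank_length=1500, seed=seed, name="assay_ref")
        locus = generate_locus(cfg)
        plen = 20
        locus, gl, gr = place_guide_pair(
            locus, cfg.flank_length - 200, len(locus) - cfg.flank_length + 180 - plen,
            nuclease="SpCas9", seed=seed)
        c1, c2 = cut_pair(gl, gr)
        scheme = design_tier_scheme(locus, c1, c2)
        ref = locus.sequence
        alleles = {
            "W": wildtype_allele(ref),
            "D": apply_deletion(ref, c1, c2),
            "V": apply_inversion(ref, c1, c2),
        }
        patterns = {}
        for letter, allele in alleles.items():
            bp = predict_band_pattern([allele, allele], scheme)
            patterns[letter] = bp.tiers
        return cls(patterns)

    def diploid_pattern(self, a: str, b: str) -> tuple[bool, bool, bool]:
        pa, pb = self.patterns[a], self.patterns[b]
        return tuple(x or y for x, y in zip(pa, pb))  # type: ignore[return-value]


def operational_frequencies(
    population: pd.DataFrame, assay: ReferenceAssay | None = None
) -> dict[str, float]:
    """Score a simulated population the way a PCR screen would.

    Band patterns come from the reference assay's per-class in-silico PCR
    results; genotypes are then called from the patterns. Complex individuals
    are excluded (and counted). Returns percentages: ``deletion_freq_pct``
    (tier-1-positive individuals) and ``delinver_freq_pct`` (DV calls).
    """
    if assay is None:
        assay = ReferenceAssay.build()
    usable = population[(population.allele_a != "C") & (population.allele_b != "C")]
    n = len(usable)
    if n == 0:
        return {"n": 0, "n_complex": len(population), "deletion_freq_pct": 0.0,
                "delinver_freq_pct": 0.0, "n_deletion": 0, "n_delinver": 0}
    # only six unordered class pairs exist; score each once, then count
    verdicts: dict[tuple[str, str], tuple[bool, bool]] = {}
    for x in "WDV":
        for y in "WDV":
            pattern = assay.diploid_pattern(x, y)
            is_dv = call_genotype(pattern, "three_tier").calls == frozenset({"DV"})
            verdicts[(x, y)] = (pattern[0], is_dv)
    tier1_pos = 0
    dv_calls = 0
    for a, b in zip(usable.allele_a, usable.allele_b):
        t1, is_dv = verdicts[(a, b)]
        tier1_pos += t1
        dv_calls += is_dv
    return {
        "n": n,
        "n_complex": len(population) - n,
        "n_deletion": tier1_pos,
        "n_delinver": dv_calls,
        "deletion_freq_pct": 100.0 * tier1_pos / n,
        "delinver_freq_pct": 100.0 * dv_calls / n,
    }


def sweep_efficiency(
    model_family: str,
    efficiencies: Sequence[float],
    n_per_point: int = 500,
    seed: int = 0,
    inversion_bias: float = 0.35,
    fate_weights: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2),
) -> pd.DataFrame:
    """Simulate populations across a grid of cutting efficiencies and score
    them operationally.

    An efficiency ``e`` is the per-cut success probability; a homolog is
    excised when both cuts fire (probability ``e**2``). In the empirical
    family an excised homolog becomes an inversion with probability
    ``inversion_bias`` and a deletion otherwise, coupling the two outcome
    frequencies the way concurrent cutting does. Returns one row per grid
    point with the operational deletion and delinver percentages.
    """
    if len(efficiencies) == 0:
        raise ParameterError("efficiency grid must be non-empty")
    if model_family not in ("empirical", "five_fate"):
        raise ParameterError(f"unknown model family {model_family!r}")
    assay = ReferenceAssay.build()
    rows = []
    for k, e in enumerate(efficiencies):
        if not 0.0 <= e <= 1.0:
            raise ParameterError("efficiencies must be in [0, 1]")
        excise = e * e
        if model_family == "empirical":
            model = EmpiricalModel(p_del=excise * (1 - inversion_bias),
                                   p_inv=excise * inversion_bias)
        else:
            model = FiveFateModel(cut_prob=excise, weights=fate_weights)
        pop = simulate_t1(PopulationConfig(n_per_point, model, seed=seed + k))
        freqs = operational_frequencies(pop, assay)
        rows.append({"efficiency": e, **freqs})
    return pd.DataFrame(rows)
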