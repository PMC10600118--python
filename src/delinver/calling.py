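"""Inverting band patterns to genotype classes.

A single allele contributes at most one positive tier: a wild-type (or
small-indel) allele amplifies only in tier 2, a deletion allele only in
tier 1, an inversion allele only in tier 3. A diploid's pattern is the OR of
its two alleles, so the six diploid classes map to six distinct three-tier
patterns — which is exactly why the third, co-aligned-primer tier is needed:
with tiers 1-2 alone the pairs {WW, WV} and {DD, DV} collapse, and a
deletion-inversion bi-allele is indistinguishable from a homozygous
deletion.

The caller works from this truth table. Small repair indels are invisible to
the assay by design (primers keep clear of the cut sites), so indel carriers
call as wild-type-like; every batch report carries that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Literal, Mapping

import pandas as pd

from .assay import BandPattern
from .editing import genotype_label
from .errors import ParameterError

Mode = Literal["two_tier", "three_tier"]

#: per-allele tier response (tier1, tier2, tier3)
ALLELE_TIER_RESPONSE: dict[str, tuple[bool, bool, bool]] = {
    "W": (False, True, False),
    "D": (True, False, False),
    "V": (False, False, True),
}

INDEL_CAVEAT = (
    "small indels at the cut sites are invisible to this assay; "
    "W calls cover wild-type and indel alleles"
)


@dataclass(frozen=True)
class TruthTable:
    """Mapping from an observed band pattern to the set of diploid classes
    that produce it, for a two- or three-tier assay."""

    mode: Mode
    mapping: Mapping[tuple[bool, ...], frozenset[str]]

    def lookup(self, pattern: tuple[bool, ...]) -> frozenset[str]:
        return self.mapping.get(tuple(pattern), frozenset())


def diploid_pattern(class_label: str) -> tuple[bool, bool, bool]:
    """Three-tier pattern of a diploid class: OR of its allele responses."""
    a, b = class_label
    ra, rb = ALLELE_TIER_RESPONSE[a], ALLELE_TIER_RESPONSE[b]
    return tuple(x or y for x, y in zip(ra, rb))  # type: ignore[return-value]


def build_truth_table(mode: Mode = "three_tier") -> TruthTable:
    if mode not in ("two_tier", "three_tier"):
        raise ParameterError(f"unknown mode {mode!r}")
    k = 3 if mode == "three_tier" else 2
    mapping: dict[tuple[bool, ...], set[str]] = {}
    for pair in combinations_with_replacement("WDV", 2):
        label = genotype_label(*pair)
        pat = diploid_pattern(label)[:k]
        mapping.setdefault(pat, set()).add(label)
    return TruthTable(mode, {p: frozenset(s) for p, s in mapping.items()})


_TABLES = {m: build_truth_table(m) for m in ("two_tier", "three_tier")}


@dataclass(frozen=True)
class CallResult:
    calls: frozenset[str]
    ambiguous: bool
    uninterpretable: bool

    @property
    def label(self) -> str:
        if self.uninterpretable:
            return "uninterpretable"
        return "/".join(sorted(self.calls))


def call_genotype(pattern: BandPattern | tuple[bool, ...], mode: Mode = "three_tier") -> CallResult:
    """Invert a band pattern to the set of compatible diploid classes.

    Three-tier calls are unique for every constructible class; two-tier calls
    return ambiguity sets ({WW, WV} and {DD, DV}). A pattern no genotype can
    produce (e.g. all-negative) yields an empty set flagged uninterpretable.
    """
    tiers = pattern.tiers if isinstance(pattern, BandPattern) else tuple(pattern)
    k = 3 if mode == "three_tier" else 2
    if len(tiers) < k:
        raise ParameterError(f"{mode} requires {k} tier booleans, got {len(tiers)}")
    calls = _TABLES[mode].lookup(tuple(bool(t) for t in tiers[:k]))
    return CallResult(calls, ambiguous=len(calls) > 1, uninterpretable=len(calls) == 0)


def call_batch(patterns: pd.DataFrame, mode: Mode = "three_tier") -> tuple[pd.DataFrame, dict]:
    """Call a table of individuals (columns: individual, tier1, tier2[, tier3]).

    Returns the per-individual call table and a summary dict with counts by
    call label, the number of malformed rows skipped, and the indel caveat.
    Malformed rows (missing tier values) are skipped and counted, not fatal.
    """
    needed = ["tier1", "tier2"] + (["tier3"] if mode == "three_tier" else [])
    rows, skipped = [], 0
    for idx, row in patterns.iterrows():
        try:
            if any(c not in row or pd.isna(row[c]) for c in needed):
                raise ValueError("missing tier value")
            tiers = tuple(bool(row[c]) for c in needed)
        except (KeyError, ValueError, TypeError):
            skipped += 1
            continue
        res = call_genotype(tiers, mode)
        rows.append({
            "individual": row["individual"] if "individual" in row else idx,
            **{c: row[c] for c in needed},
            "call": res.label,
            "ambiguous": res.ambiguous,
            "uninterpretable": res.uninterpretable,
        })
    calls = pd.DataFrame(
        rows,
        columns=["individual", *needed, "call", "ambiguous", "uninterpretable"],
    )
    counts = calls["call"].value_counts().to_dict() if len(calls) else {}
    summary = {"counts": counts, "n_called": len(calls), "n_skipped": skipped,
               "caveat": INDEL_CAVEAT}
    return calls, summary
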