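"""Summary statistics over genotype screens and re-entered count tables.

Works on per-guide-pair counts of the kind a paired-guide deletion screen
reports: how many transgenics were genotyped, how many carried a deletion
(tier-1 positive), and how many of those were deletion-inversion (DV)
bi-alleles. Derived quantities are the deletion frequency, the delinver
frequency, and the delinver:deletion ratio — plus Pearson correlation
between frequencies across guide pairs, median/maximum ratios, and a
chi-square goodness-of-fit test for Mendelian segregation counts.

Percentages are displayed rounded half-up to one decimal (full precision is
kept internally); re-entered published tables are reproduced to within one
rounding unit (0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ZeroVarianceError

_FIXTURES = {
    "table2": "table2_arabidopsis_tags.tsv",
    "table3": "table3_rice_tags.tsv",
    "table4": "table4_arabidopsis_nontags.tsv",
    "segregation": "segregation_t2.tsv",
}

#: the guide pairs of the 12-pair R-gene-locus block in the Arabidopsis table
RGENE_LOCUS = "AT5G45240/AtRPS4/AtRRS1"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the shipped count tables ('table2', 'table3', 'table4',
    'segregation') as a DataFrame."""
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise ParameterError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    ref = resources.files("delinver.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class SummaryRow:
    """One guide pair's screen outcome with derived frequencies.

    ``delinver_deletion_ratio_pct`` is None when no deletion carriers were
    found (the ratio is undefined, not zero).
    """

    locus: str
    guide_pair: str
    deletion_size_kb: str | float | None
    n_transgenic: int
    n_deletion: int
    n_delinver: int

    def __post_init__(self):
        if not 0 <= self.n_delinver <= self.n_deletion <= self.n_transgenic:
            raise ParameterError(
                f"{self.guide_pair}: need n_delinver <= n_deletion <= n_transgenic"
            )

    @property
    def deletion_freq_pct(self) -> float:
        return 100.0 * self.n_deletion / self.n_transgenic if self.n_transgenic else 0.0

    @property
    def delinver_freq_pct(self) -> float:
        return 100.0 * self.n_delinver / self.n_transgenic if self.n_transgenic else 0.0

    @property
    def delinver_deletion_ratio_pct(self) -> float | None:
        if self.n_deletion == 0:
            return None
        return 100.0 * self.n_delinver / self.n_deletion

    def as_dict(self, display: bool = False) -> dict:
        rnd = (lambda v: None if v is None else round_half_up(v)) if display else (lambda v: v)
        return {
            "locus": self.locus,
            "guide_pair": self.guide_pair,
            "deletion_size_kb": self.deletion_size_kb,
            "n_transgenic": self.n_transgenic,
            "n_deletion": self.n_deletion,
            "deletion_freq_pct": rnd(self.deletion_freq_pct),
            "n_delinver": self.n_delinver,
            "delinver_freq_pct": rnd(self.delinver_freq_pct),
            "delinver_deletion_ratio_pct": rnd(self.delinver_deletion_ratio_pct),
        }


def rows_from_counts(table: pd.DataFrame) -> list[SummaryRow]:
    """Build SummaryRows from a count table (fixture-style columns)."""
    rows = []
    for _, r in table.iterrows():
        rows.append(SummaryRow(
            locus=str(r.get("locus", "")),
            guide_pair=str(r["guide_pair"]),
            deletion_size_kb=r.get("deletion_size_kb"),
            n_transgenic=int(r["n_transgenic"]),
            n_deletion=int(r["n_deletion"]),
            n_delinver=int(r["n_delinver"]),
        ))
    return rows


def summarize(calls: pd.DataFrame, group_col: str = "guide_pair") -> list[SummaryRow]:
    """Summarise a per-individual call table into one row per guide pair.

    Expects columns ``tier1`` (deletion screen band) and ``call`` (three-tier
    call label); every individual counts toward ``n_transgenic``.
    """
    rows = []
    for key, grp in calls.groupby(group_col, sort=True):
        rows.append(SummaryRow(
            locus=str(grp["locus"].iloc[0]) if "locus" in grp else "",
            guide_pair=str(key),
            deletion_size_kb=grp["deletion_size_kb"].iloc[0] if "deletion_size_kb" in grp else None,
            n_transgenic=len(grp),
            n_deletion=int(grp["tier1"].astype(bool).sum()),
            n_delinver=int((grp["call"] == "DV").sum()),
        ))
    return rows


def pearson_r2(x, y) -> dict[str, float]:
    """Pearson product-moment correlation and its square.

    Requires at least 3 paired points with non-zero variance in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("need two equal-length vectors of >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(sps.pearsonr(x, y).statistic)
    return {"r": r, "r_squared": r * r}


def frequency_correlation(rows: list[SummaryRow]) -> dict[str, float]:
    """R² between per-pair delinver and deletion frequencies (all pairs of the
    block included, zero-deletion pairs too)."""
    x = [r.deletion_freq_pct for r in rows]
    y = [r.delinver_freq_pct for r in rows]
    return pearson_r2(x, y)


def ratio_summary(rows: list[SummaryRow]) -> dict:
    """Median and maximum delinver:deletion ratio over rows where the ratio is
    defined (pairs with zero deletion carriers are excluded, not zeroed)."""
    ratios = [r.delinver_deletion_ratio_pct for r in rows
              if r.delinver_deletion_ratio_pct is not None]
    if not ratios:
        return {"median_ratio_pct": None, "max_ratio_pct": None, "n_defined": 0}
    return {
        "median_ratio_pct": float(np.median(ratios)),
        "max_ratio_pct": float(max(ratios)),
        "n_defined": len(ratios),
    }


def chisq_gof(observed, expected_ratios) -> dict[str, float]:
    """Pearson chi-square goodness of fit of counts against expected
    proportions, with df = k - 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_ratios, dtype=float)
    if obs.shape != props.shape or obs.ndim != 1:
        raise ParameterError("observed and expected_ratios must be equal-length vectors")
    if (obs < 0).any():
        raise ParameterError("counts must be non-negative")
    if not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise ParameterError("expected proportions must sum to 1")
    if (props <= 0).any():
        raise ParameterError("zero expected cell")
    expected = props * obs.sum()
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return {"chi2": float(chi2), "df": len(obs) - 1, "p": float(p)}


def verify_table_percentages(table: pd.DataFrame, tol: float = 0.1) -> pd.DataFrame:
    """Recompute every derived percentage of a printed count table and report
    the absolute error against the printed value.

    Printed ratio cells with a zero denominator are skipped (the published
    tables print 0 there, but the quantity is undefined).
    """
    rows = rows_from_counts(table)
    recs = []
    for row, (_, printed) in zip(rows, table.iterrows()):
        checks = [
            ("deletion_freq_pct", row.deletion_freq_pct, printed["printed_deletion_freq_pct"]),
            ("delinver_freq_pct", row.delinver_freq_pct, printed["printed_delinver_freq_pct"]),
        ]
        if row.delinver_deletion_ratio_pct is not None:
            checks.append(("delinver_deletion_ratio_pct",
                           row.delinver_deletion_ratio_pct, printed["printed_ratio_pct"]))
        for name, computed, printed_val in checks:
            recs.append({
                "guide_pair": row.guide_pair,
                "quantity": name,
                "computed": computed,
                "printed": float(printed_val),
                "abs_error": abs(computed - float(printed_val)),
                "within_tol": abs(computed - float(printed_val)) <= tol,
            })
    return pd.DataFrame(recs)
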