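"""Burden statistics: corrected odds ratios, exact tests, FDR, tallies.

The carrier unit throughout is the sample: for a given gene, a case is
positive if it harbors at least one qualifying variant, however many it
has. Odds ratios and their 95% confidence intervals are computed on
Haldane–Anscombe corrected tables (0.5 added to each of the four cells,
unconditionally), which keeps zero-cell tables finite and reproduces
published values; exact tests are computed on the uncorrected integer
tables, since exact null distributions require integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._round import format_ci_bound, format_or, format_pct, round_half_up

__all__ = [
    "ContingencyTable",
    "BurdenResult",
    "ha_odds_ratio",
    "woolf_ci",
    "fisher_two_sided",
    "bh_fdr",
    "binomial_two_sided",
    "spearman_rho2",
    "per_gene_burden",
    "case_tally",
    "SARCOMERE_PRIOR",
]

# Prior for the sarcomere-enrichment binomial test: the fraction of
# sarcomere genes on the curated 84-gene panel.
SARCOMERE_PRIOR = 9 / 84


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: (case/control) x (positive/negative)."""

    a: int  # case positive
    b: int  # case negative
    c: int  # control positive
    d: int  # control negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_carriers(cls, case_carriers: int, n_cases: int, control_carriers: int, n_controls: int) -> "ContingencyTable":
        return cls(case_carriers, n_cases - case_carriers, control_carriers, n_controls - control_carriers)

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass
class BurdenResult:
    gene: str
    table: ContingencyTable
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    q: Optional[float] = None

    def display(self) -> str:
        return (
            f"{self.gene}: OR = {format_or(self.or_value)}, "
            f"CI: {format_ci_bound(self.ci_low)}-{format_ci_bound(self.ci_high)}"
        )


def ha_odds_ratio(t: ContingencyTable) -> float:
    """Odds ratio on the 0.5-corrected table; always finite and positive."""
    return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))


def woolf_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-OR interval on the corrected cells.

    exp(ln OR ± z * sqrt(Σ 1/(cell + 0.5))) with z the standard-normal
    quantile for ``level``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    log_or = math.log(ha_odds_ratio(t))
    se = math.sqrt(sum(1.0 / (cell + 0.5) for cell in (t.a, t.b, t.c, t.d)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p on the uncorrected integer table.

    Two-sidedness follows the point-probability (minimum-likelihood) rule:
    the p-value sums hypergeometric probabilities of all tables with the
    same margins whose point probability does not exceed the observed one.
    """
    return float(sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1])


def bh_fdr(
    pvalues: Sequence[float], tested_mask: Optional[Sequence[bool]] = None
) -> list[Optional[float]]:
    """Benjamini–Hochberg step-up over the masked-in subset.

    Entries with ``tested_mask`` False (e.g. genes where no variant was
    observed in any sample) receive ``None`` and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    mask = np.ones(len(p), bool) if tested_mask is None else np.asarray(tested_mask, bool)
    out: list[Optional[float]] = [None] * len(p)
    if mask.any():
        q = multipletests(p[mask], method="fdr_bh")[1]
        for i, qi in zip(np.flatnonzero(mask), q):
            out[i] = float(qi)
    return out


def binomial_two_sided(k: int, n: int, p0: float = SARCOMERE_PRIOR) -> float:
    """Two-sided exact binomial p (minimum-likelihood rule)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def spearman_rho2(
    x: Sequence[float], y: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Squared Spearman correlation with its two-sided t-approximation p.

    Average ranks for ties; a constant vector leaves the correlation
    undefined and returns ``(None, None)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (None, None)
    rho, p = sps.spearmanr(x, y)
    return (float(rho) ** 2, float(p))


def per_gene_burden(
    carriers_by_gene: Mapping[str, tuple[int, int]],
    n_cases: int,
    n_controls: int,
) -> list[BurdenResult]:
    """Per-gene OR/CI/Fisher with FDR over genes where any carrier was seen.

    ``carriers_by_gene`` maps gene -> (case carriers, control carriers),
    counting distinct carrier samples.
    """
    genes = sorted(carriers_by_gene)
    results = []
    for g in genes:
        a, c = carriers_by_gene[g]
        if a > n_cases or c > n_controls:
            raise ValueError(f"carrier counts exceed cohort sizes for {g}")
        t = ContingencyTable.from_carriers(a, n_cases, c, n_controls)
        lo, hi = woolf_ci(t)
        results.append(
            BurdenResult(
                gene=g,
                table=t,
                or_value=ha_odds_ratio(t),
                ci_low=lo,
                ci_high=hi,
                p=fisher_two_sided(t),
            )
        )
    tested = [r.table.a + r.table.c > 0 for r in results]
    for r, q in zip(results, bh_fdr([r.p for r in results], tested)):
        r.q = q
    return results


_TALLY_FIELDS = (
    ("coding_positive", "cases with pathogenic coding variants in known genes"),
    ("cnv_positive", "cases with pathogenic CNVs in known genes"),
    ("regulatory_positive", "gene-elusive cases with prioritized regulatory variants"),
    ("candidate_lof", "gene-elusive cases with candidate-gene LoF variants"),
    ("gene_elusive", "cases without pathogenic coding variants in known genes"),
    ("multiple_coding", "cases with multiple coding variants"),
    ("multiple_regulatory", "cases with multiple prioritized regulatory variants"),
    ("both_types", "cases with both coding and regulatory variants"),
)


def case_tally(classifications: Sequence, n_cases: int) -> list[dict]:
    """Cohort yield table: counts and percentages per verdict category.

    ``classifications`` are per-case objects with boolean attributes named
    as in the table rows. Percentages are half-up with one decimal; the
    whole-percent rendering used in summary figures is also provided.
    """
    rows = []
    for name, description in _TALLY_FIELDS:
        count = sum(1 for c in classifications if getattr(c, name, False))
        pct = 100.0 * count / n_cases if n_cases else 0.0
        rows.append(
            {
                "category": name,
                "description": description,
                "count": count,
                "pct": round_half_up(pct, 1),
                "pct_display": format_pct(pct, 1),
                "pct_whole": f"{round_half_up(pct, 0):.0f}",
            }
        )
    return rows
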