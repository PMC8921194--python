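"""High-risk regulatory variant cascade and two-pass gene prioritization.

A regulatory SNV is *high-risk* when it falls in an established regulatory
site (Regulatory Build overlap), is rare in population controls (gnomAD
MAF < 0.01%, strict; absent passes) and is predicted to alter TF binding
by at least 3 of 4 tools. CNVs and indels under 1 kb overlapping
promoter/enhancer regions bypass the TFBS consensus (the predictors are
SNV-oriented) but face every other gate.

Prioritization is two-pass, restricted to gene-elusive cases: pass 1
keeps high-risk candidates in LV-active elements with Popmax AF < 0.1%
that are not cohort-frequent (< 1.5% of case samples) and are carried by a
gene-elusive case; pass 2 computes the per-gene Haldane–Anscombe odds
ratio over distinct carrier samples of pass-1 variants (cases vs
controls) and keeps candidates whose gene reaches OR >= 1.3.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .cohort import SampleEntry
from .regions import RegulatoryRegion
from .stats import ContingencyTable, ha_odds_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "RegThresholds",
    "RegulatoryCandidate",
    "tfbs_consensus",
    "high_risk_filter",
    "cohort_frequency_exclusion",
    "pass1_filter",
    "prioritize",
    "carriers_by_gene",
]


@dataclass(frozen=True)
class RegThresholds:
    """Regulatory cascade thresholds; defaults follow the published rules."""

    tfbs_min_tools: int = 3  # at least 3 of 4 tools
    gnomad_af_max: float = 1e-4  # MAF < 0.01%, strict
    popmax_af_max: float = 1e-3  # Popmax AF < 0.1%, strict
    cohort_fraction_max: float = 0.015  # excluded at >= 1.5%, inclusive
    or_min: float = 1.3  # per-gene enrichment gate, inclusive


@dataclass
class RegulatoryCandidate:
    variant_key: tuple[str, int, str, str]
    sample_id: str
    region: RegulatoryRegion
    gene: str
    tfbs_altered_count: int = 0
    gnomad_af: Optional[float] = None
    popmax_af: Optional[float] = None
    variant_class: Literal["snv", "indel", "cnv"] = "snv"
    cohort_fraction: float = 0.0
    high_risk: bool = False
    prioritized: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.tfbs_altered_count <= 4):
            raise ValueError("tfbs_altered_count must be 0-4")


def tfbs_consensus(verdicts: Sequence[bool], min_tools: int = 3) -> bool:
    """TF-binding alteration consensus: >= ``min_tools`` of exactly 4 verdicts."""
    if len(verdicts) != 4:
        raise ValueError(f"exactly 4 TFBS verdicts required, got {len(verdicts)}")
    return sum(bool(v) for v in verdicts) >= min_tools


def _passes_af(af: Optional[float], threshold: float) -> bool:
    return af is None or af < threshold


def high_risk_filter(
    candidate: RegulatoryCandidate, thresholds: RegThresholds = RegThresholds()
) -> bool:
    """Regulatory-build overlap + rarity + TFBS consensus (SNVs only for TFBS)."""
    if not candidate.region.in_regulatory_build:
        return False
    if not _passes_af(candidate.gnomad_af, thresholds.gnomad_af_max):
        return False
    if candidate.variant_class == "snv":
        return candidate.tfbs_altered_count >= thresholds.tfbs_min_tools
    # CNVs / sub-kb indels bypass the SNV-oriented TFBS predictors
    return True


def cohort_frequency_exclusion(
    carriers: int, n_samples: int, threshold: float = 0.015
) -> bool:
    """True (excluded) when carriers / n_samples >= threshold (inclusive)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return carriers / n_samples >= threshold


def carriers_by_gene(
    candidates: Sequence[RegulatoryCandidate], samples: Sequence[SampleEntry]
) -> dict[str, tuple[int, int]]:
    """Distinct carrier samples per gene, split case/control."""
    cohort_of = {s.sample_id: s.cohort for s in samples}
    case_carriers: dict[str, set[str]] = defaultdict(set)
    control_carriers: dict[str, set[str]] = defaultdict(set)
    for c in candidates:
        cohort = cohort_of.get(c.sample_id)
        if cohort == "case":
            case_carriers[c.gene].add(c.sample_id)
        elif cohort == "control":
            control_carriers[c.gene].add(c.sample_id)
    genes = set(case_carriers) | set(control_carriers)
    return {g: (len(case_carriers[g]), len(control_carriers[g])) for g in genes}


def pass1_filter(
    candidates: Sequence[RegulatoryCandidate],
    samples: Sequence[SampleEntry],
    gene_elusive: set[str],
    thresholds: RegThresholds = RegThresholds(),
) -> list[RegulatoryCandidate]:
    """Variant-level pass: high-risk + LV-active + Popmax rarity + cohort
    frequency, with the gene-elusive gate applied to case carriers.

    Control candidates face every variant-level filter but no gene-elusive
    gate (controls have no coding workup); they feed the per-gene tables.
    """
    n_cases = sum(1 for s in samples if s.cohort == "case")
    cohort_of = {s.sample_id: s.cohort for s in samples}

    # cohort frequency per variant, over case samples of the study cohort
    case_carriers_by_key: dict[tuple, set[str]] = defaultdict(set)
    for c in candidates:
        if cohort_of.get(c.sample_id) == "case":
            case_carriers_by_key[c.variant_key].add(c.sample_id)

    pass1: list[RegulatoryCandidate] = []
    for c in candidates:
        c.high_risk = high_risk_filter(c, thresholds)
        c.cohort_fraction = len(case_carriers_by_key[c.variant_key]) / n_cases if n_cases else 0.0
        if not c.high_risk or not c.region.lv_active:
            continue
        if not _passes_af(c.popmax_af, thresholds.popmax_af_max):
            continue
        if cohort_frequency_exclusion(
            len(case_carriers_by_key[c.variant_key]), n_cases, thresholds.cohort_fraction_max
        ):
            continue
        is_case = cohort_of.get(c.sample_id) == "case"
        if is_case and c.sample_id not in gene_elusive:
            continue
        pass1.append(c)
    return pass1


def prioritize(
    candidates: Sequence[RegulatoryCandidate],
    samples: Sequence[SampleEntry],
    gene_elusive: set[str],
    thresholds: RegThresholds = RegThresholds(),
) -> list[RegulatoryCandidate]:
    """Two-pass prioritization of regulatory candidates (see module docstring).

    Returns the retained case candidates; every one is carried by a
    gene-elusive case and sits in a gene whose pass-1 carrier odds ratio is
    at least ``thresholds.or_min``. Control carriers contribute to the
    per-gene tables but are never returned.
    """
    n_cases = sum(1 for s in samples if s.cohort == "case")
    n_controls = sum(1 for s in samples if s.cohort == "control")
    if n_controls == 0:
        raise ValueError("no control samples supplied; odds ratios are undefined")
    cohort_of = {s.sample_id: s.cohort for s in samples}

    pass1 = pass1_filter(candidates, samples, gene_elusive, thresholds)
    counts = carriers_by_gene(pass1, samples)
    gene_or = {
        g: ha_odds_ratio(ContingencyTable.from_carriers(a, n_cases, c_, n_controls))
        for g, (a, c_) in counts.items()
    }
    retained = []
    for c in pass1:
        if cohort_of.get(c.sample_id) != "case":
            continue
        if gene_or.get(c.gene, 0.0) >= thresholds.or_min:
            c.prioritized = True
            c.flags.append(f"gene_or={gene_or[c.gene]:.3g}")
            retained.append(c)
    logger.info(
        "prioritize: %d candidates -> %d pass-1 -> %d retained in %d genes",
        len(candidates),
        len(pass1),
        len(retained),
        len({c.gene for c in retained}),
    )
    return retained
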