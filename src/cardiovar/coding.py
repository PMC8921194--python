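"""Protein-coding variant prioritization cascade.

Rules, in cascade order: population rarity (gnomAD MAF < 0.01%, strict,
with gnomAD-absent treated as rare), loss-of-function consequence with
high annotator confidence, cryptic-splice delta score >= 0.5 inside
transcribed regions, missense consensus across prediction tools, and
zygosity concordance with the gene's expected mode of inheritance. A
case is coding-positive if at least one variant survives the cascade in a
known panel gene; Tier-2 and secondary genes additionally require a
reportable ClinVar assertion. Gene-elusive cases are then scanned for
rare high-confidence LoF variants in candidate genes expressed in heart.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .cohort import GeneEntry, SampleEntry, VariantAnnotation, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "CodingVerdict",
    "is_rare",
    "classify_lof",
    "cryptic_splice_filter",
    "missense_consensus",
    "zygosity_concordance",
    "classify_variant_coding",
    "classify_case_coding",
    "candidate_lof_scan",
]

LOF_CONSEQUENCES = frozenset({"frameshift", "stopgain", "stoploss", "splice_dinucleotide"})
# consequences placed inside a gene's transcribed sequence
TRANSCRIBED = frozenset(
    {"missense", "frameshift", "stopgain", "stoploss", "splice_dinucleotide", "synonymous", "intronic"}
)


@dataclass(frozen=True)
class Thresholds:
    """Cascade thresholds; defaults follow the published filter rules."""

    rare_af: float = 1e-4  # gnomAD MAF < 0.01%, strict
    splice_delta_min: float = 0.5  # delta score threshold, inclusive
    pli_min: float = 0.9  # pLI > 0.9, strict
    family_frac_max: float = 0.01  # carried by < 1% of unrelated families, strict
    missense_tools_min: int = 5  # at least five predictors must report


@dataclass
class CodingVerdict:
    sample_id: str
    variant_key: tuple[str, int, str, str]
    gene: str
    klass: Literal[
        "pathogenic_lof", "pathogenic_missense", "cryptic_splice", "candidate_lof", "not_prioritized"
    ]
    zygosity_concordant: bool = False
    reasons: list[str] = field(default_factory=list)
    genotype: str = "missing"
    clinvar_status: str = "unreported"
    prioritized: bool = False

    def __post_init__(self) -> None:
        if self.klass != "not_prioritized" and not self.reasons:
            raise ValueError("a prioritized verdict must carry reasons")


def is_rare(af: Optional[float], threshold: float) -> bool:
    """Strictly below threshold; absent from the reference population passes."""
    if af is None:
        return True
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency must be in [0, 1], got {af}")
    return af < threshold


def classify_lof(annotation: VariantAnnotation) -> bool:
    """High-confidence loss of function: LoF consequence + high annotator confidence.

    Low-confidence flags (LOFTEE-style rescue signals) demote the call.
    """
    return annotation.consequence in LOF_CONSEQUENCES and annotation.lof_confidence == "high"


def cryptic_splice_filter(delta: Optional[float], in_transcribed_region: bool) -> bool:
    """Cryptic-splice call: delta score >= 0.5 (inclusive) inside a transcribed region."""
    if delta is None:
        return False
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"splice delta must be in [0, 1], got {delta}")
    return delta >= 0.5 and in_transcribed_region


def missense_consensus(
    verdicts: Sequence[tuple[str, bool]], min_tools: int = 5
) -> bool:
    """Deleterious consensus: >= ``min_tools`` reporting and a strict majority deleterious."""
    if not verdicts:
        raise ValueError("at least one missense verdict required")
    n = len(verdicts)
    if n < min_tools:
        return False
    deleterious = sum(1 for _, v in verdicts if v)
    return 2 * deleterious > n


def zygosity_concordance(genotype: str, inheritance: str) -> bool:
    """Observed zygosity vs the gene's expected disease mode of inheritance.

    Compound heterozygosity in AR genes is resolved at case level
    (two distinct qualifying het alleles in the same gene and sample).
    """
    if genotype == "missing":
        raise ValueError("genotype must not be missing")
    if inheritance not in ("AD", "AR", "XL"):
        logger.warning("unknown inheritance %r; treating as AD", inheritance)
        inheritance = "AD"
    if inheritance == "AD":
        return genotype in ("het", "hom_alt")
    if inheritance == "AR":
        return genotype == "hom_alt"
    return genotype in ("hemi", "hom_alt")


def classify_variant_coding(
    record: VariantRecord,
    gene: GeneEntry,
    thresholds: Thresholds = Thresholds(),
) -> CodingVerdict:
    """Per-variant verdict for one record mapped to one panel gene."""
    a = record.annotation
    reasons: list[str] = []
    klass = "not_prioritized"
    rare = is_rare(a.gnomad_af, thresholds.rare_af)
    if rare:
        if classify_lof(a):
            klass = "pathogenic_lof"
            reasons = ["rare", "high_confidence_lof"]
        elif cryptic_splice_filter(a.splice_delta, a.consequence in TRANSCRIBED):
            klass = "cryptic_splice"
            reasons = ["rare", f"splice_delta>={thresholds.splice_delta_min}"]
        elif a.consequence == "missense" and a.missense_verdicts and missense_consensus(
            a.missense_verdicts, thresholds.missense_tools_min
        ):
            klass = "pathogenic_missense"
            reasons = ["rare", "missense_consensus"]
    concordant = (
        record.genotype != "missing"
        and zygosity_concordance(record.genotype, gene.inheritance)
    )
    return CodingVerdict(
        sample_id=record.sample_id,
        variant_key=record.key,
        gene=gene.symbol,
        klass=klass,
        zygosity_concordant=concordant,
        reasons=reasons,
        genotype=record.genotype,
        clinvar_status=a.clinvar_status,
    )


_POSITIVE_CLASSES = frozenset({"pathogenic_lof", "pathogenic_missense", "cryptic_splice"})
_REPORTABLE = frozenset({"pathogenic", "likely_pathogenic"})


def classify_case_coding(
    sample_id: str,
    verdicts: Sequence[CodingVerdict],
    registry: Sequence[GeneEntry],
) -> bool:
    """Case-level coding status from the sample's per-variant verdicts.

    Positive iff >= 1 prioritized variant in a known panel gene that is
    zygosity-concordant — with AR compound heterozygosity allowed (two
    distinct qualifying het alleles in one gene; phase unknown, so this can
    over-call cis pairs). Tier-2/secondary genes require a reportable
    ClinVar assertion (pathogenic or likely pathogenic).
    """
    genes = {e.symbol: e for e in registry}
    mine = [v for v in verdicts if v.sample_id == sample_id and v.klass in _POSITIVE_CLASSES]
    by_gene: dict[str, list[CodingVerdict]] = defaultdict(list)
    for v in mine:
        if v.gene in genes and genes[v.gene].tier in ("1", "2"):
            by_gene[v.gene].append(v)
    for gene, vs in by_gene.items():
        entry = genes[gene]
        gated = vs
        if entry.tier == "2" or entry.cmp_class == "secondary":
            gated = [v for v in vs if v.clinvar_status in _REPORTABLE]
        if not gated:
            continue
        if any(v.zygosity_concordant for v in gated):
            return True
        if entry.inheritance == "AR":
            het_keys = {v.variant_key for v in gated if v.genotype == "het"}
            if len(het_keys) >= 2:  # compound het
                return True
    return False


def candidate_lof_scan(
    gene_elusive_samples: Sequence[str],
    variants: Sequence[VariantRecord],
    candidate_genes: Sequence[GeneEntry],
    samples: Sequence[SampleEntry],
    thresholds: Thresholds = Thresholds(),
    gene_of_variant: Optional[dict[tuple[str, int, str, str], str]] = None,
) -> list[CodingVerdict]:
    """Rare LoF scan over candidate genes in gene-elusive cases.

    Retains high-confidence LoF variants with gnomAD AF < 0.01%, carried by
    < 1% of distinct families in the case cohort (strict fraction over
    family_ids, never sample counts), in genes with moderate-to-high heart
    expression. Variants in highly constrained genes (pLI > 0.9) are
    additionally flagged as prioritized.
    """
    candidates = {e.symbol: e for e in candidate_genes}
    family_of = {s.sample_id: s.family_id for s in samples if s.cohort == "case"}
    n_families = len(set(family_of.values()))
    elusive = set(gene_elusive_samples)

    families_by_key: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)
    for r in variants:
        if r.sample_id in family_of:
            families_by_key[r.key].add(family_of[r.sample_id])

    out = []
    for r in variants:
        if r.sample_id not in elusive:
            continue
        gene_symbol = gene_of_variant.get(r.key) if gene_of_variant else None
        if gene_symbol is None or gene_symbol not in candidates:
            continue
        gene = candidates[gene_symbol]
        a = r.annotation
        if not classify_lof(a):
            continue
        if not is_rare(a.gnomad_af, thresholds.rare_af):
            continue
        frac = len(families_by_key[r.key]) / n_families if n_families else 1.0
        if not (frac < thresholds.family_frac_max):
            continue
        if gene.heart_expression not in ("moderate", "high"):
            continue
        prioritized = gene.pli is not None and gene.pli > thresholds.pli_min
        reasons = ["high_confidence_lof", "rare", "family_frac<1%", "heart_expressed"]
        if prioritized:
            reasons.append("pli>0.9")
        out.append(
            CodingVerdict(
                sample_id=r.sample_id,
                variant_key=r.key,
                gene=gene.symbol,
                klass="candidate_lof",
                zygosity_concordant=True,
                reasons=reasons,
                genotype=r.genotype,
                clinvar_status=a.clinvar_status,
                prioritized=prioritized,
            )
        )
    return out
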