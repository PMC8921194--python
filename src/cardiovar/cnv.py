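"""CNV consensus and context filtering.

Two read-depth callers produce per-sample callsets; a call is kept only
when both callers agree (>= 50% reciprocal overlap, same copy-number
type), the consensus interval is > 1 kb, it lies mostly outside
problematic sequence (< 70% of its bases in telomere/centromere/segmental
duplication masks, < 30% in copy-number-prone regions), and it is rare
(< 1% frequency in a reference CNV panel, matched at >= 50% reciprocal
overlap). The consensus representative is the intersection of the two
calls — the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "CnvCall",
    "GenomicMask",
    "reciprocal_overlap",
    "mask_overlap_fraction",
    "consensus_filter",
    "cnv_gene_overlap",
]

MIN_CONSENSUS_LEN = 1000  # "> 1 kb", strict
MIN_RECIPROCAL = 0.5  # "at least 50%", inclusive
MAX_MASK_FRAC = 0.7  # "< 70%", strict
MAX_CN_PRONE_FRAC = 0.3  # "< 30%", strict
MAX_PANEL_FREQ = 0.01  # "< 1%", strict


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    cn_type: Literal["deletion", "duplication"]
    caller: Literal["A", "B"]

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"CNV interval must span >= 1 bp: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class GenomicMask:
    """Named set of masked intervals per chromosome, merged on construction."""

    name: Literal["telomere", "centromere", "segdup", "cn_prone"]
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {c: _merge_intervals(iv) for c, iv in self.intervals.items()}


def reciprocal_overlap(
    i1: tuple[str, int, int], i2: tuple[str, int, int]
) -> tuple[float, float]:
    """Overlap of two intervals as a fraction of each interval's own length."""
    c1, s1, e1 = i1
    c2, s2, e2 = i2
    if c1 != c2:
        return (0.0, 0.0)
    inter = max(0, min(e1, e2) - max(s1, s2))
    return (inter / (e1 - s1), inter / (e2 - s2))


def mask_overlap_fraction(
    cnv: tuple[str, int, int], mask: GenomicMask | Sequence[GenomicMask]
) -> float:
    """Fraction of CNV bases covered by the union of mask intervals."""
    chrom, start, end = cnv
    masks = [mask] if isinstance(mask, GenomicMask) else list(mask)
    pooled = [iv for m in masks for iv in m.intervals.get(chrom, [])]
    covered = sum(
        max(0, min(end, me) - max(start, ms)) for ms, me in _merge_intervals(pooled)
    )
    return covered / (end - start)


def _panel_frequency(
    interval: tuple[str, int, int],
    cn_type: str,
    panel_freqs: Sequence[tuple[tuple[str, int, int], str, float]],
) -> float:
    """Highest frequency among panel regions matching at >= 50% reciprocal overlap."""
    best = 0.0
    for region, ptype, freq in panel_freqs:
        if ptype != cn_type:
            continue
        f1, f2 = reciprocal_overlap(interval, region)
        if f1 >= MIN_RECIPROCAL and f2 >= MIN_RECIPROCAL:
            best = max(best, freq)
    return best


def consensus_filter(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    masks: dict[str, GenomicMask],
    panel_freqs: Sequence[tuple[tuple[str, int, int], str, float]] = (),
) -> list[CnvCall]:
    """Consensus calls surviving size, context and rarity filters.

    A sample with calls from only one caller yields no consensus (no
    single-caller rescue). The retained call is the intersection interval,
    attributed to caller A.
    """
    context_masks = [masks[n] for n in ("telomere", "centromere", "segdup") if n in masks]
    cn_prone = masks.get("cn_prone")

    by_sample_b: dict[tuple[str, str, str], list[CnvCall]] = {}
    for b in calls_b:
        by_sample_b.setdefault((b.sample_id, b.chrom, b.cn_type), []).append(b)

    retained: list[CnvCall] = []
    seen: set[tuple] = set()
    for a in calls_a:
        for b in by_sample_b.get((a.sample_id, a.chrom, a.cn_type), []):
            f1, f2 = reciprocal_overlap((a.chrom, a.start, a.end), (b.chrom, b.start, b.end))
            if f1 < MIN_RECIPROCAL or f2 < MIN_RECIPROCAL:
                continue
            start, end = max(a.start, b.start), min(a.end, b.end)
            interval = (a.chrom, start, end)
            if end - start <= MIN_CONSENSUS_LEN:
                continue
            if context_masks and not (
                mask_overlap_fraction(interval, context_masks) < MAX_MASK_FRAC
            ):
                continue
            if cn_prone is not None and not (
                mask_overlap_fraction(interval, cn_prone) < MAX_CN_PRONE_FRAC
            ):
                continue
            if not (_panel_frequency(interval, a.cn_type, panel_freqs) < MAX_PANEL_FREQ):
                continue
            key = (a.sample_id, a.chrom, start, end, a.cn_type)
            if key not in seen:
                seen.add(key)
                retained.append(
                    CnvCall(
                        sample_id=a.sample_id,
                        chrom=a.chrom,
                        start=start,
                        end=end,
                        cn_type=a.cn_type,
                        caller="A",
                    )
                )
    return retained


def cnv_gene_overlap(
    cnv: CnvCall,
    registry_exons: Sequence[tuple[str, tuple[str, int, int]]],
    regulatory_regions: Sequence = (),
) -> dict[str, list]:
    """Label a CNV with the coding exons and regulatory regions it touches.

    ``registry_exons`` are ``(gene, (chrom, start, end))`` pairs; regulatory
    regions are :class:`~cardiovar.regions.RegulatoryRegion`. Returns
    ``{"coding": [genes], "regulatory": [(kind, genes)]}``.
    """
    coding = sorted(
        {
            gene
            for gene, (chrom, s, e) in registry_exons
            if chrom == cnv.chrom and max(cnv.start, s) < min(cnv.end, e)
        }
    )
    regulatory = [
        (r.kind, list(r.linked_genes))
        for r in regulatory_regions
        if r.chrom == cnv.chrom and max(cnv.start, r.start) < min(cnv.end, r.end)
    ]
    return {"coding": coding, "regulatory": regulatory}
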