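"""Regulatory element construction: promoters, enhancers, gene links.

Coordinates are BED-style 0-based half-open throughout. A VCF 1-based
position ``p`` overlaps a region ``[s, e)`` iff ``s <= p - 1 < e``.

The experimentally derived heart regulatory element set (open-chromatin and
histone-mark peaks merged per gene) is consumed as a BED input; the
fallback promoter window (1.5 kb upstream / 1 kb downstream of the TSS)
applies only to genes without provided regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryRegion",
    "Tss",
    "fallback_promoter",
    "merge_regions",
    "link_enhancer_to_gene",
    "region_set_summary",
    "variant_overlaps_region",
    "read_regions_bed",
    "write_regions_bed",
    "read_tss_table",
]

PROMOTER_UP = 1500
PROMOTER_DOWN = 1000


@dataclass
class RegulatoryRegion:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    kind: Literal["promoter", "enhancer"]
    linked_genes: list[str] = field(default_factory=list)
    lv_active: bool = False
    in_regulatory_build: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if not self.linked_genes:
            raise ValueError("linked_genes must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Tss:
    gene: str
    chrom: str
    position: int  # 0-based
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")


def fallback_promoter(
    tss: Tss, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
) -> RegulatoryRegion:
    """Promoter window around a TSS: ``up`` bp upstream, ``down`` downstream.

    Upstream/downstream follow the gene's strand; the window is clipped at
    the chromosome start. Width is ``up + down`` when unclipped, on either
    strand.
    """
    if up <= 0 or down <= 0:
        raise ValueError("up and down must be positive")
    if tss.strand == "+":
        start, end = tss.position - up, tss.position + down
    else:
        start, end = tss.position - down, tss.position + up
    start = max(start, 0)
    if start >= end:
        raise ValueError(f"promoter window for {tss.gene} is empty after clipping")
    return RegulatoryRegion(
        chrom=tss.chrom,
        start=start,
        end=end,
        kind="promoter",
        linked_genes=[tss.gene],
        lv_active=False,
        in_regulatory_build=False,
    )


def merge_regions(regions: Sequence[RegulatoryRegion]) -> list[RegulatoryRegion]:
    """Merge overlapping or book-ended regions of the same kind.

    Gene links take the union; activity/regulatory-build flags take the
    logical OR. Kinds never merge with each other. Output is sorted and,
    within each kind, non-overlapping. The merged set covers exactly the
    same bases as the input.
    """
    merged: list[RegulatoryRegion] = []
    for kind in ("promoter", "enhancer"):
        pool = sorted(
            (r for r in regions if r.kind == kind), key=lambda r: (r.chrom, r.start, r.end)
        )
        current: Optional[RegulatoryRegion] = None
        for r in pool:
            if (
                current is not None
                and r.chrom == current.chrom
                and r.start <= current.end  # book-ended intervals merge
            ):
                current.end = max(current.end, r.end)
                current.linked_genes = sorted(set(current.linked_genes) | set(r.linked_genes))
                current.lv_active = current.lv_active or r.lv_active
                current.in_regulatory_build = current.in_regulatory_build or r.in_regulatory_build
            else:
                if current is not None:
                    merged.append(current)
                current = RegulatoryRegion(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    kind=r.kind,
                    linked_genes=sorted(set(r.linked_genes)),
                    lv_active=r.lv_active,
                    in_regulatory_build=r.in_regulatory_build,
                )
        if current is not None:
            merged.append(current)
    merged.sort(key=lambda r: (r.chrom, r.start, r.end, r.kind))
    return merged


def link_enhancer_to_gene(
    enhancer: tuple[str, int, int],
    tss_list: Sequence[Tss],
    provided_links: Optional[Mapping[tuple[str, int, int], Sequence[str]]] = None,
) -> list[str]:
    """Gene assignment for an enhancer interval ``(chrom, start, end)``.

    A curated link (external enhancer-gene map) takes precedence; otherwise
    the gene(s) whose TSS is nearest to the enhancer midpoint are returned,
    all ties included.
    """
    if not tss_list:
        raise ValueError("tss_list must be non-empty")
    if provided_links is not None and enhancer in provided_links:
        return list(provided_links[enhancer])
    chrom, start, end = enhancer
    mid = (start + end) / 2
    on_chrom = [t for t in tss_list if t.chrom == chrom]
    if not on_chrom:
        logger.warning("no TSS on chromosome %s for enhancer %s", chrom, enhancer)
        return []
    dists = {t.gene: abs(t.position - mid) for t in on_chrom}
    best = min(dists.values())
    return sorted(g for g, d in dists.items() if d == best)


def _union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def region_set_summary(
    regions: Sequence[RegulatoryRegion], registry: Optional[Sequence] = None
) -> dict:
    """Per-gene region counts and covered bp, plus global totals.

    Per-gene coverage is the union of that gene's regions. The global
    ``total_bp`` counts each base once even when regions are shared between
    genes; ``total_bp_by_gene_sum`` is the alternative convention that sums
    the per-gene unions (shared regions counted once per linked gene).
    """
    genes = sorted({g for r in regions for g in r.linked_genes})
    if registry is not None:
        genes = sorted(set(genes) | {e.symbol for e in registry})
    per_gene = {}
    for g in genes:
        mine = [r for r in regions if g in r.linked_genes]
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in mine:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        per_gene[g] = {
            "n_regions": len(mine),
            "covered_bp": sum(_union_bp(iv) for iv in by_chrom.values()),
        }
    by_chrom_all: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom_all.setdefault(r.chrom, []).append((r.start, r.end))
    return {
        "per_gene": per_gene,
        "n_regions": len(regions),
        "total_bp": sum(_union_bp(iv) for iv in by_chrom_all.values()),
        "total_bp_by_gene_sum": sum(v["covered_bp"] for v in per_gene.values()),
    }


def variant_overlaps_region(pos_1based: int, region: RegulatoryRegion) -> bool:
    return region.start <= pos_1based - 1 < region.end


# ---------------------------------------------------------------------------
# BED6+ dialect: chrom, start, end, kind, genes (semicolon-joined),
# lv_active, in_regulatory_build
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "kind", "linked_genes", "lv_active", "in_regulatory_build"]


def write_regions_bed(regions: Iterable[RegulatoryRegion], path: str | Path) -> None:
    rows = [
        (r.chrom, r.start, r.end, r.kind, ";".join(r.linked_genes), int(r.lv_active), int(r.in_regulatory_build))
        for r in regions
    ]
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path: str | Path) -> list[RegulatoryRegion]:
    df = pd.read_csv(path, sep="\t", names=_BED_COLUMNS, dtype=str)
    return [
        RegulatoryRegion(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            kind=row.kind,
            linked_genes=row.linked_genes.split(";"),
            lv_active=bool(int(row.lv_active)),
            in_regulatory_build=bool(int(row.in_regulatory_build)),
        )
        for row in df.itertuples()
    ]


def read_tss_table(path: str | Path) -> list[Tss]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Tss(gene=row.gene, chrom=row.chrom, position=int(row.position), strand=row.strand)
        for row in df.itertuples()
    ]
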