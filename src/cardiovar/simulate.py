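"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the discovery design — 209 unrelated case probands
against 1326 cancer-cohort controls — on a synthetic coordinate system:
one promoter region per panel gene, per-gene carrier probabilities planted
on the odds scale (control carrier odds scaled by the gene's true odds
ratio), an allele-frequency spectrum with a point mass at
absent-from-gnomAD plus a log-uniform rare tail, four TF-binding verdicts
that agree with a latent truth at a configurable rate, planted CNVs
emitted into both caller tracks with jittered breakpoints, and a
down-shifted myocardial expression distribution for planted LoF carriers.

All randomness flows from ``SimConfig.seed``; identical configs reproduce
outputs byte-for-byte. It also ships the worked-example carrier tables for
the four most enriched genes, reconstructed at call time from their
published odds ratios and confidence intervals by an exhaustive scan that
must find exactly one table per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._round import format_ci_bound, format_or
from .cohort import (
    GeneEntry,
    SampleEntry,
    VariantAnnotation,
    VariantRecord,
    load_bundled_registry,
    read_sample_sheet,
    read_variant_table,
    write_sample_sheet,
    write_variant_table,
)
from .cnv import CnvCall, GenomicMask
from .regions import RegulatoryRegion, Tss, fallback_promoter, read_regions_bed, write_regions_bed
from .stats import ContingencyTable, ha_odds_ratio, woolf_ci

__all__ = [
    "AfSpectrum",
    "PlantedCnv",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "worked_example_tables",
    "write_cohort",
    "read_cohort",
]

TFBS_TOOLS = ("regulome", "motifbreak", "deepsea", "fathmm_mkl")
MISSENSE_TOOLS = ("sift", "polyphen2", "mutation_taster", "cadd", "provean", "metasvm")
_PHENOTYPES = ("DCM", "HCM", "LVNC", "RCM", "ACM")
_PHENO_P = (0.52, 0.31, 0.07, 0.05, 0.05)  # discovery-cohort subtype mix

# synthetic coordinate layout: all genes on one contig, evenly spaced
_CHROM = "chr1"
_GENE_SPACING = 200_000
_GENE_BODY = 20_000


@dataclass(frozen=True)
class AfSpectrum:
    """Point mass at absent-from-gnomAD plus a log-uniform rare tail."""

    p_absent: float = 0.6
    tail_min: float = 1e-7
    tail_max: float = 1e-3

    def draw(self, rng: np.random.Generator) -> Optional[float]:
        if rng.random() < self.p_absent:
            return None
        return float(
            10 ** rng.uniform(np.log10(self.tail_min), np.log10(self.tail_max))
        )


@dataclass(frozen=True)
class PlantedCnv:
    gene: str
    cn_type: str = "deletion"
    length: int = 5000


@dataclass
class SimConfig:
    n_cases: int = 209
    n_controls: int = 1326
    genes: Optional[list[GeneEntry]] = None  # default: bundled panel
    per_gene_true_or: dict[str, float] = field(default_factory=dict)
    baseline_control_carrier_rate: float = 0.05
    af_spectrum: AfSpectrum = AfSpectrum()
    tfbs_tool_agreement: float = 0.9
    coding_positive_rate: float = 0.37
    cnv_positive_rate: float = 0.02
    planted_cnvs: list[PlantedCnv] = field(default_factory=list)
    expression_noise_sd: float = 0.3
    qc_fail_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_control_carrier_rate < 1.0):
            raise ValueError("baseline_control_carrier_rate must be in [0, 1)")
        for g, theta in self.per_gene_true_or.items():
            if theta <= 0:
                raise ValueError(f"true OR for {g} must be positive, got {theta}")
        if not (0.0 <= self.tfbs_tool_agreement <= 1.0):
            raise ValueError("tfbs_tool_agreement must be in [0, 1]")


@dataclass
class SimulatedCohort:
    samples: list[SampleEntry]
    variants: list[VariantRecord]
    regions: list[RegulatoryRegion]
    gene_of_variant: dict[tuple[str, int, str, str], str]
    cnv_calls_a: list[CnvCall]
    cnv_calls_b: list[CnvCall]
    masks: dict[str, GenomicMask]
    exons: list[tuple[str, tuple[str, int, int]]]
    expression: "object"  # pandas DataFrame, genes x case samples
    config: SimConfig


def _case_rate_from_or(control_rate: float, theta: float) -> float:
    """Plant effects on the odds scale so the estimand matches the statistic."""
    odds = control_rate / (1.0 - control_rate)
    case_odds = theta * odds
    return case_odds / (1.0 + case_odds)


def gene_layout(genes: Sequence[GeneEntry]) -> dict[str, Tss]:
    """Deterministic synthetic TSS per gene: evenly spaced on one contig."""
    return {
        e.symbol: Tss(gene=e.symbol, chrom=_CHROM, position=(i + 1) * _GENE_SPACING, strand="+")
        for i, e in enumerate(genes)
    }


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    genes = config.genes if config.genes is not None else load_bundled_registry()
    layout = gene_layout(genes)

    # --- samples: unrelated case probands + controls --------------------
    samples = [
        SampleEntry(
            sample_id=f"case_{i:04d}",
            cohort="case",
            family_id=f"fam_{i:04d}",
            phenotype=_PHENOTYPES[rng.choice(len(_PHENOTYPES), p=_PHENO_P)],
            trio_complete=bool(rng.random() < 32 / 209),
        )
        for i in range(config.n_cases)
    ] + [
        SampleEntry(
            sample_id=f"ctrl_{i:04d}", cohort="control", family_id=f"cfam_{i:04d}"
        )
        for i in range(config.n_controls)
    ]
    case_ids = [s.sample_id for s in samples if s.cohort == "case"]
    control_ids = [s.sample_id for s in samples if s.cohort == "control"]

    # --- regulatory regions: LV-active promoter per gene ----------------
    regions = []
    for e in genes:
        r = fallback_promoter(layout[e.symbol])
        r.lv_active = True
        r.in_regulatory_build = True
        regions.append(r)
    region_of = {r.linked_genes[0]: r for r in regions}

    variants: list[VariantRecord] = []
    gene_of_variant: dict[tuple[str, int, str, str], str] = {}

    def _depth_and_flag() -> tuple[int, str]:
        depth = int(max(0, rng.poisson(31)))
        flag = "PASS"
        if rng.random() < config.qc_fail_rate:
            if rng.random() < 0.5:
                flag = "LowQual"
            else:
                depth = int(rng.integers(0, 10))
        return depth, flag

    # --- regulatory SNVs: per-gene carriers on the odds scale -----------
    r0 = config.baseline_control_carrier_rate
    for e in genes:
        theta = config.per_gene_true_or.get(e.symbol, 1.0)
        p_case = _case_rate_from_or(r0, theta)
        region = region_of[e.symbol]
        positions = rng.choice(
            np.arange(region.start + 1, region.end + 1),  # 1-based inside region
            size=min(region.length, config.n_cases + config.n_controls),
            replace=False,
        )
        pos_iter = iter(int(p) for p in positions)
        for sample_id, p_carrier in [(s, p_case) for s in case_ids] + [
            (s, r0) for s in control_ids
        ]:
            if rng.random() >= p_carrier:
                continue
            pos = next(pos_iter)
            af = config.af_spectrum.draw(rng)
            popmax = None if af is None else min(1.0, af * float(rng.uniform(1.0, 5.0)))
            truth_altered = True  # planted variants hit a TF-binding site
            verdicts = [
                (tool, bool(rng.random() < config.tfbs_tool_agreement) == truth_altered)
                for tool in TFBS_TOOLS
            ]
            depth, flag = _depth_and_flag()
            rec = VariantRecord(
                sample_id=sample_id,
                chrom=region.chrom,
                pos=pos,
                ref="G",
                alt="A",
                filter_flag=flag,
                depth=depth,
                genotype="het",
                gq=int(rng.integers(20, 99)),
                annotation=VariantAnnotation(
                    gnomad_af=af,
                    popmax_af=popmax,
                    consequence="regulatory",
                    tfbs_verdicts=verdicts,
                ),
            )
            variants.append(rec)
            gene_of_variant[rec.key] = e.symbol

    # --- pathogenic coding variants in a subset of cases ----------------
    tier1_ad = [e for e in genes if e.tier == "1" and e.inheritance == "AD"]
    coding_positive: list[str] = []
    lof_carriers: dict[str, str] = {}  # sample -> gene, for expression shift
    for sample_id in case_ids:
        if rng.random() >= config.coding_positive_rate:
            continue
        e = tier1_ad[int(rng.integers(0, len(tier1_ad)))]
        tss = layout[e.symbol]
        pos = int(tss.position + 1 + rng.integers(0, _GENE_BODY))
        depth, flag = _depth_and_flag()
        rec = VariantRecord(
            sample_id=sample_id,
            chrom=tss.chrom,
            pos=pos,
            ref="C",
            alt="CT",
            filter_flag=flag,
            depth=depth,
            genotype="het",
            gq=int(rng.integers(20, 99)),
            annotation=VariantAnnotation(
                gnomad_af=None,
                consequence="frameshift",
                lof_confidence="high",
                clinvar_status="pathogenic",
            ),
        )
        variants.append(rec)
        gene_of_variant[rec.key] = e.symbol
        coding_positive.append(sample_id)
        lof_carriers[sample_id] = e.symbol

    # --- CNVs: planted events into both caller tracks -------------------
    planted = list(config.planted_cnvs)
    for sample_id in case_ids:
        if rng.random() < config.cnv_positive_rate:
            e = tier1_ad[int(rng.integers(0, len(tier1_ad)))]
            planted.append(PlantedCnv(gene=e.symbol))
    cnv_calls_a: list[CnvCall] = []
    cnv_calls_b: list[CnvCall] = []
    cnv_sample_iter = iter(rng.permutation(case_ids).tolist())
    for cnv in planted:
        tss = layout[cnv.gene]
        start = tss.position
        end = start + cnv.length
        sample_id = next(cnv_sample_iter)
        for track, calls in (("A", cnv_calls_a), ("B", cnv_calls_b)):
            jitter = rng.integers(-cnv.length // 10, cnv.length // 10 + 1, size=2)
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    chrom=tss.chrom,
                    start=max(0, int(start + jitter[0])),
                    end=int(end + jitter[1]),
                    cn_type=cnv.cn_type,
                    caller=track,
                )
            )

    # masks: problematic sequence far from the gene slots
    masks = {
        "telomere": GenomicMask("telomere", {_CHROM: [(0, 10_000)]}),
        "centromere": GenomicMask("centromere", {_CHROM: [(95_000, 150_000)]}),
        "segdup": GenomicMask("segdup", {_CHROM: [(50_000, 60_000)]}),
        "cn_prone": GenomicMask("cn_prone", {_CHROM: [(60_000, 80_000)]}),
    }
    exons = [
        (e.symbol, (_CHROM, layout[e.symbol].position, layout[e.symbol].position + _GENE_BODY))
        for e in genes
    ]

    # --- myocardial expression for cases: LoF carriers down-shifted -----
    base = rng.lognormal(mean=3.0, sigma=0.5, size=len(genes))
    values = np.empty((len(genes), len(case_ids)))
    for j, sample_id in enumerate(case_ids):
        noise = rng.lognormal(mean=0.0, sigma=config.expression_noise_sd, size=len(genes))
        values[:, j] = base * noise
    sym_index = {e.symbol: i for i, e in enumerate(genes)}
    for sample_id, gene in lof_carriers.items():
        values[sym_index[gene], case_ids.index(sample_id)] *= 0.4
    expression = pd.DataFrame(
        values, index=[e.symbol for e in genes], columns=case_ids
    )

    return SimulatedCohort(
        samples=samples,
        variants=variants,
        regions=regions,
        gene_of_variant=gene_of_variant,
        cnv_calls_a=cnv_calls_a,
        cnv_calls_b=cnv_calls_b,
        masks=masks,
        exons=exons,
        expression=expression,
        config=config,
    )


# ---------------------------------------------------------------------------
# Worked-example carrier tables
# ---------------------------------------------------------------------------

# Published per-gene burden results for the four most enriched genes:
# (odds ratio, CI lower, CI upper) after display rounding.
WORKED_EXAMPLES = {
    "FKTN": (58.1, 3.1, 1083),
    "DTNA": (6.7, 3.0, 14.8),
    "DSC2": (32.0, 1.5, 668),
    "DSG2": (10.6, 1.4, 81),
}
_WE_N_CASES = 209
_WE_N_CONTROLS = 1326


def _display_bound(x: float) -> float:
    return float(format_ci_bound(x))


def worked_example_tables(
    max_carriers: int = 30,
) -> list[tuple[str, ContingencyTable]]:
    """Reconstruct the four carrier tables from their published OR/CI.

    Exhaustively scans case carriers a <= ``max_carriers`` and control
    carriers c <= ``max_carriers`` for tables whose corrected odds ratio
    and Woolf CI bounds all round to the printed values. Exactly one table
    must match per gene; zero or multiple matches raise.
    """
    out = []
    for gene, (or_printed, lo_printed, hi_printed) in WORKED_EXAMPLES.items():
        matches = []
        for a in range(max_carriers + 1):
            for c in range(max_carriers + 1):
                t = ContingencyTable.from_carriers(a, _WE_N_CASES, c, _WE_N_CONTROLS)
                if float(format_or(ha_odds_ratio(t))) != or_printed:
                    continue
                lo, hi = woolf_ci(t)
                if _display_bound(lo) == lo_printed and _display_bound(hi) == hi_printed:
                    matches.append(t)
        if len(matches) != 1:
            raise RuntimeError(
                f"worked-example reconstruction for {gene}: expected exactly one "
                f"matching table, found {len(matches)}: "
                f"{[(t.a, t.c) for t in matches]}"
            )
        out.append((gene, matches[0]))
    return out


# ---------------------------------------------------------------------------
# On-disk cohort bundle (all plain text)
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(cohort.samples, outdir / "samples.tsv")
    write_variant_table(cohort.variants, outdir / "variants.tsv")
    write_regions_bed(cohort.regions, outdir / "regions.bed")
    pd.DataFrame(
        [(k[0], k[1], k[2], k[3], g) for k, g in sorted(cohort.gene_of_variant.items())],
        columns=["chrom", "pos", "ref", "alt", "gene"],
    ).to_csv(outdir / "variant_genes.tsv", sep="\t", index=False)
    for name, calls in (("cnv_calls_a", cohort.cnv_calls_a), ("cnv_calls_b", cohort.cnv_calls_b)):
        pd.DataFrame(
            [(c.chrom, c.start, c.end, c.cn_type, c.sample_id, c.caller) for c in calls],
            columns=["chrom", "start", "end", "cn_type", "sample_id", "caller"],
        ).to_csv(outdir / f"{name}.bed", sep="\t", index=False, header=False)
    mask_rows = [
        (m.name, chrom, s, e)
        for m in cohort.masks.values()
        for chrom, ivs in m.intervals.items()
        for s, e in ivs
    ]
    pd.DataFrame(mask_rows, columns=["name", "chrom", "start", "end"]).to_csv(
        outdir / "masks.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(g, chrom, s, e) for g, (chrom, s, e) in cohort.exons],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(outdir / "exons.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")


def read_cohort(indir: str | Path, config: Optional[SimConfig] = None) -> SimulatedCohort:
    import pandas as pd

    indir = Path(indir)
    samples = read_sample_sheet(indir / "samples.tsv")
    variants = read_variant_table(indir / "variants.tsv")
    regions = read_regions_bed(indir / "regions.bed")
    vg = pd.read_csv(indir / "variant_genes.tsv", sep="\t", dtype=str)
    gene_of_variant = {
        (r.chrom, int(r.pos), r.ref, r.alt): r.gene for r in vg.itertuples()
    }
    calls = {}
    for name in ("cnv_calls_a", "cnv_calls_b"):
        df = pd.read_csv(
            indir / f"{name}.bed",
            sep="\t",
            names=["chrom", "start", "end", "cn_type", "sample_id", "caller"],
            dtype=str,
        )
        calls[name] = [
            CnvCall(
                sample_id=r.sample_id,
                chrom=r.chrom,
                start=int(r.start),
                end=int(r.end),
                cn_type=r.cn_type,
                caller=r.caller,
            )
            for r in df.itertuples()
        ]
    mdf = pd.read_csv(indir / "masks.tsv", sep="\t", dtype=str)
    masks: dict[str, GenomicMask] = {}
    for name, grp in mdf.groupby("name"):
        intervals: dict[str, list[tuple[int, int]]] = {}
        for r in grp.itertuples():
            intervals.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        masks[name] = GenomicMask(name, intervals)
    edf = pd.read_csv(indir / "exons.tsv", sep="\t", dtype=str)
    exons = [(r.gene, (r.chrom, int(r.start), int(r.end))) for r in edf.itertuples()]
    expression = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    return SimulatedCohort(
        samples=samples,
        variants=variants,
        regions=regions,
        gene_of_variant=gene_of_variant,
        cnv_calls_a=calls["cnv_calls_a"],
        cnv_calls_b=calls["cnv_calls_b"],
        masks=masks,
        exons=exons,
        expression=expression,
        config=config if config is not None else SimConfig(),
    )
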