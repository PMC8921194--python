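"""End-to-end orchestration: QC -> coding -> CNV -> candidate LoF ->
regulatory -> burden -> tallies.

Gene-elusive status is computed once, after the coding and CNV stages
(cases without a pathogenic or likely pathogenic coding variant, SNV,
indel or CNV, in a known panel gene), and frozen; later stages never
revisit it. Every stage writes a TSV into the output directory, along
with a per-stage drop-count log, so runs with identical config and seed
reproduce all report files byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cnv import consensus_filter, cnv_gene_overlap
from .coding import CodingVerdict, Thresholds, candidate_lof_scan, classify_case_coding, classify_variant_coding
from .cohort import GeneEntry, load_bundled_registry, qc_filter
from .regions import variant_overlaps_region
from .regulatory import (
    RegThresholds,
    RegulatoryCandidate,
    carriers_by_gene,
    pass1_filter,
    prioritize,
)
from .simulate import SimConfig, SimulatedCohort, read_cohort, simulate_cohort
from .stats import case_tally, per_gene_burden

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CaseClassification", "PipelineError", "run_pipeline", "build_regulatory_candidates"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class CaseClassification:
    """Per-case pipeline verdict feeding the cohort yield table."""

    sample_id: str
    coding_positive: bool = False
    cnv_positive: bool = False
    candidate_lof: bool = False
    regulatory_positive: bool = False
    gene_elusive: bool = False
    n_coding_variants: int = 0
    n_regulatory_variants: int = 0

    @property
    def multiple_coding(self) -> bool:
        return self.n_coding_variants >= 2

    @property
    def multiple_regulatory(self) -> bool:
        return self.n_regulatory_variants >= 2

    @property
    def both_types(self) -> bool:
        return (self.coding_positive or self.cnv_positive) and self.regulatory_positive


@dataclass
class RunConfig:
    outdir: str | Path = "cardiovar_out"
    cohort_dir: Optional[str | Path] = None  # load an existing cohort bundle
    sim: Optional[SimConfig] = None  # or simulate one
    thresholds: Thresholds = field(default_factory=Thresholds)
    reg_thresholds: RegThresholds = field(default_factory=RegThresholds)
    candidate_genes: list[GeneEntry] = field(default_factory=list)
    seed: int = 0


def build_regulatory_candidates(cohort: SimulatedCohort) -> list[RegulatoryCandidate]:
    """Map regulatory-consequence variant records onto regulatory regions."""
    candidates = []
    for r in cohort.variants:
        if r.annotation.consequence != "regulatory":
            continue
        for region in cohort.regions:
            if region.chrom == r.chrom and variant_overlaps_region(r.pos, region):
                gene = cohort.gene_of_variant.get(r.key, region.linked_genes[0])
                candidates.append(
                    RegulatoryCandidate(
                        variant_key=r.key,
                        sample_id=r.sample_id,
                        region=region,
                        gene=gene,
                        tfbs_altered_count=sum(v for _, v in r.annotation.tfbs_verdicts),
                        gnomad_af=r.annotation.gnomad_af,
                        popmax_af=r.annotation.popmax_af,
                        variant_class="snv" if len(r.ref) == len(r.alt) == 1 else "indel",
                    )
                )
                break
    return candidates


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a simulated or loaded cohort; return the report bundle.

    Writes per-stage TSVs, a burden table, the case-tally table and a
    drop-count log under ``config.outdir``. Raises :class:`PipelineError`
    naming the failing stage; partial outputs are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drops: dict[str, dict] = {}

    # --- input -----------------------------------------------------------
    stage = "input"
    try:
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
        else:
            sim = config.sim if config.sim is not None else SimConfig(seed=config.seed)
            cohort = simulate_cohort(sim)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    registry = cohort.config.genes if cohort.config.genes is not None else load_bundled_registry()
    genes_by_symbol = {e.symbol: e for e in registry}
    case_ids = [s.sample_id for s in cohort.samples if s.cohort == "case"]
    n_cases = len(case_ids)
    n_controls = sum(1 for s in cohort.samples if s.cohort == "control")

    # --- QC --------------------------------------------------------------
    stage = "qc"
    try:
        records = qc_filter(cohort.variants)
        drops[stage] = {"input": len(cohort.variants), "kept": len(records)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- coding cascade --------------------------------------------------
    stage = "coding"
    try:
        verdicts: list[CodingVerdict] = []
        for r in records:
            gene_symbol = cohort.gene_of_variant.get(r.key)
            if gene_symbol is None or gene_symbol not in genes_by_symbol:
                continue
            if r.annotation.consequence == "regulatory":
                continue
            verdicts.append(
                classify_variant_coding(r, genes_by_symbol[gene_symbol], config.thresholds)
            )
        coding_positive = {
            s for s in case_ids if classify_case_coding(s, verdicts, registry)
        }
        prioritized_coding = [v for v in verdicts if v.klass != "not_prioritized"]
        pd.DataFrame(
            [
                (v.sample_id, *v.variant_key, v.gene, v.klass, v.zygosity_concordant, ";".join(v.reasons))
                for v in prioritized_coding
            ],
            columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "class", "zygosity_concordant", "reasons"],
        ).to_csv(outdir / "coding_verdicts.tsv", sep="\t", index=False)
        drops[stage] = {
            "variants_classified": len(verdicts),
            "prioritized": len(prioritized_coding),
            "coding_positive_cases": len(coding_positive),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- CNV consensus ---------------------------------------------------
    stage = "cnv"
    try:
        consensus = consensus_filter(cohort.cnv_calls_a, cohort.cnv_calls_b, cohort.masks)
        cnv_positive = set()
        cnv_rows = []
        for call in consensus:
            labels = cnv_gene_overlap(call, cohort.exons, cohort.regions)
            panel_hits = [g for g in labels["coding"] if g in genes_by_symbol]
            if panel_hits and call.sample_id in case_ids:
                cnv_positive.add(call.sample_id)
            cnv_rows.append(
                (
                    call.chrom, call.start, call.end, call.cn_type, call.sample_id,
                    ";".join(labels["coding"]),
                    ";".join(f"{k}:{','.join(gs)}" for k, gs in labels["regulatory"]),
                )
            )
        pd.DataFrame(
            cnv_rows,
            columns=["chrom", "start", "end", "cn_type", "sample_id", "coding_genes", "regulatory_hits"],
        ).to_csv(outdir / "cnv_retained.tsv", sep="\t", index=False)
        drops[stage] = {
            "caller_a": len(cohort.cnv_calls_a),
            "caller_b": len(cohort.cnv_calls_b),
            "consensus_retained": len(consensus),
            "cnv_positive_cases": len(cnv_positive),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # gene-elusive: frozen after coding + CNV
    gene_elusive = {s for s in case_ids if s not in coding_positive and s not in cnv_positive}

    # --- candidate LoF scan ---------------------------------------------
    stage = "candidate_lof"
    try:
        candidate_verdicts = candidate_lof_scan(
            sorted(gene_elusive),
            records,
            config.candidate_genes,
            cohort.samples,
            config.thresholds,
            cohort.gene_of_variant,
        )
        pd.DataFrame(
            [
                (v.sample_id, *v.variant_key, v.gene, v.prioritized, ";".join(v.reasons))
                for v in candidate_verdicts
            ],
            columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "prioritized", "reasons"],
        ).to_csv(outdir / "candidate_lof.tsv", sep="\t", index=False)
        drops[stage] = {"retained": len(candidate_verdicts)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- regulatory prioritization --------------------------------------
    stage = "regulatory"
    try:
        if n_controls == 0:
            raise ValueError("no control samples supplied; odds ratios are undefined")
        candidates = build_regulatory_candidates(cohort)
        retained = prioritize(candidates, cohort.samples, gene_elusive, config.reg_thresholds)
        pass1 = pass1_filter(candidates, cohort.samples, gene_elusive, config.reg_thresholds)
        pd.DataFrame(
            [
                (c.sample_id, *c.variant_key, c.gene, c.tfbs_altered_count, c.cohort_fraction, ";".join(c.flags))
                for c in retained
            ],
            columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "tfbs_altered", "cohort_fraction", "flags"],
        ).to_csv(outdir / "regulatory_prioritized.tsv", sep="\t", index=False)
        drops[stage] = {
            "candidates": len(candidates),
            "pass1": len(pass1),
            "prioritized": len(retained),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- burden ----------------------------------------------------------
    stage = "burden"
    try:
        counts = carriers_by_gene(pass1, cohort.samples)
        burden = per_gene_burden(counts, n_cases, n_controls)
        pd.DataFrame(
            [
                (
                    b.gene, b.table.a, b.table.b, b.table.c, b.table.d,
                    repr(b.or_value), repr(b.ci_low), repr(b.ci_high), repr(b.p),
                    "" if b.q is None else repr(b.q), b.display(),
                )
                for b in burden
            ],
            columns=["gene", "a", "b", "c", "d", "or", "ci_low", "ci_high", "p", "q", "display"],
        ).to_csv(outdir / "burden.tsv", sep="\t", index=False)
        drops[stage] = {"genes_tested": len(burden)}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- tallies ---------------------------------------------------------
    stage = "tally"
    try:
        coding_count = Counter(v.sample_id for v in prioritized_coding if v.sample_id in coding_positive)
        reg_count = Counter(c.sample_id for c in retained)
        candidate_samples = {v.sample_id for v in candidate_verdicts}
        classifications = [
            CaseClassification(
                sample_id=s,
                coding_positive=s in coding_positive,
                cnv_positive=s in cnv_positive,
                candidate_lof=s in candidate_samples,
                regulatory_positive=s in reg_count,
                gene_elusive=s in gene_elusive,
                n_coding_variants=coding_count.get(s, 0),
                n_regulatory_variants=reg_count.get(s, 0),
            )
            for s in case_ids
        ]
        tally = case_tally(classifications, n_cases)
        pd.DataFrame(tally).to_csv(outdir / "case_tally.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "drop_counts.json", "w") as fh:
        json.dump(drops, fh, indent=2, sort_keys=True)

    return {
        "classifications": classifications,
        "tally": tally,
        "burden": burden,
        "prioritized_regulatory": retained,
        "candidate_lof": candidate_verdicts,
        "gene_elusive": gene_elusive,
        "coding_positive": coding_positive,
        "cnv_positive": cnv_positive,
        "drop_counts": drops,
    }
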