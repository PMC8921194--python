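"""Domain types, readers/writers, QC filtering and the gene registry.

The cohort model mirrors how short-variant calls arrive from a WGS joint
call: one record per sample per bi-allelic allele, carrying the caller's
FILTER flag, read depth (DP for SNVs, DPI at the base preceding an indel —
collapsed to one ``depth`` field by the producer), genotype and genotype
quality, plus an annotation bundle (population frequencies, consequence,
LoF confidence, splice delta score, per-tool missense and TFBS verdicts).

Variant identity is ``(chrom, pos, ref, alt)``; multi-allelic sites must be
pre-split into bi-allelic records because every downstream filter operates
at allele level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAnnotation",
    "VariantRecord",
    "GeneEntry",
    "SampleEntry",
    "qc_filter",
    "denovo_trio_filter",
    "load_gene_registry",
    "load_bundled_registry",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "write_vcf",
]

Genotype = Literal["het", "hom_alt", "hemi", "missing"]
Consequence = Literal[
    "missense",
    "frameshift",
    "stopgain",
    "stoploss",
    "splice_dinucleotide",
    "synonymous",
    "intronic",
    "regulatory",
    "other",
]

# QC thresholds: PASS filter flag and total filtered read depth of at least
# 10x; trio de novo calls additionally require GQ >= 20 in all members.
MIN_DEPTH = 10
MIN_TRIO_GQ = 20

PANEL_SIZE = 84
PANEL_SARCOMERE = 9


def _check_af(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class VariantAnnotation:
    """Annotation bundle consumed from upstream predictors.

    ``tfbs_verdicts`` has exactly 0 (not assessed) or 4 entries, one per
    TF-binding prediction tool, with distinct tool names.
    """

    gnomad_af: Optional[float] = None
    popmax_af: Optional[float] = None
    consequence: Consequence = "other"
    lof_confidence: Literal["high", "low", "none"] = "none"
    splice_delta: Optional[float] = None
    missense_verdicts: list[tuple[str, bool]] = field(default_factory=list)
    tfbs_verdicts: list[tuple[str, bool]] = field(default_factory=list)
    clinvar_status: Literal[
        "pathogenic", "likely_pathogenic", "vus", "benign", "unreported"
    ] = "unreported"

    def __post_init__(self) -> None:
        _check_af("gnomad_af", self.gnomad_af)
        _check_af("popmax_af", self.popmax_af)
        if self.splice_delta is not None and not (0.0 <= self.splice_delta <= 1.0):
            raise ValueError(f"splice_delta must be in [0, 1], got {self.splice_delta}")
        n = len(self.tfbs_verdicts)
        if n not in (0, 4):
            raise ValueError(f"tfbs_verdicts must have length 0 or 4, got {n}")
        tools = [t for t, _ in self.tfbs_verdicts]
        if len(set(tools)) != len(tools):
            raise ValueError("tfbs_verdicts tool names must be distinct")


@dataclass
class VariantRecord:
    """One called short variant in one sample (bi-allelic, 1-based pos)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_flag: str
    depth: int
    genotype: Genotype
    gq: Optional[int] = None
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneEntry:
    """One gene of the curated disease panel, or a candidate gene."""

    symbol: str
    tier: Literal["1", "2", "candidate"]
    cmp_class: Literal["primary", "secondary", "candidate"]
    category: Literal[
        "sarcomere", "desmosomal", "cytoskeletal", "dystroglycan", "ion_channel", "other"
    ]
    inheritance: Literal["AD", "AR", "XL"]
    pli: Optional[float] = None
    heart_expression: Literal["high", "moderate", "low", "not_expressed"] = "moderate"

    def __post_init__(self) -> None:
        _check_af("pli", self.pli)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    cohort: Literal["case", "control"]
    family_id: str
    phenotype: Literal["HCM", "DCM", "LVNC", "RCM", "ACM", "none"] = "none"
    trio_complete: bool = False

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be non-empty")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep records with a PASS FILTER flag and read depth >= 10 (inclusive).

    Order is preserved; records are not mutated. Idempotent by construction.
    """
    kept = [r for r in records if r.filter_flag == "PASS" and r.depth >= MIN_DEPTH]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("qc_filter: dropped %d of %d records", dropped, len(records))
    return kept


def denovo_trio_filter(
    trio_genotypes: Sequence[tuple[str, Optional[int], int]],
) -> bool:
    """High-confidence de novo call from a (proband, mother, father) trio.

    Each member is a ``(genotype, gq, depth)`` triple; parental genotypes may
    be ``hom_ref``. True iff every member has GQ >= 20 and depth >= 10 and
    the proband carries an alt allele absent from both parents.
    """
    if len(trio_genotypes) != 3:
        raise ValueError("exactly three members required: proband, mother, father")
    for label, (gt, gq, depth) in zip(("proband", "mother", "father"), trio_genotypes):
        if gt == "missing" or gt is None:
            logger.info("denovo_trio_filter: %s genotype missing -> rejected", label)
            return False
        if gq is None or gq < MIN_TRIO_GQ or depth < MIN_DEPTH:
            return False
    proband, mother, father = (gt for gt, _, _ in trio_genotypes)
    carries_alt = proband in ("het", "hom_alt", "hemi")
    parents_ref = mother == "hom_ref" and father == "hom_ref"
    return carries_alt and parents_ref


# ---------------------------------------------------------------------------
# Gene registry
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "symbol",
    "tier",
    "cmp_class",
    "category",
    "inheritance",
    "pli",
    "heart_expression",
]


def load_gene_registry(path: str | Path, strict_panel: bool = False) -> list[GeneEntry]:
    """Load a gene registry TSV into validated ``GeneEntry`` rows.

    With ``strict_panel`` the known-panel invariants (84 genes, 9 of them
    sarcomere) are errors; otherwise violations only warn, so callers may
    substitute their own panel. Duplicate symbols are always an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    if df["symbol"].duplicated().any():
        dupes = sorted(df.loc[df["symbol"].duplicated(), "symbol"])
        raise ValueError(f"duplicate gene symbols in registry: {dupes}")
    entries = []
    for i, row in df.iterrows():
        try:
            pli = None if pd.isna(row["pli"]) or row["pli"] == "" else float(row["pli"])
            entries.append(
                GeneEntry(
                    symbol=row["symbol"],
                    tier=row["tier"],
                    cmp_class=row["cmp_class"],
                    category=row["category"],
                    inheritance=row["inheritance"],
                    pli=pli,
                    heart_expression=row["heart_expression"],
                )
            )
        except (ValueError, KeyError) as exc:  # pragma: no cover - message path
            raise ValueError(f"malformed registry row {i} ({row['symbol']}): {exc}") from exc
    n_sarc = sum(1 for e in entries if e.category == "sarcomere")
    known = [e for e in entries if e.tier in ("1", "2")]
    if strict_panel:
        if len(known) != PANEL_SIZE:
            raise ValueError(f"known-gene panel must have {PANEL_SIZE} genes, got {len(known)}")
        if n_sarc != PANEL_SARCOMERE:
            raise ValueError(
                f"known-gene panel must have {PANEL_SARCOMERE} sarcomere genes, got {n_sarc}"
            )
    else:
        if len(known) != PANEL_SIZE or n_sarc != PANEL_SARCOMERE:
            warnings.warn(
                f"registry has {len(known)} known genes / {n_sarc} sarcomere "
                f"(curated panel: {PANEL_SIZE}/{PANEL_SARCOMERE})",
                stacklevel=2,
            )
    return entries


def load_bundled_registry() -> list[GeneEntry]:
    """Load the registry TSV shipped with the package.

    The bundled table is a synthetic stand-in for the curated 84-gene panel
    (real gene symbols from commercial panels; tier/category/inheritance/pLI
    values are plausible but not the study's): it satisfies the panel
    invariants (84 known genes, exactly 9 sarcomere) and is validated
    strictly at load time.
    """
    with resources.as_file(
        resources.files("cardiovar.data").joinpath("gene_registry_synthetic.tsv")
    ) as p:
        return load_gene_registry(p, strict_panel=True)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> list[SampleEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleEntry(
            sample_id=row.sample_id,
            cohort=row.cohort,
            family_id=row.family_id,
            phenotype=row.phenotype,
            trio_complete=str(row.trio_complete).lower() in ("true", "1"),
        )
        for row in df.itertuples()
    ]


def write_sample_sheet(samples: Iterable[SampleEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.cohort, s.family_id, s.phenotype, s.trio_complete)
            for s in samples
        ],
        columns=["sample_id", "cohort", "family_id", "phenotype", "trio_complete"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Flattened variant TSV dialect (one row per sample-allele, annotations inline)
# ---------------------------------------------------------------------------

_OPT_FLOAT = ("gnomad_af", "popmax_af", "splice_delta")


def _verdicts_to_str(verdicts: list[tuple[str, bool]]) -> str:
    return ";".join(f"{tool}={'1' if v else '0'}" for tool, v in verdicts)


def _verdicts_from_str(text: str) -> list[tuple[str, bool]]:
    if not text:
        return []
    out = []
    for item in text.split(";"):
        tool, _, flag = item.partition("=")
        out.append((tool, flag == "1"))
    return out


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        a = r.annotation
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "filter_flag": r.filter_flag,
                "depth": r.depth,
                "genotype": r.genotype,
                "gq": "" if r.gq is None else r.gq,
                "gnomad_af": "" if a.gnomad_af is None else repr(a.gnomad_af),
                "popmax_af": "" if a.popmax_af is None else repr(a.popmax_af),
                "consequence": a.consequence,
                "lof_confidence": a.lof_confidence,
                "splice_delta": "" if a.splice_delta is None else repr(a.splice_delta),
                "missense_verdicts": _verdicts_to_str(a.missense_verdicts),
                "tfbs_verdicts": _verdicts_to_str(a.tfbs_verdicts),
                "clinvar_status": a.clinvar_status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        ann = VariantAnnotation(
            gnomad_af=float(row["gnomad_af"]) if row["gnomad_af"] else None,
            popmax_af=float(row["popmax_af"]) if row["popmax_af"] else None,
            consequence=row["consequence"],
            lof_confidence=row["lof_confidence"],
            splice_delta=float(row["splice_delta"]) if row["splice_delta"] else None,
            missense_verdicts=_verdicts_from_str(row["missense_verdicts"]),
            tfbs_verdicts=_verdicts_from_str(row["tfbs_verdicts"]),
            clinvar_status=row["clinvar_status"],
        )
        records.append(
            VariantRecord(
                sample_id=row["sample_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                filter_flag=row["filter_flag"],
                depth=int(row["depth"]),
                genotype=row["genotype"],
                gq=int(row["gq"]) if row["gq"] else None,
                annotation=ann,
            )
        )
    return records


# ---------------------------------------------------------------------------
# VCF dialect: per-sample GT/DP/GQ in an uncompressed VCF, annotations in a
# sidecar TSV keyed by (chrom, pos, ref, alt). Multi-allelic sites are not
# produced and are rejected on read.
# ---------------------------------------------------------------------------


def write_vcf(
    records: Sequence[VariantRecord],
    vcf_path: str | Path,
    annotation_path: str | Path,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    import pysam

    samples = sorted({r.sample_id for r in records})
    by_site: dict[tuple[str, int, str, str], dict[str, VariantRecord]] = {}
    for r in records:
        by_site.setdefault(r.key, {})[r.sample_id] = r

    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    if contigs is None:
        contigs = sorted({k[0] for k in by_site})
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    for s in samples:
        header.add_sample(s)

    gt_codes = {"het": (0, 1), "hom_alt": (1, 1), "hemi": (1,), "missing": (None,)}
    ann_rows = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for key in sorted(by_site, key=lambda k: (k[0], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            site = by_site[key]
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            # FILTER is per-call in this model; the site takes PASS if any
            # sample's call passed, else the first non-PASS flag seen.
            flags = {r.filter_flag for r in site.values()}
            rec.filter.add("PASS" if "PASS" in flags else sorted(flags)[0])
            for s in samples:
                call = site.get(s)
                if call is None:
                    rec.samples[s]["GT"] = (None,)
                    continue
                rec.samples[s]["GT"] = gt_codes[call.genotype]
                rec.samples[s]["DP"] = call.depth
                if call.gq is not None:
                    rec.samples[s]["GQ"] = call.gq
            out.write(rec)
            a = next(iter(site.values())).annotation
            ann_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gnomad_af": "" if a.gnomad_af is None else repr(a.gnomad_af),
                    "popmax_af": "" if a.popmax_af is None else repr(a.popmax_af),
                    "consequence": a.consequence,
                    "lof_confidence": a.lof_confidence,
                    "splice_delta": "" if a.splice_delta is None else repr(a.splice_delta),
                    "missense_verdicts": _verdicts_to_str(a.missense_verdicts),
                    "tfbs_verdicts": _verdicts_to_str(a.tfbs_verdicts),
                    "clinvar_status": a.clinvar_status,
                }
            )
    pd.DataFrame(ann_rows).to_csv(annotation_path, sep="\t", index=False)


def read_vcf(
    vcf_path: str | Path,
    annotation_path: Optional[str | Path] = None,
    filter_flags: Optional[dict[tuple[str, str, int, str, str], str]] = None,
) -> list[VariantRecord]:
    """Read per-sample records from a VCF plus optional sidecar annotations.

    ``filter_flags`` optionally restores per-sample FILTER flags written by
    an external producer; otherwise the site-level FILTER applies to every
    sample at the site.
    """
    import pysam

    annotations: dict[tuple[str, int, str, str], VariantAnnotation] = {}
    if annotation_path is not None:
        adf = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
        for row in adf.to_dict("records"):
            annotations[(row["chrom"], int(row["pos"]), row["ref"], row["alt"])] = (
                VariantAnnotation(
                    gnomad_af=float(row["gnomad_af"]) if row["gnomad_af"] else None,
                    popmax_af=float(row["popmax_af"]) if row["popmax_af"] else None,
                    consequence=row["consequence"],
                    lof_confidence=row["lof_confidence"],
                    splice_delta=float(row["splice_delta"]) if row["splice_delta"] else None,
                    missense_verdicts=_verdicts_from_str(row["missense_verdicts"]),
                    tfbs_verdicts=_verdicts_from_str(row["tfbs_verdicts"]),
                    clinvar_status=row["clinvar_status"],
                )
            )

    records = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"multi-allelic site at {rec.contig}:{rec.pos}; pre-split required"
                )
            key = (rec.contig, rec.pos, rec.ref, rec.alts[0])
            site_flag = ";".join(rec.filter.keys()) or "PASS"
            ann = annotations.get(key, VariantAnnotation())
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                alleles = [a for a in gt if a is not None]
                if len(alleles) == 1:
                    genotype = "hemi" if alleles[0] == 1 else "missing"
                elif sum(alleles) == 1:
                    genotype = "het"
                elif sum(alleles) == 2:
                    genotype = "hom_alt"
                else:
                    continue  # hom-ref carries no alt allele record
                if genotype == "missing":
                    continue
                flag = site_flag
                if filter_flags is not None:
                    flag = filter_flags.get((sample, *key), site_flag)
                records.append(
                    VariantRecord(
                        sample_id=sample,
                        chrom=key[0],
                        pos=key[1],
                        ref=key[2],
                        alt=key[3],
                        filter_flag=flag,
                        depth=int(call.get("DP") or 0),
                        genotype=genotype,
                        gq=None if call.get("GQ") is None else int(call.get("GQ")),
                        annotation=replace(ann),
                    )
                )
    return records
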