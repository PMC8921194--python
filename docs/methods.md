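# Methods

## The analysis model

The pipeline classifies each case proband of a WGS case–control study into
a small set of diagnostic categories and tests per-gene carrier enrichment
against controls. Stages run in a fixed order:

1. **QC** — keep calls with a `PASS` FILTER flag and filtered read depth
   ≥ 10 (inclusive; DP for SNVs, DPI at the base before an indel, collapsed
   upstream into one `depth` field). Trio de novo calls additionally
   require GQ ≥ 20 and depth ≥ 10 in all three members and an alt allele
   absent from both parents. Hemizygous X-linked calls are depth-filtered
   identically to autosomal calls.
2. **Coding cascade** — a variant in a known panel gene is prioritized if
   it is rare (gnomAD MAF < 0.01%, strict; absent-from-gnomAD passes, since
   absence is a stronger rarity signal than any finite threshold) and is
   either (a) a high-confidence loss-of-function consequence (frameshift,
   stopgain/stoploss, splice-dinucleotide with a high annotator confidence
   flag; low-confidence rescue flags demote), (b) a cryptic-splice call
   with delta score ≥ 0.5 (inclusive) inside a transcribed region, or (c) a
   missense call on which ≥ 5 prediction tools report and a strict majority
   call deleterious. Observed zygosity must match the gene's inheritance
   mode (AD: het or hom; AR: hom, or two distinct qualifying het alleles in
   the same gene and sample — phase is unavailable, so compound-het calls
   can over-call cis pairs; XL: hemi or hom). Tier-2 and secondary-CMP
   genes additionally require a reportable ClinVar assertion (pathogenic or
   likely pathogenic).
3. **CNV consensus** — calls from two read-depth callers form a consensus
   when they share a chromosome and copy-number type with ≥ 50% reciprocal
   overlap (inclusive). The representative interval is the intersection of
   the pair — the paper trail is silent on the representative, and the
   intersection is the conservative, deterministic choice. Retained calls
   must exceed 1 kb (strict), have < 70% of their bases in the merged union
   of telomere/centromere/segmental-duplication masks (strict; merged-union
   rather than summed per-feature overlap), < 30% in copy-number-prone
   regions, and < 1% frequency in a reference CNV panel matched at ≥ 50%
   reciprocal overlap. A sample with calls from one caller only yields no
   consensus.
4. **Gene-elusive freeze** — cases with no pathogenic coding variant (SNV,
   indel or CNV) in a known panel gene. Computed once, never revisited.
5. **Candidate LoF scan** — gene-elusive cases are scanned for
   high-confidence LoF variants in candidate genes with gnomAD AF < 0.01%,
   carried by < 1% of distinct families (family identifiers, never sample
   counts: with 209 families the cutoff is ≤ 2 carrier families), in genes
   with moderate-to-high heart expression; pLI > 0.9 adds a "prioritized"
   flag.
6. **Regulatory cascade** — two passes over candidate variants mapped to
   promoter/enhancer elements of panel genes. Pass 1 (variant level):
   element overlaps the genome-wide regulatory segmentation ("regulatory
   build"), gnomAD MAF < 0.01% (absent passes), TF-binding alteration
   called by ≥ 3 of 4 predictors (CNVs and sub-kb indels bypass this gate —
   the predictors are SNV-oriented — but face every other filter), element
   active in left ventricle, Popmax AF < 0.1% (strict), variant carried by
   < 1.5% of case samples (exclusion is inclusive at 1.5%), and the carrier
   is gene-elusive. Pass 2 (gene level): the per-gene corrected odds ratio
   over distinct carrier samples of pass-1 variants (cases vs controls)
   must reach 1.3. The OR gate is computed on pass-1 candidates — the
   published ordering is ambiguous; this post-filter placement is the
   package's documented, configurable choice. Control carriers pass the
   variant-level filters but no gene-elusive gate (controls have no coding
   workup) and are never returned, only counted.
7. **Burden and tallies** — per-gene OR/CI/Fisher/FDR plus the cohort yield
   table (counts and percentages per category).

## Statistical conventions

- **Haldane–Anscombe correction**: 0.5 is added to all four cells
  unconditionally, for both the OR and the Woolf CI. This choice (rather
  than correcting only zero-cell tables) is what reproduces all four
  published gene OR/CI pairs simultaneously, including the no-zero-cell
  table 12/197/12/1314.
- **Woolf interval**: exp(ln OR ± z·SE), SE = sqrt of summed reciprocal
  corrected cells, z the exact standard-normal quantile (1.95996…; the
  rounded 1.96 changes no displayed value).
- **Exact tests on integers**: Fisher and binomial p-values are computed on
  uncorrected tables — exact null distributions require integer counts.
  Both use the minimum-likelihood two-sided rule (sum the probabilities of
  outcomes no more likely than observed), the dominant convention in
  standard statistical software; implementations delegate to
  scipy.stats (`fisher_exact`, `binomtest`) and are verified against
  hand-written enumeration oracles in the test suite.
- **FDR**: Benjamini–Hochberg step-up (statsmodels) over genes with at
  least one carrier anywhere; all-zero genes are reported without a q.
- **Spearman**: average-rank correlation squared with the two-sided
  t-approximation on n−2 df (the gene counts involved are too large for
  exact permutation to matter and too small for it to be needed).
- **Display rounding** (reports only; full precision everywhere else):
  half-up rounding; odds ratios to one decimal; CI bounds to one decimal
  below 20 and to the nearest integer at or above 20. The cutoff at 20 is
  the convention that matches all eight published CI bounds
  (3.1/1083, 3.0/14.8, 1.5/668, 1.4/81); a cutoff at 10 would misprint
  14.785 as 15. Percentages print with one decimal, plus a whole-percent
  rendering for figure-style summaries.

## Worked-example table reconstruction

The published per-gene results report only OR and CI, not the carrier
counts. `simulate.worked_example_tables()` reconstructs each table at call
time by exhaustively scanning case carriers a ≤ 30 and control carriers
c ≤ 30 (n = 209/1326) for tables whose corrected OR **and both** CI bounds
round to the printed values; the scan must find exactly one table per gene
(it does: 4/0, 12/12, 2/0, 2/1) and raises otherwise, so the package never
silently asserts an unverified reconstruction.

## The synthetic cohort generator

`simulate.simulate_cohort` emulates the study design the pipeline assumes —
it is a statistical emulation, not a sequence simulator.

What it models:

- **Cohort**: 209 unrelated case probands (each its own family; subtype mix
  52/31/7/5/5% DCM/HCM/LVNC/RCM/ACM) and 1326 controls.
- **Per-gene carriers on the odds scale**: control carrier probability is
  the baseline rate r; a gene with true OR θ gets case carrier probability
  p = θr′/(1−r′+θr′) with r′ = r, so the planted estimand is exactly the
  quantity the carrier-based OR estimates.
- **Allele frequencies**: point mass at absent-from-gnomAD (default 0.6)
  plus a log-uniform tail over [1e-7, 1e-3] — so a realistic fraction of
  variants fails the rarity gates rather than all passing trivially.
- **TFBS verdicts**: 4 named tools each agree with a latent truth
  independently at rate `tfbs_tool_agreement` (default 0.9 → a truly
  disruptive variant passes the 3-of-4 consensus with probability ≈ 0.95).
- **Coding background**: a configurable fraction of cases (default 0.37,
  the published coding-positive yield) carries a pathogenic LoF in a
  Tier-1 AD gene, creating the non-gene-elusive stratum.
- **CNVs**: planted events are written into both caller tracks with
  breakpoints jittered by < 20% of event length, so true events always
  reach the ≥ 50% reciprocal-overlap consensus.
- **Expression**: log-normal per-gene baselines with per-sample log-normal
  noise (sd 0.3); planted LoF carriers are down-shifted ×0.4, placing them
  low against the cohort.
- **QC noise**: 2% of records fail QC (LowQual flag or depth < 10).

Default baseline carrier rate: **0.05 per gene**. At the study's margins
the exact Fisher test is conservative for sparse tables (achieved size at
α = 0.05 is ≈ 0.020 at rate 0.005 and ≈ 0.026 at 0.01, by exact
computation over the null table distribution); 0.05 puts per-gene tables
in the near-nominal regime (achieved size ≈ 0.041) so that calibration
checks measure the statistics rather than discreteness. Cascade-recovery
checks that exercise sparse-table behavior use 0.005, the sparse regime of
the per-gene counts behind the published results.

What it does **not** model: sequence context, linkage disequilibrium,
population stratification and ancestry-specific frequencies, relatedness
beyond the family-ID structure, caller-specific error profiles, and any
correlation between coding and regulatory carrier status. Tests passing on
synthetic cohorts therefore demonstrate the correctness and calibration of
the filters and statistics under the stated model, not robustness to those
real-data complications.

The bundled gene registry (`data/gene_registry_synthetic.tsv`) is a
synthetic stand-in for the curated 84-gene panel: real CMP-panel gene
symbols, with tier/category/inheritance/pLI/heart-expression values that
are plausible but not the study's. It satisfies the panel invariants the
statistics rely on (84 known genes, exactly 9 sarcomere — the 9/84
binomial prior) and is validated strictly at load; user-substituted
registries downgrade those checks to warnings.

## Numerical and interface choices

- Coordinates are BED-style 0-based half-open internally; a VCF 1-based
  position p overlaps [s, e) iff s ≤ p−1 < e. Book-ended regions merge
  (maximal merged elements make coverage totals deterministic).
- Variant identity is (chrom, pos, ref, alt); multi-allelic sites must be
  pre-split and are rejected on VCF ingest.
- The fallback promoter (1.5 kb upstream / 1 kb downstream of the TSS,
  strand-aware, clipped at the chromosome start) applies only to genes
  without experimentally derived elements; which transcript's TSS anchors
  it is the caller's choice via the TSS table (the convention for
  multi-TSS genes is genuinely open; the generator uses one TSS per gene).
- Region coverage totals are reported under both conventions — distinct
  bases globally, and summed per-gene unions — since shared elements make
  the two differ.
- Enhancer–gene links: a curated external map takes precedence; otherwise
  nearest TSS midpoint, all ties returned.
- Interval arithmetic is plain sorted-list merging; the scales involved
  (hundreds of regions per gene) never justify an interval-tree index, and
  brute-force base-enumeration oracles in the tests cover the logic.
- CNV panel-frequency matching uses ≥ 50% reciprocal overlap with the
  panel region, taking the highest matching frequency.
- The missense combination rule (≥ 5 tools reporting, strict majority
  deleterious) is a declared convention: the underlying studies list nine
  predictors but no vote rule. It is reproducible and monotone, and is the
  most likely surface of divergence from any specific study's manual
  calls.

## Calibration and problem sizes

The acceptance tests run at the design size n = 209/1326 with fixed seeds:
exact-test agreement with enumeration oracles (exhaustive to margins 16,
seeded sampling to 30), BH-FDR against a naive sort-and-step oracle on
1000 random vectors, type-I error of the per-gene Fisher test over 1000
null genes (band 0.03–0.07 at α = 0.05), mean corrected-OR recovery over
500 genes per stratum at true ORs {1, 3, 10} (≤ 15% bias at OR 3,
monotone), and full-cascade recovery of a gene planted at OR 10 (baseline
0.005) in ≥ 95% of 200 replicates against 10 null genes. These extents are
the package's documented calibration sizes; they complete in well under a
minute on one CPU.

## Known limitations

- Compound-het detection without phase over-calls cis pairs.
- The overall (all-genes pooled) regulatory burden OR is not computed: no
  per-sample 2×2 at n = 209/1326 reconstructs the published pooled value,
  so the counting unit behind it is ambiguous; the per-gene unit (distinct
  carrier samples) is the one that reproduces every per-gene result and is
  the only unit this package reports.
- The experimentally derived regulatory element set (≈ 910 regions,
  ≈ 3.0 Mb) depends on external epigenome data and is consumed as BED
  input, not rebuilt; printed totals tied to it are out of reach by
  design.
- External predictor outputs (splice delta scores, LoF confidence, missense
  and TFBS verdicts, ClinVar assertions) are consumed as annotations; the
  predictors themselves are not reimplemented.
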