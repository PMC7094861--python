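# Methods

## The assay model

The package models a tumor-only targeted-resequencing assay on FFPE tissue
with a mirrored dual-pool amplicon design: two pools, A and B, tile the same
target region with amplicons of opposite template strand. The raw input per
sample is one allele-count table per pool (`SiteCounts`): per target
position, read counts for A/C/G/T plus composite indel alleles
(`"REF>ALT"`), with depth equal to the sum of allele counts.

Three read-generating processes are distinguished:

* **True variants** (somatic or germline) contribute alt reads
  binomially at their allele fraction, independently in each pool — both
  template strands carry the change.
* **FFPE deamination artifacts** are C→T changes on a single damaged strand
  (G→A in reference orientation when the damaged strand is "−"). Their alt
  reads appear only in the pool whose template strand matches the damage;
  the mirrored pool sees base-error-level counts only.
* **Base-call errors** occur per read per site at rate ε (default 10⁻³),
  uniformly over the three non-reference bases.

This asymmetry is the entire basis of artifact suppression: requiring a
call in both pools removes single-strand lesions wholesale while costing
true variants essentially nothing at panel depths.

## Per-pool caller

The upstream instrument software that produced per-pool calls in the
original assay is proprietary; the caller here is a transparent stand-in
with the same observable contract. Allele *a* at a site is called iff

1. `alt_count ≥ min_alt_reads` (default 4), and
2. the exact one-sided binomial tail `P(X ≥ alt_count | depth, ε) ≤ α`
   (default α = 10⁻⁶), computed with `scipy.stats.binom.sf`.

At the default cumulative depth this yields a detection floor around 0.5–1%
allele fraction, comfortably below both the 3% reporting gate and the 6–17%
range in which low-frequency drivers were validated. Indel alleles use the
same count-plus-tail rule on their composite keys; multi-allelic sites
produce one independent record per alt allele.

## Consensus merge and QC cascade

`merge_pools` emits one `ConsensusVariant` per allele called in either
pool, with per-pool evidence `(depth, alt, vaf)` filled from raw counts even
for the uncalled pool, cumulative depth `d_A + d_B`, and merged VAF
`(alt_A + alt_B) / (d_A + d_B)`. A reference-base disagreement between
pools at the same position is a panel/reference inconsistency and raises.

The QC gates annotate flags rather than delete records (every rejection is
auditable; `status == PASS` ⇔ no flags):

| gate | flag | rule |
|---|---|---|
| both pools | `single_pool` | called in both mirrored pools |
| depth | `low_depth` | cumulative ≥ 1000X; the equivalent per-pool-average form (≥ 500X/pool) is kept in config for designs with ≠ 2 pools |
| allele fraction | `low_vaf` | merged VAF strictly > 3% |
| normals | `in_normals` | exact `(chrom, pos, ref, alt)` key present in the panel of normals |
| effect | `effect_excluded` | synonymous, intronic or UTR — unless splice site |

The three QC gates are conjunctive, hence order-independent and idempotent
(property-tested). Panel-of-normals matching is allele-exact rather than
position-only: position-only matching would delete true hotspot somatic
variants that happen to share a position with a germline polymorphism.
Whether the 3% gate applies before or after normal subtraction is
immaterial under flag semantics, which is why flags were chosen.

## Effect annotation

Single-transcript gene models (ordered CDS intervals, strand, splice window)
drive a deliberately small effect classifier: strand-aware translation of
the affected codon (Biopython, standard code) for SNVs; frameshift vs
in-frame by indel length mod 3; positions within 2 bp of an intron boundary
— the essential donor/acceptor dinucleotide — are splice sites; remaining
positions fall to intronic, UTR (inside the transcript span, outside CDS
and introns) or intergenic. Indels spanning a CDS/intron boundary classify
as splice sites with a warning. Protein changes are rendered in the field's
shorthand (`H1047R`, `T56fs`, `D246_splice`).

Driver classification: activating if the (gene, protein change) is a
catalogued hotspot; inactivating if the gene is a catalogued tumor
suppressor (PTEN, TP53) and the effect is nonsense/frameshift/splice;
candidate driver for any TP53 missense (the DNA-binding-domain enrichment
reported for real cohorts is descriptive, not a filter); VUS for other
changes in catalog genes; none otherwise.

Canine→human homology is a per-gene table of constant-offset segments:
PLCG1 +72 (273→345, 797→869), PTEN +22 (56→78, 246→268), PIK3CA/NRAS/TP53
offset 0. Positions outside every segment map to nothing — no guessing.

## Subtype assignment

Cases collapse onto five mutually exclusive subtypes from their PASS driver
variants, in precedence order: **PI3K_pathway** (PIK3CA activating or PTEN
inactivating — both elevate PI3K signaling), **NRAS**, **PLCG1**,
**TP53_only**, **NONE**. Real cohorts show these patterns as mutually
exclusive, so precedence matters only for out-of-distribution inputs; any
case carrying more than one of the PI3K/NRAS/PLCG1 classes is flagged
`conflict` rather than silently resolved. A hypothetical PTEN missense
(non-LoF) does not join the PI3K group; it stays VUS. Metastatic duplicates
(`tissue == "MT"`) are never counted in cohort denominators. Printed
percentages use largest-remainder reconciliation to one decimal so they sum
to 100.0 exactly, and the informative rate is defined as the complement of
the printed NONE percentage.

## Synthetic cohort: what it emulates, and what it does not

`SimConfig` defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_cases` | 50 | cohort size |
| `subtype_proportions` | 0.52/0.24/0.12/0.04/0.08 | PI3K/NRAS/TP53-only/PLCG1/none |
| `vaf_range` | 0.05–0.40 | driver/passenger allele fraction |
| `low_vaf_range`, `low_vaf_fraction` | 0.06–0.17, 0.3 | share of drivers drawn in the low-AF validation band |
| `depth_mean_per_pool`, `depth_dispersion` | 700, 100 | negative-binomial per-pool depth (cumulative mean 1400X) |
| `base_error_rate` | 10⁻³ | per-read per-site |
| `artifact_site_rate`, `artifact_vaf_range` | 0.02, 0.01–0.08 | fraction of eligible C:G sites damaged, artifact fraction |
| `n_normals` | 30 | matched normals pooled into the PoN |
| `n_passengers`, `n_germline_per_case`, `germline_pool_size` | 3, 5, 12 | per-case somatic passengers; heterozygous germline SNVs drawn from a shared population pool |

Subtype counts are the deterministic largest-remainder apportionment of
`n_cases × proportions` (50 cases → 26/12/6/2/4). Within the PI3K group,
3/26 of cases receive a PTEN LoF lesion and the rest a PIK3CA hotspot; 90%
of PI3K cases, 1/6 of NRAS cases and half of PLCG1 cases receive a TP53
co-lesion; 1/12 of NRAS cases carry E153K rather than Q61R; TP53 lesions
are 60% missense / 40% LoF. These within-group rates reproduce the observed
cohort composition; where a real cohort printed only totals, the rate is
the observed fraction.

The depth defaults deserve a note. The assay's depth averaged "over 1000X"
cumulative with high uniformity, and it confidently detected 6–17% AF
variants and re-identified every exome-validated driver — i.e. the 1000X QC
gate essentially never rejected a true-variant site in practice. The
generator therefore places cumulative depth at mean 1400X with CV ≈ 8%
(per-pool 700, dispersion 100), where `P(site < 1000X) ≈ 7×10⁻⁵`; with the
mean at the gate itself, half of all true variants would fail QC by
construction, which matches no observed behaviour of such assays.

Randomness: one master stream seeded from `SimConfig.seed` draws
cohort-level structure; each case's content and read counts come from
substreams keyed by a stable hash of the case id, so results are
reproducible and independent of iteration order.

"Passenger" draws that would meet the driver definition (TP53
nonsynonymous, PTEN/TP53 LoF, catalogued hotspots) are rejected and
redrawn: under this panel's driver definition such a change *is* a driver,
so labelling it passenger would make the truth internally inconsistent.
Gene sequences are random with hotspot codons planted, so internal stop
codons occur in untranslated reading positions; only the affected codon is
ever translated, so this is cosmetic (a passenger may be reported at a
reference `*` codon).

Deliberately not modelled: read-level data (FASTQ/BAM), PCR duplicates,
copy-number and structural variation, tumor purity as a separate parameter
(folded into allele fraction), isoform selection, population germline
frequency databases. Consequently, passing tests demonstrate the logic of
dual-pool artifact suppression, QC, PoN subtraction, annotation and
subtyping under the stated read model — not robustness to alignment
artifacts, FFPE fragment-length effects or CNV-driven allele-fraction
distortion in real data.

## Numerical and interface choices

* Genomic intervals are 0-based half-open (BED); variant positions 1-based
  (VCF); conversion is centralised in `panel_model`.
* The default synthetic panel is a scaled-down design: full coding regions
  of the five driver genes, 174 amplicons of 175 bp (mirrored pairs),
  12,775 bp merged target — configuration, not a hard-coded constant. TP53
  is placed on the minus strand to exercise strand-aware annotation.
* The VAF gate is strict (`>` 3%): a variant at exactly 3% fails.
* Ties in largest-remainder apportionment break lexicographically.
* Depth-0 sites emit no calls; evidence lookups at uncovered positions
  raise rather than default.
* Zero-normal PoN construction warns and yields an empty set.
* Output VCFs (pysam) carry per-pool depth/alt INFO keys (DPA/DPB/ADA/ADB),
  merged VAF (CVAF), annotation keys (GENE/EFF/PCH/HCH/DRV) and the filter
  flags verbatim in FILTER.

## Problem sizes used by the test and acceptance suites

Unit and property tests run on toy tables and the default panel. The
end-to-end suites use 50-case cohorts (plus 30 normals each) across 20
seeds for subtype recovery and artifact suppression (>120,000 injected
artifact sites in total), 600 replicate sites for VAF calibration, and an
exhaustive caller-vs-oracle sweep over all depths ≤ 200. The acceptance
script rebuilds the 50-case published composition and simulates one default
tumor sample for the coverage figure.

## Known limitations

* The per-pool caller is a contract-level stand-in, not a re-implementation
  of any proprietary caller's internals; its thresholds (4 reads, α = 10⁻⁶)
  are calibration choices.
* Homology mapping assumes constant offsets within segments; genes with
  internal indel differences between species would need multi-segment
  tables.
* Single-transcript gene models; no HGVS c. notation; no regulatory
  effects.
* TP53 gain-of-function missense changes are not distinguished from other
  candidate drivers.
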