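# Methods

## Classification model

`toscalite` classifies tumor-only variant calls with a sequential,
early-exiting three-phase decision tree. The phases are a pipeline: a
decision taken at one phase is final except where noted.

**Phase 1 — quality and variant type.** A call is `filtered` when any gate
fails: caller filter ≠ PASS, total depth < `min_depth`, VAF < `min_vaf` (an
undeterminable VAF — zero depth with no explicit AF field — always fails),
or a consequence outside the non-synonymous whitelist. All failing gates are
reported, not only the first. A zero-depth call can pass only when
`min_depth = 0` *and* an explicit VAF was provided.

**Phase 2 — population frequency with catalogue override.** A somatic-
catalogue hit decides somatic immediately, even when the variant is also
common in a germline population source (reason `COSMIC_OVERRIDE` when such
evidence coexists, `COSMIC` otherwise). Failing that, a hit in any of the
four population sources with allele frequency ≥ `germline_maf_cutoff`
(inclusive, default 0.01) decides germline. The four sources are pooled
(any-hit); priority affects reporting only — the reason names the highest-
priority qualifying source, default ranking ExAC > 1000G > ESP > dbSNP,
reflecting dbSNP's weaker discrimination of true germline variation.

**Phase 3 — clinical significance, then the somatic default.** An undecided
variant with a benign clinical record becomes germline
(`CLINVAR_BENIGN`); all other survivors default to somatic
(`NO_EVIDENCE_DEFAULT_SOMATIC`). The default exists because the method is
total: a novel non-synonymous variant absent from every germline catalogue
is the canonical somatic candidate, and no "unknown" bucket exists.

### Evidence semantics

- *Benign* means: at least one of {benign, likely_benign} and **no**
  pathogenic-family or conflicting term. Mixed or conflicting assertions
  never count as benign evidence.
- An AF-less dbSNP-style hit decides phase 2 only when flagged common, or
  globally when `dbsnp_presence_is_germline` is set; otherwise it is
  recorded but non-deciding. A dbSNP record that does carry a numeric AF is
  treated like any other frequency source.
- The stored AF is compared directly to the cutoff; `maf_folding` (default
  off) folds AF > 0.5 to the minor allele first. The default follows the
  simplest reading of a "minor allele frequency of 1%" rule where catalogued
  AFs are alternate-allele frequencies.
- A catalogue-somatic call survives a benign clinical record by default, by
  analogy with the catalogue's precedence over population frequency;
  `clinvar_overrides_cosmic` inverts this, as the opposite convention is
  also defensible.

### Variant identity

All joins use a normalized key (contig, 1-based position, ref, alt).
Normalization is reference-free parsimony trimming: shared trailing bases
removed, then shared leading bases while both alleles stay longer than one
base (the remaining lead base is the VCF anchor for indels). Multiallelic
records are split per alternate allele before normalization. Contig-name
`chr` prefixes are harmonized under a single configurable policy
(strip/add/as-is). Reference-FASTA left-alignment across repeat tracts is
deliberately out of scope: two spellings anchored at different repeat
copies will not unify, which is an accepted limitation of a reference-free
key.

## Thresholds

| parameter | default | unit | role |
|---|---|---|---|
| `min_vaf` | 0.05 (TS and WES) | fraction | phase-1 tumor VAF floor |
| `min_depth` | 50 (TS), 20 (WES) | reads | phase-1 depth floor |
| `germline_maf_cutoff` | 0.01 | fraction | phase-2 population-frequency rule (inclusive ≥) |
| `normal_af_cutoff` | 0.05 | fraction | gold standard: normal AF strictly above ⇒ germline |

The `min_vaf`/`min_depth` values are this package's own defaults for the
two assay modes, chosen as round, conventional panel/exome cutoffs; both
are prominently config-overridable. The 1% population cutoff is inclusive
(≥) because "at 1%" is conventionally read inclusively; the 5% normal
cutoff is strict (>) because the rule is phrased as an exceedance. The
boundary behavior of both is pinned by tests.

## Paired-normal gold standard and metrics

Truth labels come from the matched normal: a tumor variant whose normalized
key matches a normal call with VAF > 5% is germline; every other tumor
variant — absent from the normal, or matched at ≤ 5% — is somatic
(the complement rule). Matching ignores genotype; normal-only variants are
ignored. Somatic is the positive class: sensitivity = TP/(TP+FN) over
truth-somatic, specificity = TN/(TN+FP) over truth-germline. Phase-1
`filtered` calls are excluded from the confusion matrix before scoring
(the evaluation concerns somatic-vs-germline decisions); a metric whose
denominator class is absent is reported as undefined rather than 0/0.

## Synthetic cohort generator

The generator emulates an annotated matched tumor/normal variant set with
known truth, not sequencing reads. Per variant:

- unique position on one synthetic 10 Mb contig (sampled without
  replacement); 10% short (1–3 bp) indels by default, to exercise key
  normalization; non-synonymous consequences throughout.
- truth label germline with probability `germline_fraction` (default 0.57,
  the class balance of the validation cohort shape we default to, with
  `n_variants` = 655); germline variants are heterozygous (true AF 0.5) or
  homozygous (1.0, 20% of them), somatic variants have true tumor AF
  `tumor_purity`/2 (default 0.4, a clonal heterozygous mutation at 80%
  purity) and true normal AF 0.
- read support is binomial sampling at a Poisson depth (`mean_depth`,
  default 250, a deep targeted panel) — the simplest noise model consistent
  with depth/VAF thresholds. The normal VCF contains a variant only when at
  least one alternate read was drawn.
- database membership is an independent Bernoulli channel per source:
  a germline variant enters each population source with probability
  `db_sensitivity` (default 0.45 per source, i.e. ~91% are in at least one
  of the four) at a log-uniform AF in [cutoff, 0.5]; a somatic variant
  erroneously enters with `db_false_common` (0.02). Somatic variants enter
  the somatic catalogue with `cosmic_sensitivity` (0.30); germline variants
  leak in with `cosmic_germline_leak` (0.03), modeling the catalogue's
  known germline contamination. Germline variants carry a benign clinical
  record with `clinvar_benign_rate` (0.20). The completeness/noise rates
  are this package's choices of a realistic partially-annotated setting;
  they are documented here because no external source fixes them.

Everything derives from one `numpy` generator seeded by `params.seed`; two
runs with equal parameters are byte-identical on disk.

**What passing synthetic tests does not show.** Independent Bernoulli
membership ignores the strong correlation between real population
databases; binomial read noise ignores mapping artifacts, strand bias and
FFPE damage; there is no subclonal structure, copy number, or mutational
signature. Synthetic results validate the decision logic and its plumbing,
not performance on any real cohort.

## Numerical and degenerate-input choices

- VAF source precedence: explicit AF field > AD-derived > TSV column; a
  disagreement > 0.01 is logged and the explicit field wins.
- Duplicate database keys keep the maximum AF (population) or the first
  record (catalogue/clinical), logged.
- VAFs are serialized at 6 decimals; round-trips are asserted to 4.
- Empty inputs produce header-only outputs; an empty database is a warning,
  not an error.
- Output files are bit-stable for identical input (fixed formatting, no
  timestamps); a run manifest records thresholds, switches and database
  checksums in lieu of workflow-engine provenance.

## Benchmark problem sizes

The default benchmark and the acceptance script use cohorts of 655 variants
(the validation-cohort shape) for the noisy pure-mode run and 10⁴ variants
for the totality and noiseless-recovery checks; the decision-tree oracle
comparison enumerates the full evidence truth table (16 000 states across
all switch settings). These sizes give binomial standard errors well under
the effects being checked while keeping any run under a few seconds.

## Known limitations

- Reference-free normalization cannot unify indel spellings anchored at
  different copies of a repeat tract (needs FASTA-aware left-alignment,
  left as an extension point).
- No purity/ploidy-aware reclassification (the "hybrid" pool-of-normals
  approach): only the pure tumor-only decision tree is implemented here.
- Population-AF semantics assume a biallelic alternate-allele frequency;
  multi-population AF vectors (e.g. per-ancestry fields) must be reduced to
  a single AF upstream or via the configurable AF key.
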