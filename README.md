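# toscalite

Tumor-only somatic vs germline variant classification.

## The problem

When a tumor is sequenced without a matched normal sample — the common
situation in clinical panel (TS) and increasingly in whole-exome (WES)
testing — every variant call is a mixture of the patient's inherited
(germline) variation and the tumor's acquired (somatic) mutations. Telling
them apart from the tumor alone requires external evidence: population
allele-frequency catalogues identify common inherited variants, a somatic
mutation catalogue identifies recurrently acquired ones, and clinical
significance assertions rescue rarer inherited variants.

`toscalite` implements this as a three-phase, database-prioritized decision
tree, together with the paired-normal gold standard used to validate such a
classifier and a deterministic synthetic cohort generator, so the whole
pipeline is testable end to end without any external downloads. It is a
library plus a command-line tool for bioinformaticians building or
benchmarking tumor-only calling workflows.

## The algorithm

For each tumor call with variant allele fraction (VAF), depth, caller filter
status and functional consequence:

1. **Quality / variant type.** Discard calls that fail the caller filter,
   have depth < `min_depth`, VAF < `min_vaf`, or are not of a
   non-synonymous consequence class. Discarded calls are labeled
   `filtered` and take no further part.
2. **Databases.** A hit in the somatic catalogue (COSMIC-style) labels the
   variant **somatic**, *even when population-frequency evidence coexists*.
   Otherwise, presence in any of the four germline population sources
   (1000 Genomes-, ESP-, ExAC-, dbSNP-style) at a minor allele frequency
   ≥ 1% (`germline_maf_cutoff`, inclusive) labels it **germline**; the
   reported reason names the highest-priority database
   (ExAC > 1000G > ESP > dbSNP). An AF-less dbSNP hit decides only when
   flagged common (or via a config switch).
3. **Clinical significance.** Remaining undecided variants with a strictly
   benign/likely-benign ClinVar-style assertion become **germline**; every
   other survivor defaults to **somatic**. Every variant that passes phase 1
   therefore receives a definitive label.

Validation uses a matched normal: a tumor variant present in the normal at
allele fraction > 5% (strict) is truth-germline, all others truth-somatic.
With somatic as the positive class, sensitivity = TP/(TP+FN) over
truth-somatic variants and specificity = TN/(TN+FP) over truth-germline
variants.

## Worked example

Simulate a cohort with known truth, classify the tumor sample tumor-only,
derive the paired-normal gold standard, and score:

```sh
toscalite simulate --seed 5 --out demo/
cd demo
cat > config.yaml <<'EOF'
mode: TS
switches: {chr_policy: as-is}
databases:
  - {name: KG1000, kind: population, path: kg1000.tsv, format: tsv}
  - {name: ESP, kind: population, path: esp.tsv, format: tsv}
  - {name: EXAC, kind: population, path: exac.tsv, format: tsv}
  - {name: DBSNP, kind: population, path: dbsnp.tsv, format: tsv}
  - {name: COSMIC, kind: somatic, path: cosmic.tsv, format: tsv}
  - {name: CLINVAR, kind: clinical, path: clinvar.tsv, format: tsv}
EOF
toscalite check --config config.yaml
toscalite classify --tumor tumor.vcf --config config.yaml --out run
toscalite truth --tumor tumor.vcf --normal normal.vcf --out gold.tsv
toscalite evaluate --pred run.classified.tsv --truth gold.tsv --out report.tsv
```

which prints:

```
check passed: all inputs and parameters valid
classified 655 variants: 340 germline, 315 somatic
gold standard: 655 variants, 375 germline, 280 somatic
evaluated 655 variants (0 unmatched): sensitivity 95.0% (266/280 somatic), specificity 86.9% (326/375 germline)
```

Reading: of the 280 variants the matched normal proves somatic, tumor-only
classification recovered 266 (95.0% sensitivity); of the 375 proven
germline, it recognized 326 (86.9% specificity). The misses are germline
variants absent from the (deliberately incomplete) population databases and
somatic variants that leaked into them — the structural failure modes of
tumor-only calling. `run.classified.tsv`/`.vcf` carry, per variant, every
database's evidence, the final label, the deciding phase, and ordered reason
codes (e.g. `GERMLINE_DB:EXAC`, `COSMIC_OVERRIDE`,
`NO_EVIDENCE_DEFAULT_SOMATIC`).

`toscalite bench --seed 5 --out bench/` runs the same loop in one step.

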