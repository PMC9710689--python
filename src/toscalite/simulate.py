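"""Deterministic synthetic tumor/normal cohorts with known truth.

The generator emulates the evidence structure the classifier consumes: a
cohort of unique variants on one synthetic contig, a known somatic/germline
truth per variant, matched tumor and normal read support (binomial read
sampling given depth and true allele fraction), and miniature versions of
the six databases whose membership is drawn from per-channel Bernoulli
rates — including the failure modes that make tumor-only calling hard:
germline variants missing from the population databases, somatic variants
erroneously present in them, germline leakage into the somatic catalogue.

Defaults mirror the validation cohort's shape (655 variants, 57% germline);
the database completeness/noise rates are this package's own choices,
documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .databases import (ClinicalDB, ClinicalRecord, DatabaseSet,
                        DEFAULT_PRIORITIES, PopulationDB, PopulationRecord,
                        SomaticCatalogue, SomaticRecord, Switches)
from .evaluation import TruthSet
from .variants import PASS, ToscaError, VariantCall, VariantKey, write_variants

logger = logging.getLogger("toscalite")

CONTIG = "1"
CONTIG_LENGTH = 10_000_000
_BASES = np.array(list("ACGT"))

SNV_CONSEQUENCE = "missense_variant"
INS_CONSEQUENCE = "inframe_insertion"
DEL_CONSEQUENCE = "frameshift_variant"

AF_DB_NAMES = ("KG1000", "ESP", "EXAC")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort; all probabilities in [0, 1].

    ``db_sensitivity`` is the per-database probability that a truth-germline
    variant is present with AF at/above the germline cutoff;
    ``db_false_common`` the per-database probability that a truth-somatic
    variant erroneously appears that way. ``cosmic_germline_leak`` models
    the somatic catalogue's known contamination with germline variants.
    """

    n_variants: int = 655
    germline_fraction: float = 0.57
    db_sensitivity: float = 0.45
    db_false_common: float = 0.02
    cosmic_sensitivity: float = 0.30
    cosmic_germline_leak: float = 0.03
    clinvar_benign_rate: float = 0.20
    tumor_purity: float = 0.8
    mean_depth: int = 250
    indel_fraction: float = 0.10
    homozygous_fraction: float = 0.20
    germline_maf_cutoff: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ToscaError(f"n_variants must be >= 1, got {self.n_variants}")
        for name in ("germline_fraction", "db_sensitivity", "db_false_common",
                     "cosmic_sensitivity", "cosmic_germline_leak",
                     "clinvar_benign_rate", "tumor_purity", "indel_fraction",
                     "homozygous_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ToscaError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth < 1:
            raise ToscaError(f"mean_depth must be >= 1, got {self.mean_depth}")


@dataclass
class SimulatedCohort:
    """In-memory result of one simulation run."""

    params: SimulationParams
    tumor_calls: list
    normal_calls: list
    databases: DatabaseSet
    truth: TruthSet
    paths: dict = field(default_factory=dict)


def _draw_alleles(rng: np.random.Generator, n: int, indel_fraction: float):
    """Unique keys on the synthetic contig: SNVs plus short (1-3 bp) indels."""
    pos = np.sort(rng.choice(
        np.arange(1_000, CONTIG_LENGTH - 1_000), size=n, replace=False))
    is_indel = rng.random(n) < indel_fraction
    refs, alts, consequences = [], [], []
    for i in range(n):
        anchor = rng.choice(_BASES)
        if not is_indel[i]:
            alt = rng.choice(_BASES[_BASES != anchor])
            refs.append(str(anchor))
            alts.append(str(alt))
            consequences.append(SNV_CONSEQUENCE)
        else:
            length = int(rng.integers(1, 4))
            extra = "".join(rng.choice(_BASES, size=length))
            if rng.random() < 0.5:  # deletion
                refs.append(str(anchor) + extra)
                alts.append(str(anchor))
                consequences.append(DEL_CONSEQUENCE)
            else:  # insertion
                refs.append(str(anchor))
                alts.append(str(anchor) + extra)
                consequences.append(INS_CONSEQUENCE)
    keys = [VariantKey(CONTIG, int(p), r, a) for p, r, a in zip(pos, refs, alts)]
    return keys, consequences


def _draw_af(rng: np.random.Generator, cutoff: float) -> float:
    """Population AF at/above the cutoff, log-uniform up to 0.5."""
    lo, hi = np.log10(cutoff), np.log10(0.5)
    return float(10 ** rng.uniform(lo, hi))


def simulate(params: SimulationParams, out_dir=None) -> SimulatedCohort:
    """Generate a matched tumor/normal cohort plus database files.

    Fully reproducible from ``params.seed`` (two runs are byte-identical when
    written to disk). When ``out_dir`` is given, writes ``tumor.vcf``,
    ``normal.vcf``, ``truth.tsv`` and one TSV per database, all parseable by
    this package's readers.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_variants
    keys, consequences = _draw_alleles(rng, n, params.indel_fraction)

    is_germline = rng.random(n) < params.germline_fraction
    hom = rng.random(n) < params.homozygous_fraction
    normal_af_true = np.where(is_germline, np.where(hom, 1.0, 0.5), 0.0)
    tumor_af_true = np.where(is_germline, normal_af_true,
                             params.tumor_purity / 2.0)

    depth_t = rng.poisson(params.mean_depth, n)
    depth_n = rng.poisson(params.mean_depth, n)
    alt_t = rng.binomial(depth_t, tumor_af_true)
    alt_n = rng.binomial(depth_n, normal_af_true)

    tumor_calls, normal_calls, truth_labels = [], [], {}
    for i, key in enumerate(keys):
        vaf_t = float(alt_t[i] / depth_t[i]) if depth_t[i] > 0 else None
        tumor_calls.append(VariantCall(
            key=key, total_depth=int(depth_t[i]), alt_depth=int(alt_t[i]),
            vaf=vaf_t, filter_status=PASS, consequence=consequences[i],
            sample_id="TUMOR"))
        if alt_n[i] > 0:
            normal_calls.append(VariantCall(
                key=key, total_depth=int(depth_n[i]), alt_depth=int(alt_n[i]),
                vaf=float(alt_n[i] / depth_n[i]), filter_status=PASS,
                consequence=consequences[i], sample_id="NORMAL"))
        truth_labels[key] = "germline" if is_germline[i] else "somatic"

    # database membership: independent Bernoulli channels per variant
    cutoff = params.germline_maf_cutoff
    population = {}
    for name in AF_DB_NAMES:
        db = PopulationDB(name=name, priority=DEFAULT_PRIORITIES[name])
        p_hit = np.where(is_germline, params.db_sensitivity, params.db_false_common)
        hits = rng.random(n) < p_hit
        for i in np.flatnonzero(hits):
            db.records[keys[i]] = PopulationRecord(af=round(_draw_af(rng, cutoff), 6))
        population[name] = db
    dbsnp = PopulationDB(name="DBSNP", priority=DEFAULT_PRIORITIES["DBSNP"])
    p_hit = np.where(is_germline, params.db_sensitivity, params.db_false_common)
    hits = rng.random(n) < p_hit
    for i in np.flatnonzero(hits):
        dbsnp.records[keys[i]] = PopulationRecord(af=None, common_flag=True)
    population["DBSNP"] = dbsnp

    cosmic = SomaticCatalogue()
    p_hit = np.where(is_germline, params.cosmic_germline_leak,
                     params.cosmic_sensitivity)
    hits = rng.random(n) < p_hit
    for j, i in enumerate(np.flatnonzero(hits)):
        cosmic.records[keys[i]] = SomaticRecord(catalogue_id=f"COSM{j + 1}")

    clinvar = ClinicalDB()
    hits = (rng.random(n) < params.clinvar_benign_rate) & is_germline
    for i in np.flatnonzero(hits):
        term = "benign" if rng.random() < 0.5 else "likely_benign"
        clinvar.records[keys[i]] = ClinicalRecord(significance=frozenset({term}))

    dbs = DatabaseSet(population=population, somatic=cosmic, clinical=clinvar,
                      switches=Switches())
    truth = TruthSet(labels=truth_labels, source_sample=("TUMOR", "NORMAL"))
    cohort = SimulatedCohort(params=params, tumor_calls=tumor_calls,
                             normal_calls=normal_calls, databases=dbs,
                             truth=truth)
    if out_dir is not None:
        cohort.paths = write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Write the cohort as the standard files the other modules consume."""
    from .evaluation import write_truth_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tumor": out / "tumor.vcf",
        "normal": out / "normal.vcf",
        "truth": out / "truth.tsv",
    }
    write_variants(cohort.tumor_calls, paths["tumor"], format="vcf")
    write_variants(cohort.normal_calls, paths["normal"], format="vcf")
    write_truth_tsv(cohort.truth, paths["truth"])
    for name, db in cohort.databases.population.items():
        p = out / f"{name.lower()}.tsv"
        paths[name] = p
        with open(p, "w") as fh:
            fh.write("chrom\tpos\tref\talt\taf\tcommon\n")
            for key in sorted(db.records):
                rec = db.records[key]
                af = f"{rec.af:.6f}" if rec.af is not None else "."
                common = {True: "1", False: "0", None: "."}[rec.common_flag]
                fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                         f"{af}\t{common}\n")
    paths["COSMIC"] = out / "cosmic.tsv"
    with open(paths["COSMIC"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tid\n")
        for key in sorted(cohort.databases.somatic.records):
            rec = cohort.databases.somatic.records[key]
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{rec.catalogue_id}\n")
    paths["CLINVAR"] = out / "clinvar.tsv"
    with open(paths["CLINVAR"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsignificance\n")
        for key in sorted(cohort.databases.clinical.records):
            rec = cohort.databases.clinical.records[key]
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{','.join(sorted(rec.significance))}\n")
    logger.info("simulated cohort written to %s (%d tumor, %d normal calls)",
                out, len(cohort.tumor_calls), len(cohort.normal_calls))
    return {k: str(v) for k, v in paths.items()}
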