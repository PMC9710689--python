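"""In-memory evidence sources and the annotation join.

Six local databases drive tumor-only classification: four germline
population-frequency sources (1000 Genomes-style, ESP-style, ExAC-style,
dbSNP-style), one somatic catalogue (COSMIC-style) and one clinical-
significance archive (ClinVar-style). Each is loaded from VCF or TSV into a
dict keyed by normalized :class:`~toscalite.variants.VariantKey`, and
``annotate`` performs an exact-key join of a call list against the set.

dbSNP is ranked below the frequency-bearing sources because presence in
dbSNP alone is weak germline evidence (it also catalogues pathogenic
variants); its hits decide phase 2 only when flagged common, carrying a
numeric AF, or when the ``dbsnp_presence_is_germline`` switch is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pysam

from .variants import (ConfigError, FormatError, VariantCall, VariantKey,
                       normalize_variant)

logger = logging.getLogger("toscalite")

POPULATION_DB_NAMES = ("KG1000", "ESP", "EXAC", "DBSNP")

#: default priority ranks (lower = higher priority); ExAC outranks the rest,
#: dbSNP last. Config-overridable.
DEFAULT_PRIORITIES = {"EXAC": 1, "KG1000": 2, "ESP": 3, "DBSNP": 4}

BENIGN_TERMS = frozenset({"benign", "likely_benign"})
PATHOGENIC_FAMILY = frozenset({"pathogenic", "likely_pathogenic"})


# ---------------------------------------------------------------------------
# Records and databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationRecord:
    af: Optional[float] = None
    common_flag: Optional[bool] = None

    def __post_init__(self):
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise FormatError(f"population AF {self.af} outside [0, 1]")


@dataclass(frozen=True)
class SomaticRecord:
    catalogue_id: str
    occurrence_count: Optional[int] = None


@dataclass(frozen=True)
class ClinicalRecord:
    significance: frozenset

    def __post_init__(self):
        if not self.significance:
            raise FormatError("clinical record with empty significance set")

    @property
    def is_benign(self) -> bool:
        """Benign evidence: at least one benign/likely_benign term and no
        pathogenic-family or conflicting term (conservative reading)."""
        sig = {s.lower() for s in self.significance}
        return bool(sig & BENIGN_TERMS) and not (sig & PATHOGENIC_FAMILY) \
            and "conflicting" not in sig and "conflicting_interpretations" not in sig


@dataclass
class PopulationDB:
    name: str
    priority: int
    records: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)


@dataclass
class SomaticCatalogue:
    records: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)


@dataclass
class ClinicalDB:
    records: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)


@dataclass(frozen=True)
class Switches:
    """Behavioral switches for ambiguous points of the filtration strategy."""

    maf_folding: bool = False            # fold AF>0.5 to minor allele before cutoff
    dbsnp_presence_is_germline: bool = False  # AF-less, non-common dbSNP hits decide
    clinvar_overrides_cosmic: bool = False    # benign ClinVar beats catalogue hit
    chr_policy: str = "strip"


@dataclass
class DatabaseSet:
    """The configured evidence sources consulted during classification."""

    population: dict = field(default_factory=dict)  # name -> PopulationDB
    somatic: SomaticCatalogue = field(default_factory=SomaticCatalogue)
    clinical: ClinicalDB = field(default_factory=ClinicalDB)
    switches: Switches = field(default_factory=Switches)

    def __post_init__(self):
        prios = [db.priority for db in self.population.values()]
        if len(prios) != len(set(prios)):
            raise ConfigError("population database priorities must be unique")

    def priority_order(self) -> list[str]:
        """Population database names, highest priority (lowest rank) first."""
        return sorted(self.population, key=lambda n: self.population[n].priority)


@dataclass(frozen=True)
class EvidenceBundle:
    """All evidence retrieved for one variant (absence is a valid state)."""

    population_hits: dict = field(default_factory=dict)  # name -> PopulationRecord
    somatic_hit: Optional[SomaticRecord] = None
    clinical_hit: Optional[ClinicalRecord] = None


@dataclass(frozen=True)
class AnnotatedVariant:
    call: VariantCall
    evidence: EvidenceBundle


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _iter_source_rows(path, format, af_key, chr_policy):
    """Yield (key, af, common_flag, ident, significance_terms) per record."""
    from .variants import sniff_format

    fmt = format or sniff_format(path)
    if fmt == "vcf":
        try:
            vf = pysam.VariantFile(str(path))
        except (OSError, ValueError) as exc:
            raise FormatError(f"cannot parse database VCF {path}: {exc}") from exc
        with vf:
            has_af = af_key in vf.header.info
            has_common = "COMMON" in vf.header.info
            has_sig = "CLNSIG" in vf.header.info
            for rec in vf:
                if rec.alts is None:
                    continue
                afs = rec.info.get(af_key, None) if has_af else None
                if afs is not None and not isinstance(afs, tuple):
                    afs = (afs,)
                common = None
                if has_common:
                    common = "COMMON" in rec.info
                sig = rec.info.get("CLNSIG", None) if has_sig else None
                if sig is not None and not isinstance(sig, tuple):
                    sig = (sig,)
                for i, alt in enumerate(rec.alts):
                    key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, chr_policy)
                    af = None
                    if afs is not None and i < len(afs) and afs[i] is not None:
                        af = float(afs[i])
                    yield key, af, common, rec.id, sig
    elif fmt == "tsv":
        import pandas as pd

        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError:
            return
        except Exception as exc:
            raise FormatError(f"cannot parse database TSV {path}: {exc}") from exc
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
        if missing:
            raise FormatError(f"database TSV {path} missing columns: {', '.join(missing)}")
        for lineno, row in enumerate(df.itertuples(index=False), start=1):
            key = normalize_variant(str(row.chrom), int(row.pos), str(row.ref),
                                    str(row.alt), chr_policy)
            raw_af = getattr(row, "af", None)
            af = None
            if raw_af not in (None, "", ".") and raw_af == raw_af:
                af = float(raw_af)
                if not (0.0 <= af <= 1.0):
                    raise FormatError(f"{path} line {lineno}: AF {af} outside [0, 1]")
            raw_common = getattr(row, "common", None)
            common = None
            if raw_common not in (None, "", ".") and raw_common == raw_common:
                common = str(raw_common).lower() in ("1", "true", "yes")
            ident = getattr(row, "id", None)
            sig = getattr(row, "significance", None)
            if sig not in (None, "", ".") and sig == sig:
                sig = tuple(str(sig).split(","))
            else:
                sig = None
            yield key, af, common, ident, sig
    else:
        raise FormatError(f"unknown database format {fmt!r}")


def load_database(path, kind: str, name: str = "", format: Optional[str] = None,
                  af_key: str = "AF", priority: Optional[int] = None,
                  chr_policy: str = "strip"):
    """Load one evidence source into its in-memory form.

    ``kind`` is ``population`` (returns :class:`PopulationDB`), ``somatic``
    (:class:`SomaticCatalogue`) or ``clinical`` (:class:`ClinicalDB`). All
    keys are normalized; duplicate keys are resolved by keeping the maximum
    AF (population) or the first record (somatic/clinical), logged.
    """
    if kind == "population":
        if priority is None:
            if name not in DEFAULT_PRIORITIES:
                raise ConfigError(f"no default priority for population DB {name!r}")
            priority = DEFAULT_PRIORITIES[name]
        db = PopulationDB(name=name, priority=priority)
        n = 0
        for key, af, common, _, _ in _iter_source_rows(path, format, af_key, chr_policy):
            n += 1
            if af is not None and not (0.0 <= af <= 1.0):
                raise FormatError(f"{path}: AF {af} outside [0, 1] at {key}")
            rec = PopulationRecord(af=af, common_flag=common)
            prev = db.records.get(key)
            if prev is not None:
                logger.warning("duplicate key %s in %s; keeping max AF", key, name)
                if (prev.af or 0.0) >= (af or 0.0):
                    continue
            db.records[key] = rec
        if n == 0:
            logger.warning("database %s loaded from %s is empty", name, path)
        return db
    if kind == "somatic":
        cat = SomaticCatalogue()
        for i, (key, _, _, ident, _) in enumerate(
                _iter_source_rows(path, format, af_key, chr_policy)):
            if key in cat.records:
                logger.warning("duplicate key %s in somatic catalogue; keeping first", key)
                continue
            cat.records[key] = SomaticRecord(catalogue_id=str(ident or f"COS{i + 1}"))
        if not cat.records:
            logger.warning("somatic catalogue loaded from %s is empty", path)
        return cat
    if kind == "clinical":
        db = ClinicalDB()
        for key, _, _, _, sig in _iter_source_rows(path, format, af_key, chr_policy):
            if sig is None:
                continue
            if key in db.records:
                logger.warning("duplicate key %s in clinical DB; keeping first", key)
                continue
            db.records[key] = ClinicalRecord(significance=frozenset(sig))
        if not db.records:
            logger.warning("clinical database loaded from %s is empty", path)
        return db
    raise ConfigError(f"unknown database kind {kind!r}; "
                      "expected population, somatic or clinical")


# ---------------------------------------------------------------------------
# Annotation join
# ---------------------------------------------------------------------------

def lookup(key: VariantKey, dbs: DatabaseSet) -> EvidenceBundle:
    """Exact lookup of one normalized key across every configured source."""
    pop_hits = {}
    for name, db in dbs.population.items():
        rec = db.records.get(key)
        if rec is not None:
            pop_hits[name] = rec
    return EvidenceBundle(
        population_hits=pop_hits,
        somatic_hit=dbs.somatic.records.get(key),
        clinical_hit=dbs.clinical.records.get(key),
    )


def annotate(calls: Sequence[VariantCall], dbs: DatabaseSet) -> list[AnnotatedVariant]:
    """Pair each call with its :class:`EvidenceBundle`; a pure join.

    Input order is preserved; a call absent from every source gets an empty
    bundle.
    """
    return [AnnotatedVariant(call=c, evidence=lookup(c.key, dbs)) for c in calls]
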