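"""Core variant data types, normalization, and VCF/TSV readers and writers.

Coordinates are 1-based, fully closed, VCF convention throughout; the TSV
dialect uses the same convention. Normalization is reference-free: alleles
are reduced to their parsimonious spelling (shared trailing bases trimmed,
shared leading bases trimmed down to the single VCF anchor base for indels).
Full FASTA-aware left-alignment across repeat tracts is out of scope; the
parsimonious key is what every database join in this package operates on.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pysam

logger = logging.getLogger("toscalite")

# ---------------------------------------------------------------------------
# Errors and exit codes (CLI maps exception class -> exit status)
# ---------------------------------------------------------------------------

EXIT_OK = 0
EXIT_CONFIG = 3
EXIT_FORMAT = 4
EXIT_IO = 5


class ToscaError(Exception):
    """Base class for all package errors."""


class InvalidVariantError(ToscaError):
    """A variant record violates the allele/position contract."""


class FormatError(ToscaError):
    """An input file does not parse under the declared format."""


class ConfigError(ToscaError):
    """A configuration value is missing, unknown, or out of range."""


# ---------------------------------------------------------------------------
# Chromosome naming policy
# ---------------------------------------------------------------------------

CHR_POLICIES = ("strip", "add", "as-is")


def apply_chr_policy(chrom: str, policy: str = "strip") -> str:
    """Harmonize the ``chr`` prefix so sources using hg19/hg38-style contig
    names join correctly. ``strip`` (default) removes a leading ``chr``;
    ``add`` prepends it when absent; ``as-is`` leaves the name untouched."""
    if policy not in CHR_POLICIES:
        raise ConfigError(f"unknown chr policy {policy!r}; expected one of {CHR_POLICIES}")
    if policy == "strip":
        return chrom[3:] if chrom.lower().startswith("chr") else chrom
    if policy == "add":
        return chrom if chrom.lower().startswith("chr") else "chr" + chrom
    return chrom


# ---------------------------------------------------------------------------
# VariantKey and normalization
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic change: the join key used everywhere.

    ``pos`` is the 1-based position of the first reference base. ``ref`` and
    ``alt`` are non-empty uppercase ACGT strings in parsimonious form.
    """

    chrom: str
    pos: int
    ref: str
    alt: str


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      chr_policy: str = "as-is") -> VariantKey:
    """Reduce (chrom, pos, ref, alt) to its parsimonious representation.

    Shared trailing bases are trimmed first, then shared leading bases while
    both alleles remain longer than one base (the remaining leading base is
    the VCF anchor for indels; ``pos`` advances with each leading trim).
    Idempotent and deterministic.

    Raises
    ------
    InvalidVariantError
        on non-ACGT characters, pos < 1, or ref == alt after trimming.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt or not (set(ref) <= _ACGT) or not (set(alt) <= _ACGT):
        raise InvalidVariantError(
            f"non-ACGT or empty allele in record {chrom}:{pos} {ref!r}>{alt!r}")
    if pos < 1:
        raise InvalidVariantError(f"position must be >= 1 in record {chrom}:{pos}")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt in record {chrom}:{pos} {ref!r}>{alt!r}")
    # trim shared trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases, keeping one anchor base when lengths differ
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise InvalidVariantError(f"ref == alt after trimming in record {chrom}:{pos}")
    return VariantKey(apply_chr_policy(chrom, chr_policy), pos, ref, alt)


# ---------------------------------------------------------------------------
# VariantCall and Thresholds
# ---------------------------------------------------------------------------

PASS = "PASS"

#: consequence terms treated as non-synonymous (Sequence Ontology style)
DEFAULT_CONSEQUENCE_WHITELIST = frozenset({
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "inframe_insertion",
    "inframe_deletion",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "protein_altering_variant",
})

#: per-assay default quality cutoffs; artifact defaults, config-overridable
MODE_DEFAULTS = {
    "TS": {"min_vaf": 0.05, "min_depth": 50},
    "WES": {"min_vaf": 0.05, "min_depth": 20},
}


@dataclass(frozen=True)
class Thresholds:
    """Tunable cutoffs for the three-phase classifier and the gold standard.

    ``germline_maf_cutoff`` is the population MAF at/above which a germline
    database hit counts as germline evidence (inclusive comparison).
    ``normal_af_cutoff`` is the matched-normal AF above which (strict >) a
    variant is gold-standard germline.
    """

    min_vaf: float = 0.05
    min_depth: int = 50
    germline_maf_cutoff: float = 0.01
    normal_af_cutoff: float = 0.05
    consequence_whitelist: frozenset = DEFAULT_CONSEQUENCE_WHITELIST
    mode: str = "TS"

    def __post_init__(self):
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ConfigError(f"min_vaf {self.min_vaf} outside [0, 1]")
        if not (0.0 < self.germline_maf_cutoff < 1.0):
            raise ConfigError(f"germline_maf_cutoff {self.germline_maf_cutoff} outside (0, 1)")
        if not (0.0 < self.normal_af_cutoff < 1.0):
            raise ConfigError(f"normal_af_cutoff {self.normal_af_cutoff} outside (0, 1)")
        if self.min_depth < 0:
            raise ConfigError(f"min_depth {self.min_depth} must be >= 0")
        if not self.consequence_whitelist:
            raise ConfigError("consequence_whitelist must be non-empty")
        if self.mode not in MODE_DEFAULTS:
            raise ConfigError(f"unknown mode {self.mode!r}; expected TS or WES")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "Thresholds":
        """Thresholds with the per-assay defaults for ``mode`` (TS or WES)."""
        if mode not in MODE_DEFAULTS:
            raise ConfigError(f"unknown mode {mode!r}; expected TS or WES")
        kw = dict(MODE_DEFAULTS[mode], mode=mode)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class VariantCall:
    """A single tumor (or normal) variant call.

    ``vaf`` is None when it cannot be determined (zero depth and no explicit
    AF field); such calls never pass phase 1.
    """

    key: VariantKey
    total_depth: int = 0
    alt_depth: int = 0
    vaf: Optional[float] = None
    filter_status: str = PASS
    consequence: str = "missense_variant"
    sample_id: str = ""

    def __post_init__(self):
        if self.total_depth < 0 or self.alt_depth < 0 or self.alt_depth > self.total_depth:
            raise InvalidVariantError(
                f"inconsistent depths at {self.key}: "
                f"alt_depth={self.alt_depth}, total_depth={self.total_depth}")
        if self.vaf is not None and self.total_depth > 0:
            derived = self.alt_depth / self.total_depth
            if abs(self.vaf - derived) > 0.01 + 1e-12:
                logger.warning(
                    "VAF %.4f disagrees with AD-derived %.4f at %s",
                    self.vaf, derived, self.key)


def _resolve_vaf(af_field: Optional[float], alt_depth: Optional[int],
                 total_depth: Optional[int], context: str) -> Optional[float]:
    """Fallback chain: explicit AF field > AD-derived > undefined.

    A discrepancy > 0.01 between the two available sources is logged; the
    explicit field wins.
    """
    derived = None
    if total_depth and total_depth > 0 and alt_depth is not None:
        derived = alt_depth / total_depth
    if af_field is not None:
        if derived is not None and abs(af_field - derived) > 0.01:
            logger.warning("AF field %.4f vs AD-derived %.4f at %s; using AF field",
                           af_field, derived, context)
        return float(af_field)
    return derived


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "total_depth", "alt_depth",
               "vaf", "filter", "consequence"]


def sniff_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".vcf") or name.endswith(".bcf"):
        return "vcf"
    if name.endswith(".tsv") or name.endswith(".txt") or name.endswith(".tab"):
        return "tsv"
    raise FormatError(f"cannot infer format of {path!r}; pass format explicitly")


def read_variants(path, format: Optional[str] = None, sample_id: str = "",
                  chr_policy: str = "as-is") -> list[VariantCall]:
    """Read tumor/normal variant calls from VCF (v4.2) or TSV.

    Multiallelic VCF records are split into one call per alternate allele
    (AD and per-allele AF are taken for that allele; depth is the site DP).
    Every record is normalized; input ordering is preserved. A zero-depth
    record with no AF field is kept with ``vaf=None`` and flagged in the log.
    """
    fmt = format or sniff_format(path)
    if fmt == "vcf":
        return _read_vcf(path, sample_id, chr_policy)
    if fmt == "tsv":
        return _read_tsv(path, sample_id, chr_policy)
    raise FormatError(f"unknown variant format {fmt!r}; expected vcf or tsv")


def _read_vcf(path, sample_id: str, chr_policy: str) -> list[VariantCall]:
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vf:
        samples = list(vf.header.samples)
        if sample_id and sample_id in samples:
            sample = sample_id
        elif samples:
            sample = samples[0]
        else:
            sample = None
        has = {k: k in vf.header.info for k in ("CSQ", "DP", "AF")}
        has_fmt = {k: k in vf.header.formats for k in ("DP", "AD", "AF")}
        for rec in vf:
            if rec.alts is None:
                continue
            filt = list(rec.filter.keys())
            filter_status = PASS if (not filt or filt == ["PASS"]) else ";".join(filt)
            csq = rec.info.get("CSQ", None) if has["CSQ"] else None
            if isinstance(csq, tuple):
                csq = csq[0]
            consequence = str(csq) if csq is not None else "missense_variant"
            fmt = rec.samples[sample] if sample is not None else {}
            dp = fmt.get("DP", None) if sample and has_fmt["DP"] else None
            if dp is None and has["DP"]:
                dp = rec.info.get("DP", None)
            ad = fmt.get("AD", None) if sample and has_fmt["AD"] else None
            af = fmt.get("AF", None) if sample and has_fmt["AF"] else None
            if af is None and has["AF"]:
                af = rec.info.get("AF", None)
            for i, alt in enumerate(rec.alts):
                if alt is None or set(alt.upper()) - _ACGT:
                    logger.warning("skipping symbolic/non-ACGT alt %r at %s:%s",
                                   alt, rec.chrom, rec.pos)
                    continue
                key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, chr_policy)
                alt_depth = None
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_depth = int(ad[i + 1])
                af_i = None
                if af is not None:
                    af_i = af[i] if isinstance(af, tuple) else af
                total = int(dp) if dp is not None else (sum(x for x in ad if x) if ad else 0)
                vaf = _resolve_vaf(af_i, alt_depth, total, f"{rec.chrom}:{rec.pos}")
                if vaf is None:
                    logger.warning("no determinable VAF at %s:%s (zero depth, no AF)",
                                   rec.chrom, rec.pos)
                calls.append(VariantCall(
                    key=key,
                    total_depth=total,
                    alt_depth=alt_depth if alt_depth is not None else 0,
                    vaf=vaf,
                    filter_status=filter_status,
                    consequence=consequence,
                    sample_id=sample_id or (sample or ""),
                ))
    return calls


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv(path, sample_id: str, chr_policy: str) -> list[VariantCall]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise FormatError(f"TSV {path} is missing mandatory columns: {', '.join(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        key = normalize_variant(str(row.chrom), int(row.pos), str(row.ref),
                                str(row.alt), chr_policy)
        total = int(float(getattr(row, "total_depth", 0) or 0))
        altd = int(float(getattr(row, "alt_depth", 0) or 0))
        raw_vaf = getattr(row, "vaf", None)
        af = float(raw_vaf) if raw_vaf not in (None, "", ".") and raw_vaf == raw_vaf else None
        vaf = _resolve_vaf(af, altd, total, f"{row.chrom}:{row.pos}")
        calls.append(VariantCall(
            key=key,
            total_depth=total,
            alt_depth=altd,
            vaf=vaf,
            filter_status=str(getattr(row, "filter", PASS) or PASS),
            consequence=str(getattr(row, "consequence", "missense_variant")),
            sample_id=sample_id,
        ))
    return calls


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _collect_filters(calls: Iterable[VariantCall]) -> set[str]:
    names: set[str] = set()
    for c in calls:
        if c.filter_status != PASS:
            names.update(c.filter_status.split(";"))
    return names


def _vcf_header(contigs: Sequence[tuple[str, int]], sample: str,
                classified: bool = False,
                extra_filters: Iterable[str] = ()) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs:
        h.contigs.add(name, length=length)
    for name in sorted(set(extra_filters) - {"PASS"}):
        h.filters.add(name, None, None, "Caller filter flag")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("DP", 1, "Integer", "Read depth")
    h.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    h.formats.add("AF", "A", "Float", "Variant allele fraction")
    h.info.add("CSQ", 1, "String", "Functional consequence (Sequence Ontology term)")
    if classified:
        h.info.add("TOSCA_LABEL", 1, "String", "Classification: somatic, germline or filtered")
        h.info.add("TOSCA_PHASE", 1, "Integer", "Decision-tree phase that decided the label")
        h.info.add("TOSCA_REASON", ".", "String", "Ordered machine-readable reason codes")
        h.info.add("KG1000_AF", 1, "Float", "1000 Genomes-style population AF")
        h.info.add("ESP_AF", 1, "Float", "ESP-style population AF")
        h.info.add("EXAC_AF", 1, "Float", "ExAC-style population AF")
        h.info.add("DBSNP_AF", 1, "Float", "dbSNP-style population AF")
        h.info.add("DBSNP_COMMON", 0, "Flag", "dbSNP-style common flag")
        h.info.add("DBSNP_PRESENT", 0, "Flag", "Variant present in dbSNP-style source")
        h.info.add("COSMIC_ID", 1, "String", "Somatic catalogue identifier")
        h.info.add("CLINVAR_SIG", ".", "String", "Clinical significance terms")
    h.add_sample(sample or "SAMPLE")
    return h


def _infer_contigs(keys: Iterable[VariantKey]) -> list[tuple[str, int]]:
    ends: dict[str, int] = {}
    for k in keys:
        ends[k.chrom] = max(ends.get(k.chrom, 0), k.pos + len(k.ref) + 1000)
    return sorted(ends.items())


def write_variants(calls: Sequence[VariantCall], path, format: Optional[str] = None) -> None:
    """Write calls as VCF or TSV; the inverse of :func:`read_variants`.

    Output is bit-stable for identical input (fixed float formatting, no
    timestamps).
    """
    fmt = format or sniff_format(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# coordinates: 1-based, VCF convention\n")
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for c in calls:
                vaf = f"{c.vaf:.6f}" if c.vaf is not None else "."
                fh.write("\t".join([
                    c.key.chrom, str(c.key.pos), c.key.ref, c.key.alt,
                    str(c.total_depth), str(c.alt_depth), vaf,
                    c.filter_status, c.consequence]) + "\n")
        return
    if fmt != "vcf":
        raise FormatError(f"unknown variant format {fmt!r}")
    sample = calls[0].sample_id if calls else "SAMPLE"
    header = _vcf_header(_infer_contigs(c.key for c in calls), sample,
                         extra_filters=_collect_filters(calls))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.key.chrom, start=c.key.pos - 1,
                alleles=(c.key.ref, c.key.alt))
            if c.filter_status == PASS:
                rec.filter.add("PASS")
            else:
                for f in c.filter_status.split(";"):
                    rec.filter.add(f)
            rec.info["CSQ"] = c.consequence
            s = rec.samples[sample or "SAMPLE"]
            s["DP"] = c.total_depth
            s["AD"] = (c.total_depth - c.alt_depth, c.alt_depth)
            if c.vaf is not None:
                s["AF"] = (round(c.vaf, 6),)
            s["GT"] = (0, 1)
            out.write(rec)


CLASSIFIED_TSV_COLUMNS = TSV_COLUMNS + [
    "kg1000_af", "esp_af", "exac_af", "dbsnp", "cosmic_id", "clinvar_sig",
    "label", "phase", "reasons"]


def write_classified(results, path, format: Optional[str] = None) -> None:
    """Write (AnnotatedVariant, ClassificationResult) pairs with all retrieved
    database evidence, the final label, the deciding phase, and reasons.

    TSV carries one declared column per field; VCF encodes the label and
    reasons as header-declared INFO fields. Bit-stable for identical input.
    """
    fmt = format or sniff_format(path)
    if fmt == "tsv":
        _write_classified_tsv(results, path)
    elif fmt == "vcf":
        _write_classified_vcf(results, path)
    else:
        raise FormatError(f"unknown output format {fmt!r}")


def _fmt_af(af) -> str:
    return f"{af:.6f}" if af is not None else "."


def _dbsnp_cell(rec) -> str:
    if rec is None:
        return "."
    if rec.af is not None:
        return f"{rec.af:.6f}"
    return "common" if rec.common_flag else "present"


def _write_classified_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, VCF convention\n")
        fh.write("\t".join(CLASSIFIED_TSV_COLUMNS) + "\n")
        for av, res in results:
            c = av.call
            ev = av.evidence
            pop = ev.population_hits
            vaf = f"{c.vaf:.6f}" if c.vaf is not None else "."
            row = [
                c.key.chrom, str(c.key.pos), c.key.ref, c.key.alt,
                str(c.total_depth), str(c.alt_depth), vaf,
                c.filter_status, c.consequence,
                _fmt_af(pop["KG1000"].af if "KG1000" in pop else None),
                _fmt_af(pop["ESP"].af if "ESP" in pop else None),
                _fmt_af(pop["EXAC"].af if "EXAC" in pop else None),
                _dbsnp_cell(pop.get("DBSNP")),
                ev.somatic_hit.catalogue_id if ev.somatic_hit else ".",
                ",".join(sorted(ev.clinical_hit.significance)) if ev.clinical_hit else ".",
                res.label, str(res.phase), ",".join(res.reasons),
            ]
            fh.write("\t".join(row) + "\n")


def _write_classified_vcf(results, path) -> None:
    calls = [av.call for av, _ in results]
    sample = calls[0].sample_id if calls else "SAMPLE"
    header = _vcf_header(_infer_contigs(c.key for c in calls), sample, classified=True,
                         extra_filters=_collect_filters(calls))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for av, res in results:
            c, ev = av.call, av.evidence
            rec = out.new_record(contig=c.key.chrom, start=c.key.pos - 1,
                                 alleles=(c.key.ref, c.key.alt))
            if c.filter_status == PASS:
                rec.filter.add("PASS")
            else:
                for f in c.filter_status.split(";"):
                    rec.filter.add(f)
            rec.info["CSQ"] = c.consequence
            rec.info["TOSCA_LABEL"] = res.label
            rec.info["TOSCA_PHASE"] = res.phase
            rec.info["TOSCA_REASON"] = ",".join(res.reasons)
            for name, info_key in (("KG1000", "KG1000_AF"), ("ESP", "ESP_AF"),
                                   ("EXAC", "EXAC_AF")):
                hit = ev.population_hits.get(name)
                if hit is not None and hit.af is not None:
                    rec.info[info_key] = round(hit.af, 6)
            dbsnp = ev.population_hits.get("DBSNP")
            if dbsnp is not None:
                rec.info["DBSNP_PRESENT"] = True
                if dbsnp.af is not None:
                    rec.info["DBSNP_AF"] = round(dbsnp.af, 6)
                if dbsnp.common_flag:
                    rec.info["DBSNP_COMMON"] = True
            if ev.somatic_hit is not None:
                rec.info["COSMIC_ID"] = ev.somatic_hit.catalogue_id
            if ev.clinical_hit is not None:
                rec.info["CLINVAR_SIG"] = ",".join(sorted(ev.clinical_hit.significance))
            s = rec.samples[sample or "SAMPLE"]
            s["DP"] = c.total_depth
            s["AD"] = (c.total_depth - c.alt_depth, c.alt_depth)
            if c.vaf is not None:
                s["AF"] = (round(c.vaf, 6),)
            s["GT"] = (0, 1)
            out.write(rec)


def read_classified_tsv(path):
    """Read back a classified TSV as a list of (VariantKey, label, phase, reasons)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        out.append((key, row.label, int(row.phase), tuple(str(row.reasons).split(","))))
    return out
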