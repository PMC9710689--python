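"""Run configuration, input validation, and the end-to-end synthetic bench.

A run is declared in a YAML file: assay mode, threshold overrides, the
behavioral switches, and one entry per database (path, kind, name, priority,
AF key, format). ``check_inputs`` validates the declaration before any work
is done; ``run_bench`` wires simulate → classify → paired gold standard →
evaluate, mirroring the paired-normal validation design at synthetic scale.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .databases import DatabaseSet, Switches, load_database
from .variants import CHR_POLICIES, ConfigError, MODE_DEFAULTS, Thresholds

logger = logging.getLogger("toscalite")

_TOP_KEYS = {"mode", "thresholds", "switches", "databases", "output_prefix",
             "log_level"}
_THRESHOLD_KEYS = {"min_vaf", "min_depth", "germline_maf_cutoff",
                   "normal_af_cutoff", "consequence_whitelist"}
_SWITCH_KEYS = {"maf_folding", "dbsnp_presence_is_germline",
                "clinvar_overrides_cosmic", "chr_policy"}
_DB_KEYS = {"name", "kind", "path", "priority", "af_key", "format"}


@dataclass
class DatabaseDecl:
    name: str
    kind: str
    path: str
    priority: int | None = None
    af_key: str = "AF"
    format: str | None = None


@dataclass
class RunConfig:
    """Parsed run declaration; see the package README for the file format."""

    mode: str = "TS"
    thresholds: Thresholds = field(default_factory=lambda: Thresholds.for_mode("TS"))
    switches: Switches = field(default_factory=Switches)
    databases: list = field(default_factory=list)  # list[DatabaseDecl]
    output_prefix: str = "toscalite"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config {path} is not valid YAML: {exc}") from exc
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        mode = raw.get("mode", "TS")
        if mode not in MODE_DEFAULTS:
            raise ConfigError(f"unknown mode {mode!r}; expected TS or WES")
        t_raw = dict(raw.get("thresholds") or {})
        unknown = set(t_raw) - _THRESHOLD_KEYS
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        if "consequence_whitelist" in t_raw:
            t_raw["consequence_whitelist"] = frozenset(t_raw["consequence_whitelist"])
        thresholds = Thresholds.for_mode(mode, **t_raw)
        s_raw = dict(raw.get("switches") or {})
        unknown = set(s_raw) - _SWITCH_KEYS
        if unknown:
            raise ConfigError(f"unknown switch keys: {sorted(unknown)}")
        switches = Switches(**s_raw)
        if switches.chr_policy not in CHR_POLICIES:
            raise ConfigError(f"unknown chr_policy {switches.chr_policy!r}")
        decls = []
        for entry in raw.get("databases") or []:
            unknown = set(entry) - _DB_KEYS
            if unknown:
                raise ConfigError(f"unknown database keys: {sorted(unknown)}")
            for req in ("name", "kind", "path"):
                if req not in entry:
                    raise ConfigError(f"database entry missing {req!r}: {entry}")
            path = entry["path"]
            if base_dir is not None and not Path(path).is_absolute():
                path = str(Path(base_dir) / path)
            decls.append(DatabaseDecl(
                name=str(entry["name"]), kind=str(entry["kind"]), path=path,
                priority=entry.get("priority"), af_key=entry.get("af_key", "AF"),
                format=entry.get("format")))
        return cls(mode=mode, thresholds=thresholds, switches=switches,
                   databases=decls,
                   output_prefix=str(raw.get("output_prefix", "toscalite")),
                   log_level=str(raw.get("log_level", "INFO")))

    def load_databases(self) -> DatabaseSet:
        population = {}
        somatic = None
        clinical = None
        dbs = DatabaseSet(switches=self.switches)
        for decl in self.databases:
            db = load_database(decl.path, kind=decl.kind, name=decl.name,
                               format=decl.format, af_key=decl.af_key,
                               priority=decl.priority,
                               chr_policy=self.switches.chr_policy)
            if decl.kind == "population":
                population[decl.name] = db
            elif decl.kind == "somatic":
                somatic = db
            elif decl.kind == "clinical":
                clinical = db
        dbs.population = population
        if somatic is not None:
            dbs.somatic = somatic
        if clinical is not None:
            dbs.clinical = clinical
        dbs.__post_init__()  # re-check priority uniqueness
        return dbs


@dataclass
class ValidationReport:
    ok: bool
    findings: list

    def __str__(self) -> str:
        if self.ok:
            return "check passed: all inputs and parameters valid"
        return "check failed:\n" + "\n".join(f"  - {f}" for f in self.findings)


def check_inputs(config: RunConfig) -> ValidationReport:
    """Validate a run declaration: file existence, format sniffing,
    threshold ranges, priority uniqueness. Returns itemized findings."""
    from .variants import FormatError, sniff_format

    findings = []
    for decl in config.databases:
        if not Path(decl.path).exists():
            findings.append(f"database {decl.name}: file not found: {decl.path}")
            continue
        if decl.format is None:
            try:
                sniff_format(decl.path)
            except FormatError as exc:
                findings.append(f"database {decl.name}: {exc}")
        if decl.kind not in ("population", "somatic", "clinical"):
            findings.append(f"database {decl.name}: unknown kind {decl.kind!r}")
    prios = [d.priority for d in config.databases
             if d.kind == "population" and d.priority is not None]
    if len(prios) != len(set(prios)):
        findings.append("population database priorities are not unique")
    # Thresholds ranges are enforced at construction; re-assert for clarity
    t = config.thresholds
    if not (0.0 <= t.min_vaf <= 1.0):
        findings.append(f"min_vaf {t.min_vaf} outside [0, 1]")
    if t.min_depth < 0:
        findings.append(f"min_depth {t.min_depth} negative")
    return ValidationReport(ok=not findings, findings=findings)


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable run manifest: thresholds, switches, DB checksums."""
    t = config.thresholds
    manifest = {
        "mode": config.mode,
        "thresholds": {
            "min_vaf": t.min_vaf, "min_depth": t.min_depth,
            "germline_maf_cutoff": t.germline_maf_cutoff,
            "normal_af_cutoff": t.normal_af_cutoff,
            "consequence_whitelist": sorted(t.consequence_whitelist),
        },
        "switches": {
            "maf_folding": config.switches.maf_folding,
            "dbsnp_presence_is_germline": config.switches.dbsnp_presence_is_germline,
            "clinvar_overrides_cosmic": config.switches.clinvar_overrides_cosmic,
            "chr_policy": config.switches.chr_policy,
        },
        "databases": [],
    }
    for decl in config.databases:
        entry = {"name": decl.name, "kind": decl.kind, "path": decl.path}
        p = Path(decl.path)
        if p.exists():
            entry["sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["databases"].append(entry)
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def run_bench(params, thresholds: Thresholds | None = None,
              switches: Switches | None = None, out_dir=None,
              from_files: bool = False):
    """Simulate a cohort, classify it tumor-only, build the paired gold
    standard, and score the classification.

    With ``from_files=True`` (requires ``out_dir``) the simulated files are
    round-tripped through the VCF/TSV readers before classification, so the
    bench exercises the full I/O path. Returns (EvalReport, SimulatedCohort,
    results).
    """
    from .classifier import FILTERED, classify_cohort
    from .evaluation import build_gold_standard, evaluate
    from .simulate import simulate

    t = thresholds or Thresholds.for_mode("TS")
    cohort = simulate(params, out_dir=out_dir)
    if switches is not None:
        cohort.databases.switches = switches
    tumor_calls = cohort.tumor_calls
    normal_calls = cohort.normal_calls
    dbs = cohort.databases
    if from_files:
        if out_dir is None:
            raise ConfigError("from_files requires out_dir")
        from .variants import read_variants

        tumor_calls = read_variants(cohort.paths["tumor"], format="vcf",
                                    sample_id="TUMOR")
        normal_calls = read_variants(cohort.paths["normal"], format="vcf",
                                     sample_id="NORMAL")
        population = {}
        for name in ("KG1000", "ESP", "EXAC", "DBSNP"):
            population[name] = load_database(cohort.paths[name], kind="population",
                                             name=name, format="tsv",
                                             chr_policy="as-is")
        somatic = load_database(cohort.paths["COSMIC"], kind="somatic",
                                format="tsv", chr_policy="as-is")
        clinical = load_database(cohort.paths["CLINVAR"], kind="clinical",
                                 format="tsv", chr_policy="as-is")
        dbs = DatabaseSet(population=population, somatic=somatic,
                          clinical=clinical,
                          switches=switches or cohort.databases.switches)
    results = classify_cohort(tumor_calls, dbs, t)
    truth = build_gold_standard(tumor_calls, normal_calls, t)
    predicted = [(call.key, res.label)
                 for call, res in zip(tumor_calls, results)
                 if res.label != FILTERED]
    report = evaluate(predicted, truth)
    return report, cohort, results
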