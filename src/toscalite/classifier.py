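"""Three-phase tumor-only somatic/germline decision tree.

Phase 1 removes calls that fail quality gates (caller filter, depth, VAF)
or are not of a non-synonymous consequence class. Phase 2 consults the
evidence databases: a somatic-catalogue hit labels the variant somatic even
when germline-frequency evidence coexists; otherwise presence in any of the
four germline population sources at a minor allele frequency at or above the
cutoff (default 1%) labels it germline. Phase 3 labels the remaining
undecided variants germline when a benign/likely-benign clinical assertion
exists, and somatic otherwise — every variant that survives phase 1 receives
a somatic or germline label, with no unknown bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .databases import (AnnotatedVariant, DatabaseSet, EvidenceBundle,
                        annotate)
from .variants import PASS, Thresholds, VariantCall

logger = logging.getLogger("toscalite")

SOMATIC = "somatic"
GERMLINE = "germline"
FILTERED = "filtered"
UNDECIDED = "undecided"

# reason codes (first reason in a result is the deciding one)
FAIL_QUAL = "FAIL_QUAL"
FAIL_DEPTH = "FAIL_DEPTH"
FAIL_VAF = "FAIL_VAF"
SYNONYMOUS = "SYNONYMOUS"
COSMIC = "COSMIC"
COSMIC_OVERRIDE = "COSMIC_OVERRIDE"
CLINVAR_BENIGN = "CLINVAR_BENIGN"
NO_EVIDENCE_DEFAULT_SOMATIC = "NO_EVIDENCE_DEFAULT_SOMATIC"


def germline_db_reason(name: str) -> str:
    return f"GERMLINE_DB:{name}"


@dataclass(frozen=True)
class ClassificationResult:
    """Final label, the phase that decided it, and the reason trace."""

    label: str
    phase: int
    reasons: tuple

    def __post_init__(self):
        if (self.label == FILTERED) != (self.phase == 1):
            raise ValueError("label 'filtered' if and only if phase 1 decided")
        if not self.reasons:
            raise ValueError("reasons must be non-empty")


# ---------------------------------------------------------------------------
# Phase 1: quality / variant-type gate
# ---------------------------------------------------------------------------

def phase1_quality(call: VariantCall, t: Thresholds) -> tuple[bool, tuple]:
    """Return (passed, failing_reasons); all failing gates are reported."""
    reasons = []
    if call.filter_status != PASS:
        reasons.append(FAIL_QUAL)
    if call.total_depth < t.min_depth:
        reasons.append(FAIL_DEPTH)
    if call.vaf is None or call.vaf < t.min_vaf:
        reasons.append(FAIL_VAF)
    if call.consequence not in t.consequence_whitelist:
        reasons.append(SYNONYMOUS)
    return (not reasons, tuple(reasons))


# ---------------------------------------------------------------------------
# Phase 2: germline population databases + somatic catalogue
# ---------------------------------------------------------------------------

def _effective_af(af: float, dbs: DatabaseSet) -> float:
    """Raw alternate AF, or folded to the minor allele when configured."""
    return min(af, 1.0 - af) if dbs.switches.maf_folding else af


def _qualifying_germline_dbs(ev: EvidenceBundle, t: Thresholds,
                             dbs: DatabaseSet) -> list[str]:
    """Names of population databases whose hit counts as germline evidence,
    in priority order (highest first).

    An AF-bearing hit qualifies when its (optionally folded) AF is at or
    above ``germline_maf_cutoff`` (inclusive). An AF-less dbSNP-style hit
    qualifies only when flagged common or when the
    ``dbsnp_presence_is_germline`` switch is on; otherwise it is recorded
    but non-deciding.
    """
    qualifying = []
    for name in dbs.priority_order():
        rec = ev.population_hits.get(name)
        if rec is None:
            continue
        if rec.af is not None:
            if _effective_af(rec.af, dbs) >= t.germline_maf_cutoff:
                qualifying.append(name)
        elif rec.common_flag or dbs.switches.dbsnp_presence_is_germline:
            qualifying.append(name)
    return qualifying


def phase2_database(ev: EvidenceBundle, t: Thresholds,
                    dbs: DatabaseSet) -> tuple[str, tuple]:
    """Return (somatic | germline | undecided, reasons)."""
    germline_dbs = _qualifying_germline_dbs(ev, t, dbs)
    if ev.somatic_hit is not None:
        reason = COSMIC_OVERRIDE if germline_dbs else COSMIC
        return SOMATIC, (reason,)
    if germline_dbs:
        return GERMLINE, tuple(germline_db_reason(n) for n in germline_dbs)
    return UNDECIDED, ()


# ---------------------------------------------------------------------------
# Phase 3: clinical significance and the somatic default
# ---------------------------------------------------------------------------

def phase3_clinical(ev: EvidenceBundle, current: str,
                    dbs: DatabaseSet) -> tuple[str, tuple]:
    """Refine a somatic-by-catalogue or undecided call into its final label."""
    benign = ev.clinical_hit is not None and ev.clinical_hit.is_benign
    if current == SOMATIC:
        if benign and dbs.switches.clinvar_overrides_cosmic:
            return GERMLINE, (CLINVAR_BENIGN,)
        return SOMATIC, ()
    if current != UNDECIDED:
        raise ValueError(f"phase 3 expects somatic or undecided, got {current!r}")
    if benign:
        return GERMLINE, (CLINVAR_BENIGN,)
    return SOMATIC, (NO_EVIDENCE_DEFAULT_SOMATIC,)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def classify(call: VariantCall, ev: EvidenceBundle, t: Thresholds,
             dbs: DatabaseSet) -> ClassificationResult:
    """Run the three phases on one annotated call.

    Deterministic and total: every phase-1-passing variant receives a
    somatic or germline label; the reason trace records the full path, with
    the deciding reason first.
    """
    passed, fail_reasons = phase1_quality(call, t)
    if not passed:
        return ClassificationResult(label=FILTERED, phase=1, reasons=fail_reasons)
    label2, reasons2 = phase2_database(ev, t, dbs)
    if label2 == GERMLINE:
        return ClassificationResult(label=GERMLINE, phase=2, reasons=reasons2)
    label3, reasons3 = phase3_clinical(ev, label2, dbs)
    if label2 == SOMATIC and label3 == SOMATIC:
        # decided by the catalogue in phase 2; phase 3 changed nothing
        return ClassificationResult(label=SOMATIC, phase=2, reasons=reasons2)
    return ClassificationResult(label=label3, phase=3, reasons=reasons3 + reasons2)


def classify_cohort(calls: Sequence[VariantCall], dbs: DatabaseSet,
                    t: Thresholds) -> list[ClassificationResult]:
    """Annotate then classify element-wise; order preserved, counts logged."""
    annotated = annotate(calls, dbs)
    results = [classify(av.call, av.evidence, t, dbs) for av in annotated]
    counts = {FILTERED: 0, SOMATIC: 0, GERMLINE: 0}
    for r in results:
        counts[r.label] += 1
    logger.info("classified %d variants: %d filtered (phase 1), %d somatic, %d germline",
                len(results), counts[FILTERED], counts[SOMATIC], counts[GERMLINE])
    return results


def classify_annotated(annotated: Sequence[AnnotatedVariant], dbs: DatabaseSet,
                       t: Thresholds) -> list[tuple[AnnotatedVariant, ClassificationResult]]:
    """Like :func:`classify_cohort` but keeps the evidence alongside, for
    report writing."""
    return [(av, classify(av.call, av.evidence, t, dbs)) for av in annotated]
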