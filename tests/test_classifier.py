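"""Three-phase decision tree behavior, including the independent-oracle check."""

import itertools

import numpy as np
import pytest

from conftest import make_call, make_dbs
from oracles import reference_classify
from toscalite.classifier import (CLINVAR_BENIGN, COSMIC, COSMIC_OVERRIDE,
                                  FAIL_DEPTH, FAIL_QUAL, FAIL_VAF, FILTERED,
                                  GERMLINE, NO_EVIDENCE_DEFAULT_SOMATIC,
                                  SOMATIC, SYNONYMOUS, UNDECIDED, classify,
                                  classify_cohort, phase1_quality,
                                  phase2_database, phase3_clinical)
from toscalite.databases import Switches, lookup
from toscalite.simulate import SimulationParams, simulate
from toscalite.variants import Thresholds, VariantKey

KEY = VariantKey("1", 100, "A", "G")


# ---------------------------------------------------------------------------
# Phase 1
# ---------------------------------------------------------------------------

def test_phase1_passes_clean_call(thresholds):
    ok, reasons = phase1_quality(make_call(depth=100, alt=30), thresholds)
    assert ok and reasons == ()


def test_phase1_synonymous_fails(thresholds):
    ok, reasons = phase1_quality(
        make_call(depth=100, alt=30, consequence="synonymous_variant"), thresholds)
    assert not ok and reasons == (SYNONYMOUS,)


def test_phase1_reports_all_failing_gates(thresholds):
    ok, reasons = phase1_quality(
        make_call(depth=5, alt=0, vaf=0.02, filt="q10"), thresholds)
    assert not ok
    assert set(reasons) == {FAIL_QUAL, FAIL_DEPTH, FAIL_VAF}


def test_phase1_undefined_vaf_fails(thresholds):
    ok, reasons = phase1_quality(make_call(depth=100, alt=0, vaf=None), thresholds)
    # depth=0 construction path: explicit None vaf must not pass the VAF gate
    call = make_call(depth=0, alt=0, vaf=None)
    ok0, reasons0 = phase1_quality(call, thresholds)
    assert not ok0 and FAIL_VAF in reasons0 and FAIL_DEPTH in reasons0


# ---------------------------------------------------------------------------
# Phase 2
# ---------------------------------------------------------------------------

def test_catalogue_hit_overrides_germline_frequency(thresholds):
    dbs = make_dbs(pop_afs={"EXAC": 0.015}, cosmic=True, key=KEY)
    label, reasons = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == SOMATIC and reasons == (COSMIC_OVERRIDE,)


def test_catalogue_hit_alone_is_plain_cosmic(thresholds):
    dbs = make_dbs(cosmic=True, key=KEY)
    label, reasons = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == SOMATIC and reasons == (COSMIC,)


@pytest.mark.parametrize("af, expected", [
    (0.009, UNDECIDED), (0.0099999, UNDECIDED),
    (0.01, GERMLINE),   # inclusive cutoff
    (0.02, GERMLINE), (0.5, GERMLINE),
])
def test_frequency_cutoff_straddle(thresholds, af, expected):
    # oracle: direct threshold comparison over a grid straddling 1%
    dbs = make_dbs(pop_afs={"ESP": af}, key=KEY)
    label, _ = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == expected


def test_no_hits_is_undecided(thresholds):
    dbs = make_dbs(key=KEY)
    label, reasons = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == UNDECIDED and reasons == ()


def test_germline_reason_names_highest_priority_db(thresholds):
    dbs = make_dbs(pop_afs={"KG1000": 0.02, "EXAC": 0.03, "ESP": 0.04}, key=KEY)
    label, reasons = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == GERMLINE
    assert reasons[0] == "GERMLINE_DB:EXAC"  # ExAC outranks KG1000 and ESP


@pytest.mark.parametrize("state, switch, expected", [
    ("common", False, GERMLINE),    # common flag always decides
    ("present", False, UNDECIDED),  # bare presence is non-deciding by default
    ("present", True, GERMLINE),    # unless the gating switch is on
])
def test_dbsnp_presence_gating(thresholds, state, switch, expected):
    dbs = make_dbs(dbsnp=state, key=KEY,
                   switches=Switches(dbsnp_presence_is_germline=switch))
    label, _ = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == expected


def test_maf_folding_switch(thresholds):
    # AF 0.995 is a minor-allele frequency of 0.005: below the 1% cutoff
    # when folding is on, germline evidence when folding is off
    dbs = make_dbs(pop_afs={"EXAC": 0.995}, key=KEY)
    label, _ = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == GERMLINE
    dbs = make_dbs(pop_afs={"EXAC": 0.995}, key=KEY,
                   switches=Switches(maf_folding=True))
    label, _ = phase2_database(lookup(KEY, dbs), thresholds, dbs)
    assert label == UNDECIDED


# ---------------------------------------------------------------------------
# Phase 3
# ---------------------------------------------------------------------------

def test_benign_clinical_rescues_undecided(thresholds):
    dbs = make_dbs(clinvar={"benign"}, key=KEY)
    label, reasons = phase3_clinical(lookup(KEY, dbs), UNDECIDED, dbs)
    assert label == GERMLINE and reasons == (CLINVAR_BENIGN,)


def test_pathogenic_clinical_does_not_rescue(thresholds):
    dbs = make_dbs(clinvar={"pathogenic"}, key=KEY)
    label, reasons = phase3_clinical(lookup(KEY, dbs), UNDECIDED, dbs)
    assert label == SOMATIC and reasons == (NO_EVIDENCE_DEFAULT_SOMATIC,)


def test_no_clinical_hit_defaults_somatic(thresholds):
    dbs = make_dbs(key=KEY)
    label, reasons = phase3_clinical(lookup(KEY, dbs), UNDECIDED, dbs)
    assert label == SOMATIC and reasons == (NO_EVIDENCE_DEFAULT_SOMATIC,)


def test_catalogue_somatic_survives_benign_by_default(thresholds):
    dbs = make_dbs(cosmic=True, clinvar={"benign"}, key=KEY)
    res = classify(make_call(key=KEY), lookup(KEY, dbs), thresholds, dbs)
    assert res.label == SOMATIC and res.phase == 2
    flipped = make_dbs(cosmic=True, clinvar={"benign"}, key=KEY,
                       switches=Switches(clinvar_overrides_cosmic=True))
    res = classify(make_call(key=KEY), lookup(KEY, flipped), thresholds, flipped)
    assert res.label == GERMLINE and res.phase == 3
    assert res.reasons[0] == CLINVAR_BENIGN


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def test_filtered_at_phase1(thresholds):
    dbs = make_dbs(key=KEY)
    res = classify(make_call(key=KEY, consequence="synonymous_variant"),
                   lookup(KEY, dbs), thresholds, dbs)
    assert res.label == FILTERED and res.phase == 1


def test_phase2_germline_is_final(thresholds):
    # a benign record never gets consulted when frequency already decided
    dbs = make_dbs(pop_afs={"EXAC": 0.30}, clinvar={"benign"}, key=KEY)
    res = classify(make_call(key=KEY), lookup(KEY, dbs), thresholds, dbs)
    assert res.label == GERMLINE and res.phase == 2
    assert res.reasons[0] == "GERMLINE_DB:EXAC"


def test_dbsnp_presence_only_defaults_somatic(thresholds):
    dbs = make_dbs(dbsnp="present", key=KEY)
    res = classify(make_call(key=KEY), lookup(KEY, dbs), thresholds, dbs)
    assert res.label == SOMATIC and res.phase == 3
    assert res.reasons[0] == NO_EVIDENCE_DEFAULT_SOMATIC


def _truth_table_states():
    """Evidence states: consequence class x per-DB AF grid x dbSNP states x
    catalogue x clinical, a superset of the rules' decision space."""
    afs = [None, 0.005, 0.01, 0.02]
    dbsnp_states = [None, "common", "present", 0.02]
    clinvars = [None, {"benign"}, {"likely_benign"}, {"pathogenic"},
                {"benign", "pathogenic"}]
    for conseq_ok, kg, esp, exac, dbsnp, cosmic, clin in itertools.product(
            [True, False], afs, afs, afs, dbsnp_states, [False, True], clinvars):
        yield conseq_ok, kg, esp, exac, dbsnp, cosmic, clin


@pytest.mark.parametrize("maf_folding", [False, True])
@pytest.mark.parametrize("dbsnp_gate", [False, True])
@pytest.mark.parametrize("clinvar_over", [False, True])
def test_classify_matches_independent_oracle(thresholds, maf_folding,
                                             dbsnp_gate, clinvar_over):
    """Full evidence truth table against a straight-line re-implementation."""
    switches = Switches(maf_folding=maf_folding,
                        dbsnp_presence_is_germline=dbsnp_gate,
                        clinvar_overrides_cosmic=clinvar_over)
    n_checked = 0
    for conseq_ok, kg, esp, exac, dbsnp, cosmic, clin in _truth_table_states():
        pop_afs = {n: a for n, a in
                   (("KG1000", kg), ("ESP", esp), ("EXAC", exac)) if a is not None}
        dbs = make_dbs(pop_afs=pop_afs, dbsnp=dbsnp, cosmic=cosmic,
                       clinvar=clin, key=KEY, switches=switches)
        call = make_call(key=KEY, consequence=(
            "missense_variant" if conseq_ok else "synonymous_variant"))
        got = classify(call, lookup(KEY, dbs), thresholds, dbs)
        want_label, want_phase = reference_classify(
            True, call.total_depth, call.vaf, conseq_ok, pop_afs, dbsnp,
            cosmic, clin, thresholds.min_depth, thresholds.min_vaf,
            thresholds.germline_maf_cutoff, maf_folding=maf_folding,
            dbsnp_presence_is_germline=dbsnp_gate,
            clinvar_overrides_cosmic=clinvar_over)
        assert (got.label, got.phase) == (want_label, want_phase), (
            conseq_ok, pop_afs, dbsnp, cosmic, clin)
        n_checked += 1
    assert n_checked == 2 * 4 ** 3 * 4 * 2 * 5


def test_cohort_classification_is_order_independent(thresholds):
    cohort = simulate(SimulationParams(n_variants=300, seed=5))
    calls = cohort.tumor_calls
    res_fwd = classify_cohort(calls, cohort.databases, thresholds)
    rev = list(reversed(calls))
    res_rev = classify_cohort(rev, cohort.databases, thresholds)
    assert res_fwd == list(reversed(res_rev))


def test_monotonicity_in_germline_cutoff(thresholds):
    """Raising the frequency cutoff can only shrink the germline set."""
    cohort = simulate(SimulationParams(n_variants=1000, seed=9))
    prev = None
    for cutoff in (0.005, 0.01, 0.02, 0.05):
        t = Thresholds.for_mode("TS", germline_maf_cutoff=cutoff)
        res = classify_cohort(cohort.tumor_calls, cohort.databases, t)
        germ = {c.key for c, r in zip(cohort.tumor_calls, res)
                if r.label == GERMLINE}
        if prev is not None:
            assert germ <= prev
        prev = germ


def test_catalogue_dominance_differential(thresholds):
    """Adding a somatic-catalogue hit never yields a germline label."""
    from toscalite.databases import SomaticRecord

    cohort = simulate(SimulationParams(n_variants=500, seed=13))
    dbs = cohort.databases
    base = classify_cohort(cohort.tumor_calls, dbs, thresholds)
    for c in cohort.tumor_calls:
        dbs.somatic.records[c.key] = SomaticRecord(catalogue_id="FORCED")
    forced = classify_cohort(cohort.tumor_calls, dbs, thresholds)
    for b, f in zip(base, forced):
        assert f.label != GERMLINE
        if b.label == FILTERED:
            assert f.label == FILTERED  # phase 1 untouched by evidence
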