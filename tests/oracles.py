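"""Independent straight-line reference implementations used as test oracles.

These deliberately avoid importing the package's classifier internals: the
decision rules are re-coded from first principles (quality gate, population
frequency rule with catalogue override, benign clinical rescue, somatic
default) so agreement with the package is an actual cross-check.
"""

BENIGN = {"benign", "likely_benign"}
PATHOGENIC = {"pathogenic", "likely_pathogenic"}


def reference_classify(filter_is_pass, depth, vaf, consequence_ok,
                       pop_afs, dbsnp_state, cosmic, clinvar_terms,
                       min_depth, min_vaf, cutoff,
                       maf_folding=False, dbsnp_presence_is_germline=False,
                       clinvar_overrides_cosmic=False):
    """Return (label, phase) for one evidence state.

    pop_afs: dict of AF-bearing database name -> AF (absent = no hit).
    dbsnp_state: None | 'common' | 'present' | float AF.
    clinvar_terms: set of significance terms or None.
    """
    # quality / variant-type gate
    if (not filter_is_pass or depth < min_depth or vaf is None
            or vaf < min_vaf or not consequence_ok):
        return "filtered", 1

    def af_qualifies(af):
        eff = min(af, 1.0 - af) if maf_folding else af
        return eff >= cutoff

    germline_evidence = any(af_qualifies(af) for af in pop_afs.values())
    if dbsnp_state == "common":
        germline_evidence = True
    elif dbsnp_state == "present" and dbsnp_presence_is_germline:
        germline_evidence = True
    elif isinstance(dbsnp_state, float) and af_qualifies(dbsnp_state):
        germline_evidence = True

    benign = (clinvar_terms is not None
              and bool(set(clinvar_terms) & BENIGN)
              and not (set(clinvar_terms) & PATHOGENIC)
              and "conflicting" not in clinvar_terms)

    if cosmic:
        if clinvar_overrides_cosmic and benign:
            return "germline", 3
        return "somatic", 2
    if germline_evidence:
        return "germline", 2
    if benign:
        return "germline", 3
    return "somatic", 3


def is_parsimonious(ref, alt):
    """A spelling is parsimonious iff no shared trailing base and no shared
    leading base removable while both alleles stay non-empty-with-anchor."""
    if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        return False
    if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        return False
    return True


def spellings_of(pos, ref, alt, context="TTGCA"):
    """Alternate reference-free spellings of the same genomic change:
    shared suffixes appended, shared prefixes prepended (pos shifted back)."""
    out = []
    for pre_len in range(0, 3):
        for suf_len in range(0, 3):
            pre = context[:pre_len]
            suf = context[-suf_len:] if suf_len else ""
            out.append((pos - pre_len, pre + ref + suf, pre + alt + suf))
    return out


def brute_force_confusion(predicted, truth_labels):
    """Per-key tally of the somatic-positive confusion matrix."""
    tp = fn = tn = fp = unmatched = 0
    for key, label in predicted.items():
        if key not in truth_labels:
            unmatched += 1
        elif truth_labels[key] == "somatic" and label == "somatic":
            tp += 1
        elif truth_labels[key] == "somatic":
            fn += 1
        elif label == "germline":
            tn += 1
        else:
            fp += 1
    return tp, fn, tn, fp, unmatched
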