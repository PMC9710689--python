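"""Paired-normal gold standard and sensitivity/specificity scoring.

The gold standard treats the matched normal as truth: a tumor variant also
seen in the normal at an allele fraction strictly above the cutoff (default
5%) is germline; every other tumor variant — absent from the normal, or
matched at or below the cutoff — is somatic. Matching is by normalized
variant key only, not genotype. Somatic is the positive class: sensitivity
is the fraction of truth-somatic variants called somatic, specificity the
fraction of truth-germline variants called germline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .variants import Thresholds, ToscaError, VariantCall, VariantKey

logger = logging.getLogger("toscalite")

SOMATIC = "somatic"
GERMLINE = "germline"


@dataclass
class TruthSet:
    """Per-variant gold-standard labels derived from a matched normal."""

    labels: dict = field(default_factory=dict)  # VariantKey -> somatic|germline
    source_sample: tuple = ("", "")             # (tumor_id, normal_id)


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix with somatic as the positive class.

    ``sensitivity``/``specificity`` are None when their denominator class is
    absent from the evaluated truth.
    """

    tp_somatic: int
    fn_somatic: int
    tn_germline: int
    fp_germline: int
    n_evaluated: int
    n_unmatched: int

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp_somatic + self.fn_somatic
        return self.tp_somatic / denom if denom else None

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tn_germline + self.fp_germline
        return self.tn_germline / denom if denom else None

    def to_tsv(self) -> str:
        def fmt(x):
            return f"{x:.6f}" if x is not None else "NA"

        lines = ["metric\tvalue",
                 f"tp_somatic\t{self.tp_somatic}",
                 f"fn_somatic\t{self.fn_somatic}",
                 f"tn_germline\t{self.tn_germline}",
                 f"fp_germline\t{self.fp_germline}",
                 f"n_evaluated\t{self.n_evaluated}",
                 f"n_unmatched\t{self.n_unmatched}",
                 f"sensitivity\t{fmt(self.sensitivity)}",
                 f"specificity\t{fmt(self.specificity)}"]
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        def pct(x):
            return f"{100 * x:.1f}%" if x is not None else "undefined"

        return (f"evaluated {self.n_evaluated} variants ({self.n_unmatched} unmatched): "
                f"sensitivity {pct(self.sensitivity)} "
                f"({self.tp_somatic}/{self.tp_somatic + self.fn_somatic} somatic), "
                f"specificity {pct(self.specificity)} "
                f"({self.tn_germline}/{self.tn_germline + self.fp_germline} germline)")


def build_gold_standard(tumor_calls: Sequence[VariantCall],
                        normal_calls: Sequence[VariantCall],
                        t: Thresholds) -> TruthSet:
    """Label each tumor variant from its matched normal.

    Germline iff a normal call with the same normalized key has
    VAF > ``t.normal_af_cutoff`` (strict); somatic otherwise (no normal
    match, or matched at or below the cutoff). Normal-only variants are
    ignored. Tumor duplicates keep the first occurrence.
    """
    normal_vaf: dict[VariantKey, float] = {}
    for c in normal_calls:
        v = c.vaf if c.vaf is not None else 0.0
        prev = normal_vaf.get(c.key)
        if prev is None or v > prev:
            normal_vaf[c.key] = v
    labels: dict[VariantKey, str] = {}
    for c in tumor_calls:
        if c.key in labels:
            continue
        v = normal_vaf.get(c.key)
        labels[c.key] = GERMLINE if (v is not None and v > t.normal_af_cutoff) else SOMATIC
    tumor_id = tumor_calls[0].sample_id if tumor_calls else ""
    normal_id = normal_calls[0].sample_id if normal_calls else ""
    return TruthSet(labels=labels, source_sample=(tumor_id, normal_id))


def evaluate(predicted: Sequence[tuple[VariantKey, str]], truth: TruthSet) -> EvalReport:
    """Score predicted somatic/germline labels against the gold standard.

    Only keys present in both ``predicted`` and ``truth`` enter the
    confusion matrix; predicted keys absent from the truth are counted in
    ``n_unmatched``. Filtered variants must be excluded by the caller.
    """
    pred: dict[VariantKey, str] = {}
    for key, label in predicted:
        if label not in (SOMATIC, GERMLINE):
            raise ToscaError(f"predicted label {label!r} for {key} is not "
                             "somatic/germline; exclude filtered variants first")
        if key in pred and pred[key] != label:
            raise ToscaError(f"conflicting predicted labels for duplicated key {key}")
        pred[key] = label
    tp = fn = tn = fp = unmatched = 0
    for key, label in pred.items():
        true = truth.labels.get(key)
        if true is None:
            unmatched += 1
            continue
        if true == SOMATIC:
            if label == SOMATIC:
                tp += 1
            else:
                fn += 1
        else:
            if label == GERMLINE:
                tn += 1
            else:
                fp += 1
    n_eval = tp + fn + tn + fp
    report = EvalReport(tp_somatic=tp, fn_somatic=fn, tn_germline=tn,
                        fp_germline=fp, n_evaluated=n_eval, n_unmatched=unmatched)
    logger.info("%s", report)
    return report


def write_truth_tsv(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\n")
        for key in sorted(truth.labels):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t"
                     f"{truth.labels[key]}\n")


def read_truth_tsv(path) -> TruthSet:
    import pandas as pd

    from .variants import FormatError, normalize_variant

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"chrom", "pos", "ref", "alt", "label"}
    if not needed <= set(df.columns):
        raise FormatError(f"truth TSV {path} must have columns {sorted(needed)}")
    labels = {}
    for row in df.itertuples(index=False):
        key = normalize_variant(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        labels[key] = str(row.label)
    return TruthSet(labels=labels)
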