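"""Rule-based post-calling somatic variant filters.

Three auditable rule sets commonly applied after somatic SNV calling, each
implemented as a pure function over per-site read metrics (so no BAM or
pileup access is needed — computing the metrics from alignments is the job
of tools like bam-readcount and is out of scope here).

``snp_filter_v1`` — five retention rules for pileup-based calls:
  (a) site more than 10 bp from any predicted indel of quality >= 50;
  (b) maximum mapping quality at the site >= 40;
  (c) fewer than three SNV calls in a 10 bp window around the site;
  (d) site depth at least 3 and below 1e9 reads (the upper bound is
      effectively unbounded and implemented literally);
  (e) consensus quality >= 20 and SNP quality >= 20.

``false_positive_filter_v1`` — nine retention rules on read-level support:
  (a) >= 1% of variant-supporting reads on each strand;
  (b) variant allele fraction >= 5%;
  (c) more than four variant-supporting reads (i.e. >= 5);
  (d) average relative read position of the variant > 0.1;
  (e) mismatch quality-sum difference (variant - reference reads) < 50;
  (f) mapping quality difference < 30;
  (g) average supporting read-length difference < 25;
  (h) average relative distance to the effective 3' end >= 0.2;
  (i) not adjacent to a homopolymer of five or more identical bases.

``varscan_high_confidence_v1`` — four REMOVAL rules (note the polarity: a
site passes only when none fires):
  (a) caller-reported P value > 0.07;
  (b) normal VAF > 5%;
  (c) tumor VAF < 10%;
  (d) fewer than two variant-supporting reads.

Boundary semantics follow the printed inequalities exactly; each verdict
lists the codes of the violated rules so filtering decisions are auditable
rule by rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import SchemaError, ValidationError


@dataclass(frozen=True, slots=True)
class SiteMetrics:
    """Per-site read-level metrics consumed by the rule sets.

    Fractions are in [0, 1]; ``varscan_p_value`` and ``normal_vaf`` are
    only required by the high-confidence rule set.
    """

    distance_to_nearest_indel_bp: int | None = None
    nearest_indel_quality: float | None = None
    max_mapping_quality: float | None = None
    snv_calls_in_10bp_window: int | None = None
    site_depth: int | None = None
    consensus_quality: float | None = None
    snp_quality: float | None = None
    var_strand_fraction_fwd: float | None = None
    var_strand_fraction_rev: float | None = None
    tumor_vaf: float | None = None
    var_read_count: int | None = None
    avg_rel_read_position: float | None = None
    mismatch_qualsum_diff: float | None = None
    mapping_quality_diff: float | None = None
    avg_supporting_read_length_diff: float | None = None
    avg_rel_distance_to_3prime: float | None = None
    homopolymer_adjacent_length: int | None = None
    varscan_p_value: float | None = None
    normal_vaf: float | None = None

METRIC_FIELDS = [f for f in SiteMetrics.__dataclass_fields__]

# Each rule: (code, fields it reads, predicate returning True when the rule
# is SATISFIED i.e. the site may be retained).
Rule = tuple[str, tuple[str, ...], Callable[[SiteMetrics], bool]]

SNP_FILTER_V1_RULES: list[Rule] = [
    ("a", ("distance_to_nearest_indel_bp", "nearest_indel_quality"),
     lambda m: m.distance_to_nearest_indel_bp > 10 or m.nearest_indel_quality < 50),
    ("b", ("max_mapping_quality",), lambda m: m.max_mapping_quality >= 40),
    ("c", ("snv_calls_in_10bp_window",), lambda m: m.snv_calls_in_10bp_window < 3),
    ("d", ("site_depth",), lambda m: 3 <= m.site_depth < 1e9),
    ("e", ("consensus_quality", "snp_quality"),
     lambda m: m.consensus_quality >= 20 and m.snp_quality >= 20),
]

FALSE_POSITIVE_FILTER_V1_RULES: list[Rule] = [
    ("a", ("var_strand_fraction_fwd", "var_strand_fraction_rev"),
     lambda m: m.var_strand_fraction_fwd >= 0.01 and m.var_strand_fraction_rev >= 0.01),
    ("b", ("tumor_vaf",), lambda m: m.tumor_vaf >= 0.05),
    ("c", ("var_read_count",), lambda m: m.var_read_count > 4),
    ("d", ("avg_rel_read_position",), lambda m: m.avg_rel_read_position > 0.1),
    ("e", ("mismatch_qualsum_diff",), lambda m: m.mismatch_qualsum_diff < 50),
    ("f", ("mapping_quality_diff",), lambda m: m.mapping_quality_diff < 30),
    ("g", ("avg_supporting_read_length_diff",), lambda m: m.avg_supporting_read_length_diff < 25),
    ("h", ("avg_rel_distance_to_3prime",), lambda m: m.avg_rel_distance_to_3prime >= 0.2),
    ("i", ("homopolymer_adjacent_length",), lambda m: m.homopolymer_adjacent_length < 5),
]

# Removal conditions: rule code is violated when its condition FIRES.
VARSCAN_HIGH_CONFIDENCE_V1_RULES: list[Rule] = [
    ("a", ("varscan_p_value",), lambda m: not (m.varscan_p_value > 0.07)),
    ("b", ("normal_vaf",), lambda m: not (m.normal_vaf > 0.05)),
    ("c", ("tumor_vaf",), lambda m: not (m.tumor_vaf < 0.10)),
    ("d", ("var_read_count",), lambda m: not (m.var_read_count < 2)),
]

RULE_SETS: dict[str, list[Rule]] = {
    "snp-filter-v1": SNP_FILTER_V1_RULES,
    "false-positive-filter-v1": FALSE_POSITIVE_FILTER_V1_RULES,
    "varscan-high-confidence-v1": VARSCAN_HIGH_CONFIDENCE_V1_RULES,
}


def _evaluate(rules: list[Rule], m: SiteMetrics, set_name: str) -> tuple[bool, list[str]]:
    violated = []
    for code, fields, satisfied in rules:
        for f in fields:
            v = getattr(m, f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(
                    f"{set_name} rule ({code}): required metric {f!r} is missing"
                )
        if not satisfied(m):
            violated.append(code)
    return (not violated, violated)


def snp_filter_v1(m: SiteMetrics) -> tuple[bool, list[str]]:
    """Five pileup-call retention rules; pass iff all hold."""
    return _evaluate(SNP_FILTER_V1_RULES, m, "snp-filter-v1")


def false_positive_filter_v1(m: SiteMetrics) -> tuple[bool, list[str]]:
    """Nine read-support retention rules; pass iff all hold."""
    return _evaluate(FALSE_POSITIVE_FILTER_V1_RULES, m, "false-positive-filter-v1")


def varscan_high_confidence_v1(m: SiteMetrics) -> tuple[bool, list[str]]:
    """Four removal rules joined by OR; pass iff none fires."""
    return _evaluate(VARSCAN_HIGH_CONFIDENCE_V1_RULES, m, "varscan-high-confidence-v1")


FILTER_FUNCS = {
    "snp-filter-v1": snp_filter_v1,
    "false-positive-filter-v1": false_positive_filter_v1,
    "varscan-high-confidence-v1": varscan_high_confidence_v1,
}


def metrics_from_row(row: pd.Series) -> SiteMetrics:
    kwargs = {}
    for f in METRIC_FIELDS:
        if f in row.index and not pd.isna(row[f]):
            kwargs[f] = row[f]
    return SiteMetrics(**kwargs)


def apply_rule_set(metrics_table: pd.DataFrame, rule_set: str) -> pd.DataFrame:
    """Evaluate one rule set over a metrics TSV table.

    Returns the table with ``pass`` (bool) and ``violated`` (semicolon-
    joined rule codes) appended.  Requires a ``variant_id`` column.
    """
    if rule_set not in FILTER_FUNCS:
        raise SchemaError(
            f"unknown rule set {rule_set!r}; choose from {sorted(FILTER_FUNCS)}"
        )
    if "variant_id" not in metrics_table.columns:
        raise SchemaError("metrics table lacks variant_id column")
    func = FILTER_FUNCS[rule_set]
    passes, violations = [], []
    for _, row in metrics_table.iterrows():
        ok, viol = func(metrics_from_row(row))
        passes.append(ok)
        violations.append(";".join(viol))
    out = metrics_table.copy()
    out["pass"] = passes
    out["violated"] = violations
    return out


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "variant_id" not in df.columns:
        raise SchemaError(f"{path}: metrics table lacks variant_id column")
    return df
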