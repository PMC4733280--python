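"""Join read counts and expression onto candidates; depth and FPKM filters.

Sequencing evidence decides whether a predicted binder is worth making: the
variant must look somatic (little or no support in the normal DNA), be
well-covered and near-clonal in the tumor (so founder-clone mutations are
targeted), and its gene must be expressed in the tumor RNA.

Three coverage tracks are supported — normal DNA, tumor DNA, tumor RNA —
each supplying a depth and a variant allele fraction (VAF = variant reads /
total reads) per site.  Defaults follow the conventional cutoffs:

* remove when normal coverage <= 5x (too shallow to establish absence from
  the germline) or normal VAF >= 2% (likely germline or tumor-in-normal
  contamination) — two independent disqualifiers;
* keep only when every required tumor track has depth >= 10x and
  VAF >= 40% (founder clone);
* keep only when the gene's FPKM is strictly greater than 1 (raised from
  the "any expression" zero threshold to suppress noise).

VAFs are fractions in [0, 1] internally.  Missingness is data, not
failure: a candidate missing a value needed by a filter is removed with
reason ``insufficient data`` (or ``no expression data``), never silently
zero-filled.  Every removed candidate carries exactly one first-failing
reason code, so kept + removed always partitions the input.

Coverage TSV (reduced bam-readcount dialect): ``chrom, pos, track,
ref_count, var_count, total_depth`` with track in {normal_dna, tumor_dna,
tumor_rna}.  Expression TSV: ``gene, transcript_id, fpkm``
(transcript-level values preferred over gene-level when both match).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InputError, SchemaError, ValidationError

TRACKS = ("normal_dna", "tumor_dna", "tumor_rna")

COVERAGE_COLUMNS = ["chrom", "pos", "track", "ref_count", "var_count", "total_depth"]
EXPRESSION_COLUMNS = ["gene", "transcript_id", "fpkm"]

DEFAULT_NORMAL_COV_MIN = 5
DEFAULT_NORMAL_VAF_MAX = 0.02
DEFAULT_TUMOR_COV_MIN = 10
DEFAULT_TUMOR_VAF_MIN = 0.40
DEFAULT_FPKM_MIN = 1.0


@dataclass(frozen=True, slots=True)
class FilterResult:
    """Partition of a candidate table into kept rows and removed rows; the
    removed frame carries a single ``drop_reason`` per row."""

    kept: pd.DataFrame
    removed: pd.DataFrame


def compute_vaf(var_count: int, total_depth: int) -> float:
    """Variant allele fraction; NaN (missing) at zero depth."""
    if var_count < 0 or total_depth < 0:
        raise ValidationError("read counts must be non-negative")
    if var_count > total_depth:
        raise ValidationError(
            f"var_count {var_count} exceeds total depth {total_depth}"
        )
    if total_depth == 0:
        return math.nan
    return var_count / total_depth


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: coverage file missing columns {missing}")
    bad = sorted(set(df["track"]) - set(TRACKS))
    if bad:
        raise ValidationError(f"{path}: unknown coverage tracks {bad}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: expression file missing columns {missing}")
    if (df["fpkm"] < 0).any() or not pd.to_numeric(df["fpkm"]).notna().all():
        raise ValidationError(f"{path}: fpkm must be finite and non-negative")
    return df


def join_coverage_and_expression(
    candidates: pd.DataFrame,
    coverage: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate candidates with per-track depth/VAF and gene FPKM.

    Candidates must carry ``chrom``, ``pos``, ``gene`` and
    ``transcript_id``.  Keys absent from the coverage or expression tables
    yield missing values.  Transcript-level FPKM is preferred when the
    candidate's transcript matches; otherwise the gene-level value (row
    with empty transcript_id, or the single row for the gene) is used.
    """
    for col in ("chrom", "pos", "gene", "transcript_id"):
        if col not in candidates.columns:
            raise SchemaError(f"candidate table lacks required column {col!r}")
    out = candidates.copy()
    for track in TRACKS:
        sub = coverage[coverage["track"] == track]
        depth = {}
        vaf = {}
        for _, r in sub.iterrows():
            key = (str(r["chrom"]), int(r["pos"]))
            depth[key] = int(r["total_depth"])
            vaf[key] = compute_vaf(int(r["var_count"]), int(r["total_depth"]))
        keys = list(zip(out["chrom"].astype(str), out["pos"].astype(int)))
        out[f"{track}_depth"] = [depth.get(k, math.nan) for k in keys]
        out[f"{track}_vaf"] = [vaf.get(k, math.nan) for k in keys]

    tx_fpkm = {
        (str(r["gene"]), str(r["transcript_id"])): float(r["fpkm"])
        for _, r in expression.iterrows()
        if str(r["transcript_id"]) not in ("", "nan")
    }
    gene_fpkm: dict[str, float] = {}
    for _, r in expression.iterrows():
        g = str(r["gene"])
        # gene-level row wins; else remember any value as fallback
        if str(r["transcript_id"]) in ("", "nan") or g not in gene_fpkm:
            gene_fpkm[g] = float(r["fpkm"])
    out["gene_fpkm"] = [
        tx_fpkm.get((g, t), gene_fpkm.get(g, math.nan))
        for g, t in zip(out["gene"].astype(str), out["transcript_id"].astype(str))
    ]
    return out


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def apply_depth_filters(
    candidates: pd.DataFrame,
    normal_cov_min: float = DEFAULT_NORMAL_COV_MIN,
    normal_vaf_max: float = DEFAULT_NORMAL_VAF_MAX,
    tumor_cov_min: float = DEFAULT_TUMOR_COV_MIN,
    tumor_vaf_min: float = DEFAULT_TUMOR_VAF_MIN,
    tracks_required: Iterable[str] = ("tumor_dna",),
) -> FilterResult:
    """Depth/VAF filters on the normal and required tumor tracks.

    Removal logic, first failing reason wins:

    * normal DNA evidence missing -> ``insufficient data (normal_dna)``;
    * ``normal_dna_depth <= normal_cov_min`` -> ``low normal coverage``;
    * ``normal_dna_vaf >= normal_vaf_max`` -> ``high normal VAF``;
    * per required tumor track, missing depth/VAF -> ``insufficient data
      (track)``; depth < tumor_cov_min -> ``low coverage``; vaf <
      tumor_vaf_min -> ``low VAF``.
    """
    if min(normal_cov_min, normal_vaf_max, tumor_cov_min, tumor_vaf_min) < 0:
        raise InputError("filter thresholds must be non-negative")
    tracks = [t for t in TRACKS if t in set(tracks_required)]
    unknown = set(tracks_required) - set(TRACKS)
    if unknown:
        raise InputError(f"unknown coverage tracks required: {sorted(unknown)}")

    def reason(row) -> str | None:
        nd, nv = row.get("normal_dna_depth"), row.get("normal_dna_vaf")
        if _is_missing(nd):
            return "insufficient data (normal_dna)"
        if nd <= normal_cov_min:
            return "low normal coverage"
        if not _is_missing(nv) and nv >= normal_vaf_max:
            return "high normal VAF"
        for track in tracks:
            d, v = row.get(f"{track}_depth"), row.get(f"{track}_vaf")
            if _is_missing(d) or _is_missing(v):
                return f"insufficient data ({track})"
            if d < tumor_cov_min:
                return f"low coverage ({track})"
            if v < tumor_vaf_min:
                return f"low VAF ({track})"
        return None

    reasons = candidates.apply(reason, axis=1) if len(candidates) else pd.Series(dtype=object)
    kept = candidates[reasons.isna()].reset_index(drop=True) if len(candidates) else candidates.copy()
    removed = candidates[reasons.notna()].copy() if len(candidates) else candidates.copy()
    if len(removed):
        removed["drop_reason"] = reasons[reasons.notna()]
    else:
        removed["drop_reason"] = pd.Series(dtype=object)
    return FilterResult(kept, removed.reset_index(drop=True))


def apply_expression_filter(
    candidates: pd.DataFrame, fpkm_min: float = DEFAULT_FPKM_MIN
) -> FilterResult:
    """Keep candidates whose gene FPKM is strictly greater than the cutoff;
    missing FPKM removes the candidate with reason ``no expression data``."""
    if fpkm_min < 0:
        raise InputError(f"fpkm_min must be non-negative, got {fpkm_min}")
    if "gene_fpkm" not in candidates.columns:
        raise SchemaError("candidate table lacks gene_fpkm; join expression first")

    def reason(row) -> str | None:
        f = row["gene_fpkm"]
        if _is_missing(f):
            return "no expression data"
        if not f > fpkm_min:
            return "not expressed"
        return None

    reasons = candidates.apply(reason, axis=1) if len(candidates) else pd.Series(dtype=object)
    kept = candidates[reasons.isna()].reset_index(drop=True) if len(candidates) else candidates.copy()
    removed = candidates[reasons.notna()].copy() if len(candidates) else candidates.copy()
    if len(removed):
        removed["drop_reason"] = reasons[reasons.notna()]
    else:
        removed["drop_reason"] = pd.Series(dtype=object)
    return FilterResult(kept, removed.reset_index(drop=True))
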