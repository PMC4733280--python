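"""End-to-end orchestration: variants -> windows -> predictions -> filters.

The pipeline runs three conceptual steps — epitope prediction, integration
of sequencing evidence, and filtered candidate selection — and writes:

* ``peptides.fasta`` / ``peptides.key.tsv`` — the paired WT/MT windows;
* ``predictions.tsv`` — raw per-epitope affinities (external dialect);
* ``all_candidates.tsv`` — every localized binder under the threshold,
  annotated with coverage, VAF and expression;
* ``best_candidates.tsv`` — one best epitope per mutation surviving the
  depth and expression filters;
* ``dropped_candidates.tsv`` — per-variant drop reasons (auditable log);
* ``run_report.json`` — per-stage counts.

Outputs are deterministic for a fixed config and inputs: tables are sorted
and floats rendered with a fixed format, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import binding, coverage_expression as covexp, epitope_filter, fasta_gen, variant_io
from .errors import InputError, StageError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True, slots=True)
class PipelineConfig:
    """User-facing knobs; defaults are the conventional cutoffs documented
    in each stage's module."""

    alleles: tuple[str, ...]
    lengths: tuple[int, ...] = binding.DEFAULT_LENGTHS
    flank: int = fasta_gen.DEFAULT_FLANK
    binding_threshold_nm: float = epitope_filter.DEFAULT_BINDING_THRESHOLD_NM
    normal_cov_min: float = covexp.DEFAULT_NORMAL_COV_MIN
    normal_vaf_max: float = covexp.DEFAULT_NORMAL_VAF_MAX
    tumor_cov_min: float = covexp.DEFAULT_TUMOR_COV_MIN
    tumor_vaf_min: float = covexp.DEFAULT_TUMOR_VAF_MIN
    fpkm_min: float = covexp.DEFAULT_FPKM_MIN
    predictor: str = "mock"  # {"mock", "parse-file"}
    seed: int = 0
    strict: bool = False
    allow_nonstandard_lengths: bool = False

    def __post_init__(self) -> None:
        if not self.alleles:
            raise InputError("at least one HLA allele is required")
        bad = [k for k in self.lengths if not 8 <= k <= 11]
        if bad and not self.allow_nonstandard_lengths:
            raise InputError(
                f"epitope lengths outside 8-11: {bad} "
                "(pass allow_nonstandard_lengths to override)"
            )
        if self.predictor not in ("mock", "parse-file"):
            raise InputError(f"unknown predictor {self.predictor!r}")


def run_pipeline(
    config: PipelineConfig,
    variants_path: str | Path,
    coverage_path: str | Path,
    expression_path: str | Path,
    outdir: str | Path,
    predictions_path: str | Path | None = None,
) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": {
        "alleles": list(binding.validate_alleles(config.alleles)),
        "lengths": list(config.lengths),
        "flank": config.flank,
        "binding_threshold_nm": config.binding_threshold_nm,
        "normal_cov_min": config.normal_cov_min,
        "normal_vaf_max": config.normal_vaf_max,
        "tumor_cov_min": config.tumor_cov_min,
        "tumor_vaf_min": config.tumor_vaf_min,
        "fpkm_min": config.fpkm_min,
        "predictor": config.predictor,
        "seed": config.seed,
    }}
    counts = report["stages"]

    # --- stage 1: inputs -------------------------------------------------
    raw = pd.read_csv(variants_path, sep="\t", comment="#", dtype=str)
    counts["input_rows"] = len(raw)
    variants = variant_io.read_annotated_variants(variants_path, strict=config.strict)
    counts["accepted_missense_variants"] = len(variants)
    if not variants:
        raise StageError("variant_io: no variants passed validation")

    # --- stage 2: peptide windows + FASTA/key ----------------------------
    pairs, skipped = fasta_gen.build_pairs(variants, config.flank)
    counts["peptide_pairs"] = len(pairs)
    counts["windows_excluded_nonstandard"] = len(skipped)
    if not pairs:
        raise StageError("fasta_gen: no peptide windows could be built")
    fasta_path = outdir / "peptides.fasta"
    key_path = outdir / "peptides.key.tsv"
    counts["fasta_records"] = fasta_gen.write_fasta_and_key(pairs, fasta_path, key_path)

    # --- stage 3: binding predictions ------------------------------------
    if config.predictor == "mock":
        predictor = binding.make_mock_predictor(config.seed)
        preds = binding.run_predictions(pairs, config.alleles, config.lengths, predictor)
        key = fasta_gen.read_key(key_path)
        binding.write_prediction_file(preds, key, outdir / "predictions.tsv")
    else:
        if predictions_path is None:
            raise InputError("predictor 'parse-file' requires a predictions file")
        parsed = binding.parse_prediction_file(predictions_path, key_path)
        preds = binding.attach_mutant_offsets(parsed, pairs)
    counts["raw_predictions"] = len(preds)

    # --- stage 4: pair, binding filter, best selection --------------------
    paired = epitope_filter.pair_wt_mt(preds)
    counts["paired_predictions"] = len(paired)
    filtered = epitope_filter.apply_binding_filter(paired, config.binding_threshold_nm)
    filtered = epitope_filter.add_fold_change(filtered)
    counts["binding_filtered"] = len(filtered)
    counts["variants_with_binding_candidate"] = int(filtered["variant_id"].nunique())
    best = epitope_filter.select_best_candidates(filtered)

    # --- stage 5: integrate coverage + expression -------------------------
    meta = variant_io.variants_to_frame(variants)[
        ["variant_id", "chrom", "pos", "gene", "transcript_id"]
    ]
    meta["pos"] = meta["pos"].astype(int)
    coverage = covexp.read_coverage(coverage_path)
    expression = covexp.read_expression(expression_path)

    def annotate(tbl: pd.DataFrame) -> pd.DataFrame:
        merged = tbl.merge(meta, on="variant_id", how="left", validate="m:1")
        return covexp.join_coverage_and_expression(merged, coverage, expression)

    all_annotated = annotate(filtered)
    best_annotated = annotate(best)

    # --- stage 6: depth + expression filters ------------------------------
    tracks = ["tumor_dna"]
    if (coverage["track"] == "tumor_rna").any():
        tracks.append("tumor_rna")
    depth_res = covexp.apply_depth_filters(
        best_annotated,
        normal_cov_min=config.normal_cov_min,
        normal_vaf_max=config.normal_vaf_max,
        tumor_cov_min=config.tumor_cov_min,
        tumor_vaf_min=config.tumor_vaf_min,
        tracks_required=tracks,
    )
    counts["after_depth_filter"] = len(depth_res.kept)
    expr_res = covexp.apply_expression_filter(depth_res.kept, config.fpkm_min)
    final = expr_res.kept
    counts["final_candidates"] = len(final)

    dropped = pd.concat([depth_res.removed, expr_res.removed], ignore_index=True)

    # --- outputs ----------------------------------------------------------
    def write(tbl: pd.DataFrame, name: str) -> None:
        sort_cols = [c for c in ("variant_id", "hla_allele", "k", "start_offset") if c in tbl.columns]
        out = tbl.sort_values(sort_cols, kind="mergesort").reset_index(drop=True) if sort_cols else tbl
        out.to_csv(outdir / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    write(all_annotated, "all_candidates.tsv")
    write(final, "best_candidates.tsv")
    write(dropped, "dropped_candidates.tsv")
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
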