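import math

import numpy as np
import pandas as pd
import pytest

from neoepi.coverage_expression import (
    apply_depth_filters,
    apply_expression_filter,
    compute_vaf,
    join_coverage_and_expression,
)
from neoepi.errors import ValidationError


def test_compute_vaf():
    assert compute_vaf(0, 50) == 0.0
    assert compute_vaf(20, 50) == pytest.approx(0.40)
    assert math.isnan(compute_vaf(0, 0))
    with pytest.raises(ValidationError):
        compute_vaf(7, 0)
    with pytest.raises(ValidationError):
        compute_vaf(-1, 10)


def _candidates(n=1, **overrides):
    base = {
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": ["chr1"] * n,
        "pos": list(range(100, 100 + n)),
        "gene": ["G1"] * n,
        "transcript_id": ["T1"] * n,
        "normal_dna_depth": [30.0] * n,
        "normal_dna_vaf": [0.0] * n,
        "tumor_dna_depth": [30.0] * n,
        "tumor_dna_vaf": [0.45] * n,
        "tumor_rna_depth": [30.0] * n,
        "tumor_rna_vaf": [0.45] * n,
        "gene_fpkm": [5.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestJoin:
    def _coverage(self):
        rows = []
        for track, var, depth in (
            ("normal_dna", 0, 40),
            ("tumor_dna", 12, 30),
            ("tumor_rna", 20, 50),
        ):
            rows.append(("chr1", 100, track, depth - var, var, depth))
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "track", "ref_count", "var_count", "total_depth"]
        )

    def _expression(self):
        return pd.DataFrame(
            {"gene": ["G1", "G1"], "transcript_id": ["T1", "T9"], "fpkm": [2.5, 9.0]}
        )

    def test_all_tracks_populated(self):
        cand = pd.DataFrame(
            {"variant_id": ["v0"], "chrom": ["chr1"], "pos": [100],
             "gene": ["G1"], "transcript_id": ["T1"]}
        )
        out = join_coverage_and_expression(cand, self._coverage(), self._expression())
        assert out.loc[0, "tumor_dna_vaf"] == pytest.approx(0.40)  # 12/30
        assert out.loc[0, "normal_dna_vaf"] == 0.0
        assert out.loc[0, "tumor_rna_depth"] == 50
        assert out.loc[0, "gene_fpkm"] == 2.5  # transcript-level preferred

    def test_absent_keys_yield_missing_never_zero(self):
        cand = pd.DataFrame(
            {"variant_id": ["v0"], "chrom": ["chr2"], "pos": [999],
             "gene": ["G_absent"], "transcript_id": ["T_absent"]}
        )
        out = join_coverage_and_expression(cand, self._coverage(), self._expression())
        assert out.loc[0, "tumor_rna_depth"] != 0 and math.isnan(out.loc[0, "tumor_rna_depth"])
        assert math.isnan(out.loc[0, "gene_fpkm"])

    def test_gene_level_fallback_when_transcript_unmatched(self):
        cand = pd.DataFrame(
            {"variant_id": ["v0"], "chrom": ["chr1"], "pos": [100],
             "gene": ["G1"], "transcript_id": ["T_other"]}
        )
        out = join_coverage_and_expression(cand, self._coverage(), self._expression())
        assert out.loc[0, "gene_fpkm"] == 2.5


class TestDepthFilters:
    def test_passing_candidate_kept(self):
        res = apply_depth_filters(_candidates(normal_dna_depth=[6.0]))
        assert len(res.kept) == 1 and res.removed.empty

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"normal_dna_depth": [5.0]}, "low normal coverage"),
            ({"normal_dna_vaf": [0.02]}, "high normal VAF"),
            ({"tumor_dna_depth": [9.0]}, "low coverage (tumor_dna)"),
            ({"tumor_dna_vaf": [0.39]}, "low VAF (tumor_dna)"),
            ({"tumor_dna_vaf": [float("nan")], "tumor_dna_depth": [float("nan")]},
             "insufficient data (tumor_dna)"),
            ({"normal_dna_depth": [float("nan")]}, "insufficient data (normal_dna)"),
        ],
    )
    def test_boundary_removals(self, overrides, reason):
        res = apply_depth_filters(_candidates(**overrides))
        assert res.kept.empty
        assert res.removed.loc[0, "drop_reason"] == reason

    def test_boundaries_on_keeping_side(self):
        # depth 6 > 5 cutoff, normal VAF just under 2%, tumor exactly at cutoffs
        res = apply_depth_filters(
            _candidates(normal_dna_depth=[6.0], normal_dna_vaf=[0.019],
                        tumor_dna_depth=[10.0], tumor_dna_vaf=[0.40])
        )
        assert len(res.kept) == 1

    def test_lowered_tumor_vaf_cutoff_keeps_subclonal(self):
        cand = _candidates(tumor_dna_vaf=[0.25])
        assert apply_depth_filters(cand).kept.empty
        assert len(apply_depth_filters(cand, tumor_vaf_min=0.20).kept) == 1

    def test_rna_track_only_when_required(self):
        cand = _candidates(tumor_rna_depth=[float("nan")], tumor_rna_vaf=[float("nan")])
        assert len(apply_depth_filters(cand, tracks_required=("tumor_dna",)).kept) == 1
        res = apply_depth_filters(cand, tracks_required=("tumor_dna", "tumor_rna"))
        assert res.removed.loc[0, "drop_reason"] == "insufficient data (tumor_rna)"


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "fpkm,fpkm_min,kept",
        [
            (1.5, 1.0, True),
            (1.0, 1.0, False),   # strict "greater than"
            (0.4, 0.0, True),    # any expression when cutoff lowered to zero
            (0.0, 0.0, False),
            (float("nan"), 1.0, False),
        ],
    )
    def test_boundaries(self, fpkm, fpkm_min, kept):
        res = apply_expression_filter(_candidates(gene_fpkm=[fpkm]), fpkm_min)
        assert (len(res.kept) == 1) is kept

    def test_missing_reason_code(self):
        res = apply_expression_filter(_candidates(gene_fpkm=[float("nan")]))
        assert res.removed.loc[0, "drop_reason"] == "no expression data"


def _random_candidates(rng, n=300):
    return _candidates(
        n,
        normal_dna_depth=rng.integers(0, 40, n).astype(float),
        normal_dna_vaf=rng.choice([0.0, 0.01, 0.02, 0.3, np.nan], n),
        tumor_dna_depth=rng.integers(0, 60, n).astype(float),
        tumor_dna_vaf=rng.choice([0.1, 0.39, 0.4, 0.7, np.nan], n),
        tumor_rna_depth=rng.integers(0, 60, n).astype(float),
        tumor_rna_vaf=rng.choice([0.1, 0.5, np.nan], n),
        gene_fpkm=rng.choice([0.0, 0.5, 1.0, 1.1, 8.0, np.nan], n),
    )


def test_filters_conserve_and_are_order_independent():
    """kept + removed partitions the input, each removed row has exactly one
    reason, and depth-then-expression equals expression-then-depth."""
    rng = np.random.default_rng(3)
    cand = _random_candidates(rng)
    d = apply_depth_filters(cand, tracks_required=("tumor_dna", "tumor_rna"))
    de = apply_expression_filter(d.kept)
    assert len(d.kept) + len(d.removed) == len(cand)
    assert len(de.kept) + len(de.removed) == len(d.kept)
    assert d.removed["drop_reason"].notna().all()

    e = apply_expression_filter(cand)
    ed = apply_depth_filters(e.kept, tracks_required=("tumor_dna", "tumor_rna"))
    assert sorted(de.kept["variant_id"]) == sorted(ed.kept["variant_id"])


def test_kept_set_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    cand = _random_candidates(rng)
    res = apply_expression_filter(
        apply_depth_filters(cand, tracks_required=("tumor_dna", "tumor_rna")).kept
    )

    def ok(r):
        vals = [r.normal_dna_depth, r.tumor_dna_depth, r.tumor_dna_vaf,
                r.tumor_rna_depth, r.tumor_rna_vaf, r.gene_fpkm]
        if any(isinstance(v, float) and math.isnan(v) for v in vals):
            return False
        if r.normal_dna_depth <= 5:
            return False
        if not (isinstance(r.normal_dna_vaf, float) and math.isnan(r.normal_dna_vaf)):
            if r.normal_dna_vaf >= 0.02:
                return False
        for d, v in ((r.tumor_dna_depth, r.tumor_dna_vaf), (r.tumor_rna_depth, r.tumor_rna_vaf)):
            if d < 10 or v < 0.40:
                return False
        return r.gene_fpkm > 1.0

    expected = {r.variant_id for r in cand.itertuples() if ok(r)}
    assert set(res.kept["variant_id"]) == expected
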