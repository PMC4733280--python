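"""Synthetic cohort generator: every pipeline input, with planted truth.

Real inputs to the pipeline come from tumor/normal exome plus tumor RNA-seq
of a patient; none of that can ship with a test suite, so this module
fabricates statistically structured stand-ins for all of them:

* a proteome of random proteins (uniform over the 20 standard residues),
* an annotated missense-variant table whose WT residues are read from
  those proteins (so strict validation passes by construction), with a
  configurable fraction of mutations placed near a protein terminus to
  exercise the window edge rule,
* per-site read counts for the normal DNA, tumor DNA and tumor RNA tracks:
  clean somatic sites get tumor variant reads binomial around the
  configured somatic VAF and zero normal variant reads, while a planted
  fraction of germline-contaminated sites shows ~50% VAF in the normal
  (these must fall to the normal-VAF filter),
* transcript-level FPKM values, log-normal with a planted unexpressed
  fraction at exactly 0 (whose RNA track also has zero depth).

A single global seed drives everything through numpy's seed-sequence
spawning: stream ``k`` of run ``seed`` is ``default_rng([seed, k])`` with
fixed per-generator stream ids, so any subset of the fixtures is
reproducible in isolation.

The generator emulates count statistics and filter-relevant structure, not
sequencing reads: no error model, no mappability artifacts, no linkage
between neighboring sites, and no realistic HLA frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import STANDARD_AA

_AA = sorted(STANDARD_AA)
_BASES = ["A", "C", "G", "T"]

# Seed-stream ids (never reuse across generators).
_STREAM_PROTEOME = 1
_STREAM_VARIANTS = 2
_STREAM_COVERAGE = 3
_STREAM_EXPRESSION = 4

#: Negative-binomial dispersion for sequencing depths (smaller = more
#: overdispersed); 10 gives a realistic exome-like spread around the mean.
_DEPTH_DISPERSION = 10.0
#: Beta concentration of per-site somatic VAF around its mean.
_VAF_CONCENTRATION = 40.0


@dataclass(frozen=True, slots=True)
class FixtureConfig:
    """Knobs of the synthetic cohort.

    Defaults describe a plausible tumor/normal exome study: ~40x normal and
    ~80x tumor mean depth, founder-clone somatic VAF centered at 0.5, 10%
    of sites contaminated by germline signal, and 30% of genes unexpressed.
    """

    seed: int = 0
    n_proteins: int = 30
    protein_length_range: tuple[int, int] = (30, 800)
    n_variants: int = 200
    fraction_near_terminus: float = 0.2
    normal_depth_mean: float = 40.0
    tumor_depth_mean: float = 80.0
    true_somatic_vaf_mean: float = 0.5
    germline_contam_fraction: float = 0.1
    fpkm_lognormal_params: tuple[float, float] = (2.0, 1.5)
    fraction_unexpressed: float = 0.3

    def __post_init__(self) -> None:
        for name in ("fraction_near_terminus", "germline_contam_fraction",
                     "fraction_unexpressed", "true_somatic_vaf_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.normal_depth_mean <= 0 or self.tumor_depth_mean <= 0:
            raise ValueError("depth means must be positive")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_proteome(config: FixtureConfig) -> list[tuple[str, str, str]]:
    """Random proteins as ``(gene, transcript_id, sequence)`` triples.

    Residues are uniform over the 20 standard amino acids and lengths are
    uniform over the configured range; deterministic given the seed.
    """
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = _rng(config, _STREAM_PROTEOME)
    lo, hi = config.protein_length_range
    out = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length))
        out.append((f"GENE{i:04d}", f"TX{i:04d}", seq))
    return out


def proteome_to_fasta(proteome: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, tx, seq in proteome:
            fh.write(f">{tx} gene={gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def generate_variants(
    proteome: list[tuple[str, str, str]], config: FixtureConfig, flank: int = 10
) -> pd.DataFrame:
    """Missense variant table in the annotated-variant TSV schema.

    WT residues are read from the protein so every row passes strict
    validation.  A ``fraction_near_terminus`` of mutations is placed within
    ``flank`` residues of a protein end; the rest land strictly interior
    (when the protein is long enough), so the edge-handling path is
    exercised at a known rate.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    rng = _rng(config, _STREAM_VARIANTS)
    rows = []
    for i in range(config.n_variants):
        gene, tx, seq = proteome[int(rng.integers(len(proteome)))]
        L = len(seq)
        near = rng.random() < config.fraction_near_terminus
        if near or L <= 2 * flank:
            edge = min(flank, L)
            choices = sorted(set(range(1, edge + 1)) | set(range(max(1, L - edge + 1), L + 1)))
            p = int(rng.choice(choices))
        else:
            p = int(rng.integers(flank + 1, L - flank + 1))
        wt = seq[p - 1]
        mt = str(rng.choice([a for a in _AA if a != wt]))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        rows.append(
            {
                "variant_id": f"var{i:04d}",
                "chrom": f"chr{(i % 22) + 1}",
                "pos": 1_000_000 + i * 137,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "transcript_id": tx,
                "protein_change": f"p.{wt}{p}{mt}",
                "wt_protein_seq": seq,
            }
        )
    return pd.DataFrame(rows)


def _depth(rng: np.random.Generator, mean: float) -> int:
    r = _DEPTH_DISPERSION
    return int(rng.negative_binomial(r, r / (r + mean)))


def generate_coverage_and_expression(
    variants: pd.DataFrame, config: FixtureConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Coverage and expression tables plus the planted-truth table.

    Returns ``(coverage, expression, truth)``.  ``truth`` records, per
    variant, whether germline contamination was planted and whether the
    gene is expressed — the facts an oracle needs to predict the filters'
    verdicts independently of the pipeline.
    """
    if variants.empty:
        raise ValueError("variants must be non-empty")
    rng = _rng(config, _STREAM_COVERAGE)
    erng = _rng(config, _STREAM_EXPRESSION)
    mu, sigma = config.fpkm_lognormal_params

    genes = sorted(variants["gene"].unique())
    gene_tx = {g: variants.loc[variants["gene"] == g, "transcript_id"].iloc[0] for g in genes}
    expressed = {g: erng.random() >= config.fraction_unexpressed for g in genes}
    fpkm = {g: float(erng.lognormal(mu, sigma)) if expressed[g] else 0.0 for g in genes}
    expression = pd.DataFrame(
        {
            "gene": genes,
            "transcript_id": [gene_tx[g] for g in genes],
            "fpkm": [round(fpkm[g], 4) for g in genes],
        }
    )

    a = config.true_somatic_vaf_mean * _VAF_CONCENTRATION
    b = (1 - config.true_somatic_vaf_mean) * _VAF_CONCENTRATION
    cov_rows, truth_rows = [], []
    for _, v in variants.iterrows():
        is_germline = rng.random() < config.germline_contam_fraction
        site_vaf = 0.5 if is_germline else float(rng.beta(a, b))
        nd = _depth(rng, config.normal_depth_mean)
        td = _depth(rng, config.tumor_depth_mean)
        nv = int(rng.binomial(nd, 0.5)) if is_germline else 0
        tv = int(rng.binomial(td, site_vaf))
        is_expr = expressed[v["gene"]]
        rd = _depth(rng, config.tumor_depth_mean) if is_expr else 0
        rv = int(rng.binomial(rd, site_vaf)) if rd else 0
        for track, depth, var in (
            ("normal_dna", nd, nv),
            ("tumor_dna", td, tv),
            ("tumor_rna", rd, rv),
        ):
            cov_rows.append(
                {
                    "chrom": v["chrom"],
                    "pos": v["pos"],
                    "track": track,
                    "ref_count": depth - var,
                    "var_count": var,
                    "total_depth": depth,
                }
            )
        truth_rows.append(
            {
                "variant_id": v["variant_id"],
                "gene": v["gene"],
                "is_germline": is_germline,
                "is_expressed": is_expr,
                "gene_fpkm": round(fpkm[v["gene"]], 4),
                "normal_dna_depth": nd,
                "normal_dna_var": nv,
                "tumor_dna_depth": td,
                "tumor_dna_var": tv,
                "tumor_rna_depth": rd,
                "tumor_rna_var": rv,
            }
        )
    return pd.DataFrame(cov_rows), expression, pd.DataFrame(truth_rows)


def generate_cohort(config: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input set (variants, coverage, expression) plus the
    planted-truth table to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    variants = generate_variants(proteome, config)
    coverage, expression, truth = generate_coverage_and_expression(variants, config)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "variants": outdir / "variants.tsv",
        "coverage": outdir / "coverage.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
    }
    proteome_to_fasta(proteome, paths["proteome"])
    variants.to_csv(paths["variants"], sep="\t", index=False)
    coverage.to_csv(paths["coverage"], sep="\t", index=False)
    expression.to_csv(paths["expression"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
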