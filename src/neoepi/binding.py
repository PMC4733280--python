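"""Enumerate candidate k-mers and obtain IC50 binding affinities.

MHC class I molecules present peptides of 8–11 residues, so every k-mer of
each WT/MT window is scored against every patient HLA allele.  Affinities
are IC50 values in nanomolar — lower is stronger; < 500 nM is the
conventional binder threshold applied downstream.

Predictors are pluggable: any callable ``(peptide, allele) -> ic50_nm``
works.  Two implementations ship here:

* a deterministic keyed-hash mock predictor, so the whole pipeline is
  testable without a licensed binding predictor, and
* a parser for an external predictor's tab-separated output, re-associated
  with variants through the FASTA key file.

Prediction-file dialect (normative for this package): tab-separated with a
header line and columns ``record_index, start_offset, peptide, allele,
ic50_nm``, where ``record_index`` refers to the key file.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import InputError, ParseError, ValidationError
from .fasta_gen import PeptidePair, read_key
from .variant_io import STANDARD_AA

logger = logging.getLogger(__name__)

DEFAULT_LENGTHS = (8, 9, 10, 11)
#: Log-uniform IC50 range of the mock predictor, nM.
MOCK_IC50_MIN = 1.0
MOCK_IC50_MAX = 50_000.0

PREDICTION_COLUMNS = [
    "variant_id",
    "allele_class",
    "hla_allele",
    "k",
    "start_offset",
    "peptide",
    "ic50_nm",
]

PREDICTION_FILE_COLUMNS = ["record_index", "start_offset", "peptide", "allele", "ic50_nm"]

Predictor = Callable[[str, str], float]

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-C])\*?(\d{2}):?(\d{2,3})$")

#: Common HLA class I alleles accepted by default.  External predictors
#: support only a finite allele set, so requests are validated up front and
#: unsupported names fail fast.  Extend via the ``allowed`` argument.
DEFAULT_SUPPORTED_ALLELES = frozenset(
    {
        "HLA-A01:01", "HLA-A02:01", "HLA-A02:02", "HLA-A02:03", "HLA-A02:06",
        "HLA-A03:01", "HLA-A11:01", "HLA-A23:01", "HLA-A24:02", "HLA-A26:01",
        "HLA-A29:02", "HLA-A30:01", "HLA-A31:01", "HLA-A32:01", "HLA-A33:01",
        "HLA-A68:01", "HLA-A68:02", "HLA-B07:02", "HLA-B08:01", "HLA-B15:01",
        "HLA-B18:01", "HLA-B27:05", "HLA-B35:01", "HLA-B40:01", "HLA-B44:02",
        "HLA-B44:03", "HLA-B51:01", "HLA-B53:01", "HLA-B57:01", "HLA-B58:01",
        "HLA-C04:01", "HLA-C06:02", "HLA-C07:01", "HLA-C07:02",
    }
)


def normalize_allele(name: str) -> str:
    """Canonicalize an HLA class I allele name to ``HLA-A02:01`` form.

    Accepts ``HLA-A02:01``, ``HLA-A*02:01`` and ``A0201`` spellings.
    """
    m = _ALLELE_RE.match(name.strip())
    if m is None:
        raise ValidationError(f"unrecognized HLA allele name: {name!r}")
    locus, group, protein = m.groups()
    return f"HLA-{locus}{group}:{protein}"


def validate_alleles(
    alleles: Sequence[str], allowed: Iterable[str] | None = None
) -> list[str]:
    """Normalize allele names and reject any outside the allow-list."""
    if not alleles:
        raise InputError("at least one HLA allele is required")
    allow = frozenset(allowed) if allowed is not None else DEFAULT_SUPPORTED_ALLELES
    normalized = [normalize_allele(a) for a in alleles]
    unsupported = sorted(set(normalized) - allow)
    if unsupported:
        raise InputError(f"unsupported HLA alleles: {unsupported}")
    return normalized


def enumerate_kmers(window: str, k: int) -> list[tuple[int, str]]:
    """All k-mers of ``window`` as ``(start_offset, peptide)``, 1-based,
    ascending; empty when the window is shorter than k."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return [(i + 1, window[i : i + k]) for i in range(len(window) - k + 1)]


def mock_predict(peptide: str, hla_allele: str, seed: int) -> float:
    """Deterministic stand-in affinity for testing the pipeline end to end.

    A BLAKE2b hash keyed on ``(peptide, canonical allele, seed)`` is mapped
    onto a log-uniform IC50 in [1, 50000] nM, so repeated calls agree
    exactly, different alleles generally disagree, and the fraction of
    peptides under any threshold follows the closed form
    ``log(thr/min) / log(max/min)``.
    """
    if not peptide:
        raise ValidationError("empty peptide")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValidationError(f"non-standard residue(s) in peptide: {sorted(bad)}")
    allele = normalize_allele(hla_allele)
    digest = hashlib.blake2b(
        f"{peptide}|{allele}|{seed}".encode(), digest_size=8
    ).digest()
    u = int.from_bytes(digest, "big") / 2**64  # uniform in [0, 1)
    log_span = math.log(MOCK_IC50_MAX / MOCK_IC50_MIN)
    return MOCK_IC50_MIN * math.exp(u * log_span)


def make_mock_predictor(seed: int) -> Predictor:
    """Bind a seed into the plug-in predictor interface."""

    def predictor(peptide: str, allele: str) -> float:
        return mock_predict(peptide, allele, seed)

    return predictor


def run_predictions(
    pairs: list[PeptidePair],
    alleles: Sequence[str],
    lengths: Sequence[int],
    predictor: Predictor,
    allowed_alleles: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every k-mer of every WT/MT window against every allele.

    Produces exactly one row per (pair, WT/MT class, allele, length,
    enumerated k-mer); total row count is
    ``sum over pairs, lengths of 2 * n_alleles * max(0, window_len - k + 1)``.
    A predictor failure on a peptide yields a row with missing ``ic50_nm``
    and a logged warning rather than a silent drop.  The returned frame
    additionally carries ``mutant_offset`` so downstream localization needs
    no extra join.
    """
    alleles = validate_alleles(alleles, allowed_alleles)
    if not lengths:
        raise InputError("at least one epitope length is required")
    rows = []
    for pair in pairs:
        for cls, window in (("WT", pair.wt_window), ("MT", pair.mt_window)):
            for allele in alleles:
                for k in lengths:
                    for start, pep in enumerate_kmers(window, k):
                        try:
                            ic50 = float(predictor(pep, allele))
                        except Exception as exc:  # predictor is third-party code
                            logger.warning(
                                "predictor failed on %s/%s %s: %s",
                                pair.variant_id, cls, pep, exc,
                            )
                            ic50 = float("nan")
                        rows.append(
                            (pair.variant_id, cls, allele, k, start, pep, ic50,
                             pair.mutant_offset)
                        )
    return pd.DataFrame(
        rows, columns=PREDICTION_COLUMNS + ["mutant_offset"]
    )


def write_prediction_file(
    predictions: pd.DataFrame, key: pd.DataFrame, path: str | Path
) -> int:
    """Serialize predictions in the external prediction-file dialect,
    keyed by FASTA record index (header-stripped, as such tools emit)."""
    index_of = {
        (str(r["variant_id"]), str(r["class"])): int(r["record_index"])
        for _, r in key.iterrows()
    }
    out = pd.DataFrame(
        {
            "record_index": [
                index_of[(vid, cls)]
                for vid, cls in zip(predictions["variant_id"], predictions["allele_class"])
            ],
            "start_offset": predictions["start_offset"].astype(int),
            "peptide": predictions["peptide"],
            "allele": predictions["hla_allele"],
            "ic50_nm": predictions["ic50_nm"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return len(out)


def parse_prediction_file(pred_path: str | Path, key_path: str | Path) -> pd.DataFrame:
    """Parse a prediction file and re-associate rows with their variants.

    The key file maps each record index back to ``(variant_id, WT/MT)``;
    rows referencing unknown record indices are an error, as are malformed
    lines (reported with their line number).
    """
    key = read_key(key_path)
    label_of = {
        int(r["record_index"]): (str(r["variant_id"]), str(r["class"]))
        for _, r in key.iterrows()
    }
    rows = []
    with open(pred_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PREDICTION_FILE_COLUMNS:
            raise ParseError(
                f"{pred_path}: expected header {PREDICTION_FILE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{pred_path}:{lineno}: expected 5 fields, got {len(fields)}")
            try:
                rec = int(fields[0])
                start = int(fields[1])
                pep = fields[2]
                allele = normalize_allele(fields[3])
                ic50 = float(fields[4])
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{pred_path}:{lineno}: {exc}") from exc
            if rec not in label_of:
                raise ParseError(
                    f"{pred_path}:{lineno}: record index {rec} not present in key file"
                )
            vid, cls = label_of[rec]
            rows.append((vid, cls, allele, len(pep), start, pep, ic50))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


# Backwards-compatible alias: the supported external dialect.
parse_netmhc_output = parse_prediction_file


def attach_mutant_offsets(
    predictions: pd.DataFrame, pairs: list[PeptidePair]
) -> pd.DataFrame:
    """Join each variant's window mutant offset onto parsed predictions."""
    offsets = pd.DataFrame(
        {
            "variant_id": [p.variant_id for p in pairs],
            "mutant_offset": [p.mutant_offset for p in pairs],
        }
    )
    merged = predictions.merge(offsets, on="variant_id", how="left", validate="m:1")
    if merged["mutant_offset"].isna().any():
        missing = sorted(
            merged.loc[merged["mutant_offset"].isna(), "variant_id"].unique()
        )
        raise InputError(f"predictions reference unknown variants: {missing}")
    merged["mutant_offset"] = merged["mutant_offset"].astype(int)
    return merged


def expected_prediction_rows(
    pairs: list[PeptidePair], n_alleles: int, lengths: Sequence[int]
) -> int:
    """Closed-form row count of :func:`run_predictions`."""
    return sum(
        2 * n_alleles * max(0, len(p.wt_window) - k + 1)
        for p in pairs
        for k in lengths
    )
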