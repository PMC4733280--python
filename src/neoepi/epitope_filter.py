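"""Pair WT with MT predictions, filter binders, and pick best candidates.

The neoepitope logic: a k-mer from the mutant window is only informative if
it actually contains the mutated residue (a "localized" peptide) — k-mers
upstream or downstream of the mutation are identical between WT and MT
windows and carry no tumor specificity.  Localized mutant peptides with a
predicted IC50 below the binding threshold (default: strictly less than
500 nM) are candidate neoepitopes; each is paired with the WT peptide at
the same window coordinates so the wild-type affinity and the WT/MT fold
change (WT IC50 / MT IC50) can be reported.  The WT score is informational
only — it never affects retention.

Per mutation, the single "best candidate" is the localized filtered peptide
with the lowest mutant IC50 across all tested lengths and all patient HLA
alleles.  Exact IC50 ties are broken deterministically: shorter k first,
then lexicographically smaller allele, then smaller start offset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BINDING_THRESHOLD_NM = 500.0

PAIR_KEY = ["variant_id", "hla_allele", "k", "start_offset"]

CANDIDATE_COLUMNS = [
    "variant_id",
    "hla_allele",
    "k",
    "start_offset",
    "mutant_offset",
    "mt_peptide",
    "wt_peptide",
    "mt_ic50_nm",
    "wt_ic50_nm",
    "fold_change",
    "log2_fold_change",
]


def is_localized(start_offset: int, k: int, mutant_offset: int) -> bool:
    """True iff the k-mer starting at ``start_offset`` covers the mutated
    residue of its window (all coordinates 1-based within the window)."""
    if start_offset < 1 or k < 1 or mutant_offset < 1:
        raise ValidationError("offsets and k must be positive")
    return start_offset <= mutant_offset <= start_offset + k - 1


def pair_wt_mt(predictions: pd.DataFrame) -> pd.DataFrame:
    """Join WT and MT predictions at identical window coordinates.

    One output row per (variant, allele, k, start_offset) that has an MT
    prediction.  An MT row with no WT partner is kept with a missing WT
    score and logged — this occurs when only the WT window was excluded
    (e.g. a non-standard residue outside the shared region).  WT-only
    coordinates are dropped: with no mutant peptide there is nothing to
    consider.  Duplicate (variant, allele, k, start, class) rows are an
    error.
    """
    dup = predictions.duplicated(subset=PAIR_KEY + ["allele_class"])
    if dup.any():
        examples = predictions.loc[dup, PAIR_KEY + ["allele_class"]].head(5)
        raise InputError(f"duplicate prediction rows:\n{examples}")
    mt = predictions[predictions["allele_class"] == "MT"]
    wt = predictions[predictions["allele_class"] == "WT"]
    carry = ["mutant_offset"] if "mutant_offset" in predictions.columns else []
    paired = mt[PAIR_KEY + carry + ["peptide", "ic50_nm"]].rename(
        columns={"peptide": "mt_peptide", "ic50_nm": "mt_ic50_nm"}
    ).merge(
        wt[PAIR_KEY + ["peptide", "ic50_nm"]].rename(
            columns={"peptide": "wt_peptide", "ic50_nm": "wt_ic50_nm"}
        ),
        on=PAIR_KEY,
        how="left",
    )
    n_unpaired = int(paired["wt_ic50_nm"].isna().sum())
    if n_unpaired:
        logger.warning("%d MT predictions lack a WT partner at identical coordinates", n_unpaired)
    return paired.reset_index(drop=True)


def add_fold_change(paired: pd.DataFrame) -> pd.DataFrame:
    """WT/MT affinity ratio; > 1 means the mutant binds more strongly.
    Missing WT scores propagate as missing fold changes, never imputed."""
    out = paired.copy()
    out["fold_change"] = out["wt_ic50_nm"] / out["mt_ic50_nm"]
    out["log2_fold_change"] = np.log2(out["fold_change"])
    return out


def apply_binding_filter(
    paired: pd.DataFrame, threshold_nm: float = DEFAULT_BINDING_THRESHOLD_NM
) -> pd.DataFrame:
    """Keep localized mutant peptides with MT IC50 strictly below threshold.

    The WT score never affects retention.  ``paired`` must carry a
    ``mutant_offset`` column (see ``binding.attach_mutant_offsets`` for
    parsed prediction files).
    """
    if threshold_nm <= 0:
        raise InputError(f"binding threshold must be positive, got {threshold_nm}")
    if "mutant_offset" not in paired.columns:
        raise InputError("paired table lacks mutant_offset; attach it before filtering")
    localized = [
        is_localized(int(s), int(k), int(m))
        for s, k, m in zip(paired["start_offset"], paired["k"], paired["mutant_offset"])
    ]
    keep = pd.Series(localized, index=paired.index) & (paired["mt_ic50_nm"] < threshold_nm)
    return paired[keep].reset_index(drop=True)


def select_best_candidates(filtered: pd.DataFrame) -> pd.DataFrame:
    """One row per variant: minimum MT IC50 across alleles, lengths and
    starts, with the documented deterministic tie-break (smaller k, then
    allele string order, then smaller start offset)."""
    if filtered.empty:
        return filtered.copy()
    ordered = filtered.sort_values(
        ["variant_id", "mt_ic50_nm", "k", "hla_allele", "start_offset"],
        kind="mergesort",
    )
    return ordered.groupby("variant_id", as_index=False, sort=True).head(1).reset_index(
        drop=True
    )


def select_best_candidate(filtered_one_variant: pd.DataFrame) -> pd.Series:
    """Best row for a single variant's filtered predictions."""
    if filtered_one_variant.empty:
        raise InputError("no filtered rows for this variant")
    if filtered_one_variant["variant_id"].nunique() != 1:
        raise InputError("select_best_candidate expects rows of a single variant")
    return select_best_candidates(filtered_one_variant).iloc[0]
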