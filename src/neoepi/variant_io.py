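"""Read, validate and normalize the annotated missense-variant table.

The pipeline's atomic input is one missense SNV per row, annotated with the
protein-level change (e.g. ``p.V600E``) and the full wild-type protein
sequence of the affected transcript.  Those two pieces — amino-acid change
and transcript protein sequence — are all that downstream peptide windowing
needs; genomic coordinates are carried along for the coverage join.

Coordinate conventions: protein positions are 1-based (so ``V600E`` means
residue 600 of the protein is V in the wild type), and genomic ``pos`` is
1-based.

Input TSV columns (tab-separated, UTF-8, ``#`` comment lines ignored):
``variant_id, chrom, pos, ref, alt, gene, transcript_id, protein_change,
wt_protein_seq``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residues accepted in a wild-type protein sequence at load time.  'X'
#: (unknown) and 'U' (selenocysteine) are tolerated here but any peptide
#: window overlapping them is excluded later — binding predictors do not
#: score them reliably.
ALLOWED_PROTEIN_AA = STANDARD_AA | frozenset("XU")

REQUIRED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript_id",
    "protein_change",
    "wt_protein_seq",
]

_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")
# Patterns that indicate a parseable but unsupported (non-missense) change.
_NON_MISSENSE_RE = re.compile(r"fs|del|ins|dup|\*|ext", re.IGNORECASE)


@dataclass(frozen=True, slots=True)
class AnnotatedVariant:
    """One missense SNV with its protein change and WT protein sequence."""

    variant_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    gene: str
    transcript_id: str
    wt_residue: str
    protein_pos: int
    mt_residue: str
    wt_protein_seq: str
    variant_type: str = field(default="missense")

    @property
    def protein_change(self) -> str:
        return f"p.{self.wt_residue}{self.protein_pos}{self.mt_residue}"


def parse_protein_change(change: str) -> tuple[str, int, str]:
    """Split a protein-change string like ``p.V600E`` or ``G12D``.

    Returns ``(wt_residue, protein_pos, mt_residue)`` with a 1-based
    position.  Synonymous changes (WT == MT) are rejected because only
    missense variants can yield a mutant peptide, and recognizably
    non-missense notations (frameshift, stop, indel) are rejected as
    unsupported variant types.
    """
    m = _CHANGE_RE.match(change.strip())
    if m is None:
        if _NON_MISSENSE_RE.search(change):
            raise ParseError(
                f"unsupported variant type (only missense is supported): {change!r}"
            )
        raise ParseError(f"malformed protein change: {change!r}")
    wt, pos, mt = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1:
        raise ParseError(f"protein position must be positive: {change!r}")
    if wt == mt:
        raise ParseError(f"synonymous change is not missense: {change!r}")
    return wt, pos, mt


def _validate_row(row: pd.Series) -> AnnotatedVariant:
    wt, pos, mt = parse_protein_change(str(row["protein_change"]))
    seq = str(row["wt_protein_seq"]).strip().upper()
    bad = set(seq) - ALLOWED_PROTEIN_AA
    if bad:
        raise ValidationError(
            f"{row['variant_id']}: protein sequence contains invalid "
            f"residues {sorted(bad)}"
        )
    if not 1 <= pos <= len(seq):
        raise ValidationError(
            f"{row['variant_id']}: protein position {pos} outside protein "
            f"of length {len(seq)}"
        )
    observed = seq[pos - 1]
    if observed != wt:
        raise ValidationError(
            f"{row['variant_id']}: residue mismatch at protein position "
            f"{pos}: expected {wt!r} from protein change, observed "
            f"{observed!r} in wt_protein_seq"
        )
    return AnnotatedVariant(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref_base=str(row["ref"]),
        alt_base=str(row["alt"]),
        gene=str(row["gene"]),
        transcript_id=str(row["transcript_id"]),
        wt_residue=wt,
        protein_pos=pos,
        mt_residue=mt,
        wt_protein_seq=seq,
    )


def read_annotated_variants(path: str | Path, strict: bool = True) -> list[AnnotatedVariant]:
    """Load the annotated variant TSV.

    In strict mode any invalid row raises; in lenient mode invalid rows are
    dropped with a logged reason.  Duplicate ``variant_id`` values are an
    error in both modes — they would silently collide downstream.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    dup = df["variant_id"][df["variant_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate variant_ids: {sorted(set(dup))}")
    variants: list[AnnotatedVariant] = []
    for _, row in df.iterrows():
        try:
            variants.append(_validate_row(row))
        except (ParseError, ValidationError) as exc:
            if strict:
                raise
            logger.warning("dropped variant %s: %s", row.get("variant_id"), exc)
    return variants


def variants_to_frame(variants: list[AnnotatedVariant]) -> pd.DataFrame:
    """Render variants back into the input TSV schema (round-trip safe)."""
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref_base for v in variants],
            "alt": [v.alt_base for v in variants],
            "gene": [v.gene for v in variants],
            "transcript_id": [v.transcript_id for v in variants],
            "protein_change": [v.protein_change for v in variants],
            "wt_protein_seq": [v.wt_protein_seq for v in variants],
        }
    )


def write_annotated_variants(variants: list[AnnotatedVariant], path: str | Path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)
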