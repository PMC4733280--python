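"""Build paired WT/MT peptide windows and write the FASTA + key file.

For each missense variant we cut a window of the wild-type protein centered
on the mutated residue with ``flank`` residues on each side (default 10,
giving a 21-mer), then substitute the mutant residue to obtain the tumor
sequence.  When the mutation sits within ``flank`` residues of either
protein terminus the window cannot be centered, so the deficient side is
compensated by extending the other side until the window again has
``2*flank + 1`` residues (or the whole protein, if shorter).

Window construction, with protein length L, mutation position p (1-based)
and flank f::

    start = max(1, p - f); end = min(L, p + f)
    if end - start + 1 < 2f + 1:
        start = max(1, end - 2f)
        end   = min(L, start + 2f)

This symmetric-extend formula is normative for this package: a mutation at
position 1 yields the mutant residue plus the succeeding 2f residues, and a
mutation at the C-terminus the preceding 2f residues plus the mutant.

Epitope prediction software strips FASTA headers from its output, so a key
file records the order, header and WT/MT class of every FASTA record; the
parser uses it to re-associate predictions with their variant.  The WT
record of a pair always immediately precedes its MT record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ValidationError
from .variant_io import STANDARD_AA, AnnotatedVariant

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10

KEY_COLUMNS = ["record_index", "header", "variant_id", "class"]


@dataclass(frozen=True, slots=True)
class PeptidePair:
    """The WT and MT peptide windows for one variant.

    ``mutant_offset`` is the 1-based position of the mutated residue within
    the window; ``window_start`` is the 1-based protein coordinate of the
    window's first residue.
    """

    variant_id: str
    wt_window: str
    mt_window: str
    mutant_offset: int
    window_start: int
    flank: int


@dataclass(frozen=True, slots=True)
class ReconstructedPair:
    """A pair read back from FASTA + key; window coordinates in the source
    protein are not recoverable from those files, only the windows, the
    mutant offset and the WT/MT labels."""

    variant_id: str
    wt_window: str
    mt_window: str
    mutant_offset: int


def build_peptide_window(
    protein: str,
    protein_pos: int,
    mt_residue: str,
    flank: int = DEFAULT_FLANK,
    variant_id: str = "",
) -> PeptidePair:
    """Cut the WT window around ``protein_pos`` and substitute the mutant.

    Raises if ``protein_pos`` is out of range or the substitution would be
    synonymous; exclusion of windows overlapping non-standard residues is
    the caller's responsibility (see :func:`build_pairs`).
    """
    L = len(protein)
    if not 1 <= protein_pos <= L:
        raise ValidationError(
            f"protein position {protein_pos} outside protein of length {L}"
        )
    if flank < 1:
        raise ValidationError(f"flank must be >= 1, got {flank}")
    if protein[protein_pos - 1] == mt_residue:
        raise ValidationError(
            f"synonymous substitution at position {protein_pos}"
        )
    start = max(1, protein_pos - flank)
    end = min(L, protein_pos + flank)
    if end - start + 1 < 2 * flank + 1:
        start = max(1, end - 2 * flank)
        end = min(L, start + 2 * flank)
    wt_window = protein[start - 1 : end]
    offset = protein_pos - start + 1
    mt_window = wt_window[: offset - 1] + mt_residue + wt_window[offset:]
    return PeptidePair(
        variant_id=variant_id,
        wt_window=wt_window,
        mt_window=mt_window,
        mutant_offset=offset,
        window_start=start,
        flank=flank,
    )


def build_pairs(
    variants: list[AnnotatedVariant], flank: int = DEFAULT_FLANK
) -> tuple[list[PeptidePair], list[tuple[str, str]]]:
    """Build windows for all variants, excluding those whose window (WT or
    MT) contains a residue outside the 20 standard amino acids.

    Returns ``(pairs, skipped)`` where ``skipped`` is a list of
    ``(variant_id, reason)``.
    """
    pairs: list[PeptidePair] = []
    skipped: list[tuple[str, str]] = []
    for v in variants:
        pair = build_peptide_window(
            v.wt_protein_seq, v.protein_pos, v.mt_residue, flank, v.variant_id
        )
        nonstd = (set(pair.wt_window) | set(pair.mt_window)) - STANDARD_AA
        if nonstd:
            reason = f"window overlaps non-standard residue(s) {sorted(nonstd)}"
            logger.warning("excluded %s: %s", v.variant_id, reason)
            skipped.append((v.variant_id, reason))
            continue
        pairs.append(pair)
    return pairs, skipped


def write_fasta_and_key(
    pairs: list[PeptidePair], fasta_path: str | Path, key_path: str | Path
) -> int:
    """Write two FASTA records per pair (WT first, then MT) plus the key.

    Headers are ``{variant_id}.WT`` / ``{variant_id}.MT``; sequences wrap at
    60 columns.  Returns the number of FASTA records written.
    """
    if not pairs:
        raise InputError("no peptide pairs to write")
    ids = [p.variant_id for p in pairs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate variant_ids in pairs: {dup}")
    records = []
    key_rows = []
    for pair in pairs:
        for cls, window in (("WT", pair.wt_window), ("MT", pair.mt_window)):
            header = f"{pair.variant_id}.{cls}"
            records.append(SeqRecord(Seq(window), id=header, description=""))
            key_rows.append(
                {
                    "record_index": len(key_rows),
                    "header": header,
                    "variant_id": pair.variant_id,
                    "class": cls,
                }
            )
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(key_rows, columns=KEY_COLUMNS).to_csv(key_path, sep="\t", index=False)
    return len(records)


def read_key(key_path: str | Path) -> pd.DataFrame:
    key = pd.read_csv(key_path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in KEY_COLUMNS if c not in key.columns]
    if missing:
        raise InputError(f"{key_path}: key file missing columns {missing}")
    return key


def read_fasta_and_key(
    fasta_path: str | Path, key_path: str | Path
) -> list[ReconstructedPair]:
    """Re-read a FASTA + key pair written by :func:`write_fasta_and_key`.

    Reconstructs each variant's WT/MT windows and the mutant offset (the
    single position where the two windows differ).
    """
    key = read_key(key_path)
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    if len(seqs) != len(key):
        raise InputError(
            f"FASTA has {len(seqs)} records but key lists {len(key)}"
        )
    by_variant: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for idx, row in key.iterrows():
        vid, cls = str(row["variant_id"]), str(row["class"])
        if vid not in by_variant:
            by_variant[vid] = {}
            order.append(vid)
        by_variant[vid][cls] = seqs[int(row["record_index"])]
    out = []
    for vid in order:
        wt, mt = by_variant[vid]["WT"], by_variant[vid]["MT"]
        diffs = [i for i, (a, b) in enumerate(zip(wt, mt)) if a != b]
        if len(wt) != len(mt) or len(diffs) != 1:
            raise InputError(f"{vid}: WT/MT windows do not differ at exactly one site")
        out.append(ReconstructedPair(vid, wt, mt, diffs[0] + 1))
    return out
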