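# Methods

## Scope and model

`neoepi` prioritizes candidate neoepitopes arising from missense somatic
SNVs only. Frameshifts, stop gains/losses, splice variants and fusions can
also create neoantigens but change the peptide sequence in ways a
single-residue window substitution cannot represent; they are out of scope.
The pipeline assumes annotation has already happened upstream: each input
row carries the protein change and the full WT transcript protein
sequence, which together are sufficient to build both peptide windows.
Multiple transcripts of one genomic variant are handled as separate rows
with distinct variant ids.

## Peptide windows

The window is `flank` residues (default 10) on each side of the mutated
residue. Near a terminus the deficient side is compensated by extending
the other side (`start = max(1, end − 2f)`, then `end = min(L, start +
2f)`), so the window keeps length `2f + 1` whenever the protein allows it
and every possible mutant-containing k-mer up to k = 2f + 1... is
enumerable from it; a protein shorter than the full window yields the
whole protein. This symmetric-extend formula is the package's normative
edge rule. `flank` is configurable (`--flank`); 10 covers the standard
8–11-mer class I lengths with margin.

The WT record precedes its MT record in the FASTA, and the key file
(record index → variant id, WT/MT) makes the order immaterial downstream —
epitope prediction tools strip FASTA headers from their output, so the key
file is the only way to re-associate predictions with variants.

Windows overlapping `X` (unknown) or `U` (selenocysteine) are excluded
with a logged reason rather than scored: binding predictors do not handle
non-standard residues reliably, and silently scoring them would
contaminate the candidate list. The variants themselves are accepted at
load so the exclusion is visible in stage counts.

## Binding predictions

The predictor is a plug-in: any callable `(peptide, allele) → IC50 nM`.
The shipped mock predictor hashes `(peptide, canonical allele, seed)` with
BLAKE2b and maps the 64-bit digest log-uniformly onto [1, 50000] nM. It is
not a binding model — it exists so every downstream stage (pairing,
localization, thresholding, best-candidate selection, integration) is
exercisable deterministically and its statistics are known in closed form:
the expected fraction of peptides under a threshold t is
`log(t)/log(50000)` (≈ 0.574 at 500 nM). Real predictions enter through
the prediction-file parser (tab-separated `record_index, start_offset,
peptide, allele, ic50_nm`), which validates record indices against the key
file and fails on malformed lines with their line number.

Allele names are canonicalized to the `HLA-A02:01` form (accepting
`HLA-A*02:01` and `A0201`) and validated against an allow-list up front,
because external predictors support finite allele sets and a late failure
after hours of scoring is worse than an early one.

## Candidate filtering

All thresholds follow their conventional printed inequality directions
exactly, because candidates sit on these boundaries in practice:

| parameter | default | semantics |
|---|---|---|
| binding threshold | 500 nM | keep MT IC50 **strictly less than** |
| normal coverage | 5× | remove when depth **≤** 5 |
| normal VAF | 2% | remove when VAF **≥** 0.02 |
| tumor coverage | 10× | keep when depth **≥** 10, per required track |
| tumor VAF | 40% | keep when VAF **≥** 0.40, per required track |
| FPKM | 1.0 | keep when **strictly greater** |

VAFs are fractions internally; the CLI accepts percentages where flagged.
The tumor VAF default targets founder-clone mutations; lowering it admits
subclonal variants. The normal-sample conditions are implemented as two
*independent* disqualifiers — shallow normal coverage cannot establish the
variant's absence from the germline, and elevated normal VAF suggests a
germline variant or tumor contamination — each with its own reason code so
the choice is auditable.

Missingness is data: a candidate lacking a value a filter needs is removed
with reason `insufficient data (<track>)` or `no expression data`, never
zero-filled and never silently kept. Missing normal-DNA evidence also
removes (the germline status is simply unknown); this is the conservative
reading of an underdetermined case. Every removed candidate carries
exactly one first-failing reason, so kept + removed partitions the input
and the filters commute on the kept set.

The WT affinity and the fold change (WT IC50 / MT IC50, with log2) are
reported but never filter: a strong WT binder does not disqualify a strong
MT binder. When the WT partner is missing the fold change is missing, not
imputed.

Best-candidate selection takes the global minimum mutant IC50 across
lengths, alleles and start offsets. Exact ties are possible with file-based
predictors of limited precision; the tie-break (smaller k, then allele
string order, then smaller start offset) is arbitrary but fixed, chosen for
reproducibility. Both the full filtered table and the best-per-mutation
table are emitted: experimental validation typically wants the full list.
`--restrict-allele`-style per-allele selection is not implemented; filter
the full table instead.

## Somatic filter rule engine

The three rule sets (5 retention rules for pileup calls, 9 read-support
retention rules, 4 removal rules for VarScan calls) operate on a per-site
metrics table, not on alignments — computing the metrics is the job of
bam-readcount-class tools. Boundary semantics are literal: "more than four
reads" means ≥ 5, "greater than 0.07" removes at 0.0701, and the
"less than 1 × 10^9 reads" depth ceiling is implemented literally even
though it is effectively unbounded. The pileup rule "consensus and SNP
quality ≥ 20" is read as both qualities ≥ 20. The strand rule "≥ 1% of
variant allele support from each strand" is read as each strand
contributing ≥ 1% of *variant-supporting* reads (the sentence admits a
reads-overall reading; the variant-support reading is the stricter and
more common one). The VarScan set has removal polarity: its four
conditions are joined by OR and a site passes only when none fires.

## Synthetic cohort

The generator emulates the *shape* of a tumor/normal exome + tumor RNA
study, not reads: uniform-residue proteins (lengths 30–800), 200 missense
variants with 20% placed within the flank of a terminus (to exercise the
edge rule), negative-binomial depths (dispersion 10) around 40× normal and
80× tumor means, per-site somatic VAF beta-distributed around 0.5
(founder clone), a 10% planted germline-contamination fraction (normal VAF
≈ 50%, which the normal-VAF filter must catch), and log-normal FPKM
(μ = 2, σ = 1.5 on the log scale, median ≈ 7.4) with 30% of genes planted
at exactly 0 and a silent RNA track. One seed drives everything through
fixed numpy seed-sequence streams (`default_rng([seed, stream_id])`), so
fixtures are reproducible per generator and across platforms.

What passing the planted-truth test shows: the pipeline's composition of
window construction, mock scoring, localization, thresholding and the
depth/expression filters equals an independently coded oracle on these
inputs. What it does not show: performance on real data — no sequencing
error, mappability bias, annotation error, HLA frequency structure or
predictor accuracy is modeled.

## Numerical and I/O choices

Affinities are plain floats in nM; no percentile ranks are used, since all
thresholds here are in nM. Output tables are sorted on stable keys and
floats rendered with `%.6g`, making re-runs byte-identical (tested).
Degenerate inputs are defined rather than accidental: depth 0 gives a
missing VAF; a window shorter than k enumerates no k-mers; a variant with
no surviving peptide is absent from the candidate list (not an error); an
empty prediction file parses to an empty table.

## Known limitations

- Only missense SNVs; no indel/fusion/splice windows.
- No immunogenicity, TCR-recognition or manufacturability modeling; IC50
  binding is the only peptide-level criterion.
- The mock predictor carries no biology; conclusions about real epitopes
  require an external predictor's output.
- FPKM-based expression filtering inherits FPKM's length/depth biases; no
  spike-in normalization or sample-specific cutoff estimation.
- The rule engine trusts the supplied site metrics; it does not recompute
  them from alignments.
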