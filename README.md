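# neoepi

Genome-guided prioritization of candidate tumor neoepitopes from annotated
missense somatic variants.

## The problem

Tumors accumulate somatic mutations; a missense SNV changes one amino acid
in a protein, and the resulting mutant peptide — absent from normal cells —
can be presented by the patient's HLA class I molecules and recognized by
CD8+ T cells as a *neoantigen*. Personalized cancer vaccines need a short,
high-confidence list of such peptides, but raw epitope prediction over a
patient's hundreds of mutations produces tens of thousands of calls.
`neoepi` automates the narrowing: it builds paired wild-type/mutant peptide
windows, scores every 8–11-mer against the patient's HLA alleles, and
filters candidates on binding strength, mutant localization, sequencing
evidence and expression. It is written for bioinformaticians working
downstream of a somatic variant-calling and annotation pipeline.

## Method

For each missense variant at protein position *p* with flank *f* (default
10), a window of the WT protein is cut as

```
start = max(1, p − f);  end = min(L, p + f)
if end − start + 1 < 2f + 1:   # mutation near a terminus
    start = max(1, end − 2f);  end = min(L, start + 2f)
```

and the mutant residue substituted, giving paired 21-mers (WT, MT). Every
k-mer (k = 8..11) of both windows is scored against every patient HLA
class I allele by a pluggable predictor returning an IC50 affinity in nM
(lower = stronger binder). Candidates are then:

1. **localized** — the k-mer must contain the mutated residue (otherwise it
   is identical to a WT peptide);
2. **binders** — mutant IC50 strictly < 500 nM (configurable);
3. **paired** — the WT peptide at the same coordinates is reported with the
   fold change FC = IC50(WT) / IC50(MT) (informational, never a filter);
4. **best per mutation** — the single row with the lowest mutant IC50
   across all lengths and alleles (ties: smaller k, then allele name, then
   smaller start offset);
5. **supported by sequencing** — removed if normal coverage ≤ 5× or normal
   VAF ≥ 2% (germline suspicion); kept only if each required tumor track
   (DNA, and RNA when provided) has depth ≥ 10× and VAF ≥ 40% (founder
   clone); kept only if gene FPKM > 1 (expressed).

A separate rule engine implements three standard post-calling somatic
filter sets (5 + 9 + 4 printed rules) over per-site read metrics, with
per-rule violation codes for auditability. A synthetic cohort generator
emulates every input with planted truth, so the full pipeline is testable
with no patient data and no licensed predictor.

## Worked example

```
neoepi simulate --seed 7 --n-variants 50 --outdir demo
neoepi run --variants demo/variants.tsv --coverage demo/coverage.tsv \
    --expression demo/expression.tsv \
    --allele HLA-A02:01 --allele HLA-B07:02 --seed 7 --outdir demo/out
```

prints the per-stage counts:

```
input_rows	50
accepted_missense_variants	50
peptide_pairs	50
windows_excluded_nonstandard	0
fasta_records	100
raw_predictions	10000
paired_predictions	5000
binding_filtered	1899
variants_with_binding_candidate	50
after_depth_filter	25
final_candidates	23
```

Reading the funnel: 50 missense variants give 100 FASTA records (one WT and
one MT 21-mer each) and 10,000 raw affinity calls (2 windows × 2 alleles ×
k = 8..11 k-mers per window); 1,899 localized mutant peptides bind under
500 nM, covering all 50 variants; the depth filters (normal/tumor coverage
and VAF) cut those to 25 mutations and the FPKM > 1 expression filter to a
final 23. `demo/out/best_candidates.tsv` holds one best epitope per kept
mutation, e.g.

```
variant_id  hla_allele  k   start_offset  mt_peptide   mt_ic50_nm  wt_ic50_nm  fold_change
var0004     HLA-B07:02  11  8             YHKVYGSPYWM  1.39        3758.96     2697.32
```

— an 11-mer on HLA-B07:02 predicted to bind ~2,700-fold more strongly than
its wild-type counterpart. (These demo affinities come from the built-in
deterministic mock predictor; plug in a real predictor's output file via
`neoepi run --predictions ...` for production use.)

## Layout

- `neoepi.variant_io` — annotated-variant TSV reading and validation
- `neoepi.fasta_gen` — peptide windows, FASTA + key file
- `neoepi.binding` — k-mer enumeration, mock predictor, prediction-file parser
- `neoepi.epitope_filter` — WT/MT pairing, binding filter, best-candidate selection
- `neoepi.coverage_expression` — depth/VAF/FPKM integration and filters
- `neoepi.somatic_filters` — the three rule sets over site metrics
- `neoepi.synthetic` — synthetic cohort generator with planted truth
- `neoepi.pipeline`, `neoepi.cli` — orchestration and the `neoepi` command

See `docs/methods.md` for the modeling choices and their rationale.
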