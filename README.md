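# apaseq

PolyA-site mapping and differential alternative-polyadenylation (APA)
analysis for 3'-end direct-RNA-sequencing (DRS) data.

Most human genes carry more than one polyadenylation site, and shifting
cleavage from a distal to a proximal site shortens the mRNA — either
trimming the 3'UTR (UTR-APA, removing miRNA target sites and stabilizing
the transcript) or truncating the coding region (CR-APA, yielding
C-terminally truncated proteins).  Tumors often show exactly this proximal
shift.  `apaseq` implements the full analysis for the study design in which
a small tumor group (three samples) is contrasted against a single
reference sample using DRS read 3'-ends:

1. **Read QC** (`apaseq.readqc`) — leading-T trimming for raw sequences;
   uniquely mapped reads with length ≥ 21 nt and score ≥ 4; removal of
   internal-priming artifacts, i.e. reads whose 10-nt genomic context
   immediately 3' of the cleavage position starts with ≥ 6 adenines on the
   transcript strand.
2. **Site calling** (`apaseq.cluster`) — single-linkage clustering of read
   ends < 24 nt apart per (chromosome, strand), pooled across samples; the
   site coordinate is the read-weighted median of the cluster; a site is
   retained if it has ≥ 1 read in ≥ 2 samples or ≥ 2 reads in total.
3. **Annotation** (`apaseq.annotate`) — each site is classified as 5UTR /
   CODING / 3UTR / ncGENE / PROMOTER / DOWNSTREAM / INTERGENIC
   (strand-matched, ±1 kb flanks); intronic positions in the coding region
   are CODING because their usage truncates the ORF; sites ≤ 1 kb
   downstream are attributed to the upstream gene.
4. **APA statistics** (`apaseq.stats`) — per protein-coding gene, a
   samples × sites contingency table over the sites reaching ≥ 10% of the
   gene's reads in at least one sample.  For every pair of samples a
   two-sided Fisher exact test is run on the 2 × C table (full enumeration
   over fixed-margin tables when feasible, seeded Monte-Carlo otherwise).
   With tumor samples *T*₁..₃ and reference *R*, and Benjamini–Hochberg
   q-values computed per pair across genes, a gene is called
   **tumor-specific APA** iff

   q(*Tᵢ*, *Tⱼ*) > 0.1 for all tumor pairs  and  q(*Tᵢ*, *R*) < 0.1 for all *i*.

5. **Curation** (`apaseq.curation`) — five ordered removal rules
   (tandem-transcript signal, overlapping gene, implicated sites with < 10
   reads in 2/3 tumors, distal site dominant in the tumors, proximal site
   dominant in the reference) reduce the significant list to genuine
   tumor-specific 3'-truncation.
6. **Downstream** — miRNA target-site loss in the truncated 3'UTR interval
   intersected with tumor-expressed miRNAs (`apaseq.mirna`), and qPCR
   ΔCt isoform ratios with outlier-robust triplicate medians and
   reference-sample normalization (`apaseq.qpcr`).

`apaseq.simulate` generates fully synthetic fixture bundles (genome FASTA,
GTF, per-sample read-end BED, miRNA targets, ground truth) with planted
proximal shifts, cleavage jitter and internal-priming decoys, so every
stage can be validated against known truth.

## Worked example

```python
from apaseq import SimConfig, run_pipeline_on_bundle
from apaseq.simulate import generate_bundle
from apaseq.pipeline import recovery_metrics
from apaseq.annotate import category_report

bundle = generate_bundle(SimConfig(n_genes=100, seed=42))
result = run_pipeline_on_bundle(bundle)

print(result.qc_stats)
print(category_report(result.annotated))
print("significant:", len(result.significant_genes),
      "curated:", len(result.curated_genes))
print(recovery_metrics(bundle, result))
```

prints

```
{'input': 118478, 'failed_mapping': 0, 'internal_priming': 5804, 'kept': 112674}
            n_sites  mean_reads
category
3UTR            235  375.119149
CODING           35  414.457143
DOWNSTREAM       35  286.142857
significant: 9 curated: 9
{'n_planted': 9, 'n_null': 91, 'n_called': 9, 'sensitivity': 1.0, 'false_call_rate': 0.0}
```

All 5,804 reads relocated to planted A-rich decoys are removed by the
internal-priming filter (4.9% of input, none of the true-site reads); the
called sites classify into the planted categories; and the nine genes with
a planted proximal shift — and no others — are called significant and
survive curation.  A verdict exposes the six pairwise q-values, e.g. for
`gene0007`:

```
{'NE_MTT|NE_CT1': 0.8734, 'NE_MTT|NE_2TC': 0.7578, 'NE_CT1|NE_2TC': 0.9613,
 'NE_MTT|PIT': 0.0, 'NE_CT1|PIT': 0.0, 'NE_2TC|PIT': 0.0}
```

— the tumor group is homogeneous while every tumor differs from the
reference, the signature of tumor-specific APA.

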