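# chromlink

Integrative analysis of DNA hypermethylation, chromatin-accessibility
loss, TAD co-occurrence and Hi-C contacts — with a seeded synthetic-data
generator so every stage is verifiable end-to-end.

## The problem

In the neonatal mouse liver, a brief burst of locally produced thyroid
hormone (T3) helps finalize the epigenetic programming of hepatocytes.
When that burst is removed (liver-specific *Dio2* knockout), the adult
liver carries ~1,500 CpG hypermethylation sites (**H-sites**), thousands
of regions of reduced chromatin accessibility (**RCAs**) at promoters and
intergenic enhancers, and ~1,400 downregulated genes. Linking these
layers requires a chain of genomic-interval and statistical operations:
differential peak subtraction, genomic-context annotation, chromatin-state
classification, proximity statistics, a TAD-level contingency test and
Hi-C contact mining. `chromlink` packages that chain as a reusable,
tested pipeline for anyone analyzing paired condition ATAC/ChIP/RNA/Hi-C
data with interval-level bookkeeping requirements.

## What it computes

* **RCA calling** — control-condition ATAC peaks with no knockout-peak
  overlap (whole-peak subtraction); annotation into promoter (±200 bp of
  a TSS) / exon / intron / intergenic, yielding **p-RCAs** and **i-RCAs**.
* **Chromatin-state classification** — per-region TPM
  (TPM_i = (c_i/L_i)/Σ_j(c_j/L_j) × 10⁶) of H3K4me3, H3K4me1 and ATAC;
  a gated rule (TPM > 4; ratio thresholds 1.5 and 0.67; ATAC vs H3K4me1)
  assigns promoter / weak-promoter / enhancer / insulator / weak-insulator,
  and insulators are sub-typed CAC (CTCF + cohesin) or CNC (cohesin only).
* **HH-sites** — H-sites embedded in knockout-only H3K9me3 peaks
  (−log10 p > 2), with flanking counts of T3-bound vs unoccupied thyroid
  receptor peaks within 10 kbp.
* **Pairing** — p-RCAs within 5 kbp of a downregulated gene body
  (|fold| > 1.2, p < 0.05, down), the *p-RCA:n-RNA-seq* configuration.
* **Association statistics** — per-chromosome feature densities with
  Spearman correlations (exact permutation p for ≤ 9 chromosomes), and
  the TAD co-occurrence 2×2 test: χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
  uncorrected, 1 df, with odds ratio ad/bc.
* **Hi-C mining** — intra-chromosomal contacts at separations 1 kbp–10 Mbp;
  anchors within 1 kbp of a paired p-RCA become *areas-1*, their partners
  *areas-2*, profiled for i-RCAs and H-sites within 50 kbp and joined back
  to genes.
* **Synthetic data** — a seeded generator that plants all of the above
  structure (pairings, classes, embeddings, contacts, TAD odds ratio) and
  writes a ground-truth manifest for exact recovery testing.

## Worked example

```python
from chromlink import SimConfig, generate, PipelineConfig, run

paths, manifest = generate(SimConfig(seed=1), "sim")        # synthetic inputs
summary = run(PipelineConfig.from_simulated(paths, "out"))  # full pipeline

print("RCAs:", summary["rca"]["n_rca"], summary["rca"]["by_category"])
print("pairing:", summary["pairing"])
print("insulators:", summary["insulators"])
```

prints

```
RCAs: 4977 {'promoter': 1551, 'exon': 495, 'intron': 505, 'intergenic': 2426}
pairing: {'n_downregulated': 1363, 'n_pairs': 154, 'n_unique_genes': 146, 'n_unique_prcas': 154}
insulators: {'n_paired_insulators': 34, 'n_cac': 30, 'n_cnc': 4, 'n_neither': 0}
```

i.e. the pipeline recovered exactly the planted structure: 4,977 RCAs of
which 1,551 annotate to promoters and 2,426 to intergenic space; 154
promoter-RCA/gene pairs over 146 downregulated genes; and the 30 CAC + 4
CNC insulator layout. On the same run the TAD co-occurrence table
(249/143/222/1,108 over 1,722 TADs) gives χ² = 334.1 (odds ratio 8.7) and
the 250 mined area-1 contacts average a 310 kbp area-1↔area-2 separation.
The desk-scale recomputation from the published per-TAD totals,

```python
from chromlink import CooccurrenceTable, chi_square_2x2
chi_square_2x2(CooccurrenceTable(278, 194, 399, 2667))
```

returns χ² = 556.5 (p = 4.7e-123, odds ratio 9.58).

The same stages are available from the shell:

```bash
chromlink simulate --seed 1 --outdir sim
chromlink rca-detect --genome sim/genome.tsv --control sim/atac_control.bed \
    --case sim/atac_ko.bed --out rca.bed
chromlink tad-test --genome sim/genome.tsv --tads sim/tads.bed \
    --set-a prcas.bed --set-b ircas.bed
```

## Layout

```
src/chromlink/
  genome.py      chromosome table, heat-map row ordering
  intervals.py   interval model, BED I/O, overlap/subtract/nearest/window ops
  annotation.py  gene models, promoter/exon/intron/intergenic labels, DE table
  rca.py         TPM, five-way classification, CAC/CNC sub-typing
  proximity.py   anchored matrices, distance-bracket histograms
  stats.py       densities, Spearman, pairing, TAD 2x2 chi-square
  hic.py         BEDPE contacts, area-1/area-2 mining
  simulate.py    synthetic-data generator + ground-truth manifest
  pipeline.py    end-to-end orchestration, report bundle
  cli.py         `chromlink` command-line interface
docs/methods.md  model, conventions, generator design, limitations
```
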