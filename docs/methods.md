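# Methods

## The analysis

`chromlink` re-implements, as a tested pipeline, an integrative chromatin
analysis of a mouse liver model in which a transient neonatal loss of local
thyroid-hormone (T3) signaling leaves permanent epigenetic marks. The
observable layers, and the operations that connect them, are:

* **H-sites** — CpG DNA hypermethylation sites called in the knockout adult
  liver methylome (consumed as BED input; methylome calling is out of scope).
* **HH-sites** — H-sites embedded (>= 1 bp overlap) in H3K9me3-enriched
  regions present only in the knockout neonatal chromatin, after filtering
  differential peaks to -log10(p) > 2 (strict inequality).
* **RCAs** — regions of reduced chromatin accessibility: open-chromatin
  (ATAC) peaks present in the control condition with no overlapping peak in
  the knockout. Subtraction is peak-level: a control peak is retained whole
  or dropped, never truncated.
* **p-RCA / i-RCA** — RCAs annotated to a core promoter (within 200 bp of a
  TSS) or to intergenic space. Annotation assigns exactly one label per
  region with precedence promoter > exon > intron > intergenic. A second,
  1 kbp promoter window coexists for methylation-site/promoter calls; each
  stage names which window it uses.
* **p-RCA:n-RNA-seq pairs** — p-RCAs within 5 kbp (closed bound, edge-to-
  edge) of a downregulated gene's reduced-expression region. Downregulation
  means fold change strictly below -1.2 with p strictly below 0.05. The
  reduced-expression region is proxied by the annotated gene body: the
  source analyses pair p-RCAs with "negative RNA-seq peaks" without defining
  how a coverage-dip peak is delimited, so the gene body is the defensible
  operationalization; outputs are flagged accordingly.
* **TAD co-occurrence** — every TAD is scored for overlap (any >= 1 bp; a
  containment variant is exposed as a flag) with p-RCAs and with i-RCAs; the
  2x2 table (both / A-only / B-only / neither) is tested with an
  **uncorrected** Pearson chi-square on 1 df. No continuity correction: the
  uncorrected statistic reproduces the reference computation on the printed
  counts (556.5 from cells 278/194/399/2667; Yates gives ~554). A second
  published statistic for a 146-gene subset (chi2 = 777 from cells
  81/51/131) cannot be reproduced from printed counts with any stated total
  (N = 3538 gives ~746) and is therefore reported nowhere.
* **Area-1 / area-2 mining** — significant intra-chromosomal Hi-C contacts
  are midpoint-canonicalized, deduplicated, and filtered to separations in
  [1 kbp, 10 Mbp] (both bounds inclusive). An anchor within 1 kbp
  (<= 1000 bp edge distance) of a paired p-RCA becomes an area-1; its
  partner is the area-2, profiled for i-RCAs and H-sites within a 50 kbp
  window (strictly < 50 kbp, following the source criterion's wording).
  Both anchors are eligible; a contact matching p-RCAs at both ends yields
  two hits (a `both_anchors=False` flag restricts to anchor 1).

## Coordinate conventions

Coordinates are 0-based half-open throughout (BED native); `[a, b)` and
`[b, c)` never overlap. All distances are edge-to-edge gaps in bp, 0 for
overlapping or touching intervals. Strand is carried through I/O but
ignored by overlap and distance logic; it matters only for locating the
TSS. Heat-map (anchored-matrix) binning uses interval midpoints — peaks
are centered in the source figures — while bracket histograms use edge
gaps; the mix is deliberate and matches the respective figure semantics.
Bracket boundaries default to (1, 5, 50, 500, 1000) kbp, reconstructed
from the brackets named across the source distance figures, and are fully
configurable. Distance 0 falls in the lowest bracket (closed on the left).
Matrix rows follow the source's chromosome ordering (chr1–9, chrX,
chr10–19) when the genome is mouse-like, otherwise genome-file order.

## RCA classification

Signals over the RCA region set are normalized as transcripts per kilobase
million: `TPM_i = (c_i / L_i[kb]) / sum_j (c_j / L_j[kb]) * 1e6`, so each
track sums to 1e6 over the set. The normalization basis is the RCA set
itself, not genome-wide bins — the source summarizes signal "in each RCA
region" — and users can substitute genome-wide normalization by supplying
their own table. The five-way rule:

* gate: `max(TPM_K4me3, TPM_K4me1) > 4` (TPM exactly 4 falls to the low
  branch);
* gated branch, ratio `r = TPM_K4me3 / TPM_K4me1`: promoter if `r > 1.5`,
  enhancer if `r < 0.67`, weak_promoter otherwise (ties at 1.5 and 0.67
  are "intermediate" values, hence weak_promoter); a zero denominator is
  treated as +inf (promoter) and logged;
* low branch: insulator if `ATAC > K4me1` (strict), weak_insulator
  otherwise (equality included). ATAC is TPM-normalized the same way as
  the histone tracks so the comparison is unit-consistent; the source does
  not state its scale.

The source's figure legend names a "weak enhancer" class where its methods
text defines "weak insulator"; the methods taxonomy is implemented and the
discrepancy recorded here, not resolved. Insulator sub-typing: CAC =
overlaps >= 1 Rad21 and >= 1 CTCF peak; CNC = Rad21 only; `neither`
otherwise.

## Statistics

* Spearman density correlations use average ranks for ties. The two-tailed
  p-value is an exact permutation probability for n <= 9 chromosomes (full
  enumeration of the n! rank pairings — 362,880 at n = 9, sub-second) and
  the usual t-approximation for larger n. The exact/asymptotic switch
  matters because the source reports only p bounds; with fewer than ~10
  chromosomes the t-approximation is unreliable, while enumeration beyond
  n = 9 (3.6M at n = 10) buys no practical accuracy for its cost.
  Zero-variance vectors raise instead of returning an undefined
  coefficient. No multiple-comparison adjustment is applied, matching the
  source analysis.
* The 2x2 chi-square uses the closed form `N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`,
  identical to the cell-wise `sum (O-E)^2/E` (tested to 1e-9), with p from
  the 1-df chi-square distribution and odds ratio `ad/bc` (+inf flagged when
  `bc = 0`). Degenerate margins raise.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
records every planted association in a JSON manifest, so each stage is
verifiable end-to-end without the original sequencing data. Default
conditions mirror the study's printed numbers:

| parameter | default | source of the value |
|---|---|---|
| genome | chr1..chr19 + chrX, 90–30 Mbp (1.2 Gbp total) | mouse-like naming; lengths vary so per-chromosome densities are informative |
| TAD partition | non-overlapping, mean 700 kbp (~1,700 TADs) | typical mammalian TAD scale; real TADs can nest — simplification noted below |
| TAD margins / odds ratio | pA = 0.133, pB = 0.191, OR = 9.6 | derived from the printed 472 and 677 of 3,538 TADs with 278 both |
| H-sites | 1,508; 85% clustered near i-RCAs, half-normal edge gap sd 27.5 kbp (mean ~22 kbp) | printed totals; printed ~22 kbp average neighborhood distance |
| RCAs | 1,551 promoter + 2,426 intergenic + 1,000 genic | printed promoter/intergenic totals |
| genes | 3,000; 1,363 down, 162 up | printed 1,363 downregulated of 1,525 DE genes |
| pairing | 154 p-RCAs over 146 genes (8 genes carry two) | printed counts |
| Hi-C | 500 contacts, half planted over 120 genes; separations lognormal(mu 12.366, sigma 0.8) clipped to [20 kbp, 2.4 Mbp], mean ~324 kbp | printed mean ~324 kbp and range |
| HH-sites / flanking | 86 HH-sites; 69 T3-TR and 7 uTR occasions within 10 kbp | printed counts |
| insulators | 30 CAC + 4 CNC of 34 paired insulators | printed counts |
| demethylation overlap | 25 of ~3,000 normally-demethylated sites | printed count |

Placement is rejection-sampled against a per-chromosome occupancy index
with per-feature margins (default 3 kbp between claimed blocks), which
guarantees that unintended proximities — an extra p-RCA within 5 kbp of a
downregulated gene, a stray anchor within 1 kbp of a p-RCA, an H-site
inside a noise H3K9me3 peak — cannot occur. Discrete recovery tests can
therefore demand exact agreement with the manifest, and continuous ones
(mean contact separation, H-site scatter) use sampling tolerances (10% at
the default sizes). Per-class signal count rates are chosen so each planted
class sits deep inside its decision region under Poisson count noise:
promoter/enhancer rates are symmetric so track totals balance and TPM
ratios track raw count ratios; insulator classes carry zero histone counts
(the gate then cannot flip), with weak_insulator fully signal-free so the
ATAC == K4me1 tie rule applies deterministically. A single integer seed
drives one generator stream; identical seeds reproduce every output file
byte-identically.

What the generator does **not** emulate: nested/overlapping TADs, read- or
fragment-level noise, realistic ChIP peak shapes, inter-chromosomal
contacts, copy-number or mappability artifacts, and correlated biological
replicates. Passing recovery tests therefore demonstrate the pipeline's
bookkeeping and boundary semantics, not robustness to the messiness of
real libraries.

## Calibration and problem sizes

The null harness (`null_resample`) draws per-TAD feature presence
independently at the configured margins (odds ratio fixed at 1), builds
the contingency table and applies the chi-square test; at the default
~1,700 TADs the empirical rejection rate over 2,000 replicates is within
3 binomial standard errors of the nominal 0.05. Power at a planted odds
ratio of 5 with 200 TADs exceeds 0.9. The default test suite runs the
full generator + pipeline once (a few seconds) and the oracle-equivalence
suite on 60 randomized instances of up to 1,000 features; the complete
suite finishes in well under a minute.

## Known limitations

* The gene-body proxy for reduced-expression regions can only lengthen
  pairing distances relative to a true coverage-dip peak; pair counts on
  real data are thus conservative near the 5 kbp cap.
* TAD membership by any-overlap lets one feature count for two adjacent
  TADs; the containment flag gives the stricter bedops-style reading.
* Whether the source's area counts derive from one- or both-anchor
  matching is unstated; both-anchor is the default, with a flag to
  restrict.
* The anchored matrix reports raw counts per offset bin; no smoothing or
  row normalization is applied (rendering is out of scope).
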