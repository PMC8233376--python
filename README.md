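# chromacell

Cell-type-resolved 3D-genome analysis: A/B compartments, TADs, FIREs,
promoter-anchored loops, enhancer–gene networks, and chromatin-interaction
based SNP→gene annotation — with a synthetic Hi-C generator that plants known
ground truth so every stage can be validated end to end.

## Who this is for

Genomicists working with sorted-cell-type Hi-C (e.g. neuronal vs glial nuclei
from brain tissue) who want a compact, testable reimplementation of the
standard analysis ladder from binned contact matrices down to gene-level GWAS
annotation files, and methodologists who want planted-truth benchmarks for
those stages.

## What it computes

All analyses are cis, per chromosome, on binned contact matrices
(100 kb for compartments, 40 kb for TADs and FIREs, 10 kb for loops).

* **Balancing (ICE)** — iterative correction `b_i ← b_i · (Σ_j c_ij / mean)`
  until unmasked row sums are equal; low-coverage bins masked.
* **Reproducibility (SCC)** — stratum-adjusted correlation: smooth both maps
  with a (2h+1)² mean filter, compute the Pearson correlation ρ_d per distance
  stratum, and combine with weights `w_d = N_d · σ_{x,d} σ_{y,d}`.
* **Compartments** — eigenvectors of the Pearson correlation matrix of the
  observed/expected map; among the first four, the one most correlated with a
  gene-density track is chosen per chromosome and oriented so r ≥ 0; A = bins
  with positive values. Switch regions are maximal runs of bins whose A/B
  label differs between two cell types.
* **TADs** — directionality index per 40-kb bin over a 2-Mb window,
  `DI = sign(B−A) · ((A−E)²/E + (B−E)²/E)` with `E = (A+B)/2`; a 3-state
  Gaussian HMM on rank-normalized DI yields upstream-/none/downstream-biased
  states; a domain runs from the start of a downstream-biased run to the end
  of the last upstream-biased run before the next one.
* **FIREs** — local cis count C_i (contacts 15–200 kb away) on the raw 40-kb
  matrix, scored `z = (log(C+1) − mean)/sd`; FIRE ⇔ one-sided p < 0.05.
  Differential FIREs between cell types A and B use quantile rules
  (A-specific: `z_A > Φ⁻¹(0.975)` and `z_B < Φ⁻¹(0.9)`; common: FIRE in both
  with `|z_A − z_B| < 0.5`). Super-FIREs are clusters of adjacent FIRE bins
  ranked by cumulative z and cut at the slope-1 point of the scaled
  hockey-stick curve.
* **Loops** — promoter-anchored interaction calling against a Weibull null:
  for each chromosome and distance stratum, a Weibull(k, λ) is fitted to the
  nonzero interaction frequencies of length- and GC-matched random background
  anchors; each promoter–candidate pair in [20 kb, 2 Mb] gets
  `p = exp(−(x/λ)^k)`, Benjamini–Hochberg across all tested pairs, and calls
  at FDR < 0.01. Calls are classed E-P / P-P / other and flagged when both
  anchors share a TAD.
* **Networks** — peaks link to genes by promoter overlap or through a loop
  anchor whose partner overlaps a promoter; mean expression is summarized by
  linked-enhancer count (0–9, pooled "10+"); module enrichment is Fisher's
  exact test with BH correction.
* **snp2gene** — exonic and promoter SNPs are assigned positionally; other
  SNPs through loops whose partner anchor overlaps a promoter or exon; output
  in MAGMA gene-annotation format
  (`GENE  chrom:start:stop  rs1 rs2 ...`).
* **synthetic** — the generator plants all of the above: power-law decay
  `E[c_ij] = L·|i−j|^(−α)` modulated by a compartment checkerboard
  (`1 + β·s_i s_j`), TAD blocks (`tad_boost`), FIRE bins (`fire_boost`),
  loop pixels (`loop_boost`), optional per-bin bias and pixel-level rate
  variability, with Poisson (optionally negative-binomial) counts — plus
  peaks at planted enhancer bins, expression rising with enhancer count and
  saturating at 10, and SNPs in four placement strata with known target
  genes.

## Worked example

Run the full synthetic pipeline (simulate → balance → compartments → TADs →
FIREs → loops → networks → snp2gene) on a 20-Mb chromosome with two cell
types:

```python
from chromacell.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(out_dir="out", seed=1))
```

or equivalently `chromacell all --out out --seed 1`. Selected stage metrics
from `out/report.json` at seed 1:

```
compartments  neuron: label_agreement_with_truth 1.00 (chosen PC 1)
              glia:   label_agreement_with_truth 1.00, 2 switch regions
tads          neuron: boundary_recall 1.00 (36 domains)
fires         A-specific: precision 1.00, recall 0.75
              B-specific: precision 1.00, recall 0.80
loops         neuron: 347 calls, sensitivity 0.965, empirical FDR 0.038,
              frac_EP 0.91, frac_PP 0.07
networks      336 peak–gene links; expression vs enhancer-count Spearman 1.00
snp2gene      96 genes annotated; truth agreement (mean Jaccard) 1.00
```

Reading it: every stage is scored against the planted truth of its own
resolution — compartment labels agree bin-by-bin with the planted
checkerboard; all planted domain boundaries are recovered within one bin;
differential FIRE calls are exact on the planted cell-type-specific hotspot
bins (recall < 1 reflects planted bins whose simulated counts fell below the
quantile thresholds); loop calls recover planted 3× contacts at the intended
false-discovery level; and SNPs map back to their true target genes through
the called loops. `out/` also holds every intermediate file (contact
triplets, bias vectors, bedGraphs, BEDs, BEDPE, the MAGMA annotation), each
stamped with the config hash and seed; a rerun with the same config is
byte-identical.

Stage-level CLI subcommands (`chromacell balance|compartments|tads|fires|
loops|network|snp2gene`) run the same analyses on user-supplied files in the
plain-text formats above.

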