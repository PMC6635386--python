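# meiohic

Analysis toolkit for binned Hi-C contact maps, built around the questions a
chromatin-architecture study of gamete formation asks: how chromosome
territories, A/B compartments, topological domains (TADs) and the meiotic
telomere bouquet change between cell types, and how insulator/cohesin
occupancy relates to local insulation and gene expression.

The package has two halves that validate each other:

* **Analysis** — contact-matrix conditioning (low-count bin filtering, ICE
  balancing, depth scaling, observed/expected), compartment and TAD calling,
  whole-genome architecture statistics (contact-probability decay P(s),
  inter/intra-chromosomal ratios, sub-telomeric bouquet scores,
  stratum-adjusted correlation), and peak/expression association
  (annotation, permutation Z-scores, occupancy enrichment, rank-sum
  comparisons, CPM, hypergeometric GO enrichment with BH correction).
* **Simulation** — a generator that plants every one of those signals with
  known parameters in a synthetic multi-chromosome genome, so each analysis
  is tested by parameter recovery rather than by eyeballing.

## The statistics at the core

* **ICE balancing.** Iteratively divide the counts by the outer product of
  normalized row sums until the coefficient of variation of row sums drops
  below tolerance: `M_ij -> M_ij / (b_i b_j)` with per-bin visibility
  biases `b`. A single-pass variant feeds the compartment pathway.
* **A/B compartments.** Per chromosome: distance-normalize (obs/exp), one
  ICE pass, Pearson correlation matrix of the bins, leading eigenvector
  `E1`; sign oriented so the gene-dense side is positive; `E1 > 0` is A,
  `E1 < 0` is B, 0/masked is NA.
* **Insulation and TAD borders.** For bin *i* and window *w*, the mean
  contact in the `w x w` square spanning the *w* bins upstream by the *w*
  bins downstream; the score is `log2(value / chromosome mean)`. Borders
  are prominent local minima over ten window sizes (4–40 bins); a border's
  robustness (1–10) counts the window sizes supporting it.
* **P(s) decay.** Mean contact probability per genomic separation; the
  log-log slope over a chosen range summarizes polymer state.
* **Inter/intra ratio.** `R_c = inter-chromosomal sum of c / intra sum of c`
  (diagonal included), with its Spearman correlation against chromosome
  length.
* **Bouquet score.** Summed per-million-contact inter-chromosomal counts
  between sub-telomeric windows of every chromosome pair; cell types are
  compared by a two-sided rank-sum test.
* **SCC reproducibility.** 2D-mean-smoothed matrices compared per distance
  stratum by Pearson correlation, combined with weights proportional to
  stratum size times the rank-stabilized spread; the genome score is the
  mean over chromosomes.
* **Permutation association.** Mean of a per-bin track (insulation,
  expression) over a peak set versus its distribution at random
  length-preserving relocations: `Z = (obs - mean_null) / sd_null`, with a
  local Z profile across ±250 kbp flanks.

## A worked example

`examples/02_compartments_and_tads.py` simulates the default toy genome
(3 × 10 Mbp chromosomes at 50-kbp bins; checkerboard amplitude 0.6, 5×
within-TAD enrichment), samples one million contacts, and recovers both
layers:

```
compartments: 48.0% A, 48.0% B, 4.0% NA; planted-label recovery 100.0%
mean A-segment size 2.40 Mbp
TAD borders called at bins [49, 99, 149, 249, 299, 349, 450, 499, 549]
planted borders at bins    [50, 100, 150, 250, 300, 350, 450, 500, 550]
robustness (of 10 window sizes): [10, 10, 10, 10, 10, 10, 10, 10, 10]
```

Every called border lies within one bin of a planted boundary (boundary
bins themselves are masked by the low-count filter, so the caller reports
the masked-gap midpoint) and insulates at all ten window scales. The other
example scripts cover matrix conditioning, the architecture metrics
(decay slope −1.01 for a planted exponent of −1; sub-telomeric scores
rising 24 → 133 per million when the bouquet factor goes 1 → 5; an SCC
series strictly decreasing along a contamination titration), and the
peak/expression statistics.

There is also a thin CLI mirroring the library
(`meiohic simulate|filter|normalize|compartments|tads|metrics|peaks|goea|run`),
plus a YAML-configured pipeline: `meiohic run --config pipeline.yaml`
executes simulate → filter → normalize → compartments → tads → metrics →
peaks and writes a JSON report with an output manifest (re-running an
unchanged config is bit-identical).

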