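# Methods

This note documents the models, the parameter choices, and the numerical
decisions behind `meiohic`, in the spirit of a methods supplement: what
each procedure assumes, which knobs matter, and what the synthetic
validation does and does not demonstrate about real data.

## Coordinate and matrix conventions

Coordinates are 0-based, half-open everywhere. A `GenomeLayout` tiles each
chromosome from position 0 into fixed-width bins (default 50 kbp, the
working resolution of the study design this package serves); the last bin
may be short. Contact matrices are dense, symmetric, real-valued arrays
over the global bin index; a read-level contact appears at `[i, j]` and
`[j, i]`, so the number of contacts is the upper-triangle-plus-diagonal
sum while `matrix.total()` is the full sum. The interchange format is the
7-column interaction table (`chrom1 start1 end1 chrom2 start2 end2
count`), one unordered bin pair per row.

## The synthetic genome

The generator's purpose is falsifiable validation: every signal the
analysis half measures is planted with known parameters, and the tests ask
whether it is recovered. The default scale is 3 chromosomes × 10 Mbp at
50-kbp bins (600 bins): large enough for stable eigenvectors and
insulation profiles, small enough that the full pipeline runs in seconds.

The expected contact for an intra-chromosomal pair at separation `d` bins
is

```
K(d) * (1 + a * e_i * e_j) * tau^[same TAD]
```

with `K` a (piecewise) power law `d^-alpha` (continuous at breakpoints;
`alpha = 1` by default, the classic polymer regime), `e = +1/-1` the A/B
checkerboard with amplitude `a = 0.6`, and `tau = 5` the within-TAD
enrichment. The kernel is evaluated in **bin units** with the diagonal at
`d = 1`; this keeps it O(1) near the diagonal so the inter-chromosomal
background weight `beta = 0.005` is directly comparable to long-range
intra values (in bp units any usable `beta` would swamp the intra mass).
Inter-chromosomal pairs get `beta`, multiplied by a bouquet factor `gamma`
when both bins lie in telomere windows (first/last 500 kbp) and by a
chromocenter factor when both lie in the start window (acrocentric
convention: the centromere is the chromosome start). `beta` can also be
set in closed form to hit a target inter/intra ratio, since the inter sum
is linear in it.

Compartment blocks and TAD segments both default to 50 bins (2.5 Mbp),
**aligned**. This is deliberate: a compartment transition is itself an
insulation discontinuity (the checkerboard factor drops four-fold across
it), so placing compartment boundaries mid-TAD would plant domain
boundaries the TAD truth-set does not list. Real genomes behave the same
way — compartment transitions coincide with domain boundaries — so the
aligned default is both the realistic and the measurable choice. Both
lengths are per-spec tunable for experiments that want them decoupled.

Reads are drawn multinomially over unordered bin pairs (diagonal mass
half-weighted so the symmetric-matrix algebra stays exact), which makes
sampled matrices bit-reproducible per seed and preserves the total contact
count exactly. The mixture simulator resamples `round(p*n)` contacts from
pool B and the remainder from pool A for each proportion — an exact split,
so the canonical six-dataset purity titration (0 to 100% in 20% steps) is
exactly reproducible.

Genes (default 1,000) choose an A-compartment bin with probability
`r/(1+r)` (density ratio `r = 2`), a uniform TSS within the bin, and a
fair-coin strand. Peaks (default 500, 200 bp wide) land inside strand-aware
2-kbp upstream promoter windows of distinct random genes for a fraction
(default 0.8) and uniformly in non-promoter space otherwise, rejecting
overlaps. Expression is log-normal, `log2 FPKM ~ N(3, 2)`, with additive
one-log2 effects for A-compartment genes and promoter-peak genes; counts
are scaled, rounded FPKM. The generative model is a declared stand-in —
the study it emulates only ever mixed real sequencing reads — so its role
is parameter recovery, not distributional realism.

What the simulation does **not** contain: mappability structure, GC and
fragment-length biases, translocation or copy-number artifacts, unbalanced
chromosome lengths, replicate-level batch effects, or a sex chromosome.
Passing recovery tests therefore demonstrates the correctness of the
estimators under a clean generative model, not their robustness to every
artifact of real libraries.

## Matrix conditioning

**Low-count filtering.** Per-bin marginals are histogrammed on the
`log1p` scale with Freedman–Diaconis bins and smoothed with a 3-bin moving
average; the first local minimum whose height falls below a quarter of the
tallest mode is the antimode, and the threshold is `max(antimode,
min_count)` with `min_count = 10`. The depth condition matters: without
it, noise wiggles in a healthy unimodal marginal distribution read as
antimodes and mask a few percent of perfectly usable bins. When the
distribution is genuinely bimodal (dead or depleted bins versus the main
mass) the antimode separates exactly the low mode. Masked bins are zeroed
and never unmasked downstream.

**ICE.** Iterative proportional fitting over the unmasked submatrix until
the row-sum CV drops below `tol = 1e-5` (maximum 200 passes; one-pass
variant for the compartment pathway). The result is rescaled to preserve
the mean unmasked row sum and carries the accumulated biases and a
convergence flag; non-convergence warns but is not fatal.

**Obs/exp.** Per chromosome, each entry is divided by the mean of its
diagonal over unmasked pairs; empty strata and inter-chromosomal entries
are NaN, and NaN propagates (meta-profiles average NaN-aware).

## Compartments

Per chromosome with at least 10 usable bins: obs/exp on the filtered raw
block, one ICE pass, Pearson correlation matrix over usable bins
(zero-variance rows dropped to NA), leading eigenvector of the
correlation matrix. The sign is chosen so the positive side has the higher
mean gene density (ties fall back to the larger eigenvector mass, with a
warning); positive bins are A, negative B, everything else NA. Labels are
invariant to global matrix rescaling and to eigenvector sign flips by
construction. Summaries report genome fractions (A + B + NA = 1 exactly)
and contiguous-segment sizes per label. The switch ratio between two cell
types excludes bins NA in either profile from numerator and denominator;
cell-specific A bins demand A in one type and a definite B everywhere
else.

## Insulation and TAD borders

The insulation value of bin `i` at window `w` is the mean contact in the
square `[i-w, i) x (i, i+w]` — the bin's own row and column are never part
of the square, so bins masked for low visibility still receive a score
while masked rows/columns are excluded from the mean. Zero-contact squares
are floored at half the smallest positive value in that
chromosome/window: total depletion is maximal insulation, not missing
data. The score is `log2(value / chromosome mean)`; the aggregate track
averages the ten default windows (geometric, 4–40 bins), and per-
chromosome score variance quantifies how much domain structure a map has
(a planted-TAD matrix strictly exceeds its kernel-only counterpart).

Border calling: prominent local minima of the aggregate (prominence ≥
`min_depth = 0.1` on the log2 scale). Each candidate absorbs adjacent
masked-bin runs — a boundary depleted enough to be filtered lies *inside*
the masked gap, and the two minima flanking the same gap are one border,
reported at the gap midpoint. Remaining candidates within one bin merge to
the deepest. Robustness counts the window sizes (of 10) whose own score
has a minimum within one bin of the border interval; candidates below
`min_robustness = 8` are discarded. That operating point reflects a
strongly bimodal observable: genuine boundaries in the validation genomes
insulate at essentially all ten scales while sampling-noise minima rarely
persist past seven. TADs are the partition between consecutive retained
borders.

## Architecture metrics

**P(s)** pools unmasked intra pairs per bin-distance; the slope is an
ordinary least-squares fit of `log10 P` on `log10 s` over a caller-chosen
range. **Inter/intra ratios** use full-block sums with the diagonal
included, and values above 1 are expressible (sperm-like maps need them).
**Sub-telomeric scores** sum inter-chromosomal counts between
chromosome-start windows (default [3.0, 3.5) Mbp, skipping the masked
centromeric starts of real mouse maps; bins belong by midpoint) expressed
per million *contacts*. Normalizing by the contact count rather than the
raw matrix sum is a deliberate subtlety: the raw sum is `2n - trace`, so
two equal-depth libraries would receive infinitesimally different factors,
and on heavily tied small counts that breaks every cross-group tie in one
direction — enough to visibly inflate the rank-sum comparison between cell
types. Per-contact scaling keeps tied counts tied and the comparison
calibrated, and remains invariant to global rescaling.

**SCC** smooths both maps with a (2h+1)-wide 2D mean filter (default
h = 5), correlates smoothed entries per distance stratum up to 10 Mbp, and
combines strata with weights ∝ stratum size × rank-stabilized spread;
the genome score is the unweighted chromosome mean. Entries within `h`
bins of the matrix boundary are trimmed from every stratum: their
truncated smoothing windows carry a deterministic distance-decay bump
shared by any two maps, which otherwise fabricates correlation (~0.26)
between completely unrelated samples. With `h = 0` the statistic reduces
to the weighted stratified Pearson of the raw entries. The "considered
distance" is read as *up to* 10 Mbp; a `min_distance` argument provides
the *beyond* reading.

## Association statistics

**Permutation Z.** The observed statistic is the mean per-bin track value
over the query peaks; the null relocates each peak uniformly within its
own chromosome, length preserved, redrawing placements that touch masked
bins. Masked bins are excluded from the observed statistic's universe as
well — an asymmetric treatment biases Z by over a standard deviation on
real insulation tracks, because masked bins sit in deep valleys. The
empirical p uses the add-one estimator, two-sided by doubling the smaller
tail; the local profile re-evaluates Z at ±250 kbp shifts in bin steps
against the same null. A vectorized path handles the common case of
single-bin peaks on an unmasked genome. Default 10,000 permutations;
calibration checks use 500 and stay inside the binomial band around the
nominal 5% level.

**Rank-sum comparisons** (expression groups, bouquet scores) use exact
enumeration for untied groups up to 12, and a midrank permutation null
(10,000 resamples, fixed internal seed, hence deterministic) whenever ties
are present — the normal approximation rejects at roughly twice the
nominal level on small-count data. Large untied samples use the normal
approximation with continuity correction.

**Peak annotation** is priority-ordered promoter > gene body > intergenic,
with the promoter as the strand-aware 2-kbp window strictly upstream of
the TSS (`promoter_mode="symmetric"` switches to ±2 kbp). Venn-style
overlaps are reported per set so asymmetric spanning relationships stay
visible. **CPM** scales each library column to 1e6. **Enrichment** is the
upper-tail hypergeometric per term over a flat term→gene map (no DAG
propagation), BH-adjusted, significant at q ≤ 0.01.

## Pipeline

`run_pipeline` executes a validated stage list (simulate, filter,
normalize, compartments, tads, metrics, peaks) in dependency order,
refuses unknown stages before any computation, writes TSV/BED artifacts
plus a JSON report with per-stage summaries and sha256 checksums, and is
bit-reproducible for a fixed config. Existing outputs are only overwritten
with `force`. All stochastic stages take explicit seeds; there is no
hidden global random state anywhere in the package.

## Validation problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen once: the default 600-bin genome with 1e6 contacts for compartment
and TAD recovery; a 6 × 5 Mbp genome (15 chromosome pairs) at 150k
contacts per library and 100 seeds for bouquet power and null calibration
— six chromosomes because a rank-sum over chromosome-pair scores needs
more than the 3 pairs a 3-chromosome genome offers (the exact two-sided
floor at 3 vs 3 is p = 0.1); 400k-contact pools for the mixture/SCC
series, where shallower series leave the pure and 20%-contaminated points
inside resampling noise of each other; 200 replicates × 500 permutations
for the Z calibration. The full suite runs in under a minute on one core.

## Known limitations

* Dense matrices bound the practical genome size to a few thousand bins;
  the algorithms do not change for sparse storage, but this implementation
  does not provide it.
* Compartment eigenvectors are computed per chromosome; a genome-wide
  (trans-aware) eigendecomposition is not offered.
* The border robustness score is a multi-window consensus count, a
  reinterpretation chosen for testability; it is not numerically
  comparable to any external caller's score.
* GO enrichment treats the term map as flat; parent-term propagation is
  out of scope.
* The permutation universe treats chromosomes as independent placement
  spaces; peaks are never relocated across chromosomes.
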