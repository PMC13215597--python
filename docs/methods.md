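# Methods

`clonecn` reconstructs clone-level absolute (integer) copy-number profiles and
tumor clonal substructure from a sparse scATAC-seq peak-by-cell count matrix,
using non-malignant cells from the same dataset as a diploid reference. No
matched DNA sequencing is required. This note describes the model, the
defaults and why they are what they are, what the synthetic benchmark does and
does not emulate, and the numerical choices that matter.

## Model overview

The central quantity is the relative copy ratio. After quality filtering,
counts are truncated to [0, 4], each cell is rescaled to its group's mean
library size, and each peak of each candidate tumor ("inferred") cell is
divided by the mean signal of the reference cells at that peak:

    R[i, j] = Y'[i, j] / mean_ref(X'[i, ·])

Because reference cells are diploid and each group is rescaled to its own
mean library size, R ≈ CN/2 up to a clone-specific scale factor: a ratio of
1 corresponds to two copies, and one copy step moves the ratio by roughly
0.5. Copy-number inference proceeds in four stages:

1. **Initial clustering.** Per-peak ratios are averaged within windows of 5
   consecutive peaks per chromosome; cells are clustered on the window
   matrix (top 2000 highly variable windows by mean-normalized dispersion of
   log1p values, z-scoring, PCA to 50 components, shared-nearest-neighbor
   graph with k = 20 and Jaccard weights, Leiden at resolution 1.0).
2. **Segmentation.** Each subgroup's mean window-ratio profile is segmented
   per chromosome by PELT under a normal mean-shift (L2) cost. The penalty
   defaults to 3·log(n)·σ̂², with σ̂ estimated from the median absolute
   deviation of first differences (floored at 1e-8 so noiseless profiles
   remain segmentable). Segments shorter than 2 Mb are merged into the
   neighbor with the nearer median ratio (ties go left); if absorbing a
   sliver leaves two flanks with identical medians the artifact boundary is
   collapsed. Segment ratio = median of member-window ratios; genomic
   fraction w_j = segment length / covered length, so Σ w_j = 1. An exact
   O(n²) optimal-partitioning solver (the `fpop` flag) solves the identical
   problem without pruning and is used as an internal cross-check.
3. **Integer CN inference.** Segment ratios are modeled as a mixture over
   integer states Q = {1..8} with a shared variance σ² and a
   maximum-entropy prior P(q | θ_q, w_j) ∝ exp(−θ_q·q#·w_j), where q# is
   the 1-based rank of q. θ is estimated once per subgroup by Nelder–Mead
   so that each θ_q matches the expected genomic fraction of its state
   (deterministic start from the nearest-state frequencies under a
   diploid-anchored 0.5 spacing). Expected ratios are constrained to a line
   μ_q = μ1 + (q−1)·Δ; candidate spacings Δ come from the w-weighted
   Gaussian-KDE modes of the segment-ratio histogram (gaps between adjacent
   modes, their halves and thirds, and proportional placements mode/q), each
   anchored proportionally (μ1 = Δ) and at the diploid point (μ1 = 1 − Δ),
   with a ±Δ/4 maximum-likelihood refinement of μ1. Each candidate is fit
   by maximizing the genomic-fraction-weighted mixture log-likelihood; the
   candidate with minimum AIC (k = |Q| + 2) wins. Integer calls are the
   posterior argmax per segment; ploidy = Σ w_j·q̂_j.
4. **Clone refinement.** Every pair of subgroups is compared on the
   segmented ratio of their mean normalized peak profiles: Welch two-sided
   t-tests per segment over per-peak signals, Benjamini–Hochberg adjusted
   across segments. Two subgroups remain separate only if some segment has
   adjusted p < 0.05 AND a differing lifted integer CN. Clones are connected
   components of the resulting adjacency matrix; segmentation and CN
   inference are re-estimated per clone, and a composite reliability score
   in [0, 1] summarizes each clone's fit.

## Key parameter choices

| Parameter | Default | Rationale |
|---|---|---|
| window_size | 5 peaks | aggregation scale balancing sparsity vs resolution |
| min_cell_frac / min_peaks | 5% / 10 000 | detection filter, relaxed in 0.5-pp steps until 10 000 peaks remain; scale min_peaks pro rata when analyzing a partial genome |
| cell percentile band | [5, 95], inclusive, linear-interpolation quantiles | removes depth outliers within each group |
| per-chromosome dropout rule | max(0.60, group median zero fraction + 0.15) | a fixed 60% cap removes every cell of realistically sparse data; the adaptive term turns the rule into what it is for — flagging chromosome-scale dropout outliers — while the fixed cap still binds on dense data |
| truncation | counts capped at 4 before normalization | limits the leverage of amplified or artifact peaks |
| ref_agg | mean (median available) | the ratio definition uses the reference mean |
| min_seg_len | 2 Mb | events below this are below the method's resolution |
| max_cn (I) | 8 | covers observed amplification levels; configurable |
| σ² floor | 1e-6 | prevents degenerate likelihood spikes on exact fits |
| outlier mass ε | 0.01 uniform | a lone noisy segment stranded between states must not drive σ² or spacing selection |
| Δ bounds | raw mode gaps in [0.2, 1); derived spacings in [0.3, 0.8] | the diploid reference pins one copy step near 0.5; spacings < 0.2 are unrealistically small for a single copy |
| AIC near-tie window | 2 units | conventional "substantial support" threshold |
| alpha (merge tests) | 0.05, BH across segments within a pair | follows the published merging rule |

**Ladder identifiability.** A spacing Δ and its half fit the same ratio
levels equally well — the finer ladder merely skips states — so AIC alone
cannot discriminate them, and the near-uniform maximum-entropy prior is too
weak to do so reliably. Among candidates within 2 AIC units of the minimum,
the tie is broken by the diploid-reference principle: prefer the candidate
whose dominant-genomic-fraction state is closest to CN 2, then lower implied
ploidy, then smaller Δ. This resolves both halving (everything doubled) and
the gains-only ambiguity (levels 1.0/1.9 read as CN 1/2) in favor of the
physically grounded interpretation. A genome-doubled clone exhibiting only
even states is intrinsically unresolvable from ratios alone and is called at
the lower scale — the standard conservative behavior of ploidy callers.

**Likelihood weighting.** Per-segment log-likelihood terms are weighted by
genomic fraction (normalized to mean 1). Long segments carry precise median
ratios while short ones are noisy; fraction weighting approximates
inverse-variance weighting and keeps many tiny noisy segments from dominating
spacing selection.

## Synthetic benchmark

The generator plants clonal CNVs in a Gamma–Poisson (negative-binomial
marginal) count model with lognormal cell depths:

    λ_i ~ Gamma(shape 0.6, mean 0.4)     per-peak accessibility
    d_c ~ LogNormal, mean 1, CV 0.5      per-cell depth
    count[i, c] ~ Poisson(d_c · λ_i · CN[clone(c), i] / 2)

with optional extra zero-inflation. Reference cells are diploid everywhere.
The genome is 6 autosomes of 3 Gb/22 ≈ 136 Mb each (~818 Mb total) at ~10
peaks/Mb. Clonal events are contiguous segments (default ≥ 5 Mb, drawn until
a target genomic fraction is covered) that keep a 5 Mb margin from chromosome
ends and from each other, because slivers below the method's ~2–4 Mb
resolution are unresolvable by construction. Configurations span 50–10 000
cells, 1–5 clones with prevalences in [0.10, 0.90] (a 10% clone acts as the
rare clone), and CNV genomic fractions of 10–60%.

What the generator does **not** emulate: GC and mappability bias (the ratio
construction cancels them in real data, so planting them would test the
cancellation, not the inference), accessibility heterogeneity between cell
states, doublets, fragment-level structure, and peak-calling artifacts.
Passing benchmarks therefore demonstrate correct recovery under the assumed
count model, not robustness to every artifact of real chromatin data.

## Evaluation suite

CNV detection is scored on non-overlapping 100-kb bins; bins straddling a
segment boundary in either the truth or the inferred profile are excluded.
"CNV present" means CN ≠ 2. Confusion metrics use their standard
definitions (degenerate all-negative cases define precision/recall as 1,
logged). Clone recovery is scored by Hungarian matching of inferred to true
clones on cell overlap, per-clone balanced accuracy (TPR+TNR)/2 over bins,
weighted by clone cell fraction; unmatched true clones score 0. Integer-CN
error is bin-level RMSE (with the mean-centering transform applied first for
methods that emit scores rather than integers). The dispersion score is 1 −
mean pairwise Gaussian-KDE overlap between inferred-signal distributions of
adjacent true CN states, clipped to [0, 1]. Breakpoint deviation matches
each true breakpoint to the nearest inferred breakpoint on the same
chromosome within a 10 Mb radius; breakpoints without a match within the
radius are missed detections (captured by sensitivity) and are counted
separately rather than averaged as localization error.

## Benchmark suites and problem sizes

Two standard suites (`clonecn.suites`) drive the automated checks, sized to
run in minutes on one CPU:

- **CN-error suite**: 10 datasets, 500–1000 cells, 1–3 clones, CNV fraction
  20–40%, events ≥ 10 Mb. Checks the per-dataset bin-level integer-CN RMSE
  and clone-recovery BACC.
- **Broad-event suite**: cells {200, 1000} × clones {1, 2, 3} × CNV fraction
  {0.1, 0.3, 0.6}, with a 10%-prevalence rare clone when ≥ 2 clones, events
  ≥ 20 Mb. Checks broad-event sensitivity and breakpoint localization.

`scripts/acceptance.py` reruns both suites from scratch for a given seed.

## Numerical choices and degenerate inputs

- KDE bandwidth for ratio-histogram modes: Silverman's rule capped at 0.08
  ratio units (segment medians cluster with sd ≈ 0.05 around states ≥ 0.2
  apart; an uncapped bandwidth merges adjacent states). Plateau-aware peak
  finding avoids missing symmetric ties on the evaluation grid.
- Nelder–Mead is used for θ (deterministic start, 5000 iterations) and for
  (μ1, log σ²) per candidate, with bounds. Non-convergence returns the best
  point with a warning.
- Posterior ties resolve to the lower CN state. Chromosomes with < 3 windows
  form a single segment. A chromosome with fewer peaks than the window size
  forms one short window. Subgroups of one cell, single-mode histograms, and
  all-diploid data all take documented fallback paths.
- One global seed fans out to per-stage child seeds through a counter-based
  scheme, so stage re-runs are independently reproducible and end-to-end
  output is byte-identical for a fixed seed.

## Known limitations

- Resolution is bounded by peak density and the 2 Mb segment floor; focal
  events below a few Mb are not resolved as independent CNVs.
- Rare clones need roughly 20 cells after QC to form their own cluster; at
  the boundary (e.g. 20 cells before QC in a 200-cell dataset) the rare
  clone may be absorbed into a major clone.
- The clone-specific library-size scale couples ploidy across clones in one
  dataset; extreme ploidy differences between clones shift each clone's
  ratio ladder, which candidate anchoring absorbs only within the allowed
  spacing range.
- Allele-specific copy number, purity as an explicit parameter, and
  phylogenetic ordering of clones are out of scope.
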