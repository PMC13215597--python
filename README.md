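# clonecn

Clone-level **absolute copy-number inference from single-cell ATAC-seq**.

Chromosomal copy-number variations (CNVs) reshape chromatin accessibility in
the regions they span, so a scATAC-seq experiment carries a readable imprint
of each tumor clone's karyotype. Existing accessibility-based callers mostly
stop at relative gain/loss calls; `clonecn` goes further and reconstructs
**integer** copy-number profiles per clone — and the clonal substructure
itself — directly from a sparse peak-by-cell count matrix, using the
non-malignant cells of the same dataset (immune, endothelial, fibroblast) as
a diploid reference. No matched bulk or single-cell DNA sequencing is needed.

It is intended for researchers analyzing solid-tumor scATAC-seq who want to
separate genetic (CNV-driven) from epigenetic (CRE-regulated) accessibility
differences between tumor subpopulations.

## Method at a glance

For inferred (tumor-candidate) cell *j* and peak *i*, the relative copy
ratio is

    R_ij = Y'_ij / mean_ref(X'_i)          (≈ CN/2 under a diploid reference)

after count truncation to [0,4] and library-size normalization. Cells are
clustered on 5-peak-window ratios (HVF → PCA → SNN graph → Leiden), each
subgroup's profile is segmented by PELT, and the segment ratios R_j with
genomic fractions w_j are modeled as a mixture over integer states
Q = {1,…,8}:

    P(R_j | μ, σ², θ, w_j) = Σ_q P(q | θ_q, w_j) · N(R_j | μ_q, σ²)
    P(q | θ_q, w_j) = exp(−θ_q·q#·w_j) / Σ_k exp(−θ_k·k#·w_j)

with a maximum-entropy prior (θ estimated by Nelder–Mead) and the state
means constrained to a line μ_q = μ₁ + (q−1)·Δ. Candidate spacings Δ are
read off the density modes of the segment-ratio histogram; the candidate
with minimum AIC fixes the integer states, the posterior argmax calls each
segment, and ploidy = Σ_j w_j·q̂_j. Subgroups whose profiles show no segment
that is both statistically different (Welch t-test, BH-adjusted p < .05) and
differently called in integer CN are merged into clones, and profiles are
re-estimated per clone. See `docs/methods.md` for the full treatment.

## Worked example

Simulate a benchmark dataset with a planted 70/30 clone structure, run the
pipeline, and score it against the planted truth:

```bash
clonecn simulate --config sim.yaml --out data/ --seed 4
clonecn run --counts data/counts.mtx --peaks data/peaks.bed \
            --barcodes data/barcodes.txt --annot data/annotation.tsv \
            --out results/ --seed 4
clonecn evaluate --truth data/ --pred results/ --out eval.json
```

with `sim.yaml`:

```yaml
n_cells: 400
n_ref_cells: 150
clone_prevalences: [0.7, 0.3]
cnv_genome_frac: 0.25
min_event_mb: 20
```

The same analysis from Python:

```python
from clonecn.simulate import SimConfig, simulate_dataset
from clonecn.pipeline import RunConfig, run, evaluate_run, _combine

cfg = SimConfig(n_cells=400, n_ref_cells=150, clone_prevalences=(0.7, 0.3),
                cnv_genome_frac=0.25, min_event_mb=20, seed=4)
ref, inf, truth = simulate_dataset(cfg)
counts, ann = _combine(ref, inf)
result = run(counts, ann, RunConfig(seed=4, min_peaks=2700))
for p in result.profiles:
    print(p.clone_id, p.n_cells, round(p.ploidy, 2), round(p.reliability, 2))
print(evaluate_run(truth, result).to_dict())
```

prints (clone id, cells, ploidy, reliability score) per clone and the
evaluation report:

```
0 239 2.26 1.0
1 102 2.37 0.99
{'precision': 0.998, 'recall': 0.998, 'accuracy': 0.999, 'f1': 0.998,
 'bacc_weighted': 0.999, 'rmse': 0.062, ... 'broad_sensitivity': 1.0}
```

Two clones are recovered at the planted 70/30 prevalences with ploidies 2.26
and 2.37 (each carrying ~25% of its genome in gains), bin-level integer-CN
RMSE is 0.06 copies, and every planted broad event is detected in the
correct clone (sensitivity 1.0, clone-assignment balanced accuracy 0.999).

Outputs on disk: `clones.tsv` (barcode → clone), `segments.tsv` (per-clone
segments with copy ratio, integer CN and posterior), `clone_summary.json`
(ploidy, reliability, cell counts), `clone_models.json` (fitted mixture
parameters) and `run_report.json` (all parameters and filter tallies).

For real data, supply your own Matrix Market counts, BED peak coordinates,
barcodes file, and a two-column TSV annotating each barcode as `reference`
or `inferred` (`--ref-group` remaps a custom label).

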