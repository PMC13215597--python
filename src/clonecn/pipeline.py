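"""End-to-end orchestration: preprocessing -> clustering -> segmentation ->
integer CN inference -> clone refinement -> outputs."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clonecn import cluster, cn_model, preprocess, refine
from clonecn.io import CellAnnotation, CloneProfile, CountMatrix, write_outputs
from clonecn.segmentation import Segmentation, segment_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the published settings."""

    window_size: int = 5
    n_hvf: int = 2000
    n_pcs: int = 50
    resolution: float = 1.0
    knn_k: int = 20
    min_cell_frac: float = 0.05
    min_peaks: int = 10_000
    cell_pct_low: float = 5.0
    cell_pct_high: float = 95.0
    max_zero_frac_per_chrom: float = 0.60
    ref_agg: str = "mean"
    seg_method: str = "pelt"
    min_seg_mb: float = 2.0
    seg_penalty: float | None = None
    max_cn: int = 8
    alpha: float = 0.05
    bin_kb: int = 100
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def child_seed(self, stage: int) -> int:
        """Counter-based per-stage seed fan-out."""
        return int((self.seed * 1_000_003 + stage) % (2**31 - 1))


@dataclass
class RunResult:
    """Pipeline outputs kept in memory for evaluation or writing."""

    clones: pd.Series  # QC-passing inferred barcode -> clone id
    profiles: list[CloneProfile]
    report: dict = field(default_factory=dict)

    def clone_segment_frame(self, clone_id: int) -> pd.DataFrame:
        """(chrom, start, end, cn) frame for one clone, for evaluation."""
        for p in self.profiles:
            if p.clone_id == clone_id:
                seg = p.segments.rename(columns={"integer_cn": "cn"})
                return seg[["chrom", "start", "end", "cn"]].copy()
        raise KeyError(clone_id)

    def clone_frames(self) -> dict[int, pd.DataFrame]:
        return {p.clone_id: self.clone_segment_frame(p.clone_id) for p in self.profiles}


def _segment_subgroup(
    windows: cluster.WindowMatrix,
    labels: np.ndarray,
    subgroup: int,
    config: RunConfig,
) -> Segmentation:
    profile = cluster.subgroup_window_profile(windows, labels, subgroup)
    return segment_profile(
        windows.chrom,
        windows.start,
        windows.end,
        profile,
        method=config.seg_method,
        min_seg_len=config.min_seg_mb * 1e6,
        penalty=config.seg_penalty,
    )


def run(
    counts: CountMatrix,
    annotation: CellAnnotation,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full inference pipeline on an annotated count matrix.

    Deterministic for a fixed ``config.seed``.  If ``out_dir`` is given, the
    standard output files are written there.
    """
    config = config or RunConfig()
    report: dict = {"config": {k: v for k, v in asdict(config).items()}}

    # --- preprocessing -----------------------------------------------------
    counts, peak_info = preprocess.filter_peaks(
        counts, config.min_cell_frac, config.min_peaks
    )
    report["peak_filter"] = peak_info

    ref_bc = [b for b in counts.barcodes if annotation.groups.get(b) == "reference"]
    inf_bc = [b for b in counts.barcodes if annotation.groups.get(b) == "inferred"]
    if not ref_bc or not inf_bc:
        raise ValueError("both reference and inferred groups must be non-empty")
    bc_index = {b: i for i, b in enumerate(counts.barcodes)}
    ref_counts = counts.subset_cells(np.array([bc_index[b] for b in ref_bc]))
    inf_counts = counts.subset_cells(np.array([bc_index[b] for b in inf_bc]))

    pct = (config.cell_pct_low, config.cell_pct_high)
    ref_counts, ref_info = preprocess.filter_cells(
        ref_counts, pct, config.max_zero_frac_per_chrom, "reference"
    )
    inf_counts, inf_info = preprocess.filter_cells(
        inf_counts, pct, config.max_zero_frac_per_chrom, "inferred"
    )
    report["cell_filter"] = [ref_info, inf_info]

    ref_norm = preprocess.truncate_and_normalize(ref_counts)
    inf_norm = preprocess.truncate_and_normalize(inf_counts)
    ratios, ratio_info = preprocess.compute_ratio(
        inf_norm, ref_norm, config.ref_agg
    )
    ratio_kept_idx = ratio_info.pop("kept_idx")
    report["ratio"] = ratio_info

    # --- initial clustering ------------------------------------------------
    windows = cluster.bin_ratios(ratios, config.window_size)
    labels = cluster.initial_subgroups(
        windows,
        n_hvf=config.n_hvf,
        n_pcs=config.n_pcs,
        resolution=config.resolution,
        seed=config.child_seed(1),
        knn_k=config.knn_k,
    )
    subgroup_ids = np.unique(labels)
    report["n_subgroups"] = int(len(subgroup_ids))

    # --- per-subgroup segmentation and CN inference ------------------------
    seg_by_sub, cn_by_sub = [], []
    for s in subgroup_ids:
        seg = _segment_subgroup(windows, labels, s, config)
        _, prof = cn_model.infer_clone_cn(seg, max_cn=config.max_cn)
        seg_by_sub.append(seg)
        cn_by_sub.append(prof.cn)

    # --- clone refinement --------------------------------------------------
    if len(subgroup_ids) > 1:
        # restrict to the ratio matrix's peaks (zero-reference peaks dropped)
        inf_dense = inf_norm.values.toarray()[ratio_kept_idx]
        mean_profiles = np.vstack(
            [inf_dense[:, labels == s].mean(axis=1) for s in subgroup_ids]
        )
        A = refine.build_adjacency(
            mean_profiles,
            ratios.peaks,
            seg_by_sub,
            cn_by_sub,
            window_size=config.window_size,
            alpha=config.alpha,
            min_seg_len=config.min_seg_mb * 1e6,
            seg_method=config.seg_method,
        )
        clone_labels = refine.finalize_clones(A, labels)
    else:
        clone_labels = np.zeros_like(labels)
    clone_ids = np.unique(clone_labels)
    report["n_clones"] = int(len(clone_ids))

    # --- per-clone re-estimation -------------------------------------------
    profiles: list[CloneProfile] = []
    for c in clone_ids:
        seg = _segment_subgroup(windows, clone_labels, c, config)
        model, prof = cn_model.infer_clone_cn(seg, max_cn=config.max_cn)
        seg_df = pd.DataFrame(
            {
                "chrom": seg.table["chrom"],
                "start": seg.table["start"],
                "end": seg.table["end"],
                "segment_ratio": seg.table["ratio"],
                "integer_cn": prof.cn,
                "posterior_prob": prof.posterior.max(axis=1),
            }
        )
        profiles.append(
            CloneProfile(
                clone_id=int(c),
                segments=seg_df,
                ploidy=prof.ploidy,
                reliability=prof.reliability,
                n_cells=int(np.sum(clone_labels == c)),
                model=cn_model.model_to_dict(model),
            )
        )

    clones = pd.Series(clone_labels, index=inf_norm.barcodes)
    result = RunResult(clones=clones, profiles=profiles, report=report)
    if out_dir is not None:
        write_outputs(clones, profiles, out_dir, run_report=report)
    return result


def evaluate_run(truth, result: RunResult, bin_size: int = 100_000):
    """Score a pipeline result against a simulated TruthProfile."""
    from clonecn import evaluate as ev

    chrom_lengths = truth.chrom_lengths
    truth_frames = {
        int(c): truth.clone_segments(int(c))[["chrom", "start", "end", "cn"]]
        for c in truth.cell_clones.unique()
    }
    pred_frames = result.clone_frames()
    matching = ev.match_clones(truth.cell_clones, result.clones)
    weights = truth.cell_clones.value_counts(normalize=True)

    # per-clone inferred segment-ratio profiles, for the dispersion score
    ratio_frames = {
        p.clone_id: p.segments.rename(columns={"segment_ratio": "cn"})[
            ["chrom", "start", "end", "cn"]
        ]
        for p in result.profiles
    }

    report = ev.EvalReport()
    # clone-weighted confusion + RMSE over matched clones
    conf_keys = ("precision", "recall", "accuracy", "f1")
    agg = {k: 0.0 for k in conf_keys}
    rmse_sq, rmse_w = 0.0, 0.0
    excluded = 0
    all_dev: list[float] = []
    disp_vals, disp_cn = [], []
    for t_clone, w in weights.items():
        if t_clone not in matching:
            continue
        p_clone = matching[t_clone]
        conf = ev.bin_and_classify(
            truth_frames[t_clone], pred_frames[p_clone], chrom_lengths, bin_size
        )
        for k in conf_keys:
            agg[k] += w * conf[k]
        excluded += conf["bins_excluded"]
        tb = ev.bin_profile(truth_frames[t_clone], chrom_lengths, bin_size)
        pb = ev.bin_profile(pred_frames[p_clone], chrom_lengths, bin_size)
        t, p, _ = ev._flatten_bins(tb, pb)
        rmse_sq += w * float(np.mean((t - p) ** 2))
        rmse_w += w
        # inferred per-bin copy-ratio signal grouped by true CN state
        rb = ev.bin_profile(ratio_frames[p_clone], chrom_lengths, bin_size)
        t2, r2, _ = ev._flatten_bins(tb, rb)
        disp_vals.append(r2)
        disp_cn.append(t2)
        # breakpoints: interior truth boundaries vs inferred CN-change points
        t_bp = _profile_breakpoints(truth_frames[t_clone])
        p_bp = _profile_breakpoints(pred_frames[p_clone])
        _, devs, _ = ev.breakpoint_deviation(t_bp, p_bp)
        all_dev.extend(devs)

    for k in conf_keys:
        setattr(report, k, agg[k])
    report.rmse = float(np.sqrt(rmse_sq / rmse_w)) if rmse_w else np.nan
    report.bins_excluded = excluded
    report.bacc_weighted = ev.bacc_subclones(
        truth.cell_clones,
        result.clones,
        truth_frames,
        pred_frames,
        chrom_lengths,
        bin_size,
    )
    report.breakpoint_deviations = all_dev
    report.breakpoint_deviation_mb = (
        float(np.mean(all_dev)) if all_dev else np.nan
    )
    if disp_vals:
        disp = ev.dispersion_score(
            np.concatenate(disp_vals), np.concatenate(disp_cn)
        )
        report.dispersion = np.nan if disp is None else disp
    sens, n_ev = ev.broad_event_sensitivity(truth, pred_frames, matching)
    report.broad_sensitivity = sens
    report.extras["n_broad_events"] = n_ev
    report.extras["n_clones_inferred"] = len(pred_frames)
    report.extras["n_clones_true"] = len(truth_frames)
    return report


def _profile_breakpoints(frame: pd.DataFrame) -> pd.DataFrame:
    """Interior boundaries where the integer CN changes."""
    rows = []
    for chrom, grp in frame.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cn = grp["cn"].to_numpy()
        pos = grp["start"].to_numpy()
        for i in range(1, len(grp)):
            if cn[i] != cn[i - 1]:
                rows.append((chrom, int(pos[i])))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def benchmark(
    configs,
    run_config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate + run + evaluate each config; one EvalReport row per dataset.

    Individual dataset failures are recorded and the sweep continues.
    """
    from clonecn.simulate import simulate_dataset

    rows = []
    for i, cfg in enumerate(configs):
        rc = run_config or RunConfig(seed=cfg.seed)
        try:
            ref, inf, truth = simulate_dataset(cfg)
            counts, ann = _combine(ref, inf)
            result = run(counts, ann, rc)
            rep = evaluate_run(truth, result, bin_size=rc.bin_kb * 1000)
            row = rep.to_dict()
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 — sweep must continue
            logger.error("dataset %d failed: %s", i, exc)
            row = {"error": str(exc)}
        row.update(
            {
                "dataset": i,
                "n_cells": cfg.n_cells,
                "n_clones_planted": len(cfg.clone_prevalences),
                "cnv_frac": cfg.cnv_genome_frac,
                "seed": cfg.seed,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "benchmark.tsv", sep="\t", index=False)
    return table


def _combine(ref: CountMatrix, inf: CountMatrix):
    """Stack a simulated (reference, inferred) pair into one annotated matrix."""
    import scipy.sparse as sp

    counts = CountMatrix(
        ref.peaks,
        ref.barcodes + inf.barcodes,
        sp.hstack([ref.counts, inf.counts], format="csr"),
    )
    ann = CellAnnotation(
        pd.Series(
            ["reference"] * len(ref.barcodes) + ["inferred"] * len(inf.barcodes),
            index=ref.barcodes + inf.barcodes,
        )
    )
    return counts, ann
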