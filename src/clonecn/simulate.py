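"""Seedable benchmark simulator: sparse scATAC-like peak counts with planted
clonal copy-number ground truth.

The generative model is a Gamma-Poisson (negative-binomial marginal) with
lognormal per-cell depth: per-peak baseline accessibility lambda_i ~ Gamma,
cell depth d_c ~ LogNormal, and

    count[i, c] ~ Poisson(d_c * lambda_i * CN[clone(c), i] / 2)

with optional extra zero-inflation.  Reference cells are diploid everywhere.
Clonal CNV events are contiguous segments drawn uniformly over chromosomes
until a target genomic fraction is covered; the diploid baseline is CN 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from clonecn.io import AUTOSOMES, CountMatrix, PeakSet, build_peak_set

logger = logging.getLogger(__name__)

#: whole-genome size emulated (scaled down by using fewer chromosomes)
GENOME_BP = 3_000_000_000
#: chromosome length when the genome is scaled to n_chroms autosomes
CHROM_BP = GENOME_BP // 22


@dataclass
class SimConfig:
    """Benchmark dataset configuration.

    Paper-faithful ranges: 50-10 000 inferred cells, 1-5 clones with
    prevalences in [0.10, 0.90], CNV genomic fractions in [0.10, 0.60], with
    a 10%-prevalence clone acting as the rare clone.
    """

    n_cells: int = 500
    n_ref_cells: int = 200
    clone_prevalences: tuple[float, ...] = (1.0,)
    cnv_genome_frac: float = 0.30
    cnv_states: tuple[int, ...] = (1, 3, 4)
    n_peaks: int = 8000
    n_chroms: int = 6
    lam_shape: float = 0.6
    lam_mean: float = 0.4
    depth_cv: float = 0.5
    dropout: float = 0.0
    min_event_mb: float = 5.0
    max_event_mb: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        prev = np.asarray(self.clone_prevalences, dtype=float)
        if not np.isclose(prev.sum(), 1.0):
            raise ValueError("clone prevalences must sum to 1")
        if len(prev) < 1 or len(prev) > 5:
            raise ValueError("1-5 clones supported")
        if np.any(np.floor(prev * self.n_cells) < 1):
            raise ValueError("infeasible config: a clone would have <1 cell")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {AUTOSOMES[i]: CHROM_BP for i in range(self.n_chroms)}


@dataclass
class TruthProfile:
    """Planted ground truth: per-clone CN segment maps and cell assignments."""

    segments: pd.DataFrame  # clone, chrom, start, end, cn — tiles each chrom
    cell_clones: pd.Series  # inferred barcode -> clone id
    rare_clones: tuple[int, ...] = field(default=())
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def clone_segments(self, clone: int) -> pd.DataFrame:
        return self.segments[self.segments["clone"] == clone].reset_index(
            drop=True
        )

    def events(self, clone: int) -> pd.DataFrame:
        """Non-diploid planted segments of one clone."""
        seg = self.clone_segments(clone)
        return seg[seg["cn"] != 2].reset_index(drop=True)

    def validate(self) -> None:
        for clone, grp in self.segments.groupby("clone"):
            for chrom, cg in grp.groupby("chrom"):
                cg = cg.sort_values("start")
                if cg["start"].iloc[0] != 0:
                    raise AssertionError("segments must start at 0")
                if int(cg["end"].iloc[-1]) != self.chrom_lengths[chrom]:
                    raise AssertionError("segments must end at chrom end")
                if not np.array_equal(
                    cg["end"].to_numpy()[:-1], cg["start"].to_numpy()[1:]
                ):
                    raise AssertionError(f"gaps in clone {clone} {chrom}")


def _make_peaks(cfg: SimConfig, rng: np.random.Generator) -> PeakSet:
    """Evenly spaced peaks with jitter, width 500 bp, across n_chroms."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_peaks // cfg.n_chroms)
    per_chrom[: cfg.n_peaks % cfg.n_chroms] += 1
    chroms, starts, ends = [], [], []
    for ci in range(cfg.n_chroms):
        k = per_chrom[ci]
        spacing = CHROM_BP / k
        centers = (np.arange(k) + 0.5) * spacing
        centers = centers + rng.uniform(-0.3, 0.3, size=k) * spacing
        centers = np.sort(np.clip(centers, 300, CHROM_BP - 300))
        chroms.extend([AUTOSOMES[ci]] * k)
        starts.extend((centers - 250).astype(np.int64))
        ends.extend((centers + 250).astype(np.int64))
    ps, _, _ = build_peak_set(chroms, starts, ends)
    return ps


def _plant_events(
    cfg: SimConfig, rng: np.random.Generator
) -> list[pd.DataFrame]:
    """Per-clone CNV event lists (non-overlapping within a clone).

    Events keep a margin from chromosome ends and from each other so that
    the diploid stretches between events stay resolvable (segments below
    ~2 Mb are by construction below the method's resolution).
    """
    target_bp = cfg.cnv_genome_frac * cfg.n_chroms * CHROM_BP
    min_bp = cfg.min_event_mb * 1e6
    max_bp = min(cfg.max_event_mb * 1e6, 0.9 * CHROM_BP)
    margin = 5e6
    all_events = []
    for _ in range(len(cfg.clone_prevalences)):
        events: list[tuple[str, int, int, int]] = []
        covered = 0.0
        attempts = 0
        while covered < target_bp and attempts < 10_000:
            attempts += 1
            chrom = AUTOSOMES[rng.integers(cfg.n_chroms)]
            length = int(rng.uniform(min_bp, max_bp))
            if length + 2 * margin > CHROM_BP:
                continue
            start = int(rng.uniform(margin, CHROM_BP - length - margin))
            end = start + length
            clash = any(
                c == chrom and s < end + margin and e > start - margin
                for c, s, e, _ in events
            )
            if clash:
                continue
            cn = int(rng.choice(cfg.cnv_states))
            events.append((chrom, start, end, cn))
            covered += length
        all_events.append(
            pd.DataFrame(events, columns=["chrom", "start", "end", "cn"])
        )
    return all_events


def _truth_from_events(
    cfg: SimConfig, events: list[pd.DataFrame]
) -> pd.DataFrame:
    rows = []
    for clone, ev in enumerate(events):
        for ci in range(cfg.n_chroms):
            chrom = AUTOSOMES[ci]
            sub = ev[ev["chrom"] == chrom].sort_values("start")
            pos = 0
            for _, r in sub.iterrows():
                if r["start"] > pos:
                    rows.append((clone, chrom, pos, int(r["start"]), 2))
                rows.append(
                    (clone, chrom, int(r["start"]), int(r["end"]), int(r["cn"]))
                )
                pos = int(r["end"])
            if pos < CHROM_BP:
                rows.append((clone, chrom, pos, CHROM_BP, 2))
    return pd.DataFrame(rows, columns=["clone", "chrom", "start", "end", "cn"])


def _peak_cn(peaks: PeakSet, clone_segments: pd.DataFrame) -> np.ndarray:
    """Integer CN at each peak midpoint for one clone."""
    cn = np.full(len(peaks), 2, dtype=int)
    mid = (peaks.start + peaks.end) // 2
    for chrom, grp in clone_segments.groupby("chrom"):
        on = peaks.chrom == chrom
        if not on.any():
            continue
        bounds = grp.sort_values("start")
        idx = np.searchsorted(bounds["start"].to_numpy(), mid[on], side="right") - 1
        cn[np.flatnonzero(on)] = bounds["cn"].to_numpy()[idx]
    return cn


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[CountMatrix, CountMatrix, TruthProfile]:
    """Generate (reference, inferred, truth) for one benchmark dataset.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    peaks = _make_peaks(cfg, rng)
    events = _plant_events(cfg, rng)
    truth_segments = _truth_from_events(cfg, events)

    lam = rng.gamma(cfg.lam_shape, cfg.lam_mean / cfg.lam_shape, size=len(peaks))
    sigma2 = np.log1p(cfg.depth_cv**2)
    mu = -sigma2 / 2.0  # unit-mean depth

    def _counts(n_cells: int, cn_factor: np.ndarray) -> sp.csr_matrix:
        depth = rng.lognormal(mu, np.sqrt(sigma2), size=n_cells)
        rate = (lam * cn_factor)[:, None] * depth[None, :]
        counts = rng.poisson(rate)
        if cfg.dropout > 0:
            counts = counts * (rng.random(counts.shape) >= cfg.dropout)
        return sp.csr_matrix(counts)

    ref_counts = _counts(cfg.n_ref_cells, np.ones(len(peaks)))
    ref = CountMatrix(
        peaks, [f"REF_{i}" for i in range(cfg.n_ref_cells)], ref_counts
    )

    prev = np.asarray(cfg.clone_prevalences)
    clone_sizes = np.floor(prev * cfg.n_cells).astype(int)
    clone_sizes[0] += cfg.n_cells - clone_sizes.sum()
    blocks, cell_clones = [], []
    for clone, size in enumerate(clone_sizes):
        cn_factor = _peak_cn(peaks, truth_segments[truth_segments["clone"] == clone]) / 2.0
        blocks.append(_counts(size, cn_factor))
        cell_clones.extend([clone] * size)
    inf_counts = sp.hstack(blocks, format="csr")
    inf_barcodes = [f"TUM_{i}" for i in range(cfg.n_cells)]
    inferred = CountMatrix(peaks, inf_barcodes, inf_counts)

    rare = tuple(int(i) for i, p in enumerate(prev) if p <= 0.10 + 1e-9)
    truth = TruthProfile(
        segments=truth_segments,
        cell_clones=pd.Series(cell_clones, index=inf_barcodes),
        rare_clones=rare,
        chrom_lengths=cfg.chrom_lengths,
    )
    return ref, inferred, truth


def benchmark_grid(
    cell_sizes: tuple[int, ...] = (50, 200, 1000, 5000),
    clone_counts: tuple[int, ...] = (1, 2, 3, 4, 5),
    cnv_fracs: tuple[float, ...] = (0.1, 0.3, 0.6),
    replicates: int = 1,
    base_seed: int = 0,
    **overrides,
) -> list[SimConfig]:
    """Cross-product benchmark grid emulating the published evaluation design.

    With >= 2 clones, one clone is placed at 10% prevalence (the rare clone)
    and the remainder is split evenly among the others.
    """
    configs = []
    i = 0
    for n_cells in cell_sizes:
        for k in clone_counts:
            if k == 1:
                prev: tuple[float, ...] = (1.0,)
            else:
                rest = round(0.9 / (k - 1), 10)
                prev = tuple([rest] * (k - 1) + [1.0 - rest * (k - 1)])
            for frac in cnv_fracs:
                for rep in range(replicates):
                    configs.append(
                        SimConfig(
                            n_cells=n_cells,
                            clone_prevalences=prev,
                            cnv_genome_frac=frac,
                            seed=(base_seed + 104_729 * i) % (2**31),
                            **overrides,
                        )
                    )
                    i += 1
    return configs


# ---------------------------------------------------------------------------
# on-disk dataset export (same formats io.read_inputs consumes)
# ---------------------------------------------------------------------------


def write_dataset(
    ref: CountMatrix,
    inferred: CountMatrix,
    truth: TruthProfile,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = sp.hstack([ref.counts, inferred.counts], format="coo")
    scipy.io.mmwrite(str(out / "counts.mtx"), combined, field="integer")
    ref.peaks.to_frame().to_csv(
        out / "peaks.bed", sep="\t", header=False, index=False
    )
    barcodes = ref.barcodes + inferred.barcodes
    (out / "barcodes.txt").write_text("\n".join(barcodes) + "\n")
    ann = pd.DataFrame(
        {
            "barcode": barcodes,
            "group": ["reference"] * len(ref.barcodes)
            + ["inferred"] * len(inferred.barcodes),
        }
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
    truth.cell_clones.rename_axis("barcode").rename("clone").to_csv(
        out / "truth_cells.tsv", sep="\t"
    )
    (out / "truth_meta.json").write_text(
        json.dumps(
            {
                "rare_clones": list(truth.rare_clones),
                "chrom_lengths": truth.chrom_lengths,
            },
            indent=2,
        )
    )


def read_truth(out_dir: str | Path) -> TruthProfile:
    out = Path(out_dir)
    segments = pd.read_csv(out / "truth_segments.tsv", sep="\t")
    cells = pd.read_csv(out / "truth_cells.tsv", sep="\t")
    meta = json.loads((out / "truth_meta.json").read_text())
    return TruthProfile(
        segments=segments,
        cell_clones=pd.Series(cells["clone"].values, index=cells["barcode"].values),
        rare_clones=tuple(meta["rare_clones"]),
        chrom_lengths={k: int(v) for k, v in meta["chrom_lengths"].items()},
    )
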