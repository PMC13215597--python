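"""Core data containers and readers/writers for on-disk formats.

Inputs are a peak-by-cell count matrix (Matrix Market triplet), peak
coordinates (BED, 0-based half-open), cell barcodes (one per line) and a cell
annotation table (TSV, barcode -> reference|inferred).  Only autosomal peaks
(chr1..chr22) are analyzed; chrX/chrY and non-canonical contigs are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: canonical autosomes in natural order
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_CHROM_RANK = {c: i for i, c in enumerate(AUTOSOMES)}


def _normalize_chrom(name: str) -> str:
    """Map '1'..'22' to 'chr1'..'chr22'; leave other names untouched."""
    name = str(name)
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class PeakSet:
    """Sorted autosomal peak intervals (0-based half-open)."""

    chrom: np.ndarray  # str array
    start: np.ndarray  # int64
    end: np.ndarray  # int64

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == n):
            raise ValueError("chrom/start/end length mismatch")
        if n == 0:
            return
        if np.any(self.start >= self.end):
            raise ValueError("peak intervals must satisfy start < end")
        bad = [c for c in np.unique(self.chrom) if c not in _CHROM_RANK]
        if bad:
            raise ValueError(f"non-autosomal chromosomes in PeakSet: {bad}")
        rank = np.array([_CHROM_RANK[c] for c in self.chrom])
        key = rank * 10**10 + self.start
        if np.any(np.diff(key) < 0):
            raise ValueError("PeakSet must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def chrom_rank(self) -> np.ndarray:
        return np.array([_CHROM_RANK[c] for c in self.chrom])

    def subset(self, idx: np.ndarray) -> "PeakSet":
        """Index-based subset; `idx` must preserve sort order."""
        return PeakSet(self.chrom[idx], self.start[idx], self.end[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end}
        )


def build_peak_set(
    chrom: Sequence[str], start: Sequence[int], end: Sequence[int]
) -> tuple[PeakSet, np.ndarray, int]:
    """Sort peaks into canonical order, dropping non-autosomal contigs.

    Returns (peak_set, order, n_dropped) where ``order`` gives, for every
    output row, the index of the corresponding input row — use it to permute a
    count matrix consistently.
    """
    chrom = np.array([_normalize_chrom(c) for c in chrom], dtype=object)
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    keep = np.array([c in _CHROM_RANK for c in chrom])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal peaks", n_dropped)
    idx = np.flatnonzero(keep)
    rank = np.array([_CHROM_RANK[c] for c in chrom[idx]])
    order = idx[np.lexsort((start[idx], rank))]
    ps = PeakSet(
        chrom[order].astype(object), start[order].copy(), end[order].copy()
    )
    return ps, order, n_dropped


@dataclass
class CountMatrix:
    """Sparse peaks x cells non-negative integer counts."""

    peaks: PeakSet
    barcodes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.peaks)} peaks x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_peaks(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.peaks.subset(idx), self.barcodes, self.counts[idx])

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        bc = [self.barcodes[i] for i in np.atleast_1d(idx)]
        return CountMatrix(self.peaks, bc, self.counts[:, idx])


@dataclass
class CellAnnotation:
    """Barcode -> group ('reference' | 'inferred') mapping."""

    groups: pd.Series  # index barcode, values in {reference, inferred}

    VALID = ("reference", "inferred")

    def __post_init__(self) -> None:
        bad = set(self.groups.unique()) - set(self.VALID)
        if bad:
            raise ValueError(f"unknown annotation groups: {sorted(bad)}")
        for g in self.VALID:
            if not (self.groups == g).any():
                raise ValueError(f"annotation group '{g}' is empty")

    def barcodes(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class NormalizedMatrix:
    """Depth-normalized (truncated, rescaled) counts; same layout as CountMatrix."""

    peaks: PeakSet
    barcodes: list[str]
    values: sp.csr_matrix
    mean_library_size: float = field(default=np.nan)


@dataclass
class CloneProfile:
    """Final per-clone output: segments with integer CN, ploidy, reliability."""

    clone_id: int
    segments: pd.DataFrame  # chrom,start,end,segment_ratio,integer_cn,posterior_prob
    ploidy: float
    reliability: float
    n_cells: int
    model: dict | None = None  # theta, mu, sigma2, delta, AIC table

    SEG_COLUMNS = (
        "chrom",
        "start",
        "end",
        "segment_ratio",
        "integer_cn",
        "posterior_prob",
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_inputs(
    counts_path: str | Path,
    peaks_path: str | Path,
    barcodes_path: str | Path,
    annotation_path: str | Path,
    blacklist_path: str | Path | None = None,
) -> tuple[CountMatrix, CellAnnotation]:
    """Read an MTX + BED + barcodes + annotation quartet.

    Matrix rows are re-ordered to canonical sorted peak order; chrX/chrY and
    non-canonical peaks are dropped (count logged).  An optional blacklist BED
    removes any peak overlapping a blacklisted interval.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(counts_path)))
    bed = pd.read_csv(
        peaks_path, sep="\t", header=None, comment="#", usecols=[0, 1, 2]
    )
    barcodes = [
        line.strip()
        for line in Path(barcodes_path).read_text().splitlines()
        if line.strip()
    ]
    if mat.shape[0] != len(bed):
        raise ValueError(
            f"matrix has {mat.shape[0]} rows but BED has {len(bed)} peaks"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[1]} columns but {len(barcodes)} barcodes given"
        )

    peaks, order, n_dropped = build_peak_set(bed[0], bed[1], bed[2])
    mat = mat[order]
    if blacklist_path is not None:
        keep = ~_overlaps_bed(peaks, blacklist_path)
        logger.info("blacklist removed %d peaks", int((~keep).sum()))
        peaks = peaks.subset(np.flatnonzero(keep))
        mat = mat[np.flatnonzero(keep)]

    ann = pd.read_csv(annotation_path, sep="\t")
    ann.columns = [c.lower() for c in ann.columns]
    if not {"barcode", "group"} <= set(ann.columns):
        raise ValueError("annotation TSV needs 'barcode' and 'group' columns")
    missing = sorted(set(ann["barcode"]) - set(barcodes))
    if missing:
        raise ValueError(
            f"annotated barcodes absent from matrix: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    annotation = CellAnnotation(
        pd.Series(ann["group"].values, index=ann["barcode"].values)
    )
    return CountMatrix(peaks, barcodes, mat), annotation


def _overlaps_bed(peaks: PeakSet, bed_path: str | Path) -> np.ndarray:
    """Boolean mask of peaks overlapping (>=1 bp) any interval in a BED file."""
    bl = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2])
    bl[0] = bl[0].map(_normalize_chrom)
    hit = np.zeros(len(peaks), dtype=bool)
    for chrom, grp in bl.groupby(0):
        on = peaks.chrom == chrom
        if not on.any():
            continue
        s, e = peaks.start[on], peaks.end[on]
        m = np.zeros(on.sum(), dtype=bool)
        for _, row in grp.iterrows():
            m |= (s < row[2]) & (e > row[1])
        hit[np.flatnonzero(on)] = m
    return hit


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_outputs(
    clones: pd.Series,
    profiles: Sequence[CloneProfile],
    out_dir: str | Path,
    run_report: dict | None = None,
) -> None:
    """Write clones.tsv, segments.tsv, clone_summary.json and run_report.json.

    ``clones`` maps inferred-cell barcode -> integer clone id.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    clones.rename_axis("barcode").rename("clone_id").to_csv(
        out / "clones.tsv", sep="\t"
    )

    seg_frames = []
    for p in profiles:
        seg = p.segments.loc[:, list(CloneProfile.SEG_COLUMNS[:3])].copy()
        seg["clone_id"] = p.clone_id
        seg["segment_ratio"] = p.segments["segment_ratio"].values
        seg["integer_cn"] = p.segments["integer_cn"].values
        seg["posterior_prob"] = p.segments["posterior_prob"].values
        seg_frames.append(seg)
    segments = pd.concat(seg_frames, ignore_index=True)
    segments.to_csv(out / "segments.tsv", sep="\t", index=False)

    summary = {
        str(p.clone_id): {
            "ploidy": float(p.ploidy),
            "reliability_score": float(p.reliability),
            "n_cells": int(p.n_cells),
        }
        for p in profiles
    }
    (out / "clone_summary.json").write_text(json.dumps(summary, indent=2))
    models = {
        str(p.clone_id): p.model for p in profiles if p.model is not None
    }
    if models:
        (out / "clone_models.json").write_text(json.dumps(models, indent=2))
    if run_report is not None:
        (out / "run_report.json").write_text(json.dumps(run_report, indent=2))


def read_outputs(out_dir: str | Path) -> tuple[pd.Series, list[CloneProfile]]:
    """Re-read what :func:`write_outputs` produced (round-trip support)."""
    out = Path(out_dir)
    clone_df = pd.read_csv(out / "clones.tsv", sep="\t")
    clones = pd.Series(
        clone_df["clone_id"].values, index=clone_df["barcode"].values
    )
    segments = pd.read_csv(out / "segments.tsv", sep="\t")
    summary = json.loads((out / "clone_summary.json").read_text())
    models_path = out / "clone_models.json"
    models = json.loads(models_path.read_text()) if models_path.exists() else {}
    profiles = []
    for cid_str, info in summary.items():
        cid = int(cid_str)
        seg = segments[segments["clone_id"] == cid].reset_index(drop=True)
        seg = seg.loc[:, list(CloneProfile.SEG_COLUMNS)]
        profiles.append(
            CloneProfile(
                clone_id=cid,
                segments=seg,
                ploidy=info["ploidy"],
                reliability=info["reliability_score"],
                n_cells=info["n_cells"],
                model=models.get(cid_str),
            )
        )
    profiles.sort(key=lambda p: p.clone_id)
    return clones, profiles
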