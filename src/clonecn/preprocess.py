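"""Quality filters, count truncation, depth normalization and the ratio matrix.

The pipeline compares candidate tumor ("inferred") cells against non-malignant
("reference") cells assumed diploid.  After peak/cell QC, counts are truncated
to [0, 4], each cell is normalized to its group's mean library size, and the
per-peak ratio R[i, j] = Y'[i, j] / mean_ref(X'[i, .]) encodes the relative
accessibility of inferred cell j at peak i — approximately CN/2 under a
diploid reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from clonecn.io import CountMatrix, NormalizedMatrix, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class RatioMatrix:
    """Per-peak inferred-to-reference relative accessibility ratios."""

    peaks: PeakSet
    barcodes: list[str]  # inferred cells
    ratios: sp.csr_matrix  # peaks x inferred cells, >= 0
    reference_mean: np.ndarray  # per-peak aggregated reference signal

    def __post_init__(self) -> None:
        if self.ratios.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError("ratio matrix shape inconsistent with peaks/barcodes")
        if np.any(self.reference_mean <= 0):
            raise ValueError("reference_mean must be strictly positive")


def filter_peaks(
    counts: CountMatrix,
    min_cell_frac: float = 0.05,
    min_peaks: int = 10_000,
    relax_step: float = 0.005,
) -> tuple[CountMatrix, dict]:
    """Remove peaks detected (count > 0) in fewer than ``min_cell_frac`` of cells.

    If fewer than ``min_peaks`` peaks survive, the detection threshold is
    relaxed in steps of ``relax_step`` (0.5 percentage points) until at least
    ``min_peaks`` are retained (floor at 0, i.e. keep everything).
    """
    n_peaks, n_cells = counts.shape
    detected = np.asarray((counts.counts > 0).sum(axis=1)).ravel()
    if n_peaks < min_peaks:
        logger.warning(
            "only %d peaks in input (< %d); keeping all", n_peaks, min_peaks
        )
        info = {
            "effective_threshold": 0.0,
            "n_input": n_peaks,
            "n_retained": n_peaks,
        }
        return counts, info

    frac = min_cell_frac
    while frac > 0:
        keep = detected >= frac * n_cells
        if keep.sum() >= min_peaks:
            break
        frac = max(0.0, frac - relax_step)
    else:
        keep = np.ones(n_peaks, dtype=bool)
    if frac <= 0:
        keep = np.ones(n_peaks, dtype=bool)
    info = {
        "effective_threshold": float(frac),
        "n_input": int(n_peaks),
        "n_retained": int(keep.sum()),
    }
    logger.info(
        "peak filter: %d -> %d peaks at threshold %.3f",
        n_peaks,
        info["n_retained"],
        frac,
    )
    return counts.subset_peaks(np.flatnonzero(keep)), info


def _chrom_zero_fraction(counts: CountMatrix) -> np.ndarray:
    """Per cell and chromosome, the zero-count peak fraction (chroms x cells)."""
    chroms = np.unique(counts.peaks.chrom)
    out = np.zeros((len(chroms), counts.shape[1]))
    csc = counts.counts.tocsc()
    for k, chrom in enumerate(chroms):
        rows = np.flatnonzero(counts.peaks.chrom == chrom)
        nonzero = np.asarray((csc[rows] > 0).sum(axis=0)).ravel()
        out[k] = 1.0 - nonzero / len(rows)
    return out


def filter_cells(
    counts: CountMatrix,
    pct: tuple[float, float] = (5.0, 95.0),
    max_zero_frac: float = 0.60,
    group_name: str = "",
    dropout_margin: float = 0.15,
) -> tuple[CountMatrix, dict]:
    """Keep cells whose total counts and detected-peak numbers fall within the
    group's inclusive [p5, p95] band, then drop cells showing chromosomal
    dropout: a zero-count peak fraction on any single chromosome exceeding
    max(``max_zero_frac``, that chromosome's median fraction across the group
    + ``dropout_margin``).

    The adaptive term keeps the rule meaningful on very sparse data, where
    every cell exceeds a fixed 60% zero fraction on every chromosome; on
    dense data the fixed 60% threshold binds.  Apply separately within the
    reference and the inferred group.
    """
    totals = np.asarray(counts.counts.sum(axis=0)).ravel()
    n_det = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    lo_t, hi_t = np.percentile(totals, pct)
    lo_d, hi_d = np.percentile(n_det, pct)
    keep = (
        (totals >= lo_t) & (totals <= hi_t) & (n_det >= lo_d) & (n_det <= hi_d)
    )
    zero_frac = _chrom_zero_fraction(counts)  # chroms x cells
    thresh = np.maximum(
        max_zero_frac, np.median(zero_frac, axis=1) + dropout_margin
    )
    keep &= np.all(zero_frac <= thresh[:, None], axis=0)
    if not keep.any():
        raise ValueError(
            f"cell QC left the {group_name or 'cell'} group empty "
            f"(totals band [{lo_t:.0f},{hi_t:.0f}], detected band "
            f"[{lo_d:.0f},{hi_d:.0f}], max per-chrom zero frac {max_zero_frac})"
        )
    info = {
        "group": group_name,
        "n_input": int(counts.shape[1]),
        "n_retained": int(keep.sum()),
        "totals_band": [float(lo_t), float(hi_t)],
        "detected_band": [float(lo_d), float(hi_d)],
    }
    logger.info(
        "cell filter%s: %d -> %d cells",
        f" ({group_name})" if group_name else "",
        counts.shape[1],
        info["n_retained"],
    )
    return counts.subset_cells(np.flatnonzero(keep)), info


def truncate_and_normalize(
    counts: CountMatrix, truncate_at: int = 4
) -> NormalizedMatrix:
    """Truncate counts to [0, truncate_at], then rescale each cell to the
    matrix's mean library size (computed after truncation).

    Cells with zero total after truncation are removed with a warning.
    """
    mat = counts.counts.copy().astype(np.float64)
    mat.data = np.minimum(mat.data, truncate_at)
    totals = np.asarray(mat.sum(axis=0)).ravel()
    nonempty = totals > 0
    if not nonempty.all():
        logger.warning(
            "removing %d cells with zero total after truncation",
            int((~nonempty).sum()),
        )
        mat = mat[:, nonempty]
        totals = totals[nonempty]
    barcodes = [b for b, ok in zip(counts.barcodes, nonempty) if ok]
    mean_lib = float(totals.mean())
    scale = mean_lib / totals
    mat = mat @ sp.diags(scale)
    return NormalizedMatrix(
        counts.peaks, barcodes, sp.csr_matrix(mat), mean_lib
    )


def compute_ratio(
    inferred: NormalizedMatrix,
    reference: NormalizedMatrix,
    ref_agg: str = "mean",
) -> tuple[RatioMatrix, dict]:
    """R[i, j] = Y'[i, j] / ref_agg(X'[i, .]).

    Peaks whose aggregated reference signal is zero are dropped (logged).
    ``ref_agg`` is 'mean' (default, matching the model definition) or 'median'.
    """
    if len(inferred.peaks) != len(reference.peaks) or np.any(
        inferred.peaks.start != reference.peaks.start
    ):
        raise ValueError("inferred and reference matrices must share one PeakSet")
    if ref_agg == "mean":
        ref = np.asarray(reference.values.mean(axis=1)).ravel()
    elif ref_agg == "median":
        ref = np.median(reference.values.toarray(), axis=1)
    else:
        raise ValueError(f"unknown ref_agg '{ref_agg}'")
    keep = ref > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no peak has non-zero reference signal")
    if n_dropped:
        logger.info("dropped %d peaks with zero reference signal", n_dropped)
    idx = np.flatnonzero(keep)
    values = inferred.values[idx]
    ratios = sp.diags(1.0 / ref[idx]) @ values
    rm = RatioMatrix(
        inferred.peaks.subset(idx),
        inferred.barcodes,
        sp.csr_matrix(ratios),
        ref[idx],
    )
    return rm, {"n_zero_reference_dropped": n_dropped, "kept_idx": idx}
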