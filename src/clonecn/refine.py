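"""Merging over-clustered subgroups into final clones.

Initial Leiden subgroups often over-partition a genetically homogeneous
population.  Every pair of subgroups is compared on the segmented ratio of
their mean normalized peak profiles: two subgroups stay separate only if some
segment shows BOTH a Benjamini-Hochberg-adjusted two-sided t-test p < alpha
AND a different inferred integer CN.  Clones are the connected components of
the resulting adjacency matrix; each clone's segmentation and CN profile is
then re-estimated from the merged cell set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from clonecn.io import PeakSet
from clonecn.segmentation import Segmentation, segment_profile

logger = logging.getLogger(__name__)


def _lift_cn(seg_table: pd.DataFrame, cn: np.ndarray, chrom: str, start: int, end: int) -> int | None:
    """CN call of the segment with maximal overlap of [start, end) on chrom."""
    on = seg_table["chrom"] == chrom
    if not on.any():
        return None
    s = seg_table.loc[on, "start"].to_numpy()
    e = seg_table.loc[on, "end"].to_numpy()
    overlap = np.minimum(e, end) - np.maximum(s, start)
    if overlap.max() <= 0:
        return None
    return int(cn[np.flatnonzero(on)[np.argmax(overlap)]])


def pairwise_equivalence(
    profile_i: np.ndarray,
    profile_j: np.ndarray,
    peaks: PeakSet,
    seg_i: Segmentation,
    cn_i: np.ndarray,
    seg_j: Segmentation,
    cn_j: np.ndarray,
    window_size: int = 5,
    alpha: float = 0.05,
    min_seg_len: float = 2e6,
    seg_method: str = "pelt",
    min_peaks_per_segment: int = 3,
) -> int:
    """1 if two subgroups are CN-equivalent (should merge), else 0.

    ``profile_i``/``profile_j`` are mean normalized per-peak signals of the
    two subgroups.  Their ratio profile is windowed and segmented; within each
    segment the two subgroups' per-peak signals are compared by a Welch
    two-sided t-test, BH-adjusted across segments.  Separation requires an
    adjusted p < alpha in a segment where the lifted integer CN also differs.
    """
    ok = (profile_j > 0) & np.isfinite(profile_i) & np.isfinite(profile_j)
    if ok.sum() < window_size:
        logger.warning("too few usable peaks for pairwise comparison; merging")
        return 1
    ratio = profile_i[ok] / profile_j[ok]
    chrom = peaks.chrom[ok]
    p_start = peaks.start[ok]
    p_end = peaks.end[ok]

    # window the peak-level ratio per chromosome, mirroring bin_ratios
    w_chrom, w_start, w_end, w_val, w_slice = [], [], [], [], []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        for lo in range(0, len(idx), window_size):
            member = idx[lo : lo + window_size]
            w_chrom.append(c)
            w_start.append(p_start[member[0]])
            w_end.append(p_end[member[-1]])
            w_val.append(ratio[member].mean())
            w_slice.append(member)
    seg = segment_profile(
        np.array(w_chrom, dtype=object),
        np.array(w_start, dtype=np.int64),
        np.array(w_end, dtype=np.int64),
        np.array(w_val),
        method=seg_method,
        min_seg_len=min_seg_len,
    )

    pvals, cn_differs, n_skipped = [], [], 0
    for _, row in seg.table.iterrows():
        member_peaks = np.concatenate(
            w_slice[row["win_first"] : row["win_last"]]
        )
        if len(member_peaks) < min_peaks_per_segment:
            n_skipped += 1
            continue
        a = profile_i[ok][member_peaks]
        b = profile_j[ok][member_peaks]
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(ttest_ind(a, b, equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        pvals.append(p)
        qi = _lift_cn(seg_i.table, cn_i, row["chrom"], row["start"], row["end"])
        qj = _lift_cn(seg_j.table, cn_j, row["chrom"], row["start"], row["end"])
        cn_differs.append(qi is not None and qj is not None and qi != qj)
    if n_skipped:
        logger.info("skipped %d segments with <%d peaks", n_skipped, min_peaks_per_segment)
    if not pvals:
        return 1
    rejected = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    separate = any(r and d for r, d in zip(rejected, cn_differs))
    return 0 if separate else 1


def build_adjacency(
    profiles: np.ndarray,
    peaks: PeakSet,
    segmentations: list[Segmentation],
    cn_calls: list[np.ndarray],
    **kwargs,
) -> np.ndarray:
    """Symmetric 0/1 adjacency over subgroups (diagonal 1)."""
    k = profiles.shape[0]
    A = np.eye(k, dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            A[i, j] = A[j, i] = pairwise_equivalence(
                profiles[i],
                profiles[j],
                peaks,
                segmentations[i],
                cn_calls[i],
                segmentations[j],
                cn_calls[j],
                **kwargs,
            )
    return A


def finalize_clones(A: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Clone assignment per cell: connected components of the adjacency
    matrix applied to the initial subgroup labels (transitive merging)."""
    A = np.asarray(A)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency matrix must be symmetric")
    n_comp, comp = connected_components(sp.csr_matrix(A), directed=False)
    logger.info("%d subgroups -> %d clones", A.shape[0], n_comp)
    # relabel components by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        c = comp[lab]
        if c not in remap:
            remap[c] = len(remap)
        out[i] = remap[c]
    return out
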