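"""Benchmark metrics for copy-number and clone-recovery performance.

The genome is partitioned into non-overlapping 100-kb bins; bins overlapping
a breakpoint in either the truth or the inferred profile are excluded.  On the
retained bins we compute CNV-presence confusion metrics (CNV = CN != 2),
per-subclone balanced accuracy weighted by cell fraction, bin-level RMSE of
integer CN (with a centering transform for score-based methods), a [0, 1]
dispersion score separating inferred-signal distributions of distinct true CN
states, and breakpoint localization error in Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    precision: float = np.nan
    recall: float = np.nan
    accuracy: float = np.nan
    f1: float = np.nan
    bacc_weighted: float = np.nan
    rmse: float = np.nan
    dispersion: float = np.nan
    breakpoint_deviation_mb: float = np.nan
    breakpoint_deviations: list = field(default_factory=list)
    bins_excluded: int = 0
    broad_sensitivity: float = np.nan
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "precision",
                "recall",
                "accuracy",
                "f1",
                "bacc_weighted",
                "rmse",
                "dispersion",
                "breakpoint_deviation_mb",
                "bins_excluded",
                "broad_sensitivity",
            )
        }
        d.update(self.extras)
        return d


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_profile(
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> dict[str, np.ndarray]:
    """Per-chromosome per-bin CN; NaN where a bin straddles a segment
    boundary (breakpoint bin) or falls outside the profile's coverage."""
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        vals = np.full(n_bins, np.nan)
        sub = segments[segments["chrom"] == chrom].sort_values("start")
        if len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cns = sub.iloc[:, sub.columns.get_loc("cn")].to_numpy()
            b_lo = np.arange(n_bins) * bin_size
            b_hi = np.minimum(b_lo + bin_size, length)
            # a bin gets a CN only if fully inside one segment
            idx = np.searchsorted(starts, b_lo, side="right") - 1
            ok = (idx >= 0) & (b_lo >= starts[np.clip(idx, 0, None)]) & (
                b_hi <= ends[np.clip(idx, 0, None)]
            )
            vals[ok] = cns[idx[ok]]
        out[chrom] = vals
    return out


def _flatten_bins(
    truth_bins: dict[str, np.ndarray], pred_bins: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    t, p = [], []
    excluded = 0
    for chrom in truth_bins:
        tv = truth_bins[chrom]
        pv = pred_bins.get(chrom, np.full_like(tv, np.nan))
        ok = np.isfinite(tv) & np.isfinite(pv)
        excluded += int((~ok).sum())
        t.append(tv[ok])
        p.append(pv[ok])
    return np.concatenate(t), np.concatenate(p), excluded


def bin_and_classify(
    truth_segments: pd.DataFrame,
    inferred_segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> dict:
    """CNV-presence confusion counts and rates over retained bins.

    Degenerate all-negative cases define precision/recall/F1 as 1 (logged).
    """
    tb = bin_profile(truth_segments, chrom_lengths, bin_size)
    pb = bin_profile(inferred_segments, chrom_lengths, bin_size)
    t, p, excluded = _flatten_bins(tb, pb)
    if len(t) == 0:
        raise ValueError("no overlapping retained bins between profiles")
    t_pos = t != 2
    p_pos = p != 2
    tp = int(np.sum(t_pos & p_pos))
    fp = int(np.sum(~t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    tn = int(np.sum(~t_pos & ~p_pos))
    if tp + fp == 0 or tp + fn == 0:
        logger.info("degenerate confusion table (no positives); rates default to 1")
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    accuracy = (tp + tn) / len(t)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "f1": f1,
        "bins_excluded": excluded,
        "n_bins": len(t),
    }


# ---------------------------------------------------------------------------
# clone matching and BACC
# ---------------------------------------------------------------------------


def match_clones(
    truth_cells: pd.Series, inferred_cells: pd.Series
) -> dict[int, int]:
    """Hungarian matching of truth to inferred clones maximizing cell overlap.

    Returns {truth_clone: inferred_clone}; unmatched truth clones are absent.
    """
    common = truth_cells.index.intersection(inferred_cells.index)
    t = truth_cells.loc[common]
    p = inferred_cells.loc[common]
    t_ids = np.sort(t.unique())
    p_ids = np.sort(p.unique())
    overlap = np.zeros((len(t_ids), len(p_ids)))
    for i, ti in enumerate(t_ids):
        for j, pj in enumerate(p_ids):
            overlap[i, j] = np.sum((t == ti) & (p == pj))
    rows, cols = linear_sum_assignment(-overlap)
    return {int(t_ids[r]): int(p_ids[c]) for r, c in zip(rows, cols)}


def bacc_subclones(
    truth_cells: pd.Series,
    inferred_cells: pd.Series,
    truth_profiles: dict[int, pd.DataFrame],
    inferred_profiles: dict[int, pd.DataFrame],
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> float:
    """Cell-fraction-weighted balanced accuracy of clone CN recovery.

    Per matched clone, BACC = (TPR + TNR)/2 on CNV-presence over its bins;
    truth clones left unmatched score 0.
    """
    matching = match_clones(truth_cells, inferred_cells)
    weights = truth_cells.value_counts(normalize=True)
    total = 0.0
    for t_clone, w in weights.items():
        if t_clone not in matching:
            continue  # scores 0
        p_clone = matching[t_clone]
        tb = bin_profile(truth_profiles[t_clone], chrom_lengths, bin_size)
        pb = bin_profile(inferred_profiles[p_clone], chrom_lengths, bin_size)
        t, p, _ = _flatten_bins(tb, pb)
        if len(t) == 0:
            continue
        t_pos, p_pos = t != 2, p != 2
        tpr = (
            np.sum(t_pos & p_pos) / np.sum(t_pos) if t_pos.any() else 1.0
        )
        tnr = (
            np.sum(~t_pos & ~p_pos) / np.sum(~t_pos) if (~t_pos).any() else 1.0
        )
        total += w * (tpr + tnr) / 2.0
    return float(total)


# ---------------------------------------------------------------------------
# RMSE, dispersion, breakpoints, peak classification
# ---------------------------------------------------------------------------


def center_scores(
    scores: np.ndarray, truth_cn: np.ndarray
) -> np.ndarray:
    """Align method scores with integer CN:
    CN_i = score_i - mean(score over bins with the same true CN) + true CN_i."""
    out = np.empty_like(scores, dtype=float)
    for cn in np.unique(truth_cn):
        on = truth_cn == cn
        out[on] = scores[on] - scores[on].mean() + cn
    return out


def rmse_integer_cn(
    truth_cn: np.ndarray,
    inferred: np.ndarray,
    method_kind: str = "integer",
) -> float:
    """Bin-level RMSE vs true integer CN.

    ``method_kind='integer'`` uses values as-is; ``'score'`` applies the
    centering transform first.
    """
    truth_cn = np.asarray(truth_cn, dtype=float)
    inferred = np.asarray(inferred, dtype=float)
    if method_kind == "score":
        inferred = center_scores(inferred, truth_cn)
    elif method_kind != "integer":
        raise ValueError(f"unknown method_kind '{method_kind}'")
    return float(np.sqrt(np.mean((inferred - truth_cn) ** 2)))


def _overlap_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap of the two samples' Gaussian-KDE densities, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() < 1e-12 and b.std() < 1e-12:
        return 1.0 if abs(a.mean() - b.mean()) < 1e-12 else 0.0
    if a.std() < 1e-12 or b.std() < 1e-12:
        # a point mass against a spread distribution: overlap is the density
        # mass the spread sample places in a vanishing neighborhood -> 0
        return 0.0
    ka, kb = gaussian_kde(a), gaussian_kde(b)
    lo = min(a.min(), b.min()) - 3 * max(a.std(), b.std())
    hi = max(a.max(), b.max()) + 3 * max(a.std(), b.std())
    grid = np.linspace(lo, hi, 1024)
    fa, fb = ka(grid), kb(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def dispersion_score(
    values: np.ndarray, true_cn: np.ndarray
) -> float | None:
    """1 - mean pairwise KDE-overlap between adjacent true CN states,
    clipped to [0, 1].  Returns None when < 2 states are present."""
    states = np.sort(np.unique(true_cn))
    if len(states) < 2:
        logger.warning("dispersion score undefined with a single CN state")
        return None
    overlaps = []
    for lo, hi in zip(states[:-1], states[1:]):
        overlaps.append(
            _overlap_coefficient(values[true_cn == lo], values[true_cn == hi])
        )
    return float(np.clip(1.0 - np.mean(overlaps), 0.0, 1.0))


def breakpoint_deviation(
    truth_bps: pd.DataFrame,
    inferred_bps: pd.DataFrame,
    max_match_mb: float | None = 10.0,
) -> tuple[float, list[float], int]:
    """Mean |truth - nearest inferred| breakpoint distance in Mb.

    Both inputs are (chrom, pos) tables.  A true breakpoint is matched to the
    nearest inferred breakpoint on the same chromosome; true breakpoints with
    no inferred breakpoint within ``max_match_mb`` (or none on the
    chromosome) are missed detections, not localization errors — they are
    excluded from the mean and counted as unmatched.  ``max_match_mb=None``
    disables the radius.
    """
    deviations: list[float] = []
    unmatched = 0
    for chrom, grp in truth_bps.groupby("chrom"):
        cand = inferred_bps.loc[
            inferred_bps["chrom"] == chrom, "pos"
        ].to_numpy()
        if len(cand) == 0:
            unmatched += len(grp)
            continue
        for pos in grp["pos"]:
            d = float(np.min(np.abs(cand - pos)) / 1e6)
            if max_match_mb is not None and d > max_match_mb:
                unmatched += 1
            else:
                deviations.append(d)
    mean = float(np.mean(deviations)) if deviations else np.nan
    return mean, deviations, unmatched


def classify_peaks_by_cnv(
    peak_chrom: np.ndarray,
    peak_start: np.ndarray,
    peak_end: np.ndarray,
    cnv_regions: pd.DataFrame,
) -> np.ndarray:
    """'cnv_driven' for peaks overlapping (>= 1 bp) any CNV region of the
    relevant clone, else 'cre_regulated'."""
    out = np.full(len(peak_chrom), "cre_regulated", dtype=object)
    for chrom, grp in cnv_regions.groupby("chrom"):
        on = np.asarray(peak_chrom) == chrom
        if not on.any():
            continue
        s = np.asarray(peak_start)[on]
        e = np.asarray(peak_end)[on]
        hit = np.zeros(on.sum(), dtype=bool)
        for _, r in grp.iterrows():
            hit |= (s < r["end"]) & (e > r["start"])
        out[np.flatnonzero(on)[hit]] = "cnv_driven"
    return out


def broad_event_sensitivity(
    truth,  # TruthProfile
    inferred_profiles: dict[int, pd.DataFrame],
    matching: dict[int, int],
    min_event_bp: float = 20e6,
) -> tuple[float, int]:
    """Fraction of planted events >= ``min_event_bp`` overlapped (>= 1 bp) by
    an inferred CNV call of the correct direction in the matched clone."""
    hits, n_events = 0, 0
    for t_clone in truth.cell_clones.unique():
        events = truth.events(t_clone)
        events = events[events["end"] - events["start"] >= min_event_bp]
        if t_clone not in matching:
            n_events += len(events)
            continue
        pred = inferred_profiles[matching[t_clone]]
        for _, ev in events.iterrows():
            n_events += 1
            sub = pred[
                (pred["chrom"] == ev["chrom"])
                & (pred["start"] < ev["end"])
                & (pred["end"] > ev["start"])
            ]
            direction = np.sign(ev["cn"] - 2)
            if np.any(np.sign(sub["cn"] - 2) == direction):
                hits += 1
    return (hits / n_events if n_events else np.nan), n_events
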