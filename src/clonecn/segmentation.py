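"""Changepoint segmentation of subgroup copy-ratio profiles.

Each chromosome's ordered window-ratio profile is segmented with PELT
(pruned exact linear time) under a normal mean-shift (L2) cost and an
MBIC-style penalty.  Segments shorter than a minimum genomic length
(default 2 Mb) are merged into the adjacent segment with the closer median
ratio, so the retained segments still tile the covered genome and their
genomic fractions sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# penalized L2 changepoint solvers
# ---------------------------------------------------------------------------


def _prefix_sums(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cs = np.concatenate([[0.0], np.cumsum(y)])
    css = np.concatenate([[0.0], np.cumsum(y * y)])
    return cs, css


def _seg_cost(cs: np.ndarray, css: np.ndarray, s: int, t: int) -> float:
    """Sum of squared deviations from the mean on y[s:t]."""
    n = t - s
    sm = cs[t] - cs[s]
    return (css[t] - css[s]) - sm * sm / n


def pelt(y: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized L2 changepoint detection with PELT pruning.

    Returns the sorted interior changepoint indices (a changepoint at k means
    segments split between y[k-1] and y[k]).
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n == 0:
        return []
    cs, css = _prefix_sums(y)
    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cand = [0]
    for t in range(1, n + 1):
        costs = np.array([F[s] + _seg_cost(cs, css, s, t) for s in cand])
        best = int(np.argmin(costs))
        F[t] = costs[best] + penalty
        prev[t] = cand[best]
        # PELT pruning: s stays viable only if it could still win later
        cand = [s for s, c in zip(cand, costs) if c <= F[t]] + [t]
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def optimal_partition(y: np.ndarray, penalty: float) -> list[int]:
    """Plain O(n^2) optimal partitioning (no pruning); same optimum as PELT.

    Used as the 'fpop' method: the functional-pruning speedup is not
    implemented, but the solved problem — exact penalized L2 — is identical,
    so the output contract matches.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n == 0:
        return []
    cs, css = _prefix_sums(y)
    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        costs = [F[s] + _seg_cost(cs, css, s, t) for s in range(t)]
        best = int(np.argmin(costs))
        F[t] = costs[best] + penalty
        prev[t] = best
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def mbic_penalty(y: np.ndarray, scale: float = 3.0) -> float:
    """MBIC-style default penalty: scale * log(n) * sigma^2.

    sigma is a robust noise estimate from the median absolute deviation of
    first differences (floored to keep noiseless profiles segmentable).
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 2:
        return 1.0
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    sigma2 = max((1.4826 * mad) ** 2 / 2.0, 1e-8)
    return scale * np.log(n) * sigma2


# ---------------------------------------------------------------------------
# genome segmentation
# ---------------------------------------------------------------------------


@dataclass
class Segmentation:
    """Ordered chromosomal segments of one subgroup/clone profile.

    ``table`` columns: chrom, start, end, win_first, win_last (window index
    range, half-open), n_windows, ratio (median member-window ratio), length
    (bp), w (genomic fraction; sums to 1).
    """

    table: pd.DataFrame

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()

    @property
    def w(self) -> np.ndarray:
        return self.table["w"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def breakpoints(self) -> pd.DataFrame:
        """Interior segment boundaries as (chrom, pos)."""
        rows = []
        for chrom, grp in self.table.groupby("chrom", sort=False):
            for pos in grp["start"].to_numpy()[1:]:
                rows.append((chrom, int(pos)))
        return pd.DataFrame(rows, columns=["chrom", "pos"])


def _segments_from_breaks(
    values: np.ndarray,
    w_start: np.ndarray,
    w_end: np.ndarray,
    breaks: list[int],
    offset: int,
) -> list[dict]:
    """Build per-chromosome segment records from window-index breaks.

    Inter-window gaps are assigned to the preceding segment: a segment ends
    where the next one starts, and the last segment ends at its last window's
    end coordinate.
    """
    bounds = [0] + breaks + [len(values)]
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segs.append(
            {
                "win_first": offset + lo,
                "win_last": offset + hi,
                "n_windows": hi - lo,
                "ratio": float(np.median(values[lo:hi])),
                "start": int(w_start[lo]),
                "end": int(w_end[hi - 1]),
            }
        )
    for a, b in zip(segs[:-1], segs[1:]):
        a["end"] = b["start"]
    return segs


def _merge_short(segs: list[dict], min_len: float) -> list[dict]:
    """Merge sub-threshold segments into the neighbor with the nearer ratio."""
    segs = [dict(s) for s in segs]
    while len(segs) > 1:
        lengths = [s["end"] - s["start"] for s in segs]
        short = [i for i, ln in enumerate(lengths) if ln < min_len]
        if not short:
            break
        i = min(short, key=lambda k: lengths[k])
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i < len(segs) - 1 else None
        if left is not None and right is not None:
            dl = abs(left["ratio"] - segs[i]["ratio"])
            dr = abs(right["ratio"] - segs[i]["ratio"])
            target = i - 1 if dl <= dr else i + 1  # ties -> left
        elif left is not None:
            target = i - 1
        else:
            target = i + 1
        a, b = sorted((i, target))
        merged = {
            "win_first": segs[a]["win_first"],
            "win_last": segs[b]["win_last"],
            "n_windows": segs[a]["n_windows"] + segs[b]["n_windows"],
            "ratio": np.nan,  # recomputed by caller over member windows
            "start": segs[a]["start"],
            "end": segs[b]["end"],
        }
        segs[a : b + 1] = [merged]
    return segs


def segment_profile(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    values: np.ndarray,
    method: str = "pelt",
    min_seg_len: float = 2e6,
    penalty: float | None = None,
) -> Segmentation:
    """Segment an ordered window-ratio profile, per chromosome independently.

    Chromosomes with fewer than 3 windows form a single segment.  After
    changepoint detection, sub-``min_seg_len`` segments are merged into the
    neighbor with the closer median ratio and segment ratios are recomputed as
    the median of member-window values.
    """
    solver = {"pelt": pelt, "fpop": optimal_partition}.get(method)
    if solver is None:
        raise ValueError(f"unknown segmentation method '{method}'")
    chrom = np.asarray(chrom, dtype=object)
    values = np.asarray(values, dtype=np.float64)
    records = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        v = values[idx]
        if len(v) < 3:
            breaks: list[int] = []
        else:
            pen = mbic_penalty(v) if penalty is None else penalty
            breaks = solver(v, pen)
        segs = _segments_from_breaks(v, start[idx], end[idx], breaks, idx[0])
        segs = _merge_short(segs, min_seg_len)
        for s in segs:
            lo, hi = s["win_first"] - idx[0], s["win_last"] - idx[0]
            s["ratio"] = float(np.median(v[lo:hi]))
        # absorbing a sliver can leave two flanks with identical ratios:
        # collapse such artifact boundaries
        merged = [segs[0]]
        for s in segs[1:]:
            if abs(s["ratio"] - merged[-1]["ratio"]) < 1e-9:
                prev_seg = merged[-1]
                prev_seg["win_last"] = s["win_last"]
                prev_seg["n_windows"] += s["n_windows"]
                prev_seg["end"] = s["end"]
                lo = prev_seg["win_first"] - idx[0]
                hi = prev_seg["win_last"] - idx[0]
                prev_seg["ratio"] = float(np.median(v[lo:hi]))
            else:
                merged.append(s)
        for s in merged:
            s["chrom"] = c
        records.extend(merged)
    table = pd.DataFrame.from_records(records)[
        ["chrom", "start", "end", "win_first", "win_last", "n_windows", "ratio"]
    ]
    table["length"] = table["end"] - table["start"]
    total = table["length"].sum()
    table["w"] = table["length"] / total
    return Segmentation(table)
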