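"""Genomic-window aggregation and initial cell subgrouping.

Sparse per-peak ratios are averaged within windows of consecutive peaks on
each chromosome; cells are then clustered on the window matrix (highly
variable windows -> PCA -> shared-nearest-neighbor graph -> Leiden) to obtain
initial subgroups, later merged into clones by the refinement stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from clonecn.preprocess import RatioMatrix

logger = logging.getLogger(__name__)


@dataclass
class WindowMatrix:
    """Window-averaged ratios: windows x inferred cells."""

    chrom: np.ndarray  # per-window chromosome
    start: np.ndarray  # first member-peak start
    end: np.ndarray  # last member-peak end
    peak_slices: list[tuple[int, int]]  # [first, last) peak index per window
    values: np.ndarray  # dense windows x cells
    barcodes: list[str]

    def __len__(self) -> int:
        return len(self.chrom)


@dataclass
class SubgroupProfile:
    """Per-cell subgroup labels and per-subgroup mean per-peak ratios."""

    labels: np.ndarray  # int label per inferred cell
    profiles: np.ndarray  # n_subgroups x n_peaks mean ratios
    subgroup_ids: np.ndarray  # sorted unique labels, row order of `profiles`


def bin_ratios(ratios: RatioMatrix, window_size: int = 5) -> WindowMatrix:
    """Average ratios within consecutive non-overlapping windows of
    ``window_size`` peaks per chromosome.

    A chromosome's trailing remainder (< window_size peaks) forms a short
    final window so genome coverage is preserved.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    dense = ratios.ratios.toarray()
    chroms, starts, ends, slices, rows = [], [], [], [], []
    for chrom in dict.fromkeys(ratios.peaks.chrom):  # preserves sorted order
        pk = np.flatnonzero(ratios.peaks.chrom == chrom)
        if len(pk) < window_size:
            logger.warning(
                "chromosome %s has %d peaks (< window %d): single window",
                chrom,
                len(pk),
                window_size,
            )
        for lo in range(0, len(pk), window_size):
            member = pk[lo : lo + window_size]
            chroms.append(chrom)
            starts.append(ratios.peaks.start[member[0]])
            ends.append(ratios.peaks.end[member[-1]])
            slices.append((int(member[0]), int(member[-1]) + 1))
            rows.append(dense[member].mean(axis=0))
    return WindowMatrix(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        slices,
        np.vstack(rows),
        ratios.barcodes,
    )


def _highly_variable(values: np.ndarray, n_hvf: int) -> np.ndarray:
    """Rank windows by mean-normalized dispersion of log1p values.

    A variance-stabilized dispersion ranking in the style of the standard
    single-cell HVF selection; any variance ranking passing the
    planted-partition recovery test is acceptable here.
    """
    x = np.log1p(values)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(disp)[::-1]
    return np.sort(order[:n_hvf])


def _snn_graph(pcs: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    adj = sp.lil_matrix((n, n), dtype=np.float64)
    for i in range(n):
        adj[i, idx[i, 1:]] = 1.0
    adj = sp.csr_matrix(adj)
    # shared-neighbor counts -> Jaccard similarity over kNN sets
    shared = (adj @ adj.T).toarray()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    union = deg[:, None] + deg[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, shared / union, 0.0)
    # keep edges only between kNN pairs (either direction)
    mask = ((adj + adj.T) > 0).toarray()
    jac = np.where(mask, jac, 0.0)
    np.fill_diagonal(jac, 0.0)
    src, dst = np.nonzero(np.triu(jac))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = jac[src, dst].tolist()
    return g


def initial_subgroups(
    windows: WindowMatrix,
    n_hvf: int = 2000,
    n_pcs: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
    knn_k: int = 20,
) -> np.ndarray:
    """Cluster inferred cells on the window matrix.

    Top ``n_hvf`` highly variable windows, z-scored, PCA to ``n_pcs``
    components, SNN graph (k=``knn_k``), Leiden at the given resolution.
    Deterministic given the seed.
    """
    n_cells = windows.values.shape[1]
    if n_cells == 1:
        logger.warning("single cell: one subgroup")
        return np.zeros(1, dtype=int)
    hvf = _highly_variable(windows.values, min(n_hvf, len(windows)))
    x = windows.values[hvf].T  # cells x features
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    x = (x - mu) / np.where(sd > 0, sd, 1.0)
    n_comp = min(n_pcs, x.shape[0] - 1, x.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(x)
    graph = _snn_graph(pcs, knn_k)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    labels = np.array(part.membership, dtype=int)
    logger.info("initial clustering: %d subgroups", labels.max() + 1)
    return labels


def subgroup_profiles(ratios: RatioMatrix, labels: np.ndarray) -> SubgroupProfile:
    """Per-subgroup arithmetic-mean per-peak ratio profiles."""
    labels = np.asarray(labels)
    if len(labels) != len(ratios.barcodes):
        raise ValueError("labels must cover all inferred cells")
    ids = np.unique(labels)
    dense = ratios.ratios.toarray()
    profiles = np.vstack(
        [dense[:, labels == s].mean(axis=1) for s in ids]
    )
    return SubgroupProfile(labels, profiles, ids)


def subgroup_window_profile(
    windows: WindowMatrix, labels: np.ndarray, subgroup: int
) -> np.ndarray:
    """Mean window-ratio profile of one subgroup (ordered as `windows`)."""
    member = np.asarray(labels) == subgroup
    if not member.any():
        raise ValueError(f"subgroup {subgroup} is empty")
    return windows.values[:, member].mean(axis=1)
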