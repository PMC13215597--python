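"""Shared fixtures: small synthetic inputs built programmatically."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from clonecn.io import CountMatrix, PeakSet


def make_peaks(n: int, chrom: str = "chr1", start0: int = 1000, spacing: int = 10_000):
    """n evenly spaced 500-bp peaks on one chromosome."""
    starts = start0 + spacing * np.arange(n)
    return PeakSet(
        np.array([chrom] * n, dtype=object),
        starts.astype(np.int64),
        (starts + 500).astype(np.int64),
    )


def make_counts(matrix, chrom: str = "chr1") -> CountMatrix:
    """CountMatrix from a dense peaks x cells array."""
    matrix = np.asarray(matrix)
    peaks = make_peaks(matrix.shape[0], chrom)
    barcodes = [f"BC{i}" for i in range(matrix.shape[1])]
    return CountMatrix(peaks, barcodes, sp.csr_matrix(matrix))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_inputs(tmp_path):
    """3-peak x 2-cell MTX/BED/barcodes/annotation quartet on disk."""
    import scipy.io

    mtx = sp.coo_matrix(np.array([[1, 0], [2, 3], [0, 4]]))
    scipy.io.mmwrite(str(tmp_path / "counts.mtx"), mtx, field="integer")
    (tmp_path / "peaks.bed").write_text(
        "chr1\t100\t600\nchr1\t1000\t1500\nchr2\t200\t700\n"
    )
    (tmp_path / "barcodes.txt").write_text("AAA\nBBB\n")
    (tmp_path / "annot.tsv").write_text(
        "barcode\tgroup\nAAA\treference\nBBB\tinferred\n"
    )
    return {
        "counts": tmp_path / "counts.mtx",
        "peaks": tmp_path / "peaks.bed",
        "barcodes": tmp_path / "barcodes.txt",
        "annot": tmp_path / "annot.tsv",
        "dir": tmp_path,
    }
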