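"""Symmetric sparse contact maps and their I/O.

A :class:`ContactMap` pairs a :class:`~hicstitch.genome.GenomeBins` with a
symmetric matrix of non-negative contact counts, stored internally as the
upper triangle of a sparse matrix.  Counts are kept as floats so that
normalized (non-integer) data pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .genome import GenomeBins, read_bins

__all__ = ["ContactMap", "extract_block", "read_contacts", "write_contacts"]


class ContactMap:
    """Symmetric contact-count matrix over a binned genome.

    Construct with upper-triangle COO-style arrays; duplicates (including
    mirrored ``(j, i)`` records) are summed.
    """

    def __init__(self, bins: GenomeBins, i, j, values) -> None:
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        n = bins.n_bins
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise IndexError("contact indices out of range for the bin table")
        if np.any(values < 0):
            raise ValueError("contact counts must be non-negative")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        upper = sp.coo_matrix((values, (lo, hi)), shape=(n, n)).tocsr()
        upper.sum_duplicates()
        upper.eliminate_zeros()
        self.bins = bins
        self._upper = upper

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_dense(cls, bins: GenomeBins, matrix: np.ndarray) -> "ContactMap":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (bins.n_bins, bins.n_bins):
            raise ValueError("matrix shape does not match bin count")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("contact matrix must be symmetric")
        iu, ju = np.triu_indices(bins.n_bins)
        vals = matrix[iu, ju]
        keep = vals != 0
        return cls(bins, iu[keep], ju[keep], vals[keep])

    # -- views ---------------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def nnz(self) -> int:
        """Number of stored (upper-triangle) non-zero entries."""
        return self._upper.nnz

    def triples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle entries as ``(i, j, value)`` arrays with i <= j."""
        coo = self._upper.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order], coo.data[order]

    def full(self) -> np.ndarray:
        """Dense symmetric matrix."""
        upper = self._upper.toarray()
        return upper + upper.T - np.diag(np.diag(upper))

    def symmetric_sparse(self) -> sp.csr_matrix:
        diag = sp.diags(self._upper.diagonal())
        return (self._upper + self._upper.T - diag).tocsr()

    def total_mass(self) -> float:
        """Sum of counts over distinct pairs i <= j."""
        return float(self._upper.sum())

    def block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """Dense contact block between two chromosomes, in local coordinates.

        The intra block (``chrom_a == chrom_b``) is symmetric; an inter
        block is rectangular with rows indexed by ``chrom_a`` bins.
        """
        sa = self.bins.chrom_slice(chrom_a)
        sb = self.bins.chrom_slice(chrom_b)
        return self.symmetric_sparse()[sa, sb].toarray()

    def __repr__(self) -> str:
        return (
            f"ContactMap({self.n_bins} bins, {len(self.bins.chrom_names)} chroms, "
            f"{self.nnz} stored entries)"
        )


def extract_block(cmap: ContactMap, chrom_a: str, chrom_b: str):
    """Functional alias for :meth:`ContactMap.block`."""
    return cmap.block(chrom_a, chrom_b)


def write_contacts(cmap: ContactMap, path) -> None:
    """Write upper-triangle triples ``bin_i<TAB>bin_j<TAB>count``."""
    i, j, v = cmap.triples()
    with open(path, "w") as fh:
        for a, b, c in zip(i, j, v):
            fh.write(f"{a}\t{b}\t{float(c)!r}\n")


def read_contacts(bin_table_path, triples_path) -> ContactMap:
    """Read a contact map from a bin table and a TSV triples file.

    Duplicate and mirrored records are summed; an empty triples file yields
    a valid all-zero map.  Malformed records raise with their line number.
    """
    bins = read_bins(bin_table_path)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    n = bins.n_bins
    with open(triples_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{triples_path}:{lineno}: expected 3 tab-separated fields"
                )
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{triples_path}:{lineno}: {exc}") from None
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"{triples_path}:{lineno}: bin index out of range [0, {n})"
                )
            if v < 0:
                raise ValueError(f"{triples_path}:{lineno}: negative count {v}")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    return ContactMap(bins, rows, cols, vals)
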