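"""Receptor expression fractions from a sparse genes x cells count matrix.

A cell is "positive" for a gene when its raw count exceeds zero — a
criterion invariant to any per-cell normalization, which is why fractions
computed here match fractions computed after standard normalization
pipelines. Co-expression fractions can be conditioned on a gene-defined
subpopulation (e.g., Esr1 within Crh+ cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .errors import DataError, DegenerateDataError


@dataclass
class CountMatrix:
    """Sparse genes x cells counts with row/column labels."""

    counts: sparse.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("counts must be non-negative")
        seen = set()
        dupes = {g for g in self.gene_ids if g in seen or seen.add(g)}
        if dupes:
            warnings.warn(
                f"duplicate gene symbols {sorted(dupes)}; first occurrence "
                "is used", stacklevel=2)
        self._gene_index = {}
        for i, g in enumerate(self.gene_ids):
            self._gene_index.setdefault(g, i)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> int:
        if gene not in self._gene_index:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self._gene_index[gene]

    def positive_mask(self, gene: str, threshold: int = 0) -> np.ndarray:
        """Boolean per-cell mask: count strictly above ``threshold``."""
        row = self.counts.getrow(self.gene_row(gene)).toarray().ravel()
        return row > threshold


@dataclass
class FractionResult:
    genes: tuple[str, ...]
    denominator: str
    n_cells: int
    n_positive: int
    fraction: float


def load_matrix(mtx_path: str | Path, genes_path: str | Path,
                barcodes_path: str | Path) -> CountMatrix:
    """Load a MatrixMarket matrix with gene/barcode sidecar lists.

    Gene and barcode files are one identifier per line (first tab-separated
    field is used, so 10x-style two-column gene files also parse).
    """
    mat = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    genes = [line.split("\t")[0] for line in
             Path(genes_path).read_text().splitlines() if line.strip()]
    barcodes = [line.split("\t")[0] for line in
                Path(barcodes_path).read_text().splitlines() if line.strip()]
    if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
        raise DataError(
            f"matrix {mat.shape} does not match {len(genes)} genes / "
            f"{len(barcodes)} barcodes"
        )
    return CountMatrix(counts=mat, gene_ids=genes, cell_ids=barcodes)


def write_matrix(matrix: CountMatrix, mtx_path: str | Path,
                 genes_path: str | Path, barcodes_path: str | Path) -> None:
    """Write the MatrixMarket + sidecar trio (inverse of ``load_matrix``)."""
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(matrix.counts))
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(matrix.cell_ids) + "\n")


def expression_fraction(matrix: CountMatrix, gene: str,
                        threshold: int = 0) -> FractionResult:
    """Fraction of all cells with count above threshold for ``gene``."""
    mask = matrix.positive_mask(gene, threshold)
    return FractionResult(genes=(gene,), denominator="all cells",
                          n_cells=matrix.n_cells,
                          n_positive=int(mask.sum()),
                          fraction=float(mask.mean()))


def coexpression_fraction(matrix: CountMatrix, gene_a: str,
                          gene_b: str | None = None,
                          within: str | None = None,
                          threshold: int = 0) -> FractionResult:
    """Fraction of a (sub)population positive for one gene or a pair.

    With ``within`` given, the denominator is the cells positive for that
    gene; the numerator requires positivity for ``gene_a`` (and ``gene_b``
    if provided).
    """
    num_mask = matrix.positive_mask(gene_a, threshold)
    genes = (gene_a,)
    if gene_b is not None and gene_b != gene_a:
        num_mask = num_mask & matrix.positive_mask(gene_b, threshold)
        genes = (gene_a, gene_b)
    if within is not None:
        denom_mask = matrix.positive_mask(within, threshold)
        denom_label = f"{within}+ cells"
    else:
        denom_mask = np.ones(matrix.n_cells, dtype=bool)
        denom_label = "all cells"
    n_denom = int(denom_mask.sum())
    if n_denom == 0:
        raise DegenerateDataError(f"no cells in denominator {denom_label!r}")
    n_pos = int((num_mask & denom_mask).sum())
    return FractionResult(genes=genes, denominator=denom_label,
                          n_cells=n_denom, n_positive=n_pos,
                          fraction=n_pos / n_denom)
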