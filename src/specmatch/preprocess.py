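"""Expression container, standard preprocessing, and template-parameter
estimation.

Preprocessing follows the usual single-cell recipe — drop unexpressed
genes, per-cell total-count normalization, log1p, highly variable gene
selection — delegated to scanpy.  Two L2-scaling conventions matter for
spectral template matching: cells are scaled to unit norm before
reconstruction (so the empirical cell-cell covariance has constant
diagonal, matching the unit-diagonal templates), and genes are scaled to
unit norm before gene inference (so gene scores are relative).

``estimate_alpha`` fits the neighbor-correlation parameter of a cyclic
or linear template by matching the theoretical eigenvalue spectrum to
the empirical one over a grid.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

from . import templates
from .templates import TemplateSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "standard_preprocess",
    "scale_unit",
    "estimate_alpha",
    "drop_top_component",
]

LAYER_TAGS = ("counts", "normalized", "log", "scaled")


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Dense cells x genes matrix with identifiers and a provenance tag."""

    values: np.ndarray
    cell_ids: Sequence[str]
    gene_ids: Sequence[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains NaN or Inf")
        cell_ids = [str(c) for c in self.cell_ids]
        gene_ids = [str(g) for g in self.gene_ids]
        if len(cell_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
            raise ValueError("id lengths inconsistent with matrix shape")
        for name, ids in (("cell", cell_ids), ("gene", gene_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"layer_tag must be one of {LAYER_TAGS}")
        if self.layer_tag == "counts" and values.min() < 0:
            raise ValueError("counts layer must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, layer_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids,
            layer_tag=layer_tag or self.layer_tag,
        )

    def to_anndata(self):
        import anndata as ad
        import pandas as pd

        return ad.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )

    @classmethod
    def from_anndata(cls, adata, layer_tag: str = "counts") -> "ExpressionMatrix":
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        return cls(
            values=np.asarray(X, dtype=float),
            cell_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            layer_tag=layer_tag,
        )

    @classmethod
    def from_dataframe(cls, df, layer_tag: str = "counts") -> "ExpressionMatrix":
        """Build from a cells x genes DataFrame (index = cell ids)."""
        return cls(
            values=df.to_numpy(dtype=float),
            cell_ids=list(map(str, df.index)),
            gene_ids=list(map(str, df.columns)),
            layer_tag=layer_tag,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.cell_ids), columns=list(self.gene_ids))


def standard_preprocess(raw: ExpressionMatrix, n_hvg: int = 2000) -> ExpressionMatrix:
    """Drop zero genes, normalize per-cell totals, log1p, keep top HVGs.

    Per-cell totals are scaled to the median pre-normalization total;
    highly variable genes are selected by dispersion (scanpy's seurat
    flavor on the log layer).  ``n_hvg >= remaining genes`` keeps all of
    them.  Deterministic given the input.
    """
    import scanpy as sc

    if raw.layer_tag != "counts":
        raise ValueError("standard_preprocess expects a counts layer")
    if not np.any(raw.values > 0):
        raise ValueError("all-zero expression matrix")
    adata = raw.to_anndata()
    sc.pp.filter_genes(adata, min_cells=1)
    sc.pp.normalize_total(adata)  # target = median of per-cell totals
    sc.pp.log1p(adata)
    n_keep = min(int(n_hvg), adata.n_vars)
    if n_keep < adata.n_vars:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(adata, n_top_genes=n_keep, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"].to_numpy()].copy()
    return ExpressionMatrix.from_anndata(adata, layer_tag="log")


def scale_unit(matrix: ExpressionMatrix, axis: str = "cells") -> ExpressionMatrix:
    """Scale each cell (row) or gene (column) to unit L2 norm.

    All-zero vectors are left at zero with a logged warning.  Cell
    scaling makes the diagonal of the empirical cell covariance constant,
    matching the unit-diagonal theoretical templates; gene scaling puts
    gene-informativeness scores on a common footing.
    """
    if axis not in ("cells", "genes"):
        raise ValueError("axis must be 'cells' or 'genes'")
    values = matrix.values.copy()
    ax = 1 if axis == "cells" else 0
    norms = np.linalg.norm(values, axis=ax, keepdims=True)
    zero = norms == 0
    if np.any(zero):
        logger.warning("%d all-zero %s left unscaled", int(zero.sum()), axis)
        norms = np.where(zero, 1.0, norms)
    return matrix.with_values(values / norms, layer_tag="scaled")


def _empirical_spectrum(values: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the cell-cell Gram matrix."""
    gram = values @ values.T
    lam = np.linalg.eigvalsh(gram)[::-1]
    return np.clip(lam, 0.0, None)


def _expected_sample_spectrum(theo: np.ndarray, p: int, n_draws: int = 2) -> np.ndarray:
    """Expected descending eigenvalues of a p-sample covariance whose
    population spectrum is ``theo``.

    With finitely many genes the empirical cell-cell spectrum is the
    population one broadened by Wishart sampling noise; comparing the
    data against this expectation (instead of the population spectrum)
    removes the systematic upward bias of the fitted neighbor
    correlation.  A fixed internal seed keeps the estimate
    deterministic.  Because the population covariance is diagonalizable,
    only its eigenvalues matter: sample spectra are drawn as
    eig(diag(sqrt(theo)) W diag(sqrt(theo)) / p) with W ~ Wishart(I, p).
    """
    n = theo.size
    rng = np.random.default_rng(1234)
    acc = np.zeros(n)
    root = np.sqrt(np.clip(theo, 0.0, None))
    for _ in range(n_draws):
        Z = rng.standard_normal((n, p))
        Y = root[:, None] * Z
        acc += np.linalg.eigvalsh(Y @ Y.T / p)[::-1]
    return acc / n_draws


def estimate_alpha(
    matrix: ExpressionMatrix,
    kind: str = "cyclic",
    grid: np.ndarray | None = None,
) -> float:
    """Grid-search the neighbor correlation that best matches the spectrum.

    For each candidate ``alpha`` the theoretical eigenvalues (cyclic or
    linear template), broadened to the expected p-gene sample spectrum,
    and the empirical eigenvalues of the cell-cell covariance are sorted
    descending, truncated to min(n, p) values, normalized to unit sum,
    and compared in L2; the minimizer is returned.  The matrix should be
    cell-scaled first so both spectra correspond to unit-diagonal
    covariances.
    """
    if kind not in ("cyclic", "linear"):
        raise ValueError("kind must be 'cyclic' or 'linear'")
    if grid is None:
        grid = np.arange(0.05, 0.951, 0.01)
    grid = np.asarray(grid, dtype=float)
    n, p = matrix.n_cells, matrix.n_genes
    emp = _empirical_spectrum(matrix.values)[: min(n, p)]
    if emp.sum() <= 0:
        raise ValueError("degenerate empirical spectrum (rank 0)")
    emp = emp / emp.sum()
    best_alpha, best_err = None, np.inf
    for alpha in grid:
        if kind == "cyclic":
            theo = np.sort(templates.cyclic_eigenvalues(n, alpha))[::-1]
        else:
            theo = np.sort(templates.linear_eigenvalues(n, alpha))[::-1]
        theo = _expected_sample_spectrum(theo, p)[: emp.size]
        theo = np.clip(theo, 0.0, None)
        theo = theo / theo.sum()
        err = float(np.linalg.norm(theo - emp))
        if err < best_err:
            best_alpha, best_err = float(alpha), err
    return best_alpha


def drop_top_component(spectrum: TemplateSpectrum) -> TemplateSpectrum:
    """Remove the largest-eigenvalue component from a template spectrum.

    The top theoretical component captures the mean offset (for the
    cyclic template its eigenvector is constant) and swamps the
    topology-informative components; reconstruction and masking improve
    with it removed.  A no-op with a warning if already dropped.
    """
    if spectrum.dropped_top:
        warnings.warn("top component already dropped; returning spectrum unchanged")
        return spectrum
    if spectrum.m < 2:
        raise ValueError("need at least 2 components to drop one")
    return dataclasses.replace(
        spectrum,
        eigenvalues=spectrum.eigenvalues[1:],
        eigenvectors=spectrum.eigenvectors[:, 1:],
        dropped_top=True,
    )
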