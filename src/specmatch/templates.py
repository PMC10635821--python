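"""Theoretical covariance templates and their spectra.

A *template* encodes the expected cell-cell covariance of a topological
signal: cells arranged on a cycle or a chain with geometrically decaying
neighbor correlation ``alpha``, cells grouped into clusters, several
cycles coupled into a block-circulant structure, or cells placed in 2D
space with a heat-kernel affinity over the spatial k-nearest-neighbor
graph.  Downstream algorithms only consume the eigendecomposition of the
template, held in :class:`TemplateSpectrum`.

For the cyclic topology the covariance is circulant and its spectrum is
closed-form: eigenvalues are the discrete cosine transform of the first
row and eigenvectors are phase-shifted Fourier modes.  For the linear
topology the covariance is a Kac-Murdock-Szego (KMS) Toeplitz matrix
alpha^|i-j| whose eigenvalues admit a classical approximation; its
eigenvectors are obtained numerically.  All other kinds are decomposed
numerically.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "Covariance",
    "TemplateSpectrum",
    "circulant_covariance",
    "cyclic_eigenvalues",
    "cyclic_eigenvectors",
    "cyclic_template",
    "kms_covariance",
    "linear_eigenvalues",
    "linear_template",
    "numerical_template",
    "cluster_covariance",
    "block_circulant_covariance",
    "spatial_affinity_template",
]

KINDS = ("cyclic", "linear", "cluster", "block_circulant", "spatial", "custom")

#: eigenvalues with magnitude below this are treated as exact zeros when a
#: numerically indefinite matrix must be repaired (affinity templates).
_EIG_CLIP = 1e-8


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    return alpha


def _check_n(n: int) -> int:
    n = int(n)
    if n < 2:
        raise ValueError(f"need at least 2 cells, got n={n}")
    return n


@dataclasses.dataclass(frozen=True)
class Covariance:
    """A theoretical cell-cell covariance matrix tagged with its topology kind."""

    values: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("covariance must be a square matrix")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("covariance must be symmetric to 1e-12")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclasses.dataclass(frozen=True)
class TemplateSpectrum:
    """Eigenpairs of a theoretical covariance, sorted by descending eigenvalue.

    Attributes
    ----------
    kind
        One of ``cyclic, linear, cluster, block_circulant, spatial, custom``.
    n
        Number of cells the template describes.
    alpha
        Neighbor correlation for parametric kinds, ``None`` otherwise.
    eigenvalues
        Shape ``(m,)``, nonnegative, descending.  ``m < n`` once components
        have been removed.
    eigenvectors
        Shape ``(n, m)``, orthonormal columns aligned with ``eigenvalues``.
    dropped_top
        Whether the component with the largest eigenvalue was removed (for
        the cyclic template that component is the constant vector).
    """

    kind: str
    n: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    alpha: float | None = None
    dropped_top: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown template kind {self.kind!r}")
        lam = np.asarray(self.eigenvalues, dtype=float)
        vec = np.asarray(self.eigenvectors, dtype=float)
        if vec.shape != (self.n, lam.size):
            raise ValueError("eigenvector matrix shape inconsistent with eigenvalues")
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "eigenvectors", vec)

    @property
    def m(self) -> int:
        """Number of retained components."""
        return self.eigenvalues.size

    def validate(self, atol: float = 1e-8) -> None:
        """Raise if orthonormality/ordering/nonnegativity invariants fail."""
        lam, vec = self.eigenvalues, self.eigenvectors
        if np.any(lam < -atol):
            raise ValueError("negative eigenvalue in template spectrum")
        if np.any(np.diff(lam) > atol):
            raise ValueError("eigenvalues not sorted descending")
        gram = vec.T @ vec
        if not np.allclose(gram, np.eye(self.m), atol=atol):
            raise ValueError("eigenvector columns are not orthonormal")

    def covariance(self) -> np.ndarray:
        """Reconstruct sum_i lambda_i v_i v_i^T over the retained components."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T

    def drop_top(self) -> "TemplateSpectrum":
        """Remove the largest-eigenvalue component (see :mod:`specmatch.preprocess`)."""
        from .preprocess import drop_top_component

        return drop_top_component(self)

    def truncate(self, m: int) -> "TemplateSpectrum":
        """Keep only the top ``m`` retained components (accuracy/speed trade)."""
        if not 1 <= m <= self.m:
            raise ValueError(f"m must be in [1, {self.m}]")
        return dataclasses.replace(
            self, eigenvalues=self.eigenvalues[:m], eigenvectors=self.eigenvectors[:, :m]
        )

    def save(self, path) -> None:
        np.savez(
            path,
            kind=self.kind,
            n=self.n,
            alpha=np.nan if self.alpha is None else self.alpha,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            dropped_top=self.dropped_top,
        )

    @classmethod
    def load(cls, path) -> "TemplateSpectrum":
        with np.load(path) as f:
            alpha = float(f["alpha"])
            return cls(
                kind=str(f["kind"]),
                n=int(f["n"]),
                alpha=None if np.isnan(alpha) else alpha,
                eigenvalues=f["eigenvalues"],
                eigenvectors=f["eigenvectors"],
                dropped_top=bool(f["dropped_top"]),
            )


# ---------------------------------------------------------------------------
# cyclic topology: circulant covariance, closed-form spectrum
# ---------------------------------------------------------------------------

def _circulant_first_row(n: int, alpha: float) -> np.ndarray:
    # entry j is alpha^min(j, n-j): correlation decays with the shorter arc
    j = np.arange(n)
    return alpha ** np.minimum(j, n - j)


def circulant_covariance(n: int, alpha: float) -> Covariance:
    """Expected cell-cell covariance of a cyclic signal.

    Entry ``(k, j)`` equals ``alpha**min((j-k) % n, (k-j) % n)``: cells at
    cyclic distance ``m`` have correlation ``alpha**m``, so the matrix is
    symmetric circulant with unit diagonal.
    """
    n, alpha = _check_n(n), _check_alpha(alpha)
    row = _circulant_first_row(n, alpha)
    idx = (np.arange(n)[None, :] - np.arange(n)[:, None]) % n
    return Covariance(row[idx], kind="cyclic")


def cyclic_eigenvalues(n: int, alpha: float) -> np.ndarray:
    """Eigenvalues of :func:`circulant_covariance`, frequency-ordered.

    The eigenvalue of frequency ``i`` is the discrete cosine transform of
    the first row, ``sum_j alpha**min(j, n-j) * cos(2*pi*j*i/n)``; because
    the row is symmetric this equals the real part of its DFT.  The
    eigenvalues sum to ``n`` (the trace).
    """
    n, alpha = _check_n(n), _check_alpha(alpha)
    return np.fft.fft(_circulant_first_row(n, alpha)).real


def cyclic_eigenvectors(n: int) -> np.ndarray:
    """Orthonormal eigenvectors shared by every symmetric circulant matrix.

    Column ``i`` has entries ``sqrt(2/n) * cos(2*pi*i*s/n - pi/4)``.  The
    -pi/4 phase mixes the cosine and sine Fourier modes of each frequency
    into a single real orthonormal basis; column 0 is the constant vector
    ``1/sqrt(n)``.
    """
    n = _check_n(n)
    s = np.arange(n)
    phase = 2.0 * np.pi * np.outer(s, np.arange(n)) / n
    return np.sqrt(2.0 / n) * np.cos(phase - np.pi / 4.0)


def cyclic_template(n: int, alpha: float, drop_top: bool = False) -> TemplateSpectrum:
    """Analytic spectrum of the cyclic template, sorted by descending eigenvalue.

    Eigenvalue ties (each frequency pair i, n-i is degenerate) are broken
    by ascending frequency so the output is deterministic; the fixed -pi/4
    phase convention of :func:`cyclic_eigenvectors` is kept as-is rather
    than re-orthogonalized.
    """
    lam = cyclic_eigenvalues(n, alpha)
    vec = cyclic_eigenvectors(n)
    order = np.argsort(-lam, kind="stable")
    spec = TemplateSpectrum(
        kind="cyclic", n=n, alpha=alpha, eigenvalues=lam[order], eigenvectors=vec[:, order]
    )
    return spec.drop_top() if drop_top else spec


# ---------------------------------------------------------------------------
# linear topology: Kac-Murdock-Szego covariance
# ---------------------------------------------------------------------------

def kms_covariance(n: int, alpha: float) -> Covariance:
    """Kac-Murdock-Szego matrix ``alpha**|i-j|``: covariance of a linear chain."""
    n, alpha = _check_n(n), _check_alpha(alpha)
    i = np.arange(n)
    return Covariance(alpha ** np.abs(i[:, None] - i[None, :]), kind="linear")


def linear_eigenvalues(n: int, alpha: float) -> np.ndarray:
    """Classical approximation to the KMS eigenvalues.

    ``lambda_i = (1 - alpha^2) / (1 + alpha^2 - 2*alpha*cos((i+1)*pi/(n+1)))``
    for ``i = 0..n-1``; all values are positive for ``alpha`` in [0, 1) and
    the approximation error vanishes as ``n`` grows.
    """
    n, alpha = _check_n(n), _check_alpha(alpha)
    i = np.arange(n)
    return (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos((i + 1) * np.pi / (n + 1)))


def linear_template(n: int, alpha: float, drop_top: bool = False) -> TemplateSpectrum:
    """Linear-chain template with numerically decomposed KMS eigenpairs."""
    spec = numerical_template(kms_covariance(n, alpha), drop_top=drop_top)
    return dataclasses.replace(spec, alpha=float(alpha))


# ---------------------------------------------------------------------------
# numerical templates
# ---------------------------------------------------------------------------

def numerical_template(
    cov: Covariance | np.ndarray,
    drop_top: bool = False,
    kind: str | None = None,
    negative: str = "raise",
) -> TemplateSpectrum:
    """Sorted eigendecomposition of an arbitrary symmetric covariance.

    Parameters
    ----------
    cov
        Symmetric matrix (``Covariance`` or plain array).
    drop_top
        Remove the largest-eigenvalue component from the retained spectrum.
    kind
        Override the topology tag; defaults to the tag on ``cov`` or
        ``"custom"``.
    negative : {"raise", "clip"}
        Declared covariances must be positive semidefinite: eigenvalues
        below ``-1e-8`` raise.  Affinity-derived inputs (spatial templates)
        pass ``"clip"`` to zero them instead.
    """
    if isinstance(cov, Covariance):
        values = cov.values
        kind = kind or cov.kind
    else:
        values = np.asarray(cov, dtype=float)
        kind = kind or "custom"
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("covariance must be a square matrix")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
    lam, vec = np.linalg.eigh(values)
    lam, vec = lam[::-1], vec[:, ::-1]
    if lam.min() < -_EIG_CLIP:
        if negative == "raise":
            raise ValueError(
                f"input is indefinite (min eigenvalue {lam.min():.3e}); "
                "declared covariances must be positive semidefinite"
            )
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.clip(lam, 0.0, None)
    spec = TemplateSpectrum(
        kind=kind, n=values.shape[0], eigenvalues=lam, eigenvectors=vec
    )
    return spec.drop_top() if drop_top else spec


def cluster_covariance(labels: Sequence, within_corr: float = 0.8) -> Covariance:
    """Block covariance for a cluster topology.

    Unit diagonal, ``within_corr`` between cells sharing a label, zero
    across labels.  Positive semidefinite for ``within_corr`` in (0, 1].
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    within_corr = float(within_corr)
    if not (0.0 < within_corr <= 1.0):
        raise ValueError(f"within_corr must lie in (0, 1], got {within_corr}")
    same = labels[:, None] == labels[None, :]
    values = np.where(same, within_corr, 0.0)
    np.fill_diagonal(values, 1.0)
    return Covariance(values, kind="cluster")


def block_circulant_covariance(
    block_sizes: Sequence[int],
    alphas: Sequence[float],
    cross_corr: float = 0.0,
) -> Covariance:
    """Several cyclic processes coupled by a constant cross-correlation.

    Block-diagonal stack of :func:`circulant_covariance` blocks with
    ``cross_corr`` between cells of different blocks.  The result must be
    positive semidefinite; too large a ``cross_corr`` is rejected.
    """
    block_sizes = [int(b) for b in block_sizes]
    alphas = [float(a) for a in alphas]
    if len(block_sizes) != len(alphas):
        raise ValueError("block_sizes and alphas must have equal length")
    cross_corr = float(cross_corr)
    if not (0.0 <= cross_corr < 1.0):
        raise ValueError(f"cross_corr must lie in [0, 1), got {cross_corr}")
    n = sum(block_sizes)
    values = np.full((n, n), cross_corr)
    start = 0
    for size, alpha in zip(block_sizes, alphas):
        values[start : start + size, start : start + size] = circulant_covariance(
            size, alpha
        ).values
        start += size
    if len(block_sizes) > 1:
        min_eig = np.linalg.eigvalsh(values)[0]
        if min_eig < -_EIG_CLIP:
            raise ValueError(
                f"block-circulant covariance is indefinite (min eigenvalue "
                f"{min_eig:.3e}); use a smaller cross_corr"
            )
    return Covariance(values, kind="block_circulant")


def spatial_affinity_template(
    coords: np.ndarray,
    k_neighbors: int = 10,
    bandwidth: float | None = None,
    drop_top: bool = False,
) -> TemplateSpectrum:
    """Heat-kernel affinity template over the spatial kNN graph.

    Builds the k-nearest-neighbor graph on 2D coordinates (symmetrized by
    mutual-edge union, Euclidean edge weights), computes all-pairs graph
    shortest-path distances ``d``, and forms the affinity
    ``exp(-d^2 / (2*bandwidth^2))`` with unit diagonal.  ``bandwidth``
    defaults to the median nonzero shortest-path distance.  The affinity
    need not be positive semidefinite, so negative eigenvalues are clipped
    to zero when forming the spectrum.
    """
    from sklearn.neighbors import kneighbors_graph

    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = coords.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} points, got {n}")
    graph = kneighbors_graph(coords, n_neighbors=k_neighbors, mode="distance")
    graph = graph.maximum(graph.T)  # union of directed kNN edges
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"spatial kNN graph is disconnected ({n_comp} components); "
            "increase k_neighbors"
        )
    dist = shortest_path(sp.csr_matrix(graph), directed=False)
    if bandwidth is None:
        bandwidth = float(np.median(dist[dist > 0]))
    bandwidth = float(bandwidth)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    affinity = np.exp(-(dist**2) / (2.0 * bandwidth**2))
    affinity = 0.5 * (affinity + affinity.T)
    np.fill_diagonal(affinity, 1.0)
    return numerical_template(
        Covariance(affinity, kind="spatial"), drop_top=drop_top, negative="clip"
    )
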