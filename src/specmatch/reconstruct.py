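"""Cell-order reconstruction by spectral projection over the Birkhoff
polytope.

The ordering task is a matrix permutation problem: find the row
permutation E of the expression matrix A maximizing

    sum_i lambda_i * || (E A)^T v_i ||^2

where (lambda_i, v_i) are the template eigenpairs.  Equivalently the
objective is trace(C (EA)(EA)^T) with C the retained template
covariance, so a permutation maximizing it aligns the data's variance
with the variance structure of the topology.  Permutation problems being
NP-hard, the search is relaxed to the Birkhoff polytope (doubly
stochastic matrices), optimized by projected stochastic gradient ascent
with a Bregmanian bi-stochastication projection, and greedily rounded
back to a permutation at the end.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import ExpressionMatrix
from .templates import TemplateSpectrum

__all__ = [
    "OptimizerConfig",
    "DoublyStochasticMatrix",
    "Permutation",
    "projection_objective",
    "bbs_project",
    "optimize_doubly_stochastic",
    "greedy_round",
    "reconstruct_order",
    "order_by_prior",
]


@dataclasses.dataclass(frozen=True)
class OptimizerConfig:
    """Knobs shared by the gradient-based solvers.

    step_size: "auto" uses 1/L with L the curvature bound of the
    objective's quadratic operator (estimated from the template and data
    spectra); iterations: maximum gradient steps; noise_sd: scale of the
    symmetry-breaking ascent noise, relative to the mean absolute
    gradient and decaying as 1/sqrt(t) within each annealing cycle;
    gamma: L1 weight of the masking problems; tol: relative
    objective-change stopping tolerance; round_every: interval at which
    the ordering optimizer greedily rounds the current iterate and
    records the best permutation seen (0 disables periodic rounding).
    """

    step_size: float | str = "auto"
    iterations: int = 1000
    noise_sd: float = 1.0
    seed: int = 0
    gamma: float | None = None
    tol: float = 1e-6
    round_every: int = 10

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.step_size != "auto" and float(self.step_size) <= 0:
            raise ValueError("step_size must be positive or 'auto'")
        if self.round_every < 0:
            raise ValueError("round_every must be nonnegative")


@dataclasses.dataclass(frozen=True)
class DoublyStochasticMatrix:
    """Point in the Birkhoff polytope: nonnegative, rows and columns sum to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("doubly stochastic matrix must be square")
        if values.min() < -1e-12:
            raise ValueError("doubly stochastic matrix has negative entries")
        if not (
            np.allclose(values.sum(axis=0), 1.0, atol=1e-6)
            and np.allclose(values.sum(axis=1), 1.0, atol=1e-6)
        ):
            raise ValueError("row/column sums deviate from 1 beyond 1e-6")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclasses.dataclass(frozen=True)
class Permutation:
    """Bijection on 0..n-1; ``mapping[i]`` is the target position of row i."""

    mapping: np.ndarray

    def __post_init__(self) -> None:
        mapping = np.asarray(self.mapping, dtype=int)
        n = mapping.size
        if not np.array_equal(np.sort(mapping), np.arange(n)):
            raise ValueError("mapping is not a bijection on 0..n-1")
        object.__setattr__(self, "mapping", mapping)

    @property
    def n(self) -> int:
        return self.mapping.size

    def matrix(self) -> np.ndarray:
        """Permutation matrix E with E[mapping[i], i] = 1, so (E A)[mapping[i]] = A[i]."""
        E = np.zeros((self.n, self.n))
        E[self.mapping, np.arange(self.n)] = 1.0
        return E

    def apply(self, values: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(values, dtype=float))
        out[self.mapping] = values
        return out

    def inverse(self) -> "Permutation":
        return Permutation(np.argsort(self.mapping))


def _as_array(E) -> np.ndarray:
    if isinstance(E, Permutation):
        return E.matrix()
    if isinstance(E, DoublyStochasticMatrix):
        return E.values
    return np.asarray(E, dtype=float)


def _retained_covariance(spectrum: TemplateSpectrum) -> np.ndarray:
    return spectrum.covariance()


def projection_objective(
    A: ExpressionMatrix | np.ndarray,
    spectrum: TemplateSpectrum,
    E=None,
) -> float:
    """Spectral projection score sum_i lambda_i ||(EA)^T v_i||^2.

    With all n eigenpairs retained this equals trace(C_template (EA)(EA)^T);
    the eigen-sum form is used directly.  ``E=None`` scores A as ordered.
    """
    values = A.values if isinstance(A, ExpressionMatrix) else np.asarray(A, dtype=float)
    if E is not None:
        values = _as_array(E) @ values
    if values.shape[0] != spectrum.n:
        raise ValueError(
            f"matrix has {values.shape[0]} cells but template describes {spectrum.n}"
        )
    proj = spectrum.eigenvectors.T @ values  # (m, p)
    return float(np.sum(spectrum.eigenvalues * np.einsum("ij,ij->i", proj, proj)))


def bbs_project(M: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000) -> DoublyStochasticMatrix:
    """Bregmanian bi-stochastication: nearest doubly stochastic matrix.

    Alternates the closed-form Frobenius projection onto the affine set
    {row sums = column sums = 1} with clipping of negative entries, until
    the maximum constraint violation falls below ``tol``.  Exact whenever
    the affine projection is already nonnegative.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("bbs_project requires finite entries")
    n = M.shape[0]
    X = M.copy()
    for _ in range(max_iter):
        # affine step: X + a 1^T + 1 b^T matching both sum constraints
        r = X.sum(axis=1)
        c = X.sum(axis=0)
        s = r.sum()
        shift = (n - s) / (2.0 * n)
        a = (1.0 - r - shift) / n
        b = (1.0 - c - shift) / n
        X = X + a[:, None] + b[None, :]
        neg = X.min()
        X = np.clip(X, 0.0, None)
        row_err = np.abs(X.sum(axis=1) - 1.0).max()
        col_err = np.abs(X.sum(axis=0) - 1.0).max()
        if max(row_err, col_err, -min(neg, 0.0)) < tol:
            return DoublyStochasticMatrix(X)
    raise RuntimeError(f"bi-stochastication did not converge in {max_iter} alternations")


def _auto_step(spectrum: TemplateSpectrum, gram: np.ndarray) -> float:
    """1/L with L = 2 * lambda_max(C) * lambda_max(A A^T), the Lipschitz
    constant of the objective gradient E -> 2 C E G."""
    lam_c = float(spectrum.eigenvalues.max(initial=0.0))
    # power iteration on the PSD gram matrix
    v = np.ones(gram.shape[0]) / np.sqrt(gram.shape[0])
    for _ in range(50):
        w = gram @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 1.0
        v = w / nrm
    lam_g = float(v @ gram @ v)
    L = 2.0 * lam_c * lam_g
    return 1.0 / L if L > 0 else 1.0


def optimize_doubly_stochastic(
    A: ExpressionMatrix | np.ndarray,
    spectrum: TemplateSpectrum,
    cfg: OptimizerConfig = OptimizerConfig(),
) -> tuple[DoublyStochasticMatrix, dict]:
    """Maximize the projection objective over the Birkhoff polytope.

    Projected stochastic gradient ascent from the (noise-perturbed)
    uniform barycenter: each step adds step * (2 C E G + noise), then
    projects back with :func:`bbs_project`.  The noise sd is
    ``noise_sd`` times the mean absolute gradient, decaying as 1/sqrt(t);
    after the main phase the noise clock is periodically restarted from
    a randomly tempered iterate (annealing cycles) so locally maximal
    vertices can be escaped.  Because the objective is a convex
    quadratic being maximized, iterates drift to the polytope boundary;
    the best iterate seen is returned, so the final objective is never
    below the initialization's.  Returns the matrix and a diagnostics
    dict with the per-iteration objective trace and the best greedily
    rounded permutation encountered.
    """
    values = A.values if isinstance(A, ExpressionMatrix) else np.asarray(A, dtype=float)
    n = values.shape[0]
    if n != spectrum.n:
        raise ValueError("cell count does not match template size")
    rng = np.random.default_rng(cfg.seed)
    gram = values @ values.T
    C = _retained_covariance(spectrum)
    step = _auto_step(spectrum, gram) if cfg.step_size == "auto" else float(cfg.step_size)

    E = np.full((n, n), 1.0 / n) + rng.normal(0.0, 0.01 / n, size=(n, n))
    E = bbs_project(E, tol=1e-9).values

    def objective(M: np.ndarray) -> float:
        proj = spectrum.eigenvectors.T @ (M @ values)
        return float(np.sum(spectrum.eigenvalues * np.einsum("ij,ij->i", proj, proj)))

    trace = [objective(E)]
    best, best_obj = E.copy(), trace[0]
    best_perm, best_perm_obj = None, -np.inf

    def consider_rounding(M: np.ndarray) -> None:
        nonlocal best_perm, best_perm_obj
        perm = greedy_round(M)
        obj = objective(perm.matrix())
        if obj > best_perm_obj:
            best_perm, best_perm_obj = perm, obj

    # schedule: a main ascent phase with noise decaying as 1/sqrt(t), then
    # short annealing cycles that restart the noise clock from a randomly
    # tempered iterate, to escape locally maximal vertices; the best iterate
    # and best rounded permutation seen anywhere are what is returned
    main_iters = max(1, int(0.6 * cfg.iterations))
    cycle_len = 50 if cfg.iterations > main_iters else 0
    flat = 0  # consecutive near-stationary iterations; the ascent starts in a
    # nearly flat symmetric region, so stopping needs patience, not one check
    tau = 0
    for t in range(1, cfg.iterations + 1):
        tau += 1
        if t > main_iters and cycle_len and (t - main_iters - 1) % cycle_len == 0:
            kick = rng.uniform(0.0, 1.0)  # random reheat temperature
            E = bbs_project(
                (1.0 - kick) * E + kick * rng.dirichlet(np.ones(n), size=n), tol=1e-9
            ).values
            tau = 1
        grad = 2.0 * C @ E @ gram
        if cfg.noise_sd > 0:
            scale = np.abs(grad).mean()
            grad = grad + rng.normal(0.0, cfg.noise_sd * scale / np.sqrt(tau), size=grad.shape)
        E = E + step * grad
        if not np.all(np.isfinite(E)):
            raise FloatingPointError(
                "non-finite iterate; reduce the step size (cfg.step_size)"
            )
        E = bbs_project(E, tol=1e-9).values
        obj = objective(E)
        trace.append(obj)
        if obj > best_obj:
            best, best_obj = E.copy(), obj
        if cfg.round_every and t % cfg.round_every == 0:
            consider_rounding(E)
        if t <= main_iters and flat >= 0:
            flat = flat + 1 if abs(trace[-1] - trace[-2]) < cfg.tol * max(abs(trace[-2]), 1.0) else 0
            if flat >= 25:
                # main phase converged early; hand the rest to annealing cycles
                main_iters = t
                cycle_len = 50
                flat = -1
    consider_rounding(best)
    diag = {
        "objective_trace": np.array(trace),
        "step": step,
        "best_permutation": best_perm,
        "best_permutation_objective": best_perm_obj,
    }
    return DoublyStochasticMatrix(best), diag


def greedy_round(E: DoublyStochasticMatrix | np.ndarray) -> Permutation:
    """Round a doubly stochastic matrix to a permutation.

    Iterates over rows in ascending index; each row is assigned the
    still-unassigned column with the largest entry, ties broken by the
    lowest column index.
    """
    values = np.asarray(_as_array(E), dtype=float)
    n = values.shape[0]
    taken = np.zeros(n, dtype=bool)
    cell_at = np.empty(n, dtype=int)  # row i of E is output position i
    for i in range(n):
        row = np.where(taken, -np.inf, values[i])
        cell_at[i] = int(np.argmax(row))  # argmax takes the first maximum
        taken[cell_at[i]] = True
    # E[i, j] weights data cell j at position i, so cell_at maps positions to
    # cells; Permutation stores the inverse (cell -> position)
    return Permutation(np.argsort(cell_at))


def reconstruct_order(
    A: ExpressionMatrix,
    spectrum: TemplateSpectrum,
    cfg: OptimizerConfig = OptimizerConfig(),
) -> tuple[Permutation, ExpressionMatrix, dict]:
    """Recover the cell ordering along the template topology.

    Optimizes the Birkhoff relaxation, greedily rounding the iterate at
    the interval ``cfg.round_every`` and at the end, and returns the
    best-scoring permutation, the reordered matrix (A_ordered = E A) and
    diagnostics.  For cyclic templates every circular shift or
    reflection of a solution scores identically and is an equally valid
    ordering; diagnostics record this equivalence.
    """
    ds, diag = optimize_doubly_stochastic(A, spectrum, cfg)
    perm = diag.pop("best_permutation") or greedy_round(ds)
    diag.pop("best_permutation_objective", None)
    ordered = ExpressionMatrix(
        values=perm.apply(A.values),
        cell_ids=list(np.array(A.cell_ids, dtype=object)[perm.inverse().mapping]),
        gene_ids=A.gene_ids,
        layer_tag=A.layer_tag,
    )
    diag = dict(diag)
    diag["relaxed_objective"] = projection_objective(A, spectrum, ds)
    diag["rounded_objective"] = projection_objective(A, spectrum, perm)
    diag["solution_equivalence"] = (
        "circular shifts and reflections" if spectrum.kind == "cyclic" else "reflection"
    )
    return perm, ordered, diag


def order_by_prior(
    A: ExpressionMatrix,
    labels: np.ndarray,
    seed: int = 0,
) -> tuple[Permutation, ExpressionMatrix]:
    """Order cells by prior low-resolution labels (e.g. sampling times).

    Cells are sorted by label; ties within a label are broken in a
    seeded random order.  Used in place of reconstruction when prior
    knowledge of the ordering is available.
    """
    labels = np.asarray(labels)
    if labels.size != A.n_cells:
        raise ValueError("one label per cell required")
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(labels.size)
    order = np.lexsort((jitter, labels))  # row order[j] goes to position j
    mapping = np.argsort(order)
    perm = Permutation(mapping)
    ordered = ExpressionMatrix(
        values=A.values[order],
        cell_ids=list(np.array(A.cell_ids, dtype=object)[order]),
        gene_ids=A.gene_ids,
        layer_tag=A.layer_tag,
    )
    return perm, ordered
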