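"""Constrained least-squares solvers for bulk deconvolution.

Every solver minimizes (a variant of) the mixture model objective

    min_p  sum_g ( z_g - sum_j p_j * x_{gj} )^2

where ``z`` is a bulk expression column and ``X`` the genes x cell-types
reference of cluster-mean profiles.  Variants:

* OLS      — unconstrained least squares (the naive baseline),
* NNLS     — the same objective with p >= 0,
* RLR      — robust (Huber) regression, resistant to outlier genes,
* DWLS     — dampened weighted least squares: iteratively reweighted NNLS
             with per-gene weights 1/(X p)^2 capped ("dampened") at a
             data-chosen multiple of the smallest weight.

All solvers report proportions under one convention ("C1"): negative raw
coefficients clamped to zero, then renormalized to sum 1.  The raw solution
is preserved on the result so either convention can be evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import statsmodels.api as sm

from .io_formats import CompositionMatrix, ExpressionMatrix
from .preprocess import ClusterReference

logger = logging.getLogger("squidecon")

DEFAULT_DAMPING_GRID = tuple(2.0 ** j for j in range(15))


@dataclass
class SolverSpec:
    """Solver choice plus the knobs shared by the iterative methods."""

    name: str = "DWLS"
    damping_grid: tuple[float, ...] = DEFAULT_DAMPING_GRID
    epsilon: float = 0.01
    max_iterations: int = 1000
    n_subsamples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("OLS", "NNLS", "RLR", "DWLS"):
            raise ValueError(f"unknown solver {self.name!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.name == "DWLS" and not self.damping_grid:
            raise ValueError("damping grid must be nonempty")


@dataclass
class SolverResult:
    """Raw coefficients plus reported (clamped, renormalized) proportions."""

    proportions: np.ndarray
    raw: np.ndarray
    n_iterations: int = 1
    converged: bool = True
    objective: float = np.nan
    final_weights: np.ndarray | None = None
    step_norms: list[float] = field(default_factory=list)


def _as_reference_array(ref) -> np.ndarray:
    if isinstance(ref, ClusterReference):
        return ref.profiles.to_dense(copy=False)
    if isinstance(ref, ExpressionMatrix):
        return ref.to_dense(copy=False)
    return np.asarray(ref, dtype=float)


def _check_instance(z: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != z.shape[0]:
        raise ValueError(f"bulk has {z.shape[0]} genes but reference has {X.shape[0]}")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many genes as cell types")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"reference is rank-deficient (rank {rank} < {X.shape[1]} types); "
            f"most collinear column pair: ({i}, {j})"
        )
    return z, X


def _report(raw: np.ndarray) -> np.ndarray:
    """Convention C1: clamp negatives to zero, renormalize to sum 1."""
    p = np.clip(raw, 0.0, None)
    s = p.sum()
    if s <= 0:
        return np.full_like(p, 1.0 / len(p))
    return p / s


def solve_ols(bulk_col, ref) -> SolverResult:
    """Exact unconstrained least squares (normal equations via lstsq)."""
    z, X = _check_instance(bulk_col, _as_reference_array(ref))
    raw, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ raw
    return SolverResult(_report(raw), raw, objective=float(resid @ resid))


def solve_nnls(bulk_col, ref) -> SolverResult:
    """Least squares with a non-negativity constraint (Lawson–Hanson)."""
    z, X = _check_instance(bulk_col, _as_reference_array(ref))
    raw, rnorm = scipy.optimize.nnls(X, z)
    return SolverResult(_report(raw), raw, objective=float(rnorm**2))


def solve_rlr(bulk_col, ref, max_iterations: int = 200, tol: float = 1e-8) -> SolverResult:
    """Huber M-estimation (tuning constant 1.345, IRLS) of the mixture fit."""
    z, X = _check_instance(bulk_col, _as_reference_array(ref))
    if not np.any(z):
        return SolverResult(_report(np.zeros(X.shape[1])), np.zeros(X.shape[1]), objective=0.0)
    model = sm.RLM(z, X, M=sm.robust.norms.HuberT(t=1.345))
    try:
        fit = model.fit(maxiter=max_iterations, tol=tol)
        raw = np.asarray(fit.params, dtype=float)
        n_iter = int(getattr(fit, "fit_history", {}).get("iteration", max_iterations))
        converged = True
    except Exception:  # scale collapse on degenerate (e.g. exact-fit) input
        raw, *_ = np.linalg.lstsq(X, z, rcond=None)
        n_iter, converged = 1, True
    if not np.all(np.isfinite(raw)):
        raw, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ raw
    return SolverResult(_report(raw), raw, n_iterations=n_iter, converged=converged,
                        objective=float(resid @ resid))


# ---------------------------------------------------------------------------
# dampened weighted least squares
# ---------------------------------------------------------------------------

def _weighted_nnls(z, X, w):
    sw = np.sqrt(w)
    raw, rnorm = scipy.optimize.nnls(X * sw[:, None], z * sw)
    return raw, float(rnorm**2)


def _choose_damping(z, X, w, grid, subsample_sets) -> float:
    """Pick the damping constant minimizing subsample solution variance.

    For each candidate cap d, weights are capped at d * min(w); on each
    half-gene subsample an (unconstrained) weighted least-squares solution is
    computed and normalized; the criterion is the summed across-subsample
    variance of those solutions.  Subsample index sets are shared across
    candidates so the comparison is paired.
    """
    wmin = w[w > 0].min() if np.any(w > 0) else 1.0
    best_d, best_crit = grid[0], np.inf
    for d in grid:
        wd = np.minimum(w, d * wmin)
        sols = []
        for idx in subsample_sets:
            sw = np.sqrt(wd[idx])
            sol, *_ = np.linalg.lstsq(X[idx] * sw[:, None], z[idx] * sw, rcond=None)
            s = np.abs(sol).sum()
            if s > 0:
                sols.append(sol / s)
        if len(sols) < 2:
            continue
        crit = float(np.var(np.array(sols), axis=0).sum())
        if crit < best_crit - 1e-15:
            best_crit, best_d = crit, d
    return best_d


def solve_dwls(bulk_col, ref, spec: SolverSpec | None = None) -> SolverResult:
    """Dampened weighted least squares deconvolution.

    Starting from the NNLS solution, each iteration l computes per-gene
    weights w_g = 1 / max((X p^(l-1))_g^2, delta), dampens them by capping at
    a fixed multiple of the smallest weight (the multiple is drawn from the
    grid 2^0..2^14 once per solve, by a subsample-variance criterion on the
    initial weights), solves the weighted NNLS problem, renormalizes to the
    simplex, and averages the new solution 1:4 with the previous iterate —
    the stabilization used by the original dampened-WLS procedure.
    Iteration stops when the Euclidean step ||p^(l) - p^(l-1)|| <= epsilon
    (default 0.01) or at ``max_iterations``.
    """
    spec = spec or SolverSpec(name="DWLS")
    z, X = _check_instance(bulk_col, _as_reference_array(ref))
    rng = np.random.default_rng(spec.seed)
    n_genes = X.shape[0]
    k = max(4, n_genes // 2)
    subsample_sets = [rng.choice(n_genes, size=k, replace=False)
                      for _ in range(spec.n_subsamples)]

    def _weights(p_cur: np.ndarray) -> np.ndarray:
        pred2 = (X @ p_cur) ** 2
        delta = 1e-12 * pred2.max() if pred2.max() > 0 else 1.0
        return 1.0 / np.maximum(pred2, delta)

    init = solve_nnls(z, X)
    p = init.proportions.copy()
    raw = init.raw.copy()
    # the damping cap multiple is chosen once, from the initial solution
    d = _choose_damping(z, X, _weights(p), spec.damping_grid, subsample_sets)
    step_norms: list[float] = []
    converged = False
    final_w = None
    objective = init.objective
    n_done = 0
    for l in range(1, spec.max_iterations + 1):
        w = _weights(p)
        wmin = w[w > 0].min() if np.any(w > 0) else 1.0
        wd = np.minimum(w, d * wmin)
        raw, objective = _weighted_nnls(z, X, wd)
        # damp the iterate itself: average the new solution 1:4 with the old
        p_new = (_report(raw) + 4.0 * p) / 5.0
        step = float(np.linalg.norm(p_new - p))
        step_norms.append(step)
        p = p_new
        final_w = wd
        n_done = l
        if step <= spec.epsilon:
            converged = True
            break
    if not converged:
        logger.warning("DWLS did not converge in %d iterations (last step %.3g)",
                       spec.max_iterations, step_norms[-1] if step_norms else np.nan)
    return SolverResult(p, raw, n_iterations=n_done, converged=converged,
                        objective=objective, final_weights=final_w,
                        step_norms=step_norms)


_SOLVERS = {"OLS": solve_ols, "NNLS": solve_nnls, "RLR": solve_rlr, "DWLS": solve_dwls}


def solve(bulk_col, ref, spec: SolverSpec) -> SolverResult:
    """Dispatch a single-column solve according to ``spec.name``."""
    if spec.name == "DWLS":
        return solve_dwls(bulk_col, ref, spec)
    return _SOLVERS[spec.name](bulk_col, ref)


def deconvolve_matrix(
    bulk: ExpressionMatrix,
    ref: ClusterReference,
    spec: SolverSpec,
) -> CompositionMatrix:
    """Run one solver over every bulk sample against a shared reference.

    Bulk and reference are restricted to the intersection of their gene
    universes (in bulk gene order); one composition row per bulk column.
    """
    shared = [g for g in bulk.gene_ids if g in set(ref.profiles.gene_ids)]
    if not shared:
        raise ValueError("bulk and reference share no genes")
    B = bulk.subset_genes(shared).to_dense(copy=False)
    X = ref.profiles.subset_genes(shared).to_dense(copy=False)
    rows = []
    for i, sample in enumerate(bulk.column_ids):
        try:
            rows.append(solve(B[:, i], X, spec).proportions)
        except Exception as exc:
            raise RuntimeError(f"solver {spec.name} failed on sample {sample!r}: {exc}") from exc
    return CompositionMatrix(
        np.vstack(rows), list(bulk.column_ids), list(ref.cluster_ids), kind="estimate"
    )
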