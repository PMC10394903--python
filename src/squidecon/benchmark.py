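"""Benchmarking composition estimates against gold standards.

The central comparison flattens the aligned (sample x cell-type) matrices
into paired vectors and reports the Pearson correlation and the RMSE over
all pairs — for the canonical six-mixtures-by-six-types design that is 36
points per method.  ``run_grid`` evaluates a Cartesian product of methods and
bulk/reference normalization choices on one concurrent dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolve import SolverSpec, deconvolve_matrix
from .io_formats import CompositionMatrix
from .preprocess import ClusterReference, NormalizationMethod, cluster_profiles, normalize
from .squid import ConcurrentDataset, loo_cross_validate
from . import squid as _squid

logger = logging.getLogger("squidecon")


@dataclass
class BenchmarkResult:
    """Pearson r / RMSE of one (method, normalization) cell of the grid."""

    method: str
    bulk_normalization: str
    reference_normalization: str
    pearson_r: float | None
    rmse: float
    n_points: int
    per_celltype: pd.DataFrame | None = None
    note: str = ""

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "bulk_normalization": self.bulk_normalization,
            "reference_normalization": self.reference_normalization,
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "note": self.note,
        }


def evaluate(
    est: CompositionMatrix,
    gold: CompositionMatrix,
    method: str = "",
    bulk_normalization: str = "none",
    reference_normalization: str = "none",
) -> BenchmarkResult:
    """Flattened Pearson r and RMSE of estimates versus a gold standard.

    Matrices are aligned by shared sample and cell-type ids (order
    independent); cell types present on only one side are dropped with a
    logged count.  If either flattened vector has zero variance the Pearson
    correlation is undefined and reported as None with a reason.
    """
    samples = [s for s in gold.sample_ids if s in set(est.sample_ids)]
    types = [c for c in gold.celltype_ids if c in set(est.celltype_ids)]
    dropped = (len(gold.celltype_ids) - len(types)) + (
        len(est.celltype_ids) - len(types)
    )
    if dropped:
        logger.info("evaluate: %d unmatched cell-type columns dropped", dropped)
    if not samples or not types:
        raise ValueError("no shared samples or cell types to evaluate")
    E = est.align(samples, types).values
    G = gold.align(samples, types).values
    e, g = E.ravel(), G.ravel()
    rmse = float(np.sqrt(np.mean((e - g) ** 2)))
    note = ""
    if np.ptp(e) == 0 or np.ptp(g) == 0:
        r = None
        note = "pearson undefined: zero variance in flattened vector"
    else:
        r = float(scipy.stats.pearsonr(e, g).statistic)
    rows = []
    for j, ct in enumerate(types):
        col_e, col_g = E[:, j], G[:, j]
        if np.ptp(col_e) > 0 and np.ptp(col_g) > 0:
            r_ct = float(scipy.stats.pearsonr(col_e, col_g).statistic)
        else:
            r_ct = np.nan
        rows.append({"celltype": ct, "pearson_r": r_ct,
                     "rmse": float(np.sqrt(np.mean((col_e - col_g) ** 2)))})
    return BenchmarkResult(
        method=method,
        bulk_normalization=bulk_normalization,
        reference_normalization=reference_normalization,
        pearson_r=r, rmse=rmse, n_points=int(e.size),
        per_celltype=pd.DataFrame(rows).set_index("celltype"),
        note=note,
    )


def fisher_r_test(r1: float, r2: float, n1: int, n2: int) -> float:
    """Two-sided p for equality of two independent Pearson correlations
    (Fisher z transformation)."""
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2 * scipy.stats.norm.sf(abs(z1 - z2) / se))


_SOLVER_METHODS = {"OLS", "NNLS", "RLR", "DWLS"}


def run_grid(
    ds: ConcurrentDataset,
    gold: CompositionMatrix,
    methods: list[str] = ("OLS", "NNLS", "DWLS", "SQUID"),
    bulk_norms: list[NormalizationMethod] | None = None,
    ref_norms: list[NormalizationMethod] | None = None,
    spec: SolverSpec | None = None,
    external: dict[str, CompositionMatrix] | None = None,
    squid_loo: bool = True,
) -> pd.DataFrame:
    """Evaluate methods x bulk normalizations x reference normalizations.

    SQUID always consumes the raw bulk and raw-count reference (its
    transform targets the single-cell scale), so it contributes one row per
    bulk normalization with reference normalization fixed to ``raw``.
    Externally produced composition tables (e.g. from methods not
    implemented here) join the grid under their own names.  Individual cell
    failures are recorded in the ``note`` column and the grid continues.
    """
    spec = spec or SolverSpec(name="DWLS")
    bulk_norms = list(bulk_norms) if bulk_norms is not None else [NormalizationMethod("none")]
    ref_norms = list(ref_norms) if ref_norms is not None else [NormalizationMethod("none")]
    base_ref = cluster_profiles(ds.sc, ds.labels)
    rows: list[dict] = []
    for method in methods:
        if method.upper() == "SQUID":
            try:
                est = (loo_cross_validate(ds, spec) if squid_loo
                       else _squid.squid_estimate(ds, spec))
                res = evaluate(est, gold, method="SQUID",
                               bulk_normalization="raw", reference_normalization="raw")
            except Exception as exc:
                logger.warning("SQUID failed: %s", exc)
                rows.append({"method": "SQUID", "bulk_normalization": "raw",
                             "reference_normalization": "raw", "pearson_r": None,
                             "rmse": np.nan, "n_points": 0, "note": f"failed: {exc}"})
                continue
            rows.append(res.as_row())
            continue
        if method.upper() not in _SOLVER_METHODS:
            raise ValueError(f"unknown method {method!r}")
        for bn in bulk_norms:
            for rn in ref_norms:
                try:
                    bulk = normalize(ds.bulk, bn)
                    ref_prof = normalize(base_ref.profiles, rn)
                    ref = ClusterReference(ref_prof, dict(base_ref.cell_counts))
                    mspec = SolverSpec(name=method.upper(), damping_grid=spec.damping_grid,
                                       epsilon=spec.epsilon,
                                       max_iterations=spec.max_iterations,
                                       n_subsamples=spec.n_subsamples, seed=spec.seed)
                    est = deconvolve_matrix(bulk, ref, mspec)
                    res = evaluate(est, gold, method=method.upper(),
                                   bulk_normalization=bn.name,
                                   reference_normalization=rn.name)
                    rows.append(res.as_row())
                except Exception as exc:
                    logger.warning("%s/%s/%s failed: %s", method, bn.name, rn.name, exc)
                    rows.append({"method": method.upper(), "bulk_normalization": bn.name,
                                 "reference_normalization": rn.name, "pearson_r": None,
                                 "rmse": np.nan, "n_points": 0, "note": f"failed: {exc}"})
    if external:
        for name, est in external.items():
            res = evaluate(est, gold, method=name,
                           bulk_normalization="external", reference_normalization="external")
            rows.append(res.as_row())
    return pd.DataFrame(rows)
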