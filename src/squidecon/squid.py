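"""Bulk-to-single-cell transformation and SQUID deconvolution.

Bulk RNA-seq and droplet single-cell RNA-seq measure the same transcriptome
through very different capture processes, so a cluster-mean reference built
from single-cell data is systematically distorted relative to the bulk
profile it is asked to explain.  When the same physical samples are profiled
by both assays ("concurrent" profiling), that distortion can be estimated
and removed gene by gene: for each gene g with nonzero expression in both
assays, regress the per-sample pseudobulk value on the per-sample bulk value,

    min_{a_g, b_g}  sum_i ( zhat_{g,i} - (a_g * z_{g,i} + b_g) )^2,

and map every bulk profile through z -> a_g z + b_g before deconvolving.
An alternative moment-matching map rescales each gene to the pseudobulk
mean/sd,

    z -> mean(zhat_g) + sd(zhat_g)/sd(z_g) * (z - mean(z_g)),

which does not require the profiles to be concurrent.  Either way the
transformed bulk lives on the single-cell scale, where dampened weighted
least squares against the raw cluster-mean reference — using all shared
nonzero genes, no marker selection — yields the composition estimate.

The leave-one-out driver mirrors the evaluation protocol: each sample's
composition is predicted from a transform and reference fit on all the
*other* samples, so the held-out sample's single-cell data never informs
its own prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import SolverResult, SolverSpec, solve_dwls
from .io_formats import CellLabelTable, CompositionMatrix, ExpressionMatrix
from .preprocess import ClusterReference, cluster_profiles

logger = logging.getLogger("squidecon")


@dataclass
class ConcurrentDataset:
    """Bulk and single-cell profiles of the same samples, aligned by id.

    ``pseudobulk`` may be supplied (e.g. by the expected-value simulator);
    otherwise it is derived from the cells with :func:`make_pseudobulk`.
    """

    bulk: ExpressionMatrix
    sc: ExpressionMatrix
    labels: CellLabelTable
    pseudobulk: ExpressionMatrix | None = None

    def __post_init__(self) -> None:
        sc_samples = set(self.labels.table["sample_id"])
        missing = [s for s in self.bulk.column_ids if s not in sc_samples]
        if missing:
            raise ValueError(f"bulk samples without single-cell data: {missing}")
        if self.pseudobulk is None:
            self.pseudobulk = make_pseudobulk(self.sc, self.labels, order=self.bulk.column_ids)
        elif list(self.pseudobulk.column_ids) != list(self.bulk.column_ids):
            self.pseudobulk = self.pseudobulk.subset_columns(self.bulk.column_ids)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bulk.column_ids)


@dataclass
class TransformModel:
    """Per-gene linear map from bulk space into single-cell space.

    ``mode='eq2'`` stores regression coefficients (slope, intercept) fit on
    concurrent samples; ``mode='eq3'`` stores the per-gene moments
    (pseudobulk mean/sd, bulk mean/sd) of the standardizing map.  Genes
    outside ``gene_universe`` (zero total expression in either assay, or
    zero bulk sd for eq3) carry no model and are dropped on transform.
    """

    mode: str
    gene_universe: list[str]
    slope: np.ndarray | None = None
    intercept: np.ndarray | None = None
    mean_pseudobulk: np.ndarray | None = None
    mean_bulk: np.ndarray | None = None
    sd_pseudobulk: np.ndarray | None = None
    sd_bulk: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("eq2", "eq3"):
            raise ValueError(f"unknown transform mode {self.mode!r}")
        n = len(self.gene_universe)
        if self.mode == "eq2":
            if self.slope is None or self.intercept is None:
                raise ValueError("eq2 model requires slope and intercept")
            if len(self.slope) != n or len(self.intercept) != n:
                raise ValueError("coefficient arrays must match gene universe")
            if not (np.all(np.isfinite(self.slope)) and np.all(np.isfinite(self.intercept))):
                raise ValueError("non-finite transform coefficients")
        else:
            for arr, name in ((self.mean_pseudobulk, "mean_pseudobulk"),
                              (self.mean_bulk, "mean_bulk"),
                              (self.sd_pseudobulk, "sd_pseudobulk"),
                              (self.sd_bulk, "sd_bulk")):
                if arr is None or len(arr) != n:
                    raise ValueError(f"eq3 model missing or misshapen {name}")
            if np.any(np.asarray(self.sd_bulk) <= 0):
                raise ValueError("eq3 requires positive bulk sd for every modeled gene")

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "eq2":
            return pd.DataFrame(
                {"slope": self.slope, "intercept": self.intercept}, index=self.gene_universe
            )
        return pd.DataFrame(
            {"mean_pseudobulk": self.mean_pseudobulk, "mean_bulk": self.mean_bulk,
             "sd_pseudobulk": self.sd_pseudobulk, "sd_bulk": self.sd_bulk},
            index=self.gene_universe,
        )


def make_pseudobulk(
    sc: ExpressionMatrix,
    labels: CellLabelTable,
    order: list[str] | None = None,
) -> ExpressionMatrix:
    """Per-sample pseudobulk: mean expression across each sample's cells."""
    dense = sc.to_dense(copy=False)
    samples = labels.table.loc[sc.column_ids, "sample_id"].to_numpy()
    ids = order if order is not None else sorted(pd.unique(samples))
    cols = []
    for s in ids:
        mask = samples == s
        if not mask.any():
            raise ValueError(f"sample {s!r} has no cells")
        cols.append(dense[:, mask].mean(axis=1))
    return ExpressionMatrix(np.column_stack(cols), list(sc.gene_ids), list(ids), "arbitrary")


def _aligned_arrays(ds: ConcurrentDataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = [g for g in ds.bulk.gene_ids if g in set(ds.pseudobulk.gene_ids)]
    if not shared:
        raise ValueError("bulk and pseudobulk share no genes")
    Z = ds.bulk.subset_genes(shared).to_dense(copy=False)
    Zhat = ds.pseudobulk.subset_genes(shared).to_dense(copy=False)
    return Z, Zhat, shared


def fit_gene_transform_eq2(ds: ConcurrentDataset) -> TransformModel:
    """Per-gene simple regression of pseudobulk on bulk across samples.

    Scope: genes with nonzero total expression in both assays (dataset-wide).
    Closed form: a_g = cov(z_g, zhat_g) / var(z_g); b_g = mean(zhat_g) -
    a_g * mean(z_g).  Genes with zero bulk variance fall back to the flat
    model (a=0, b = mean pseudobulk).
    """
    if ds.bulk.n_columns < 2:
        raise ValueError("per-gene regression needs at least 2 aligned samples")
    Z, Zhat, shared = _aligned_arrays(ds)
    in_scope = (Z.sum(axis=1) > 0) & (Zhat.sum(axis=1) > 0)
    if not in_scope.any():
        raise ValueError("no genes with nonzero expression in both assays")
    Z, Zhat = Z[in_scope], Zhat[in_scope]
    universe = [g for g, k in zip(shared, in_scope) if k]
    zm = Z.mean(axis=1)
    hm = Zhat.mean(axis=1)
    zc = Z - zm[:, None]
    var = (zc**2).mean(axis=1)
    cov = (zc * (Zhat - hm[:, None])).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    intercept = hm - slope * zm
    return TransformModel("eq2", universe, slope=slope, intercept=intercept)


def fit_gene_transform_eq3(ds: ConcurrentDataset) -> TransformModel:
    """Moment-matching map: per-gene means and sds of both assays.

    Scope additionally requires positive bulk standard deviation (the map
    divides by it).  Sample standard deviations (ddof=1).
    """
    if ds.bulk.n_columns < 2:
        raise ValueError("moment estimation needs at least 2 aligned samples")
    Z, Zhat, shared = _aligned_arrays(ds)
    sd_bulk = Z.std(axis=1, ddof=1)
    in_scope = (Z.sum(axis=1) > 0) & (Zhat.sum(axis=1) > 0) & (sd_bulk > 0)
    if not in_scope.any():
        raise ValueError("no genes with nonzero expression and variance in both assays")
    universe = [g for g, k in zip(shared, in_scope) if k]
    return TransformModel(
        "eq3", universe,
        mean_pseudobulk=Zhat[in_scope].mean(axis=1),
        mean_bulk=Z[in_scope].mean(axis=1),
        sd_pseudobulk=Zhat[in_scope].std(axis=1, ddof=1),
        sd_bulk=sd_bulk[in_scope],
    )


def fit_gene_transform(ds: ConcurrentDataset, mode: str = "eq2") -> TransformModel:
    """Fit the bulk-to-single-cell map in the requested mode."""
    if mode == "eq2":
        return fit_gene_transform_eq2(ds)
    if mode == "eq3":
        return fit_gene_transform_eq3(ds)
    raise ValueError(f"unknown transform mode {mode!r}")


def transform_bulk(model: TransformModel, bulk: ExpressionMatrix) -> ExpressionMatrix:
    """Map bulk profiles into single-cell space gene by gene.

    Output is restricted to the model's gene universe and tagged
    ``arbitrary`` (transformed values may be negative).
    """
    sub = bulk.subset_genes(model.gene_universe)
    Z = sub.to_dense()
    if model.mode == "eq2":
        out = model.slope[:, None] * Z + model.intercept[:, None]
    else:
        ratio = np.asarray(model.sd_pseudobulk) / np.asarray(model.sd_bulk)
        out = np.asarray(model.mean_pseudobulk)[:, None] + ratio[:, None] * (
            Z - np.asarray(model.mean_bulk)[:, None]
        )
    return ExpressionMatrix(out, list(model.gene_universe), list(bulk.column_ids), "arbitrary")


def squid_deconvolve(
    transformed_bulk_col,
    ref: ClusterReference,
    spec: SolverSpec | None = None,
    gene_ids: list[str] | None = None,
) -> SolverResult:
    """Dampened weighted least squares on all shared nonzero genes.

    ``transformed_bulk_col`` may be a bare vector aligned to the reference
    genes, or accompanied by ``gene_ids`` for alignment by name.  The solve
    universe keeps genes nonzero in the transformed column and with positive
    total reference expression; no marker selection is applied.
    """
    spec = spec or SolverSpec(name="DWLS")
    z = np.asarray(transformed_bulk_col, dtype=float).ravel()
    if gene_ids is not None:
        shared = [g for g in gene_ids if g in set(ref.profiles.gene_ids)]
        lookup = {g: i for i, g in enumerate(gene_ids)}
        z = z[[lookup[g] for g in shared]]
        X = ref.profiles.subset_genes(shared).to_dense(copy=False)
    else:
        if len(z) != ref.profiles.n_genes:
            raise ValueError("vector length does not match reference; pass gene_ids")
        X = ref.profiles.to_dense(copy=False)
    keep = (z != 0) & (X.sum(axis=1) > 0)
    if keep.sum() < ref.n_clusters:
        raise ValueError(
            f"only {int(keep.sum())} usable genes for {ref.n_clusters} cell types"
        )
    return solve_dwls(z[keep], X[keep], spec)


def squid_estimate(
    ds: ConcurrentDataset,
    spec: SolverSpec | None = None,
    mode: str = "eq2",
    ref: ClusterReference | None = None,
) -> CompositionMatrix:
    """Fit the transform on the whole dataset and deconvolve every sample."""
    spec = spec or SolverSpec(name="DWLS")
    model = fit_gene_transform(ds, mode)
    if ref is None:
        ref = cluster_profiles(ds.sc, ds.labels)
    transformed = transform_bulk(model, ds.bulk)
    T = transformed.to_dense(copy=False)
    rows = [
        squid_deconvolve(T[:, i], ref, spec, gene_ids=transformed.gene_ids).proportions
        for i in range(T.shape[1])
    ]
    return CompositionMatrix(np.vstack(rows), ds.sample_ids, ref.cluster_ids, "estimate")


def loo_cross_validate(
    ds: ConcurrentDataset,
    spec: SolverSpec | None = None,
    mode: str = "eq2",
) -> CompositionMatrix:
    """Leave-one-out SQUID: each sample predicted from the other samples.

    Per fold, the transform is fit on the bulk/pseudobulk of the training
    samples and the reference is rebuilt from the training samples' cells,
    so nothing derived from the held-out sample's single-cell data enters
    its own prediction.  Rows are assembled in input sample order; cell
    types are the union over folds (types absent from a fold's training
    data get proportion 0 for that sample).
    """
    spec = spec or SolverSpec(name="DWLS")
    samples = ds.sample_ids
    if len(samples) < 3:
        raise ValueError("leave-one-out needs at least 3 aligned samples")
    fold_rows: dict[str, pd.Series] = {}
    for held in samples:
        train = [s for s in samples if s != held]
        cell_mask = ds.labels.table["sample_id"].isin(train)
        cells = list(ds.labels.table.index[cell_mask])
        if len(train) < 2:
            raise ValueError("fold with fewer than 2 training samples")
        sc_train = ds.sc.subset_columns(cells)
        labels_train = ds.labels.subset(cells)
        fold_ds = ConcurrentDataset(
            bulk=ds.bulk.subset_columns(train),
            sc=sc_train,
            labels=labels_train,
            pseudobulk=ds.pseudobulk.subset_columns(train),
        )
        model = fit_gene_transform(fold_ds, mode)
        ref = cluster_profiles(sc_train, labels_train)
        transformed = transform_bulk(model, ds.bulk.subset_columns([held]))
        res = squid_deconvolve(
            transformed.to_dense(copy=False)[:, 0], ref, spec,
            gene_ids=transformed.gene_ids,
        )
        fold_rows[held] = pd.Series(res.proportions, index=ref.cluster_ids)
        logger.info("LOO fold %s: %d genes in model, %d DWLS iterations",
                    held, len(model.gene_universe), res.n_iterations)
    frame = pd.DataFrame({s: fold_rows[s] for s in samples}).T.fillna(0.0)
    return CompositionMatrix(frame.to_numpy(), samples, list(frame.columns), "estimate")
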