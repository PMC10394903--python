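"""Single-cell reference preprocessing.

Implements the reference-building side of the benchmarking framework:

* cell QC by extreme mitochondrial / ribosomal content (both distribution
  tails trimmed),
* detectable-gene filtering (a gene survives if, in at least one cluster, it
  is expressed in >= 10 cells or in >= 1% of that cluster's cells),
* the normalization grid (none / TPM / TMM / LogNormalize) shared by bulk and
  reference matrices,
* cluster-mean expression profiles (the deconvolution reference X),
* gold-standard compositions from per-sample cluster cell counts,
* one-vs-rest Wilcoxon marker detection with a log2(1.5) fold-change gate,
* and greedy merging of near-duplicate clusters (Pearson r >= 0.95).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CellLabelTable, CompositionMatrix, ExpressionMatrix

logger = logging.getLogger("squidecon")

MITO_PREFIXES = ("MT-", "mt-", "Mt-")
RIBO_PREFIXES = ("RPS", "RPL", "Rps", "Rpl")


@dataclass
class NormalizationMethod:
    """A normalization choice from the benchmark grid.

    name:
        one of ``none``, ``TPM``, ``TMM``, ``LogNormalize``.
    gene_lengths:
        mapping gene id -> length in bases; required for TPM only.
    pseudocount, scale_factor:
        LogNormalize parameters: ``log(1 + scale_factor * count / colsum)``
        with natural log (pseudocount fixed at 1 by that form).
    """

    name: str = "none"
    gene_lengths: dict[str, float] | None = None
    pseudocount: float = 1.0
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if self.name not in ("none", "TPM", "TMM", "LogNormalize"):
            raise ValueError(f"unknown normalization {self.name!r}")


@dataclass
class ClusterReference:
    """Cluster-mean expression profiles: the deconvolution reference X.

    ``profiles`` is genes x clusters; ``cell_counts`` records how many cells
    each cluster mean averages over; ``markers`` optionally maps cluster id to
    an ordered marker-gene list.
    """

    profiles: ExpressionMatrix
    cell_counts: dict[str, int]
    markers: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if set(self.cell_counts) != set(self.profiles.column_ids):
            raise ValueError("cell_counts keys must match profile cluster ids")
        for cid, n in self.cell_counts.items():
            if n < 1:
                raise ValueError(f"cluster {cid!r} has cell count {n} < 1")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.profiles.column_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.profiles.column_ids)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_qc_fractions(
    sc: ExpressionMatrix,
    labels: CellLabelTable,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = RIBO_PREFIXES,
) -> CellLabelTable:
    """Fill missing mito/ribo fractions from gene-name prefixes."""
    t = labels.table.copy()
    dense = sc.to_dense(copy=False)
    totals = dense.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    genes = np.array(sc.gene_ids)
    cells = pd.Index(sc.column_ids)
    order = cells.get_indexer(t.index)
    if (order < 0).any():
        raise ValueError("label table contains cells absent from the matrix")
    for col, prefixes in (("mito_fraction", mito_prefixes), ("ribo_fraction", ribo_prefixes)):
        if t[col].isna().any():
            mask = np.zeros(len(genes), dtype=bool)
            for p in prefixes:
                mask |= np.char.startswith(genes.astype(str), p)
            frac = dense[mask, :].sum(axis=0) / totals
            vals = t[col].to_numpy(dtype=float)
            missing = np.isnan(vals)
            vals[missing] = frac[order][missing]
            t[col] = vals
    return CellLabelTable(t)


def qc_filter_cells(
    sc: ExpressionMatrix,
    labels: CellLabelTable,
    tail: float = 0.005,
) -> tuple[ExpressionMatrix, CellLabelTable]:
    """Drop cells with extreme mitochondrial or ribosomal content.

    For each covariate the ``tail`` and ``1 - tail`` quantiles are computed
    over all cells jointly; a cell is removed if it lies strictly below the
    lower or strictly above the upper quantile of either covariate (so a
    constant covariate removes nothing and ``tail=0`` is the identity).
    """
    if not 0 <= tail < 0.5:
        raise ValueError("tail must lie in [0, 0.5)")
    labels = compute_qc_fractions(sc, labels)
    t = labels.table
    keep = np.ones(len(t), dtype=bool)
    for col in ("mito_fraction", "ribo_fraction"):
        x = t[col].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [tail, 1.0 - tail])
        keep &= ~((x < lo) | (x > hi))
    kept_ids = [cid for cid, k in zip(t.index, keep) if k]
    if len(kept_ids) < 10:
        raise ValueError(f"QC retained only {len(kept_ids)} cells (<10)")
    logger.info("QC: retained %d / %d cells (tail=%g)", len(kept_ids), len(t), tail)
    return sc.subset_columns(kept_ids), labels.subset(kept_ids)


# ---------------------------------------------------------------------------
# gene filter
# ---------------------------------------------------------------------------

def filter_detectable_genes(
    sc: ExpressionMatrix,
    labels: CellLabelTable,
    min_cells: int = 10,
    min_fraction: float = 0.01,
) -> ExpressionMatrix:
    """Keep genes expressed in >=10 cells or >=1% of cells of some cluster.

    Expression means count > 0.  The two arms combine with a logical OR and
    are evaluated per cluster; a gene survives if any cluster satisfies
    either arm.
    """
    dense = sc.to_dense(copy=False)
    clusters = labels.table.loc[sc.column_ids, "cluster_id"].to_numpy()
    keep = np.zeros(sc.n_genes, dtype=bool)
    for cid in pd.unique(clusters):
        mask = clusters == cid
        n_cluster = int(mask.sum())
        expressed = (dense[:, mask] > 0).sum(axis=1)
        keep |= (expressed >= min_cells) | (expressed >= min_fraction * n_cluster)
    if not keep.any():
        raise ValueError("no detectable genes remain after filtering")
    kept = [g for g, k in zip(sc.gene_ids, keep) if k]
    logger.info("gene filter: retained %d / %d genes", len(kept), sc.n_genes)
    return sc.subset_genes(kept)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _column_sums(mat: ExpressionMatrix) -> np.ndarray:
    sums = np.asarray(mat.to_dense(copy=False).sum(axis=0), dtype=float)
    zero = np.nonzero(sums == 0)[0]
    if len(zero):
        raise ValueError(f"zero column sum in column {mat.column_ids[zero[0]]!r}")
    return sums


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (Robinson & Oshlack).

    The reference column is the one whose upper quartile of scaled counts is
    closest to the mean upper quartile.  Per column, log ratios M and average
    abundances A (versus the reference) are computed over genes positive in
    both; the most extreme 30% of M and 5% of A are trimmed; the factor is
    the precision-weighted mean of the remaining M.  Factors are normalized
    to unit geometric mean, matching the standard convention.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    scaled = counts / lib
    uq = np.array([np.quantile(scaled[:, k][counts[:, k] > 0] if (counts[:, k] > 0).any() else scaled[:, k], 0.75) for k in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        yk, nk = counts[:, k], lib[k]
        mask = (yk > 0) & (yr > 0)
        if mask.sum() < 2:
            continue
        pk, pr = yk[mask] / nk, yr[mask] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # asymptotic (delta-method) binomial variance weights
        w = (nk - yk[mask]) / (nk * yk[mask]) + (nr - yr[mask]) / (nr * yr[mask])
        if np.allclose(m, m[0]):
            factors[k] = 2.0 ** m[0]
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        with np.errstate(divide="ignore"):
            inv = 1.0 / w[keep]
        f = (inv * m[keep]).sum() / inv.sum()
        factors[k] = 2.0 ** f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize(mat: ExpressionMatrix, method: NormalizationMethod) -> ExpressionMatrix:
    """Apply one normalization from the grid; ``none`` is the identity."""
    if method.name == "none":
        return mat
    dense = mat.to_dense()
    if method.name == "TPM":
        if method.gene_lengths is None:
            raise ValueError("TPM requires gene lengths")
        try:
            lengths = np.array([float(method.gene_lengths[g]) for g in mat.gene_ids])
        except KeyError as exc:
            raise ValueError(f"TPM gene length missing for gene {exc.args[0]!r}") from exc
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        rate = dense / lengths[:, None]
        sums = rate.sum(axis=0)
        zero = np.nonzero(sums == 0)[0]
        if len(zero):
            raise ValueError(f"zero column sum in column {mat.column_ids[zero[0]]!r}")
        return mat.with_values(rate / sums * 1e6, unit_tag="TPM")
    if method.name == "TMM":
        sums = _column_sums(mat)
        factors = tmm_factors(dense)
        cpm = dense / (sums * factors) * 1e6
        return mat.with_values(cpm, unit_tag="TMM")
    if method.name == "LogNormalize":
        sums = _column_sums(mat)
        return mat.with_values(
            np.log1p(method.scale_factor * dense / sums), unit_tag="lognorm"
        )
    raise AssertionError(method.name)


# ---------------------------------------------------------------------------
# cluster profiles / gold standard
# ---------------------------------------------------------------------------

def cluster_profiles(sc: ExpressionMatrix, labels: CellLabelTable) -> ClusterReference:
    """Average expression across the cells of each cluster (raw scale).

    Empty clusters (present in the label vocabulary but with zero cells in
    the matrix) are dropped with a warning.
    """
    dense = sc.to_dense(copy=False)
    clusters = labels.table.loc[sc.column_ids, "cluster_id"].to_numpy()
    ids = sorted(pd.unique(clusters))
    profiles, counts, kept = [], {}, []
    for cid in ids:
        mask = clusters == cid
        n = int(mask.sum())
        if n == 0:
            logger.warning("cluster %r has no cells; dropped", cid)
            continue
        profiles.append(dense[:, mask].mean(axis=1))
        counts[cid] = n
        kept.append(cid)
    prof = ExpressionMatrix(
        np.column_stack(profiles), list(sc.gene_ids), kept, sc.unit_tag
    )
    return ClusterReference(prof, counts)


def gold_standard_from_clusters(labels: CellLabelTable) -> CompositionMatrix:
    """Per-sample cluster cell fractions: the single-cell gold standard."""
    t = labels.table
    tab = pd.crosstab(t["sample_id"], t["cluster_id"])
    empty = tab.index[tab.sum(axis=1) == 0]
    for s in empty:
        logger.warning("sample %r has no cells; dropped", s)
    tab = tab[tab.sum(axis=1) > 0]
    props = tab.div(tab.sum(axis=1), axis=0)
    return CompositionMatrix(
        props.to_numpy(dtype=float), list(props.index), list(props.columns),
        kind="gold_standard",
    )


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def find_markers(
    sc: ExpressionMatrix,
    labels: CellLabelTable,
    lfc_threshold: float = math.log2(1.5),
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> dict[str, list[str]]:
    """One-vs-rest Wilcoxon rank-sum marker detection per cluster.

    Expects TMM-normalized input (asserted via the unit tag).  A gene is a
    marker of a cluster when log2((mean_in + pc) / (mean_out + pc)) meets the
    fold-change threshold and its Benjamini–Hochberg adjusted two-sided
    rank-sum p-value is at or below ``alpha``.  Markers are ordered by
    descending fold-change.  Clusters with fewer than 3 cells are skipped.
    """
    if sc.unit_tag != "TMM":
        raise ValueError(
            f"find_markers expects TMM-normalized input, got unit_tag={sc.unit_tag!r}"
        )
    dense = sc.to_dense(copy=False)
    clusters = labels.table.loc[sc.column_ids, "cluster_id"].to_numpy()
    out: dict[str, list[str]] = {}
    genes = np.array(sc.gene_ids)
    for cid in sorted(pd.unique(clusters)):
        mask = clusters == cid
        if mask.sum() < 3:
            logger.warning("cluster %r has <3 cells; excluded from marker calling", cid)
            continue
        inside, outside = dense[:, mask], dense[:, ~mask]
        lfc = np.log2(
            (inside.mean(axis=1) + pseudocount) / (outside.mean(axis=1) + pseudocount)
        )
        if math.isinf(lfc_threshold):
            out[cid] = []
            continue
        res = scipy.stats.mannwhitneyu(
            inside, outside, axis=1, alternative="two-sided", method="asymptotic"
        )
        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        hits = np.nonzero((lfc >= lfc_threshold) & (padj <= alpha))[0]
        order = hits[np.argsort(-lfc[hits], kind="stable")]
        out[cid] = [str(g) for g in genes[order]]
    return out


# ---------------------------------------------------------------------------
# cluster merging
# ---------------------------------------------------------------------------

def merge_similar_clusters(
    ref: ClusterReference,
    r_min: float = 0.95,
) -> tuple[ClusterReference, pd.DataFrame]:
    """Greedily merge highly correlated cluster pairs until none remain.

    Each pass computes all pairwise Pearson correlations of the cluster-mean
    profiles, selects a maximal set of non-overlapping pairs in descending
    correlation order among pairs with r >= ``r_min`` (exact ties broken by
    lexicographic cluster-id order), merges each selected pair into a single
    cluster (cell-count-weighted mean profile, summed counts, ids joined with
    '+'), and repeats.  Returns the merged reference and a merge log with
    columns (iteration, cluster_a, cluster_b, r, new_id).
    """
    profiles = ref.profiles.to_dense()
    ids = list(ref.cluster_ids)
    counts = dict(ref.cell_counts)
    log_rows = []
    iteration = 0
    while len(ids) >= 2:
        iteration += 1
        corr = np.corrcoef(profiles.T)
        pairs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = corr[i, j]
                if np.isfinite(r) and r >= r_min:
                    pairs.append((-r, ids[i], ids[j], i, j))
        if not pairs:
            break
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used: set[int] = set()
        merges = []
        for negr, ida, idb, i, j in pairs:
            if i in used or j in used:
                continue
            used.update((i, j))
            merges.append((-negr, i, j))
        drop = set()
        for r, i, j in merges:
            ida, idb = ids[i], ids[j]
            na, nb = counts[ida], counts[idb]
            merged_profile = (na * profiles[:, i] + nb * profiles[:, j]) / (na + nb)
            new_id = "+".join(sorted(ida.split("+") + idb.split("+")))
            profiles[:, i] = merged_profile
            counts[new_id] = na + nb
            del counts[ida], counts[idb]
            ids[i] = new_id
            drop.add(j)
            log_rows.append(
                {"iteration": iteration, "cluster_a": ida, "cluster_b": idb,
                 "r": float(r), "new_id": new_id}
            )
        keep = [k for k in range(len(ids)) if k not in drop]
        profiles = profiles[:, keep]
        ids = [ids[k] for k in keep]
    merged_ref = ClusterReference(
        ExpressionMatrix(profiles, list(ref.profiles.gene_ids), ids, ref.profiles.unit_tag),
        counts,
    )
    log = pd.DataFrame(log_rows, columns=["iteration", "cluster_a", "cluster_b", "r", "new_id"])
    return merged_ref, log


def merge_mapping(log: pd.DataFrame) -> dict[str, str]:
    """Original-cluster -> final-cluster mapping implied by a merge log."""
    mapping: dict[str, str] = {}
    for row in log.itertuples():
        for part in (row.cluster_a, row.cluster_b):
            for orig in part.split("+"):
                mapping[orig] = row.new_id
        # follow chains: anything previously mapped into a part follows it
        for orig, tgt in list(mapping.items()):
            if tgt in (row.cluster_a, row.cluster_b):
                mapping[orig] = row.new_id
    return mapping
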