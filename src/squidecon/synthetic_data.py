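"""Synthetic concurrent bulk + single-cell datasets with known truth.

The generator emulates a six-cell-type in vitro mixture series: three
variable "tumor" lines carrying most of the mass, two "immune" lines jointly
fixed at 15% of each mixture, and one rare "stem" type cycling through
0.5% / 1% / 2%.  One mixture is dominated by a single tumor type (>= 66%)
and one is balanced.  Each virtual sample is profiled twice:

* bulk — Poisson counts around depth-scaled mixture expectations, with
  multiplicative log-normal measurement noise;
* single-cell — cells assigned to types multinomially by the true
  proportions, with negative-binomial counts around type means that carry a
  *per-gene* multiplicative platform bias (log-normal capture factor,
  sdlog tau) and per-gene dropout thinning.

Because the injected platform bias is per-gene and type-independent, the
pseudobulk of a sample is an exactly linear per-gene function of its bulk
expectation — the distortion regime a per-gene linear transform can fully
correct.  Every dataset is emitted together with its gold-standard
composition (realized cell fractions) and the unbiased true profiles, so
solvers can be scored without external data.  All distributional choices
here are synthetic modeling assumptions of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CellLabelTable, CompositionMatrix, ExpressionMatrix
from .squid import ConcurrentDataset

logger = logging.getLogger("squidecon")

CELLTYPES = ("tumorA", "tumorB", "tumorC", "immune1", "immune2", "stem")
STEM_LEVELS = (0.005, 0.01, 0.02)
IMMUNE_TOTAL = 0.15
MARKER_FRACTION = 0.05
MARKER_BOOST = 8.0
NB_DISPERSION = 0.5


@dataclass
class MixtureDesign:
    """True mixture proportions for a panel of synthetic samples."""

    proportions: pd.DataFrame  # samples x cell types
    seed: int

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("design proportions must be non-negative")
        if np.abs(vals.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("design rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.proportions.columns)

    def as_composition(self) -> CompositionMatrix:
        return CompositionMatrix(
            self.proportions.to_numpy(dtype=float),
            self.sample_ids, self.celltype_ids, kind="gold_standard",
        )


@dataclass
class PlatformBiasModel:
    """Cross-platform distortion between bulk and single-cell measurements.

    tau:
        sdlog of the per-gene log-normal capture factor applied to
        single-cell means only.  tau=0 disables the capture bias.
    dropout_shape:
        per-gene dropout thinning 1 - exp(-shape * pooled gene mean);
        0 disables dropout.
    bulk_noise_sdlog:
        sdlog of mean-one multiplicative log-normal noise on bulk counts.
    cell_size_sdlog:
        sdlog of mean-one per-cell library-size factors.
    content:
        optional per-cell-type RNA content scalars (default: all 1).
    """

    tau: float = 0.5
    dropout_shape: float = 0.5
    bulk_noise_sdlog: float = 0.1
    cell_size_sdlog: float = 0.3
    content: np.ndarray | None = None

    @classmethod
    def unbiased(cls) -> "PlatformBiasModel":
        """No capture bias, no dropout, no noise: both assays agree exactly."""
        return cls(tau=0.0, dropout_shape=0.0, bulk_noise_sdlog=0.0, cell_size_sdlog=0.0)


def sample_design(
    seed: int,
    n_samples: int = 6,
    dominant_sample: int = 0,
    balanced_sample: int = 3,
) -> MixtureDesign:
    """Draw a mixture design on the six-type template (deterministic per seed).

    The stem type cycles 0.5% / 1% / 2%; the two immune types jointly hold
    15%; the three tumor types share the remainder, with one sample dominated
    by tumorA (>= 66% of the whole mixture) and one balanced sample.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        stem = STEM_LEVELS[i % len(STEM_LEVELS)]
        imm1 = IMMUNE_TOTAL * rng.uniform(0.3, 0.7)
        imm2 = IMMUNE_TOTAL - imm1
        mass = 1.0 - IMMUNE_TOTAL - stem
        if i == dominant_sample:
            a = rng.uniform(0.66, min(0.72, mass - 0.02))
            # concentrated split keeps both minor tumor types well above zero
            rest = rng.dirichlet([3.0, 3.0]) * (mass - a)
            tumors = np.array([a, rest[0], rest[1]])
        elif i == balanced_sample:
            tumors = np.full(3, mass / 3.0)
        else:
            tumors = rng.dirichlet([2.0, 2.0, 2.0]) * mass
        row = np.concatenate([tumors, [imm1, imm2, stem]])
        rows.append(row / row.sum())
    frame = pd.DataFrame(
        np.array(rows), index=[f"M{i+1}" for i in range(n_samples)], columns=list(CELLTYPES)
    )
    return MixtureDesign(frame, seed=seed)


def _type_means(n_genes: int, n_types: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal type mean profiles with disjoint boosted marker blocks."""
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=(n_genes, n_types))
    n_marker = int(round(MARKER_FRACTION * n_genes))
    perm = rng.permutation(n_genes)
    for j in range(n_types):
        block = perm[j * n_marker:(j + 1) * n_marker]
        mu[block, j] *= MARKER_BOOST
    return mu


def _bias_factors(mu: np.ndarray, bias: PlatformBiasModel, rng: np.random.Generator):
    n_genes, n_types = mu.shape
    capture = rng.lognormal(0.0, bias.tau, size=n_genes) if bias.tau > 0 else np.ones(n_genes)
    pooled = mu.mean(axis=1)
    if bias.dropout_shape > 0:
        keep = 1.0 - np.exp(-bias.dropout_shape * pooled)
    else:
        keep = np.ones(n_genes)
    content = (np.ones(n_types) if bias.content is None
               else np.asarray(bias.content, dtype=float))
    if len(content) != n_types or (content <= 0).any():
        raise ValueError("content must be positive, one scalar per cell type")
    return capture, keep, content


def _expectations(design: MixtureDesign, mu, capture, keep, content,
                  bulk_depth: float, cell_depth: float):
    """Exact expectations shared by the sampled and expected-value paths."""
    P = design.proportions.to_numpy()  # samples x types
    U = (mu * content[None, :]) @ P.T  # genes x samples
    bulk_scale = bulk_depth / U.sum(axis=0).mean()
    bulk_mean = bulk_scale * U
    sc_type_mean = mu * (capture * keep)[:, None] * content[None, :]  # genes x types
    cell_scale = cell_depth / sc_type_mean.sum(axis=0).mean()
    X = cell_scale * sc_type_mean  # expected per-cell counts by type
    pseudobulk = X @ P.T  # genes x samples, exact mean over cells
    return bulk_mean, X, pseudobulk


def _mean_one_lognormal(rng, sdlog, size):
    if sdlog <= 0:
        return np.ones(size)
    return rng.lognormal(-0.5 * sdlog**2, sdlog, size=size)


def generate_concurrent(
    design: MixtureDesign,
    bias: PlatformBiasModel | None = None,
    cells_per_sample: int = 2000,
    n_genes: int = 2000,
    bulk_depth: float = 1e6,
    cell_depth: float = 2000.0,
    seed: int | None = None,
) -> tuple[ConcurrentDataset, CompositionMatrix, ExpressionMatrix]:
    """Sample a concurrent dataset; returns (dataset, gold, true_profiles).

    The gold standard is the *realized* per-sample cell-type fraction (the
    quantity a single-cell experiment would report), which differs from the
    design proportions by multinomial sampling noise.
    """
    bias = bias if bias is not None else PlatformBiasModel()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    types = design.celltype_ids
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]
    mu = _type_means(n_genes, len(types), rng)
    capture, keep, content = _bias_factors(mu, bias, rng)
    bulk_mean, X, _ = _expectations(design, mu, capture, keep, content,
                                    bulk_depth, cell_depth)

    # bulk: Poisson counts + multiplicative log-normal noise
    bulk_counts = rng.poisson(bulk_mean).astype(float)
    bulk_counts *= _mean_one_lognormal(rng, bias.bulk_noise_sdlog, bulk_mean.shape)
    bulk = ExpressionMatrix(bulk_counts, gene_ids, design.sample_ids, "counts")

    # single cell: multinomial type assignment, NB counts around biased means
    P = design.proportions.to_numpy()
    sc_cols, cell_ids, cell_samples, cell_types = [], [], [], []
    gold_rows = []
    r_nb = 1.0 / NB_DISPERSION
    for i, sample in enumerate(design.sample_ids):
        counts = rng.multinomial(cells_per_sample, P[i])
        if (counts == 0).any():
            counts = rng.multinomial(cells_per_sample, P[i])
            if (counts == 0).any():
                empty = [t for t, c in zip(types, counts) if c == 0]
                raise RuntimeError(
                    f"cell type(s) {empty} received 0 cells in sample {sample} "
                    f"after one resample; increase cells_per_sample"
                )
        gold_rows.append(counts / counts.sum())
        c = 0
        for j, tname in enumerate(types):
            n_cells = int(counts[j])
            size = _mean_one_lognormal(rng, bias.cell_size_sdlog, n_cells)
            m = X[:, j][:, None] * size[None, :]
            p_nb = r_nb / (r_nb + m)
            cells = rng.negative_binomial(r_nb, p_nb).astype(float)
            sc_cols.append(cells)
            for _ in range(n_cells):
                c += 1
                cell_ids.append(f"{sample}_c{c:05d}")
                cell_samples.append(sample)
                cell_types.append(tname)
    sc_values = np.concatenate(sc_cols, axis=1)
    sc = ExpressionMatrix(sc_values, gene_ids, cell_ids, "counts")
    labels = CellLabelTable(pd.DataFrame({
        "sample_id": cell_samples,
        "cluster_id": cell_types,
        "mito_fraction": rng.beta(2.0, 38.0, size=len(cell_ids)),
        "ribo_fraction": rng.beta(4.0, 36.0, size=len(cell_ids)),
    }, index=pd.Index(cell_ids, name="cell_id")))
    gold = CompositionMatrix(np.array(gold_rows), design.sample_ids, list(types),
                             kind="gold_standard")
    true_profiles = ExpressionMatrix(mu, gene_ids, list(types), "arbitrary")
    ds = ConcurrentDataset(bulk=bulk, sc=sc, labels=labels)
    return ds, gold, true_profiles


def expected_value_mode(
    design: MixtureDesign,
    bias: PlatformBiasModel | None = None,
    n_genes: int = 2000,
    bulk_depth: float = 1e6,
    cell_depth: float = 2000.0,
    seed: int | None = None,
) -> tuple[ConcurrentDataset, CompositionMatrix, ExpressionMatrix]:
    """Emit exact expectations instead of sampled counts.

    The single-cell side is represented by one exact-mean cell per
    (sample, cell type), so cluster-mean profiles equal the expected type
    profiles exactly; the exact pseudobulk expectation (mixture-weighted
    type means) is attached to the dataset explicitly.  The gold standard
    equals the design.  Used for noise-free solver and transform tests.
    """
    bias = bias if bias is not None else PlatformBiasModel()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    types = design.celltype_ids
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]
    mu = _type_means(n_genes, len(types), rng)
    capture, keep, content = _bias_factors(mu, bias, rng)
    bulk_mean, X, pseudobulk = _expectations(design, mu, capture, keep, content,
                                             bulk_depth, cell_depth)
    bulk = ExpressionMatrix(bulk_mean, gene_ids, design.sample_ids, "counts")
    cell_ids, cell_samples, cell_types, cols = [], [], [], []
    for sample in design.sample_ids:
        for j, tname in enumerate(types):
            cell_ids.append(f"{sample}_{tname}")
            cell_samples.append(sample)
            cell_types.append(tname)
            cols.append(X[:, j])
    sc = ExpressionMatrix(np.column_stack(cols), gene_ids, cell_ids, "counts")
    labels = CellLabelTable(pd.DataFrame({
        "sample_id": cell_samples,
        "cluster_id": cell_types,
        "mito_fraction": 0.05,
        "ribo_fraction": 0.10,
    }, index=pd.Index(cell_ids, name="cell_id")))
    pb = ExpressionMatrix(pseudobulk, gene_ids, design.sample_ids, "arbitrary")
    ds = ConcurrentDataset(bulk=bulk, sc=sc, labels=labels, pseudobulk=pb)
    gold = design.as_composition()
    true_profiles = ExpressionMatrix(mu, gene_ids, list(types), "arbitrary")
    return ds, gold, true_profiles
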