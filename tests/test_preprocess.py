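import math

import numpy as np
import pandas as pd
import pytest

from squidecon import (
    CellLabelTable,
    ClusterReference,
    ExpressionMatrix,
    NormalizationMethod,
    cluster_profiles,
    filter_detectable_genes,
    find_markers,
    gold_standard_from_clusters,
    merge_similar_clusters,
    normalize,
    qc_filter_cells,
)
from squidecon.preprocess import tmm_factors


def _labels(n, sample="s1", cluster="A", mito=None, ribo=None, prefix="c"):
    idx = pd.Index([f"{prefix}{i}" for i in range(n)], name="cell_id")
    return CellLabelTable(pd.DataFrame({
        "sample_id": sample if isinstance(sample, str) else sample,
        "cluster_id": cluster if isinstance(cluster, str) else cluster,
        "mito_fraction": mito if mito is not None else 0.05,
        "ribo_fraction": ribo if ribo is not None else 0.10,
    }, index=idx))


def _matrix(n_genes, n_cells, value=1.0, prefix="c"):
    return ExpressionMatrix(
        np.full((n_genes, n_cells), value),
        [f"g{i}" for i in range(n_genes)],
        [f"{prefix}{i}" for i in range(n_cells)],
        "counts",
    )


class TestQcFilterCells:
    def test_tail_quantiles_remove_five_cells_per_side(self):
        # 1000 cells, distinct mito fractions, ribo sharing the same ranking:
        # each covariate flags the same 5 cells per tail, so the union removes
        # exactly cells ranked 0-4 and 995-999 -> 990 retained
        n = 1000
        mito = np.linspace(0.001, 0.5, n)
        ribo = np.linspace(0.01, 0.9, n)
        mat = _matrix(3, n)
        sc, labels = qc_filter_cells(mat, _labels(n, mito=mito, ribo=ribo), tail=0.005)
        assert sc.n_columns == 990
        removed = set(f"c{i}" for i in range(5)) | set(f"c{i}" for i in range(995, 1000))
        assert removed.isdisjoint(labels.cell_ids)
        assert set(labels.cell_ids) | removed == set(f"c{i}" for i in range(n))

    def test_constant_covariates_remove_nothing(self):
        mat = _matrix(3, 50)
        sc, _ = qc_filter_cells(mat, _labels(50, mito=0.05, ribo=0.05), tail=0.005)
        assert sc.n_columns == 50

    def test_zero_tail_is_identity(self):
        n = 30
        mat = _matrix(3, n)
        sc, _ = qc_filter_cells(mat, _labels(n, mito=np.linspace(0, 1, n)), tail=0.0)
        assert sc.n_columns == n

    def test_fractions_derived_from_gene_prefixes(self):
        values = np.array([[4.0, 1.0], [1.0, 4.0], [5.0, 5.0]])
        mat = ExpressionMatrix(values, ["MT-CO1", "RPS9", "other"], ["c0", "c1"], "counts")
        labels = CellLabelTable(pd.DataFrame({
            "sample_id": "s1", "cluster_id": "A",
        }, index=pd.Index(["c0", "c1"], name="cell_id")))
        from squidecon.preprocess import compute_qc_fractions
        filled = compute_qc_fractions(mat, labels)
        assert filled.table.loc["c0", "mito_fraction"] == pytest.approx(0.4)
        assert filled.table.loc["c1", "ribo_fraction"] == pytest.approx(0.4)

    def test_too_few_surviving_cells_is_an_error(self):
        mat = _matrix(2, 8)
        with pytest.raises(ValueError, match="<10|only"):
            qc_filter_cells(mat, _labels(8), tail=0.005)


class TestFilterDetectableGenes:
    def _dataset(self, expressed_per_gene, cluster_sizes):
        """Gene g expressed (count 1) in the first k cells of each cluster."""
        cells, clusters = [], []
        for cname, size in cluster_sizes.items():
            cells += [f"{cname}_{i}" for i in range(size)]
            clusters += [cname] * size
        values = np.zeros((len(expressed_per_gene), len(cells)))
        start = 0
        offsets = {}
        for cname, size in cluster_sizes.items():
            offsets[cname] = start
            start += size
        for g, spec in enumerate(expressed_per_gene):
            for cname, k in spec.items():
                o = offsets[cname]
                values[g, o:o + k] = 1.0
        mat = ExpressionMatrix(values, [f"g{g}" for g in range(len(expressed_per_gene))],
                               cells, "counts")
        labels = CellLabelTable(pd.DataFrame({
            "sample_id": "s1", "cluster_id": clusters,
            "mito_fraction": 0.05, "ribo_fraction": 0.1,
        }, index=pd.Index(cells, name="cell_id")))
        return mat, labels

    def test_ten_cell_arm_and_percent_arm(self):
        # g0: 10 cells of a 5000-cell cluster -> kept (10-cell arm)
        # g1: 3 cells of a 200-cell cluster   -> kept (3 >= 1% of 200)
        # g2: 5 cells of the 5000-cell cluster only -> dropped (5 < 10, 5 < 50)
        mat, labels = self._dataset(
            [{"big": 10}, {"small": 3}, {"big": 5}],
            {"big": 5000, "small": 200},
        )
        kept = filter_detectable_genes(mat, labels).gene_ids
        assert kept == ["g0", "g1"]

    def test_monotone_in_cluster_membership(self):
        # adding expressing cells to a cluster never removes a retained gene
        mat, labels = self._dataset([{"small": 3}], {"small": 200})
        assert filter_detectable_genes(mat, labels).gene_ids == ["g0"]
        mat2, labels2 = self._dataset([{"small": 23}], {"small": 220})
        assert filter_detectable_genes(mat2, labels2).gene_ids == ["g0"]

    def test_all_genes_filtered_is_an_error(self):
        mat, labels = self._dataset([{"big": 2}], {"big": 5000})
        with pytest.raises(ValueError, match="detectable"):
            filter_detectable_genes(mat, labels)


class TestNormalize:
    def test_none_is_identity(self):
        mat = _matrix(3, 2, value=4.0)
        assert normalize(mat, NormalizationMethod("none")) is mat

    def test_tpm_hand_computed(self):
        mat = ExpressionMatrix(np.array([[10.0], [10.0]]), ["g1", "g2"], ["s1"], "counts")
        out = normalize(mat, NormalizationMethod("TPM", gene_lengths={"g1": 1000, "g2": 2000}))
        np.testing.assert_allclose(
            out.to_dense()[:, 0], [666666.67, 333333.33], atol=1e-2)
        assert out.unit_tag == "TPM"

    def test_tpm_columns_sum_to_million(self):
        rng = np.random.default_rng(5)
        mat = ExpressionMatrix(rng.poisson(5.0, (50, 4)) + 1.0,
                               [f"g{i}" for i in range(50)], list("abcd"), "counts")
        lengths = {f"g{i}": float(rng.integers(200, 5000)) for i in range(50)}
        out = normalize(mat, NormalizationMethod("TPM", gene_lengths=lengths))
        np.testing.assert_allclose(out.to_dense().sum(axis=0), 1e6, rtol=1e-6)

    def test_tmm_identical_columns_gives_cpm(self):
        col = np.array([10.0, 5.0, 30.0, 1.0])
        mat = ExpressionMatrix(np.column_stack([col, col]), list("abcd"), ["s1", "s2"], "counts")
        out = normalize(mat, NormalizationMethod("TMM"))
        cpm = col / col.sum() * 1e6
        np.testing.assert_allclose(out.to_dense()[:, 0], cpm, rtol=1e-9)
        np.testing.assert_allclose(out.to_dense()[:, 1], cpm, rtol=1e-9)

    def test_tmm_factors_match_edger(self):
        # fixture regenerated from the recorded seed; expected factors were
        # computed with Bioconductor edgeR::calcNormFactors (method="TMM")
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.1, size=(60, 4)).astype(float)
        counts[:, 1] *= 3
        counts[:, 3] *= 2
        edger = np.array([0.9491889815, 1.0145863918, 1.0464535741, 0.9922893112])
        np.testing.assert_allclose(tmm_factors(counts), edger, rtol=1e-8)

    def test_lognormalize_zero_maps_to_zero(self):
        mat = ExpressionMatrix(np.array([[0.0], [7.0]]), ["g1", "g2"], ["s1"], "counts")
        out = normalize(mat, NormalizationMethod("LogNormalize"))
        assert out.to_dense()[0, 0] == 0.0
        assert out.to_dense()[1, 0] == pytest.approx(math.log1p(1e4))

    def test_zero_column_sum_is_an_error(self):
        mat = ExpressionMatrix(np.array([[0.0, 1.0], [0.0, 1.0]]), ["g1", "g2"],
                               ["empty", "ok"], "counts")
        with pytest.raises(ValueError, match="empty"):
            normalize(mat, NormalizationMethod("LogNormalize"))


class TestClusterProfiles:
    def test_small_means_and_counts(self, toy_sc):
        mat, labels = toy_sc
        ref = cluster_profiles(mat, labels)
        frame = ref.profiles.to_frame()
        # cluster A: 4 cells; g1 counts (2,4,0,0) -> mean 1.5
        assert frame.loc["g1", "A"] == pytest.approx(1.5)
        assert ref.cell_counts == {"A": 4, "B": 6}

    def test_single_cell_cluster_equals_cell(self):
        values = np.array([[3.0, 1.0], [0.0, 2.0]])
        mat = ExpressionMatrix(values, ["g1", "g2"], ["c0", "c1"], "counts")
        labels = _labels(2, cluster=["solo", "other"])
        ref = cluster_profiles(mat, labels)
        np.testing.assert_array_equal(ref.profiles.to_frame()["solo"], values[:, 0])

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(11)
        values = rng.poisson(3.0, size=(20, 30)).astype(float)
        clusters = rng.choice(["A", "B", "C"], size=30)
        mat = ExpressionMatrix(values, [f"g{i}" for i in range(20)],
                               [f"c{i}" for i in range(30)], "counts")
        ref = cluster_profiles(mat, _labels(30, cluster=list(clusters)))
        oracle = pd.DataFrame(values.T).groupby(clusters).mean().T
        for cid in ref.cluster_ids:
            np.testing.assert_allclose(
                ref.profiles.to_frame()[cid].to_numpy(), oracle[cid].to_numpy(), atol=1e-12)


class TestGoldStandard:
    def test_counting(self):
        labels = _labels(6, cluster=["A", "A", "B", "B", "B", "B"])
        gold = gold_standard_from_clusters(labels)
        frame = gold.to_frame()
        assert frame.loc["s1", "A"] == pytest.approx(1 / 3)
        assert frame.loc["s1", "B"] == pytest.approx(2 / 3)

    def test_single_cluster_gives_one(self):
        gold = gold_standard_from_clusters(_labels(5, cluster="only"))
        assert gold.values[0, 0] == 1.0

    def test_multinomial_concentration(self):
        rng = np.random.default_rng(2)
        truth = np.array([0.3, 0.25, 0.2, 0.13, 0.1, 0.02])
        draws = rng.choice([f"t{j}" for j in range(6)], size=10_000, p=truth)
        gold = gold_standard_from_clusters(_labels(10_000, cluster=list(draws)))
        est = gold.to_frame().loc["s1", [f"t{j}" for j in range(6)]].to_numpy()
        assert np.abs(est - truth).max() < 0.02
        assert gold.values.sum(axis=1) == pytest.approx(1.0, abs=1e-12)


class TestFindMarkers:
    def _tmm_tagged(self, values, genes, cells):
        return ExpressionMatrix(values, genes, cells, "TMM")

    def test_separated_gene_is_marker(self):
        n_in, n_out = 50, 150
        values = np.vstack([
            np.concatenate([np.full(n_in, 8.0), np.full(n_out, 1.0)]),
            np.ones(n_in + n_out),  # flat gene: not a marker
        ])
        mat = self._tmm_tagged(values, ["sep", "flat"], [f"c{i}" for i in range(200)])
        labels = _labels(200, cluster=["A"] * n_in + ["B"] * n_out)
        markers = find_markers(mat, labels)
        # lfc = log2(9/2) ~ 2.17 >= log2(1.5), fully separated ranks
        assert markers["A"] == ["sep"]
        assert "sep" not in markers["B"]

    def test_identically_distributed_gene_not_marker(self):
        rng = np.random.default_rng(8)
        values = rng.poisson(5.0, size=(1, 60)).astype(float)
        mat = self._tmm_tagged(values, ["g"], [f"c{i}" for i in range(60)])
        labels = _labels(60, cluster=["A"] * 30 + ["B"] * 30)
        markers = find_markers(mat, labels)
        assert markers["A"] == [] and markers["B"] == []

    def test_infinite_threshold_empties_marker_sets(self, toy_sc):
        mat, labels = toy_sc
        mat = ExpressionMatrix(mat.to_dense(), mat.gene_ids, mat.column_ids, "TMM")
        markers = find_markers(mat, labels, lfc_threshold=math.inf)
        assert all(v == [] for v in markers.values())

    def test_requires_tmm_unit_tag(self, toy_sc):
        mat, labels = toy_sc
        with pytest.raises(ValueError, match="TMM"):
            find_markers(mat, labels)


class TestMergeSimilarClusters:
    def _ref(self, profiles, counts):
        ids = list(counts)
        mat = ExpressionMatrix(np.column_stack([profiles[c] for c in ids]),
                               [f"g{i}" for i in range(len(next(iter(profiles.values()))))],
                               ids, "lognorm")
        return ClusterReference(mat, counts)

    def test_identical_profiles_merge(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ref = self._ref({"A": base, "B": base.copy()}, {"A": 3, "B": 5})
        merged, log = merge_similar_clusters(ref)
        assert merged.n_clusters == 1
        assert merged.cell_counts == {"A+B": 8}
        assert len(log) == 1 and log.iloc[0]["r"] == pytest.approx(1.0)

    def test_below_threshold_unchanged(self):
        rng = np.random.default_rng(4)
        a = rng.random(200)
        noise = rng.random(200)
        # mix down to r ~= 0.90 < 0.95
        b = 0.70 * a + 0.30 * noise
        r = np.corrcoef(a, b)[0, 1]
        assert 0.85 < r < 0.95
        ref = self._ref({"A": a, "B": b}, {"A": 2, "B": 2})
        merged, log = merge_similar_clusters(ref)
        assert merged.n_clusters == 2 and len(log) == 0

    def test_greedy_trace_on_three_clusters(self):
        # profiles with exact pairwise correlations 0.99 / 0.96 / 0.92,
        # built from centered orthonormal columns and a Cholesky factor
        rng = np.random.default_rng(9)
        target = np.array([[1.0, 0.99, 0.92], [0.99, 1.0, 0.96], [0.92, 0.96, 1.0]])
        raw = rng.standard_normal((500, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        q -= q.mean(axis=0)
        q /= np.linalg.norm(q, axis=0)
        vecs = q @ np.linalg.cholesky(target).T + 5.0
        a, b, c = vecs.T
        corr = np.corrcoef(np.column_stack([a, b, c]).T)
        assert corr[0, 1] > corr[1, 2] >= 0.95 > corr[0, 2]
        ref = self._ref({"A": a, "B": b, "C": c}, {"A": 1, "B": 1, "C": 1})
        merged, log = merge_similar_clusters(ref)
        # first pass merges only the top non-overlapping pair {A,B}
        first = log[log["iteration"] == 1]
        assert len(first) == 1 and set(first.iloc[0][["cluster_a", "cluster_b"]]) == {"A", "B"}
        # C joined later iff its correlation with the merged profile cleared 0.95
        if merged.n_clusters == 1:
            assert (log["iteration"] > 1).any()

    def test_terminates_and_conserves_cells(self):
        rng = np.random.default_rng(10)
        base = rng.random(100)
        profiles = {f"k{i}": base + 0.001 * rng.random(100) for i in range(6)}
        counts = {f"k{i}": i + 1 for i in range(6)}
        ref = self._ref(profiles, counts)
        merged, log = merge_similar_clusters(ref)
        assert log["iteration"].max() <= 5  # <= n_initial - 1 passes
        assert sum(merged.cell_counts.values()) == sum(counts.values())
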