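"""Build a deconvolution reference from labeled single-cell counts.

Runs the preprocessing chain on a synthetic dataset: QC on mitochondrial /
ribosomal content, detectable-gene filtering, cluster-mean profiles, TMM
normalization with Wilcoxon marker detection, and correlation-based merging
of near-duplicate clusters.
"""

from squidecon import (
    NormalizationMethod, PlatformBiasModel, cluster_profiles,
    filter_detectable_genes, find_markers, generate_concurrent,
    gold_standard_from_clusters, merge_similar_clusters, normalize,
    qc_filter_cells, sample_design,
)

design = sample_design(seed=3)
ds, gold, _ = generate_concurrent(design, PlatformBiasModel(tau=0.5),
                                  cells_per_sample=1200, n_genes=1000, seed=3)

sc, labels = qc_filter_cells(ds.sc, ds.labels, tail=0.005)
print(f"QC kept {sc.n_columns} of {ds.sc.n_columns} cells")

sc = filter_detectable_genes(sc, labels)
print(f"gene filter kept {sc.n_genes} of {ds.sc.n_genes} genes")

ref = cluster_profiles(sc, labels)
print(f"reference: {ref.profiles.shape[0]} genes x {ref.n_clusters} clusters,"
      f" cell counts {ref.cell_counts}")

tmm = normalize(sc, NormalizationMethod("TMM"))
markers = find_markers(tmm, labels)
for cluster, genes in markers.items():
    print(f"cluster {cluster}: {len(genes)} markers, top 3 {genes[:3]}")

merged, log = merge_similar_clusters(ref, r_min=0.95)
print(f"merging at r>=0.95: {ref.n_clusters} -> {merged.n_clusters} clusters"
      f" ({len(log)} merges)")

print("\nper-sample cluster fractions (single-cell gold standard):")
print(gold_standard_from_clusters(labels).to_frame().round(3))
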