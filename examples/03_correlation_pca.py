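"""Trait correlation structure and PCA of a simulated panel.

Yield-component traits are generated with a shared genotype factor so
they form a correlated block, the structure that later justifies keeping
a single representative yield trait.  PCA on z-scored traits shows how
much of the panel's variation one axis captures.
"""

import phenoscreen as ps

yield_cluster = {
    t: 0.9
    for t in (
        "grain_weight", "grain_number", "spike_weight",
        "tiller_number", "total_spike_number", "number_of_productive_tillers",
    )
}
table = ps.simulate_population(
    ps.default_catalogue(), seed=42, latent_loadings=yield_cluster
)
wide = ps.observation_matrix(table, level="means")  # 32 cell means x 24 traits
corr = ps.correlation_matrix(wide)

print("correlation of grain weight with the other yield components:")
print(corr.r.loc[list(yield_cluster), "grain_weight"].round(2), "\n")

result = ps.pca(wide, standardize=True)
print("variance explained by the first four components (%):",
      result.variance_explained[:4].round(1))
print("PC1 loadings, strongest five traits:")
print(result.loadings["PC1"].abs().sort_values(ascending=False).head(5).round(2))
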