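"""Composite trait prioritization and redundancy pruning.

Combines heritability under stress, ROC sensitivity, correlation with
grain weight (the reference yield trait) and positive heritability gain
into one robustness score per trait, then greedily drops traits that are
redundant (|r| >= 0.8) with a better-scoring one — producing a reduced
panel for drought phenotyping.
"""

import phenoscreen as ps

yield_cluster = {
    t: 0.95
    for t in (
        "grain_weight", "grain_number", "spike_weight",
        "tiller_number", "total_spike_number", "number_of_productive_tillers",
    )
}
table = ps.simulate_population(
    ps.default_catalogue(), seed=42, latent_loadings=yield_cluster
)

herit = ps.heritability_table(table, scope="per-env")
aucs = ps.auc_table(table)["auc"]
indices = ps.trait_summary(table)["index"]
corr = ps.correlation_matrix(ps.observation_matrix(table))

cards = ps.score_traits(herit, aucs, indices, corr, reference_trait="grain_weight")
result = ps.reduce_traits(cards, corr, redundancy_threshold=0.8)

frame = result.to_frame()
print(frame[["robustness", "auc", "H_s", "r_yield", "selected", "redundant_with"]]
      .round(3).head(12))
print(f"\nretained {len(result.selected)} of {len(cards)} traits; "
      f"dropped as redundant: {result.dropped_for_redundancy}")
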