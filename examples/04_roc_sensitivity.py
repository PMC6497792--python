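"""ROC sensitivity of each trait for detecting drought stress.

The AUC is the probability that a stressed replicate can be told from a
non-stressed one by that trait alone (midrank Mann-Whitney statistic,
orientation chosen per trait from the mean shift).  Traits near 1 are
near-perfect stress detectors; traits near 0.5 carry no signal.
"""

import phenoscreen as ps

table = ps.simulate_population(ps.default_catalogue(), seed=42)
aucs = ps.auc_table(table).sort_values("auc", ascending=False)
print(aucs[["auc", "orientation"]].round(3), "\n")

categories = {
    "soil_moisture": ["volumetric_water_content", "electrical_conductivity",
                      "soil_temperature"],
    "yield_components": ["tiller_number", "total_spike_number",
                         "number_of_productive_tillers", "spike_weight",
                         "grain_number", "grain_weight"],
    "photosynthetic": ["photosystem_ii", "leaf_temperature", "chlorophyll_content"],
}
print(ps.category_auc_table(table, categories, method="pc1").round(3))
print("\nCategory AUC scores the first principal component of the member traits.")
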