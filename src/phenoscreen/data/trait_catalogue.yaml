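# Default trait catalogue for the synthetic drought-phenotyping population.
#
# One entry per trait of the 24-trait screen: population mean +/- SD under
# each watering regime (non-stressed ns, stressed s) for a 16-genotype,
# 2-environment, 3-replicate spring-wheat design.  The generator splits the
# pooled squared SD into genetic / genotype-by-environment / residual
# variance with the ratios below (see docs/methods.md).
#
# bounds: [min, max] applied after noise (null = unbounded on that side);
# integer: true rounds to whole scores (ordinal 1-10 rating scales).
variance_split:
  genetic: 0.5
  gxe: 0.1
  residual: 0.4
traits:
  - {trait: volumetric_water_content, unit: "%", mu_ns: 19.49, sd_ns: 3.47, mu_s: 0.16, sd_s: 0.94, bounds: [0.0, null]}
  - {trait: electrical_conductivity, unit: "dS/m", mu_ns: 0.7, sd_ns: 0.89, mu_s: 0.0002, sd_s: 0.0014, bounds: [0.0, null]}
  - {trait: soil_temperature, unit: "degC", mu_ns: 28.22, sd_ns: 2.94, mu_s: 28.34, sd_s: 1.98}
  - {trait: relative_water_content, unit: "%", mu_ns: 92.76, sd_ns: 16.75, mu_s: 25.41, sd_s: 12.95, bounds: [0.0, 100.0]}
  - {trait: photosystem_ii, unit: "Fv/Fm", mu_ns: 0.48, sd_ns: 0.19, mu_s: 0.41, sd_s: 0.22, bounds: [0.0, 1.0]}
  - {trait: leaf_temperature, unit: "degC", mu_ns: 28.66, sd_ns: 1.79, mu_s: 29.40, sd_s: 1.36}
  - {trait: chlorophyll_content, unit: "CCI", mu_ns: 14.89, sd_ns: 7.73, mu_s: 7.60, sd_s: 5.43, bounds: [0.0, null]}
  - {trait: peroxisome_abundance, unit: "AU/mg", mu_ns: 123.31, sd_ns: 80.52, mu_s: 306.41, sd_s: 240.61, bounds: [0.0, null]}
  - {trait: plant_height, unit: "cm", mu_ns: 55.12, sd_ns: 15.22, mu_s: 41.42, sd_s: 25.44, bounds: [0.0, null]}
  - {trait: peduncle_length, unit: "cm", mu_ns: 23.13, sd_ns: 7.57, mu_s: 15.49, sd_s: 10.51, bounds: [0.0, null]}
  - {trait: awn_length, unit: "cm", mu_ns: 5.61, sd_ns: 2.60, mu_s: 3.79, sd_s: 2.74, bounds: [0.0, null]}
  - {trait: root_dry_weight, unit: "g", mu_ns: 0.69, sd_ns: 0.28, mu_s: 0.37, sd_s: 0.28, bounds: [0.0, null]}
  - {trait: total_root_length, unit: "cm", mu_ns: 377.33, sd_ns: 172.17, mu_s: 231.89, sd_s: 135.58, bounds: [0.0, null]}
  - {trait: survival_rate, unit: "score 1-10", mu_ns: 10.0, sd_ns: 0.0, mu_s: 6.37, sd_s: 1.61, bounds: [1.0, 10.0], integer: true}
  - {trait: recovery_rate, unit: "score 1-10", mu_ns: 10.0, sd_ns: 0.0, mu_s: 5.75, sd_s: 2.79, bounds: [1.0, 10.0], integer: true}
  - {trait: days_to_heading, unit: "days", mu_ns: 44.75, sd_ns: 6.12, mu_s: 47.82, sd_s: 6.90, bounds: [0.0, null]}
  - {trait: relative_plant_dry_weight, unit: "g", mu_ns: 18.71, sd_ns: 8.88, mu_s: 6.80, sd_s: 8.85, bounds: [0.0, null]}
  - {trait: standing_biomass, unit: "AU", mu_ns: 11.06, sd_ns: 5.64, mu_s: 4.20, sd_s: 5.32, bounds: [0.0, null]}
  # Tiller-count means are not reliably reported for this design; a count
  # consistent with the spike-number scale and the 61.58% reduction is used.
  - {trait: tiller_number, unit: "count", mu_ns: 12.0, sd_ns: 4.5, mu_s: 4.61, sd_s: 4.6, bounds: [0.0, null]}
  - {trait: total_spike_number, unit: "count", mu_ns: 11.52, sd_ns: 4.48, mu_s: 4.37, sd_s: 4.61, bounds: [0.0, null]}
  - {trait: number_of_productive_tillers, unit: "count", mu_ns: 10.35, sd_ns: 4.11, mu_s: 3.89, sd_s: 4.58, bounds: [0.0, null]}
  - {trait: spike_weight, unit: "g", mu_ns: 11.33, sd_ns: 6.28, mu_s: 3.74, sd_s: 5.11, bounds: [0.0, null]}
  - {trait: grain_number, unit: "count", mu_ns: 245.44, sd_ns: 131.56, mu_s: 95.85, sd_s: 130.88, bounds: [0.0, null]}
  - {trait: grain_weight, unit: "g", mu_ns: 8.29, sd_ns: 4.52, mu_s: 2.71, sd_s: 3.65, bounds: [0.0, null]}
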