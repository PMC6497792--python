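"""2^-ddCt expression fold changes of the peroxisome-biogenesis genes.

Simulates raw Ct values for the seven-gene panel (three PEX11 paralogues,
FIS1A and three dynamin-related proteins) in a tolerant and a susceptible
genotype at days 3, 8 and 14 of drought, then recovers fold changes with
the comparative-Ct method: technical replicates averaged on the Ct scale,
biological replicates on the dCt scale, each stressed cell normalized to
actin and to its genotype-matched non-stressed calibrator.
"""

import phenoscreen as ps

true_folds = ps.default_gene_folds()
qpcr = ps.simulate_qpcr(true_folds, ct_base=25.0, sd_tech=0.15, sd_bio=0.1, seed=42)
print(f"simulated {len(qpcr)} Ct measurements "
      f"({qpcr['gene'].nunique()} genes incl. actin)\n")

folds = ps.expression_matrix(qpcr, housekeeping="actin")
for day in (3, 8, 14):
    print(f"day {day} fold-change heatmap (rows: genotype x treatment):")
    print(ps.fold_change_heatmap(folds, day=day).round(2), "\n")
print("Non-stressed rows are 1 by construction; values > 1 are up-regulation.")
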