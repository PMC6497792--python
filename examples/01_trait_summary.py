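"""Per-trait stress-response summary of a simulated drought screen.

Simulates the default 16-genotype x 2-treatment x 3-replicate panel and
prints each trait's mean +/- SD per watering regime together with the
stress-response index: the percent change of the stressed mean relative
to the non-stressed mean.  Negative indices are stress-suppressed traits
(yield, water content); positive ones are stress-induced (peroxisome
abundance, leaf temperature).
"""

import phenoscreen as ps

table = ps.simulate_population(ps.default_catalogue(), g=16, s=2, r=3, seed=42)
summary = ps.trait_summary(table)

print(summary[["mean_non_stressed", "mean_stressed", "index"]].round(2))
print(
    f"\n{int((summary['index'] < 0).sum())} of {len(summary)} traits are "
    "suppressed under drought; the rest increase."
)
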