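"""Compositional analysis of cuticular-hydrocarbon profiles.

Simulates CHC relative-abundance profiles with a dominant sex effect and
a secondary evolution effect, then runs the CLR + PCA + two-way ANOVA
chain and prints the variance decomposition.
"""

import pandas as pd

import evoisol as ev

cfg = ev.SimConfig(seed=7)
profiles = ev.simulate_chc(cfg, n_samples_per_group=15)
table = ev.profiles_to_frame(profiles)

detected = ev.completeness_filter(table)   # compounds present in all samples
clr_vals = ev.clr(detected.to_numpy())
res = ev.pca(clr_vals)
print(f"PC1 explains {100 * res.variance_explained[0]:.1f}% of variance, "
      f"PC2 {100 * res.variance_explained[1]:.1f}%")

sex = table.index.get_level_values("sex").to_numpy()
grp = table.index.get_level_values("group").to_numpy()
anova = ev.anova_table(
    pd.DataFrame(clr_vals, index=table.index, columns=detected.columns),
    sex, grp, bh=True)
print(f"compounds with significant sex effect:        "
      f"{(anova['q_sex'] < 0.05).sum()}/{len(anova)}")
print(f"compounds with significant evolution effect:  "
      f"{(anova['q_evolution'] < 0.05).sum()}/{len(anova)}")
print(f"compounds with significant interaction:       "
      f"{(anova['q_interaction'] < 0.05).sum()}/{len(anova)}")

print("\nPC1 separates the sexes, PC2 ancestral from evolved samples; the"
      "\nabsence of interactions means both sexes evolved in parallel.")
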