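"""Postmating compatibility from a 3x3 diallel cross.

Simulates progeny counts with a 9% within-replicate advantage (5 vials
per cross), then contrasts within- vs between-replicate fitness with the
exact one-tailed Wilcoxon test, the design-respecting permutation test,
and the mid-parent comparison.
"""

import evoisol as ev

cfg = ev.SimConfig(seed=11, diallel_within_advantage=0.09)
sheet = ev.simulate_diallel(cfg, n_pops=3, n_vials=5)

means = ev.cross_type_means(sheet)
print(f"within-replicate mean progeny:  {means.within_mean:.1f}")
print(f"between-replicate mean progeny: {means.between_mean:.1f}")
print(f"between-cross deficit:          {-100 * means.deficit:.1f}%")

within = means.per_cross.query("sire_pop == dam_pop")["mean"].to_numpy()
between = means.per_cross.query("sire_pop != dam_pop")["mean"].to_numpy()
wil = ev.wilcoxon_one_tailed(within, between)
perm = ev.crossing_scheme_permutation(sheet, n_perm=10000)
print(f"one-tailed exact Wilcoxon p:    {wil.p:.4f}")
print(f"permutation p (84 labellings):  {perm:.4f}")

mid = ev.midparent_test(sheet)
pooled = mid[mid["cross"].str.contains("pooled")]
print(f"hybrid crosses above mid-parent expectation: "
      f"{int(pooled['exceeds'].sum())}/{len(pooled)}")

print("\nA positive deficit with hybrids at or below their mid-parent value"
      "\npoints to postmating incompatibility between evolved replicates."
      "\nAt 5 vials per cross the tests have modest power, so any single"
      "\nrun can land either side of significance; raise n_vials to see"
      "\nthe deficit converge to 1 - 1/1.09 ~ 8.3%.")
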