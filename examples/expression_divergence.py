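"""Detect genes whose expression diverged among evolved replicates.

Simulates NB counts for 10 evolved replicates plus ancestral samples,
with replicate-specific shifts confined to a designated reproduction
gene set, then runs CPM filtering, dispersion estimation, the
replicate-factor likelihood-ratio test, and per-replicate change calls.
"""

import evoisol as ev

cfg = ev.SimConfig(seed=11, n_genes=2000)
sim = ev.simulate_counts(cfg, n_samples_per_replicate=5)

filt = ev.cpm_filter(sim.matrix, threshold=0.1)
print(f"genes passing CPM > 0.1 in all samples: {len(filt.gene_ids)}"
      f" / {cfg.n_genes}")

disp = ev.estimate_dispersion(filt.evolved())
print(f"common NB dispersion (truth 0.2): {disp.common:.3f}")

div = ev.divergence_lrt(filt, disp, fdr=0.05)
repro = set(sim.reproduction_set.genes)
sig = set(div.significant_genes)
print(f"divergent genes at FDR 0.05: {div.n_significant}, of which "
      f"{len(sig & repro)} are in the reproduction set "
      f"({len(repro)} genes total)")

change = ev.per_replicate_change(filt, disp)
n_calls = int((change.direction.to_numpy() != "none").sum())
print(f"per-replicate change calls: {n_calls} "
      f"(gene, replicate) pairs")

print("\nDivergence concentrates in the reproduction set because the"
      "\ngenerator injects replicate-specific shifts only there —"
      "\ndifferent replicates recruit different genes.")
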