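"""Config-driven orchestration of the full synthetic-study pipeline.

``run`` chains simulate -> mating -> chc -> cross -> expression ->
heterogeneity -> enrich and writes one TSV per stage plus a
machine-readable JSON summary. Given the same seed the bundle is
byte-identical (no timestamps enter any output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chc, crosses, enrichment, expression, io, mating
from .config import SimConfig
from .heterogeneity import compare_gene_sets, direction_bias
from .simulate import (simulate_chc, simulate_choice_assay, simulate_counts,
                       simulate_diallel)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "evoisol_out"
    stages: list[str] = field(default_factory=lambda: ["all"])
    # study-scale knobs
    n_chc_samples_per_group: int = 15
    n_diallel_pops: int = 3
    n_diallel_vials: int = 5
    n_samples_per_replicate: int = 5
    assort_preference: float = 4.0   # ancestral-vs-evolved cages
    # analysis thresholds
    cpm_threshold: float = 0.1
    fdr: float = 0.05
    lfc_threshold: float = 1.0
    tissue_fold: float = 2.0
    zero_strategy: str = "multiplicative"
    n_boot: int = 1000
    n_random_sets: int = 1000
    n_perm: int = 10000
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self, **overrides) -> SimConfig:
        kw = {"seed": self.seed, **self.sim, **overrides}
        return SimConfig(**kw)


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns (and writes) the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    do = lambda s: "all" in stages or s in stages
    summary: dict = {"seed": config.seed}

    if do("mating") or do("all"):
        summary["mating"] = _stage_mating(config, out)
    if do("chc"):
        summary["chc"] = _stage_chc(config, out)
    if do("cross"):
        summary["cross"] = _stage_cross(config, out)
    if do("expression") or do("heterogeneity") or do("enrich"):
        expr_summary, change, repro_set, changes_tsv = _stage_expression(config, out)
        summary["expression"] = expr_summary
        if do("heterogeneity"):
            summary["heterogeneity"] = _stage_heterogeneity(
                config, out, change, repro_set)
        if do("enrich"):
            summary["enrichment"] = _stage_enrich(config, out, expr_summary,
                                                  repro_set)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
    return summary


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _stage_mating(config: PipelineConfig, out: Path) -> dict:
    res = {}
    for label, pref, stream in (("ancestral_vs_evolved",
                                 config.assort_preference, 10),
                                ("evolved_vs_evolved", 1.0, 11)):
        cfg = config.sim_config(preference=pref)
        table = simulate_choice_assay(cfg, rng=cfg.rng(stream))
        io.write_mating_table(table, out / f"mating_{label}.tsv")
        fisher = mating.fisher_exact_2x2(table)
        res[label] = {"yule_Y": mating.yules_index(table, "Y"),
                      "yule_Q": mating.yules_index(table, "Q"),
                      "fisher_p": fisher.p,
                      "odds_ratio": fisher.odds_ratio,
                      "n_pairs": table.total}
    return res


def _stage_chc(config: PipelineConfig, out: Path) -> dict:
    cfg = config.sim_config()
    profiles = simulate_chc(cfg, config.n_chc_samples_per_group)
    table = chc.profiles_to_frame(profiles)
    io.write_compositions(profiles, out / "chc_profiles.tsv")
    detected = chc.completeness_filter(table)
    clr_vals = chc.clr(detected.to_numpy(), zero_strategy=config.zero_strategy)
    res = chc.pca(clr_vals)
    sex = table.index.get_level_values("sex").to_numpy()
    grp = table.index.get_level_values("group").to_numpy()
    clr_df = pd.DataFrame(clr_vals, index=table.index, columns=detected.columns)
    anova = chc.anova_table(clr_df, sex, grp, bh=True)
    anova.to_csv(out / "chc_anova.tsv", sep="\t")
    pd.DataFrame(res.loadings[:, :3], index=detected.columns,
                 columns=["PC1", "PC2", "PC3"]).to_csv(
        out / "chc_loadings.tsv", sep="\t")
    pd.DataFrame(res.scores[:, :3], index=table.index.get_level_values(0),
                 columns=["PC1", "PC2", "PC3"]).to_csv(
        out / "chc_scores.tsv", sep="\t")
    return {"pc1_pct": 100 * float(res.variance_explained[0]),
            "pc2_pct": 100 * float(res.variance_explained[1]),
            "n_compounds": int(detected.shape[1]),
            "n_significant_interactions":
                int((anova["q_interaction"] < config.fdr).sum())}


def _stage_cross(config: PipelineConfig, out: Path) -> dict:
    cfg = config.sim_config()
    sheet = simulate_diallel(cfg, config.n_diallel_pops,
                             config.n_diallel_vials)
    io.write_diallel(sheet, out / "diallel.tsv")
    means = crosses.cross_type_means(sheet)
    means.per_cross.to_csv(out / "diallel_cross_means.tsv", sep="\t",
                           index=False)
    mid = crosses.midparent_test(sheet)
    mid.to_csv(out / "diallel_midparent.tsv", sep="\t", index=False)
    within = means.per_cross.query("sire_pop == dam_pop")["mean"].to_numpy()
    between = means.per_cross.query("sire_pop != dam_pop")["mean"].to_numpy()
    wil = crosses.wilcoxon_one_tailed(within, between)
    perm_p = crosses.crossing_scheme_permutation(
        sheet, n_perm=config.n_perm, rng=np.random.default_rng(config.seed))
    return {"within_mean": means.within_mean,
            "between_mean": means.between_mean,
            "deficit_pct": 100 * means.deficit,
            "wilcoxon_p": wil.p, "permutation_p": perm_p,
            "n_hybrid_exceed_midparent":
                int(mid.loc[mid["cross"].str.contains("pooled"),
                            "exceeds"].sum())}


def _stage_expression(config: PipelineConfig, out: Path):
    cfg = config.sim_config()
    sim = simulate_counts(cfg, config.n_samples_per_replicate)
    io.write_counts(sim.matrix, out / "counts.tsv", out / "sample_meta.tsv")
    io.write_gmt([sim.reproduction_set], out / "gene_sets.gmt")
    filtered = expression.cpm_filter(sim.matrix, config.cpm_threshold)
    disp = expression.estimate_dispersion(filtered.evolved())
    div = expression.divergence_lrt(filtered, disp, fdr=config.fdr)
    div.table.to_csv(out / "divergence.tsv", sep="\t", index=False)
    change = expression.per_replicate_change(
        filtered, disp, lfc_threshold=config.lfc_threshold, fdr=config.fdr)
    change.log2fc.to_csv(out / "per_replicate_log2fc.tsv", sep="\t")
    change.direction.to_csv(out / "per_replicate_direction.tsv", sep="\t")
    repro = set(sim.reproduction_set.genes)
    sig = set(div.significant_genes)
    summary = {"n_genes_filtered": len(filtered.gene_ids),
               "n_divergent": div.n_significant,
               "n_divergent_reproduction": len(sig & repro),
               "common_dispersion": disp.common}
    return summary, change, sim.reproduction_set, out / "per_replicate_log2fc.tsv"


def _stage_heterogeneity(config: PipelineConfig, out: Path,
                         change: expression.ChangeResult,
                         repro_set) -> dict:
    changes = change.log2fc
    comp = compare_gene_sets(
        changes, set(repro_set.genes), n_boot=config.n_boot,
        n_random=config.n_random_sets, focal_name="reproduction",
        rng=np.random.default_rng(config.seed + 1))
    pd.DataFrame({"set": list(comp.h_observed),
                  "H": list(comp.h_observed.values())}).to_csv(
        out / "heterogeneity.tsv", sep="\t", index=False)
    comp.bootstrap.to_csv(out / "heterogeneity_bootstrap.tsv", sep="\t",
                          index=False)
    bias = direction_bias(change.direction,
                                        set(repro_set.genes),
                                        set(changes.index))
    return {"H": comp.h_observed, "focal_quantile": comp.focal_quantile,
            "mw_p": comp.mw_p,
            "fraction_up": bias.fraction_up, "binom_p": bias.binom_p}


def _stage_enrich(config: PipelineConfig, out: Path, expr_summary: dict,
                  repro_set) -> dict:
    div = pd.read_csv(out / "divergence.tsv", sep="\t")
    universe = set(div["gene"])
    hits = set(div.loc[(div["q"] < config.fdr).fillna(False), "gene"])
    if not hits:
        return {"note": "no significant genes; enrichment skipped"}
    tab = enrichment.overrep_test(
        enrichment.GeneSet.of("divergent", hits),
        [enrichment.GeneSet.of(repro_set.name, repro_set.genes)], universe)
    tab.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    row = tab.iloc[0]
    return {"odds_ratio": float(row["odds_ratio"]), "p": float(row["p"]),
            "q": float(row["q"]), "overlap": int(row["overlap"])}
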