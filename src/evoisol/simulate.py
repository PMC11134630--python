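"""Synthetic data for all four study modalities.

Each generator emulates the statistical structure its downstream analysis
assumes, so parameter-recovery tests can run without any sequencing or
GC/MS data: a sequential mate-choice assay with a homotypic preference
weight, logistic-normal CHC compositions with sex and evolution shifts,
Poisson diallel progeny counts with a within-replicate advantage, and
NB-distributed RNA-seq counts where replicate-specific shifts are
concentrated in a designated "reproduction" gene set with an
up-regulation bias.

All randomness flows from ``SimConfig.seed`` through per-modality
substreams, so seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chc import CompositionProfile, closure
from .config import SimConfig
from .enrichment import GeneSet
from .expression import CountMatrix
from .mating import MatingCountTable

_STREAM = {"choice": 0, "chc": 1, "diallel": 2, "counts": 3}


def simulate_choice_assay(cfg: SimConfig, pops: tuple[str, str] = ("A", "B"),
                          rng: np.random.Generator | None = None
                          ) -> MatingCountTable:
    """One multiple-choice mating cage.

    Pair formation is sequential and without replacement: a free female
    is drawn uniformly, then a free male with weight ``preference`` if he
    is from her population and 1 otherwise. The assay stops after
    ``max_pairs`` pairs or when either sex is exhausted. The mechanism is
    deliberately simple — any exchangeable scheme with a single homotypic
    weight produces the same 2x2 count structure the mating statistics
    consume.
    """
    n = cfg.n_flies_per_pop_per_sex
    if n <= 0:
        raise ValueError("empty assay")
    rng = rng or cfg.rng(_STREAM["choice"])
    free_f = np.array([n, n], dtype=float)
    free_m = np.array([n, n], dtype=float)
    counts = np.zeros((2, 2), dtype=int)
    for _ in range(cfg.max_pairs):
        if free_f.sum() == 0 or free_m.sum() == 0:
            break
        f = rng.choice(2, p=free_f / free_f.sum())
        w = free_m.copy()
        w[f] *= cfg.preference
        m = rng.choice(2, p=w / w.sum())
        free_f[f] -= 1
        free_m[m] -= 1
        counts[f, m] += 1
    return MatingCountTable(pops=pops, counts=counts)


def simulate_chc(cfg: SimConfig, n_samples_per_group: int,
                 rng: np.random.Generator | None = None
                 ) -> list[CompositionProfile]:
    """Logistic-normal CHC profiles for the 2 (sex) x 2 (evolution) design.

    composition = closure(exp(base + sex_effect * 1[male] +
    evo_effect * 1[evolved] + noise)); every emitted vector sums to 1.
    """
    if cfg.n_compounds < 3:
        raise ValueError("need >= 3 compounds")
    rng = rng or cfg.rng(_STREAM["chc"])
    out = []
    for group in ("ancestral", "evolved"):
        for sex in ("female", "male"):
            for k in range(n_samples_per_group):
                logit = cfg.chc_base_log.copy()
                if sex == "male":
                    logit = logit + cfg.sex_effect
                if group == "evolved":
                    logit = logit + cfg.evo_effect
                logit = logit + rng.normal(0, cfg.chc_noise_sd,
                                           cfg.n_compounds)
                out.append(CompositionProfile(
                    sample_id=f"{group[:3]}_{sex[0]}{k+1}",
                    sex=sex, group=group, replicate=f"r{k % 5 + 1}",
                    abundances=closure(np.exp(logit))))
    return out


def simulate_diallel(cfg: SimConfig, n_pops: int = 3, n_vials: int = 5,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Full diallel progeny counts among evolved replicate populations.

    progeny ~ Poisson(diallel_mean * (1 + diallel_within_advantage)) for
    within-replicate crosses and Poisson(diallel_mean) for between-
    replicate ones, for every ordered (sire, dam) pair and vial.
    """
    if n_pops < 2:
        raise ValueError("need >= 2 populations for a diallel cross")
    rng = rng or cfg.rng(_STREAM["diallel"])
    pops = [f"R{i+1}" for i in range(n_pops)]
    rows = []
    for sire in pops:
        for dam in pops:
            mean = cfg.diallel_mean * (
                1 + cfg.diallel_within_advantage if sire == dam else 1)
            for v in range(n_vials):
                rows.append({"sire_pop": sire, "dam_pop": dam,
                             "vial_id": f"{sire}x{dam}_v{v+1}",
                             "progeny_count": int(rng.poisson(mean))})
    return pd.DataFrame(rows)


@dataclass
class SimulatedCounts:
    matrix: CountMatrix
    reproduction_set: GeneSet
    truth: pd.DataFrame   # gene, replicate, injected log2 fold-change


def simulate_counts(cfg: SimConfig, n_samples_per_replicate: int = 5,
                    n_ancestral_samples: int | None = None,
                    rng: np.random.Generator | None = None
                    ) -> SimulatedCounts:
    """NB-distributed gene x sample counts for ancestral + evolved samples.

    Every gene carries a shared adaptive shift (log2FC ~ N(0,
    shared_lfc_sd)) applied to all evolved samples. Genes in the
    designated reproduction set additionally receive replicate-specific
    shifts: per gene, 1 or 2 replicates (uniform) are perturbed by a
    log2FC of magnitude replicate_lfc_sd * (1 + half-normal(sd = 0.5)),
    positive with probability ``up_bias``. Counts ~ NB(mean,
    phi = nb_dispersion) with log-normal library sizes.
    """
    if not isinstance(cfg.n_genes, (int, np.integer)):
        raise ValueError("n_genes must be an integer")
    rng = rng or cfg.rng(_STREAM["counts"])
    g, r = cfg.n_genes, cfg.n_replicates
    n_anc = n_ancestral_samples or n_samples_per_replicate
    genes = [f"g{i+1}" for i in range(g)]
    n_repro = max(1, int(round(cfg.frac_reproduction_genes * g)))
    repro_idx = rng.choice(g, size=n_repro, replace=False)
    repro_set = GeneSet.of("reproduction", [genes[i] for i in repro_idx])

    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean,
                                 cfg.baseline_log2_sd, size=g)
    shared = rng.normal(0, cfg.shared_lfc_sd, size=g)
    rep_lfc = np.zeros((g, r))
    truth_rows = []
    for gi in repro_idx:
        k = rng.integers(1, 3)   # 1 or 2 affected replicates
        hit = rng.choice(r, size=k, replace=False)
        for ri in hit:
            sign = 1.0 if rng.random() < cfg.up_bias else -1.0
            # magnitude bounded away from 0: a replicate-specific "change"
            # of log2FC ~ 0 would be no change at all
            lfc = sign * cfg.replicate_lfc_sd * (1 + 0.5 * abs(rng.normal()))
            rep_lfc[gi, ri] = lfc
            truth_rows.append({"gene": genes[gi], "replicate": f"R{ri+1}",
                               "log2fc": lfc})

    sample_ids, reps, groups = [], [], []
    for a in range(n_anc):
        sample_ids.append(f"anc_s{a+1}")
        reps.append("anc")
        groups.append("ancestral")
    for ri in range(r):
        for s in range(n_samples_per_replicate):
            sample_ids.append(f"R{ri+1}_s{s+1}")
            reps.append(f"R{ri+1}")
            groups.append("evolved")
    n_samples = len(sample_ids)
    lib = cfg.library_size * np.exp(
        rng.normal(0, cfg.library_size_log_sd, size=n_samples))

    log2fc = np.zeros((g, n_samples))
    for j, (rep, grp) in enumerate(zip(reps, groups)):
        if grp == "evolved":
            ri = int(rep[1:]) - 1
            log2fc[:, j] = shared + rep_lfc[:, ri]
    mean = baseline[:, None] * 2.0 ** log2fc * (lib / cfg.library_size)[None, :]
    if cfg.nb_dispersion < 1e-12:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / cfg.nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mean / shape))
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        library_sizes=pd.Series(lib, index=sample_ids),
        sample_meta=pd.DataFrame({"replicate": reps, "group": groups},
                                 index=sample_ids))
    return SimulatedCounts(matrix=matrix, reproduction_set=repro_set,
                           truth=pd.DataFrame(
                               truth_rows, columns=["gene", "replicate",
                                                    "log2fc"]))
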