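"""Replicate-heterogeneity of expression evolution.

For a gene set, let x_i be the vector of per-gene expression changes in
evolved replicate i. The heterogeneity statistic averages the pairwise
correlation distance over replicate pairs:

    H = sum_{i<j} (1 - cor(x_i, x_j)) / N,   N = C(R, 2)

H = 0 when every replicate changed the same genes the same way; H = 2
when replicates are perfectly anti-correlated. Gene sets whose members
respond in replicate-specific fashion (different replicates recruiting
different genes) score high relative to size-matched random sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from .chc import PCAResult, pca


@dataclass
class HeterogeneityResult:
    gene_set: str
    h: float
    pair_correlations: pd.Series   # indexed by (replicate_i, replicate_j)
    n_pairs: int                   # unordered pairs entering the average
    n_genes: int


def heterogeneity(changes: pd.DataFrame, gene_set: set[str] | None = None,
                  name: str = "set", method: str = "pearson"
                  ) -> HeterogeneityResult:
    """Compute H on a genes x replicates change matrix, optionally
    restricted to a gene set.

    Pairs involving a zero-variance replicate vector have undefined
    correlation; such pairs are dropped with a warning and N reduced.
    """
    if gene_set is not None:
        genes = [g for g in changes.index if g in gene_set]
        if len(genes) < 3:
            raise ValueError("gene set must overlap >= 3 genes")
        changes = changes.loc[genes]
    reps = list(changes.columns)
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates")
    x = changes.to_numpy(dtype=float)
    if method == "spearman":
        x = sps.rankdata(x, axis=0)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = x.std(axis=0)
    cors = {}
    dropped = 0
    for i, j in itertools.combinations(range(len(reps)), 2):
        if sd[i] == 0 or sd[j] == 0:
            dropped += 1
            continue
        cors[(reps[i], reps[j])] = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
    if dropped:
        warnings.warn(f"{dropped} replicate pair(s) dropped "
                      "(zero-variance change vector)")
    if not cors:
        raise ValueError("all replicate pairs degenerate")
    pair_cor = pd.Series(cors)
    h = float((1 - pair_cor).sum() / len(pair_cor))
    return HeterogeneityResult(gene_set=name, h=h, pair_correlations=pair_cor,
                               n_pairs=len(pair_cor), n_genes=changes.shape[0])


@dataclass
class GeneSetComparison:
    h_observed: dict                 # set name -> H
    bootstrap: pd.DataFrame          # n_boot x sets, gene-resampled H
    random_set_h: np.ndarray         # H of size-matched random background sets
    focal_quantile: float            # of focal H among random sets
    mw_p: dict                       # focal-vs-set Mann-Whitney on bootstraps


def compare_gene_sets(changes: pd.DataFrame, focal_set: set[str],
                      background_sets: dict[str, set[str]] | None = None,
                      n_boot: int = 1000, n_random: int = 1000,
                      focal_name: str = "focal",
                      rng: np.random.Generator | None = None
                      ) -> GeneSetComparison:
    """Contrast a focal gene set's heterogeneity against background sets.

    Per set, H is bootstrapped by resampling member genes with
    replacement (``n_boot`` draws). Additionally ``n_random`` random sets
    of the focal size are drawn from the background (all genes in
    ``changes``) without replacement; the focal H's empirical quantile
    among their H values is the primary calibrated comparison. The
    Mann-Whitney test between bootstrap distributions is reported as a
    secondary, resampling-based contrast.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 (bootstrap distributions "
                         "are degenerate otherwise)")
    focal = [g for g in changes.index if g in focal_set]
    if len(focal) < 3:
        raise ValueError("focal set must overlap >= 3 genes")
    rng = rng or np.random.default_rng()
    sets = {focal_name: focal}
    for nm, s in (background_sets or {}).items():
        sets[nm] = [g for g in changes.index if g in s]
    sets.setdefault("background", list(changes.index))

    h_obs = {nm: heterogeneity(changes.loc[genes], name=nm).h
             for nm, genes in sets.items()}
    boot = {}
    for nm, genes in sets.items():
        draws = np.empty(n_boot)
        sub = changes.loc[genes].to_numpy(dtype=float)
        for b in range(n_boot):
            idx = rng.integers(0, len(genes), size=len(genes))
            draws[b] = _h_of_matrix(sub[idx])
        boot[nm] = draws
    boot = pd.DataFrame(boot)

    all_genes = changes.to_numpy(dtype=float)
    k = len(focal)
    rand_h = np.empty(n_random)
    for b in range(n_random):
        idx = rng.choice(all_genes.shape[0], size=k, replace=False)
        rand_h[b] = _h_of_matrix(all_genes[idx])
    quant = float(np.mean(rand_h < h_obs[focal_name]))
    mw = {nm: float(sps.mannwhitneyu(boot[focal_name], boot[nm],
                                     alternative="greater").pvalue)
          for nm in sets if nm != focal_name}
    return GeneSetComparison(h_observed=h_obs, bootstrap=boot,
                             random_set_h=rand_h, focal_quantile=quant,
                             mw_p=mw)


def _h_of_matrix(x: np.ndarray) -> float:
    """H of a genes x replicates array; degenerate pairs dropped silently
    (resampling internals)."""
    sd = x.std(axis=0)
    ok = np.flatnonzero(sd > 0)
    if len(ok) < 2:
        return float("nan")
    c = np.corrcoef(x[:, ok], rowvar=False)
    iu = np.triu_indices(len(ok), 1)
    return float((1 - c[iu]).mean())


@dataclass
class SubsetPCA:
    pca: PCAResult
    sample_labels: pd.DataFrame
    silhouette: float | None       # replicate-label separation of scores


def subset_pca(expr: pd.DataFrame, gene_set: set[str],
               sample_meta: pd.DataFrame, n_components: int = 3
               ) -> SubsetPCA:
    """PCA of samples over a gene subset (genes x samples input).

    Scores summarize how samples spread in the subset's expression space;
    the silhouette of replicate labels on the leading components reports
    whether particular replicates separate from the rest.
    """
    genes = [g for g in expr.index if g in gene_set]
    if len(genes) < 2:
        raise ValueError("gene set must overlap >= 2 genes")
    res = pca(expr.loc[genes].to_numpy(dtype=float).T)
    sil = None
    labels = sample_meta["replicate"].to_numpy()
    if len(set(labels)) >= 2 and not res.degenerate:
        k = min(n_components, res.scores.shape[1])
        sil = float(silhouette_score(res.scores[:, :k], labels))
    return SubsetPCA(pca=res, sample_labels=sample_meta.copy(), silhouette=sil)


@dataclass
class DirectionBias:
    fraction_up: float
    n_up: int
    n_down: int
    binom_p: float                 # exact two-sided vs 0.5
    fisher_p: float | None         # up/down x focal/background
    fisher_or: float | None


def direction_bias(direction: pd.DataFrame, focal_set: set[str],
                   background_set: set[str] | None = None) -> DirectionBias:
    """Up-regulation bias of "changed" calls within a gene set.

    Counts every (gene, replicate) changed call in the focal set, tests
    the up-fraction against 0.5 with an exact binomial test, and, when a
    background set is given, contrasts the up/down split between sets
    with Fisher's exact test.
    """
    def updown(genes: list[str]) -> tuple[int, int]:
        sub = direction.loc[genes].to_numpy()
        return int((sub == "up").sum()), int((sub == "down").sum())

    focal = [g for g in direction.index if g in focal_set]
    if not focal:
        raise ValueError("focal set overlaps no genes")
    n_up, n_down = updown(focal)
    n = n_up + n_down
    if n == 0:
        raise ValueError("no changed calls in focal set")
    binom_p = float(sps.binomtest(n_up, n, 0.5).pvalue)
    fisher_p = fisher_or = None
    if background_set is not None:
        bg = [g for g in direction.index
              if g in background_set and g not in focal_set]
        b_up, b_down = updown(bg)
        res = sps.fisher_exact([[n_up, n_down], [b_up, b_down]])
        fisher_or, fisher_p = float(res.statistic), float(res.pvalue)
    return DirectionBias(fraction_up=n_up / n, n_up=n_up, n_down=n_down,
                         binom_p=binom_p, fisher_p=fisher_p,
                         fisher_or=fisher_or)
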