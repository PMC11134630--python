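"""Replicate-divergence analysis of RNA-seq counts.

The question is not "evolved vs ancestral" but "do evolved replicate
populations differ from one another": per gene, a negative-binomial GLM
with a log link and library-size offsets is fitted with the replicate as
the only factor (Y = repl + error) and compared against an
intercept-only null by a likelihood-ratio test on k-1 df, followed by
Benjamini-Hochberg FDR control. The NB is parameterized by mean and
dispersion, Var = mu + phi * mu^2.

All model fits are closed over a one-factor design, which lets the Newton
solver run vectorized across genes; there is no per-gene Python-level
model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .stats import bh_adjust


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``replicate``
    (replicate label, or "anc" for ancestral samples) and ``group``
    ("ancestral" | "evolved").
    """
    counts: pd.DataFrame
    library_sizes: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        if list(self.library_sizes.index) != samples or \
                list(self.sample_meta.index) != samples:
            raise ValueError("library_sizes/sample_meta must match counts columns")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def cpm(self) -> pd.DataFrame:
        return self.counts / self.library_sizes * 1e6

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        cols = self.counts.columns[mask]
        return CountMatrix(self.counts[cols], self.library_sizes[cols],
                           self.sample_meta.loc[cols])

    def evolved(self) -> "CountMatrix":
        return self.subset_samples((self.sample_meta["group"] == "evolved").to_numpy())


def cpm_filter(m: CountMatrix, threshold: float = 0.1) -> CountMatrix:
    """Keep genes whose CPM exceeds ``threshold`` in every sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (m.cpm() > threshold).all(axis=1)
    return CountMatrix(m.counts.loc[keep], m.library_sizes, m.sample_meta)


# ----------------------------------------------------------------------
# vectorized NB GLM for a one-factor design

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB log-likelihood; mu = 0 cells contribute 0 iff y = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(np.broadcast(y, mu).shape)
    pos = mu > 0
    yp, mp = np.broadcast_to(y, out.shape)[pos], np.broadcast_to(mu, out.shape)[pos]
    if phi < 1e-12:
        out[pos] = yp * np.log(mp) - mp - special.gammaln(yp + 1)
    else:
        r = 1.0 / phi
        out[pos] = (special.gammaln(yp + r) - special.gammaln(r)
                    - special.gammaln(yp + 1)
                    + r * np.log(r / (r + mp)) + yp * np.log(mp / (r + mp)))
    return out


def _fit_group_means(y: np.ndarray, lib: np.ndarray, groups: np.ndarray,
                     phi: float, tol: float = 1e-10, max_iter: int = 50
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of per-group rates for an NB log-link model with offsets.

    y : genes x samples, lib : per-sample library sizes, groups : integer
    group label per sample. Returns (mu, rate, converged) where ``rate``
    is genes x n_groups (expected count at unit library size) and ``mu``
    the fitted genes x samples means. Newton iterations are vectorized
    over genes; for phi = 0 the solution is the closed-form weighted mean.
    """
    y = np.asarray(y, dtype=float)
    lib = np.asarray(lib, dtype=float)
    n_genes = y.shape[0]
    labels = np.unique(groups)
    rate = np.zeros((n_genes, len(labels)))
    converged = np.ones(n_genes, dtype=bool)
    for gi, lab in enumerate(labels):
        cols = np.flatnonzero(groups == lab)
        ysub, lsub = y[:, cols], lib[cols]
        m = ysub.sum(axis=1) / lsub.sum()          # Poisson MLE, Newton init
        if phi >= 1e-12:
            active = m > 0
            beta = np.log(np.where(active, m, 1.0))
            for _ in range(max_iter):
                mu = np.exp(beta)[:, None] * lsub[None, :]
                score = ((ysub - mu) / (1 + phi * mu)).sum(axis=1)
                info = (mu * (1 + phi * ysub) / (1 + phi * mu) ** 2).sum(axis=1)
                step = np.where(active & (info > 0), score / np.maximum(info, 1e-300), 0.0)
                step = np.clip(step, -5, 5)
                beta = beta + step
                if np.max(np.abs(step)) < tol:
                    break
            else:
                converged &= np.abs(step) < 1e-4
            m = np.where(active, np.exp(beta), 0.0)
        rate[:, gi] = m
    group_idx = np.searchsorted(labels, groups)
    mu = rate[:, group_idx] * lib[None, :]
    return mu, rate, converged


def _loglik_onefactor(y: np.ndarray, lib: np.ndarray, groups: np.ndarray,
                      phi: float) -> tuple[np.ndarray, np.ndarray]:
    mu, _, conv = _fit_group_means(y, lib, groups, phi)
    return nb_loglik(y, mu, phi).sum(axis=1), conv


# ----------------------------------------------------------------------
# dispersion estimation

@dataclass
class DispersionEstimate:
    common: float                 # phi_0
    per_gene: np.ndarray          # moment estimates
    shrunken: np.ndarray          # EB-weighted toward phi_0
    prior_df: float


def estimate_dispersion(m: CountMatrix, prior_df: float = 10.0,
                        groups: np.ndarray | None = None) -> DispersionEstimate:
    """Common and per-gene NB dispersions under the one-factor design.

    The common dispersion phi_0 maximizes the Cox-Reid adjusted profile
    likelihood pooled over genes: the plain profile likelihood (group
    means refitted at each candidate phi) is penalized by half the
    log-determinant of the observed information of the mean parameters,
    which removes the downward bias of plugging fitted means into the
    likelihood. Per-gene moment estimates
    phi_g = mean[((y - mu)^2 - mu)/mu^2] (df-adjusted, clipped at 0) are
    shrunk toward phi_0 with empirical-Bayes weights
    (prior_df * phi_0 + df_g * phi_g) / (prior_df + df_g).
    Genes with fewer than 2 residual df fall back to phi_0.
    """
    y = m.counts.to_numpy(dtype=float)
    lib = m.library_sizes.to_numpy(dtype=float)
    if groups is None:
        groups = m.sample_meta["replicate"].to_numpy()
    _, labels_inv = np.unique(groups, return_inverse=True)
    n_groups = labels_inv.max() + 1
    df_res = y.shape[1] - n_groups
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        mu, _, _ = _fit_group_means(y, lib, labels_inv, phi)
        ll = nb_loglik(y, mu, phi).sum()
        penalty = 0.0
        for g in range(n_groups):
            cols = labels_inv == g
            mus = mu[:, cols]
            info = (mus * (1 + phi * y[:, cols])
                    / (1 + phi * mus) ** 2).sum(axis=1)
            penalty += 0.5 * np.log(np.maximum(info, 1e-300)).sum()
        return -(ll - penalty)

    res = optimize.minimize_scalar(neg_apl, bounds=(np.log(1e-6), np.log(50)),
                                   method="bounded",
                                   options={"xatol": 1e-3})
    phi0 = float(np.exp(res.x))
    if phi0 < 2e-6:   # boundary: effectively Poisson
        phi0 = 0.0

    mu, _, _ = _fit_group_means(y, lib, labels_inv, phi0)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(mu > 0, ((y - mu) ** 2 - mu) / mu ** 2, 0.0)
    per_gene = np.maximum(contrib.sum(axis=1) / df_res, 0.0)
    if df_res < 2:
        per_gene = np.full(y.shape[0], phi0)
    shrunken = (prior_df * phi0 + df_res * per_gene) / (prior_df + df_res)
    return DispersionEstimate(common=phi0, per_gene=per_gene,
                              shrunken=shrunken, prior_df=prior_df)


# ----------------------------------------------------------------------
# divergence LRT and per-replicate attribution

@dataclass
class DivergenceResult:
    table: pd.DataFrame           # gene, lrt, df, p, q, converged
    n_significant: int
    fdr: float

    @property
    def significant_genes(self) -> list[str]:
        t = self.table
        return list(t.loc[(t["q"] < self.fdr).fillna(False), "gene"])


def divergence_lrt(m: CountMatrix, dispersion: float | DispersionEstimate
                   | None = None, fdr: float = 0.05) -> DivergenceResult:
    """LRT for expression divergence among evolved replicates.

    Only evolved samples enter the test. Full model: one NB mean per
    replicate (log link, library-size offsets); null: a single common
    mean. 2(l1 - l0) is referred to chi-square on k-1 df and BH-corrected
    across genes. Non-converged genes get p = NaN and are excluded from
    the FDR family.
    """
    ev = m.evolved()
    reps = ev.sample_meta["replicate"].to_numpy()
    labels = np.unique(reps)
    if len(labels) < 2:
        raise ValueError("need >= 2 replicates for the divergence test")
    counts_per_rep = pd.Series(reps).value_counts()
    if (counts_per_rep < 2).any():
        raise ValueError("need >= 2 samples per replicate")
    if dispersion is None:
        dispersion = estimate_dispersion(ev)
    phi = dispersion.common if isinstance(dispersion, DispersionEstimate) \
        else float(dispersion)
    y = ev.counts.to_numpy(dtype=float)
    lib = ev.library_sizes.to_numpy(dtype=float)
    _, inv = np.unique(reps, return_inverse=True)
    ll_full, conv_full = _loglik_onefactor(y, lib, inv, phi)
    ll_null, conv_null = _loglik_onefactor(y, lib, np.zeros_like(inv), phi)
    conv = conv_full & conv_null
    lrt = np.maximum(2 * (ll_full - ll_null), 0.0)
    df = len(labels) - 1
    p = stats.chi2.sf(lrt, df)
    p[~conv] = np.nan
    q = bh_adjust(p)
    tab = pd.DataFrame({"gene": ev.gene_ids, "lrt": lrt, "df": df,
                        "p": p, "q": q, "converged": conv})
    return DivergenceResult(table=tab, fdr=fdr,
                            n_significant=int((tab["q"] < fdr).sum()))


@dataclass
class ChangeResult:
    log2fc: pd.DataFrame          # genes x replicates, vs ancestral mean
    direction: pd.DataFrame       # "up" | "down" | "none"
    p: pd.DataFrame               # replicate-vs-rest LRT p
    q: pd.DataFrame               # BH over the genes x replicates family
    lfc_threshold: float
    fdr: float


def per_replicate_change(m: CountMatrix,
                         dispersion: float | DispersionEstimate | None = None,
                         lfc_threshold: float = 1.0,
                         pseudocount: float = 0.5,
                         fdr: float = 0.05) -> ChangeResult:
    """Per-replicate log2 fold-changes against the ancestral mean, with
    "changed" calls.

    log2FC = log2((mean evolved-replicate CPM + c) / (mean ancestral CPM
    + c)) with pseudo-count c (CPM units). A replicate's change call for
    a gene requires (i) |log2FC| > ``lfc_threshold``, (ii) a significant
    replicate-vs-rest NB contrast among evolved samples (1-df LRT,
    BH-corrected over the whole genes x replicates family at ``fdr``),
    and (iii) a replicate-specific deviation — the replicate's log2FC
    minus the median log2FC of the other replicates — that itself
    exceeds the threshold with the same sign as the ancestral-referenced
    log2FC. Condition (iii) stops attribution leakage: a strong shift in
    one replicate contaminates any mean-based "rest" reference and would
    otherwise let other replicates inherit calls they did not earn; the
    median of the remaining replicates is robust to 1-2 shifted ones.
    """
    anc = m.sample_meta["group"] == "ancestral"
    if not anc.any():
        raise ValueError("no ancestral samples")
    cpm = m.cpm()
    anc_mean = cpm.loc[:, anc.to_numpy()].mean(axis=1)
    ev = m.evolved()
    reps = ev.sample_meta["replicate"].to_numpy()
    labels = list(np.unique(reps))
    if dispersion is None:
        dispersion = estimate_dispersion(ev)
    phi = dispersion.common if isinstance(dispersion, DispersionEstimate) \
        else float(dispersion)
    y = ev.counts.to_numpy(dtype=float)
    lib = ev.library_sizes.to_numpy(dtype=float)
    ll_null, _ = _loglik_onefactor(y, lib, np.zeros(y.shape[1], dtype=int), phi)
    lfc = {}
    pmat = {}
    ev_cpm = ev.cpm()
    for lab in labels:
        mask = reps == lab
        rep_mean = ev_cpm.loc[:, mask].mean(axis=1)
        lfc[lab] = np.log2((rep_mean + pseudocount) / (anc_mean + pseudocount))
        ll_two, _ = _loglik_onefactor(y, lib, mask.astype(int), phi)
        lrt = np.maximum(2 * (ll_two - ll_null), 0.0)
        pmat[lab] = stats.chi2.sf(lrt, 1)
    lfc = pd.DataFrame(lfc, index=m.gene_ids)
    # replicate-specific deviation: each replicate's lfc minus the
    # median lfc of the other replicates (robust rest reference)
    deviation = lfc.copy()
    vals = lfc.to_numpy()
    if vals.shape[1] > 1:
        for j in range(vals.shape[1]):
            others = np.delete(vals, j, axis=1)
            deviation.iloc[:, j] = vals[:, j] - np.median(others, axis=1)
    p = pd.DataFrame(pmat, index=m.gene_ids)
    q = pd.DataFrame(
        bh_adjust(p.to_numpy().ravel()).reshape(p.shape),
        index=p.index, columns=p.columns)
    changed = ((lfc.abs() > lfc_threshold) & (q < fdr)
               & (deviation.abs() > lfc_threshold)
               & (np.sign(deviation) == np.sign(lfc)))
    direction = pd.DataFrame(
        np.where(changed, np.where(lfc > 0, "up", "down"), "none"),
        index=lfc.index, columns=lfc.columns)
    return ChangeResult(log2fc=lfc, direction=direction, p=p, q=q,
                        lfc_threshold=lfc_threshold, fdr=fdr)
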