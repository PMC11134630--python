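"""Postmating compatibility from a full diallel cross.

Within- vs between-replicate progeny counts, mid-parent expectations for
each hybrid cross, an exact one-tailed Wilcoxon rank-sum test, and a
design-respecting permutation test that plays the inferential role of the
mixed-model sanity check (is the within/between contrast larger than
expected for an arbitrary 3-within / 6-between labelling of cross types?).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

DIALLEL_COLUMNS = ["sire_pop", "dam_pop", "vial_id", "progeny_count"]


def validate_diallel(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sheet covers the full factorial design with nonnegative
    counts. Counts may be non-integer (vials are averaged over transfers)."""
    missing = [c for c in DIALLEL_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"diallel sheet missing columns {missing}")
    if (sheet["progeny_count"] < 0).any():
        raise ValueError("progeny_count must be nonnegative")
    pops = sorted(set(sheet["sire_pop"]) | set(sheet["dam_pop"]))
    seen = set(zip(sheet["sire_pop"], sheet["dam_pop"]))
    for s, d in itertools.product(pops, pops):
        if (s, d) not in seen:
            raise ValueError(f"missing cross type {s} x {d}")
    return sheet


@dataclass
class CrossMeans:
    per_cross: pd.DataFrame     # sire_pop, dam_pop, mean, n_vials
    within_mean: float
    between_mean: float
    deficit: float              # (between - within) / within; negative = cost


def cross_type_means(sheet: pd.DataFrame) -> CrossMeans:
    """Mean viable progeny per (sire, dam) cross type, pooled within- and
    between-replicate means, and the relative between-cross deficit."""
    validate_diallel(sheet)
    per = (sheet.groupby(["sire_pop", "dam_pop"])["progeny_count"]
           .agg(mean="mean", n_vials="size").reset_index())
    within = sheet["sire_pop"] == sheet["dam_pop"]
    wmean = float(sheet.loc[within, "progeny_count"].mean())
    bmean = float(sheet.loc[~within, "progeny_count"].mean())
    return CrossMeans(per_cross=per, within_mean=wmean, between_mean=bmean,
                      deficit=(bmean - wmean) / wmean)


def midparent_test(sheet: pd.DataFrame) -> pd.DataFrame:
    """Observed hybrid means against the mid-parent expectation.

    For every unordered population pair {A, B}, midparent =
    (mean(AxA) + mean(BxB)) / 2; the two reciprocal crosses are reported
    separately and pooled. ``exceeds`` flags a hybrid mean above its
    mid-parent expectation (heterosis); the study's pattern is that none do.
    """
    validate_diallel(sheet)
    per = sheet.groupby(["sire_pop", "dam_pop"])["progeny_count"].mean()
    pops = sorted(set(sheet["sire_pop"]))
    rows = []
    for a, b in itertools.combinations(pops, 2):
        for key in ((a, a), (b, b)):
            if key not in per.index:
                raise ValueError(f"absent parental cross {key[0]} x {key[0]}")
        mid = (per[(a, a)] + per[(b, b)]) / 2
        recip = {f"{a}x{b}": per[(a, b)], f"{b}x{a}": per[(b, a)]}
        pooled = float(np.mean(list(recip.values())))
        for label, obs in [*recip.items(), (f"{a}|{b} pooled", pooled)]:
            rows.append({"cross": label, "observed_mean": float(obs),
                         "midparent": float(mid),
                         "exceeds": bool(obs > mid)})
    return pd.DataFrame(rows)


@dataclass
class WilcoxonResult:
    w: float            # rank sum of the first sample (midranks)
    p: float
    exact: bool
    degenerate: bool = False


def wilcoxon_one_tailed(within: np.ndarray, between: np.ndarray,
                        exact: bool | None = None,
                        alternative: str = "greater") -> WilcoxonResult:
    """One-tailed Wilcoxon rank-sum test of within- vs between-replicate
    progeny counts.

    ``alternative='greater'`` tests H1: within-cross values tend to exceed
    between-cross values (rejecting the null that within-crosses produce
    an equal or smaller number of progeny). Exact p by complete
    enumeration of label assignments over midranks when n1 + n2 <= 12
    (tie-safe); otherwise a normal approximation with tie correction and
    continuity correction. All values tied -> p = 1, flagged degenerate.
    """
    x = np.asarray(within, dtype=float)
    y = np.asarray(between, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(w=float(n1 * (n + 1) / 2), p=1.0,
                              exact=True, degenerate=True)
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    if exact is None:
        exact = n <= 12
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if exact:
        ge = eq = 0
        for idx in itertools.combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            if w > w_obs + 1e-9:
                ge += 1
            elif w >= w_obs - 1e-9:
                eq += 1
        total = comb(n, n1)
        if alternative == "greater":
            p = (ge + eq) / total
        else:
            p = (total - ge) / total
        return WilcoxonResult(w=w_obs, p=p, exact=True)
    # normal approximation with tie correction + continuity correction
    mu = n1 * (n + 1) / 2
    n2 = n - n1
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if alternative == "greater":
        z = (w_obs - mu - 0.5) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    else:
        z = (w_obs - mu + 0.5) / np.sqrt(var)
        p = float(stats.norm.cdf(z))
    return WilcoxonResult(w=w_obs, p=p, exact=False)


def crossing_scheme_permutation(sheet: pd.DataFrame, n_perm: int = 10000,
                                rng: np.random.Generator | None = None) -> float:
    """Permutation test of the within/between mean difference over cross
    types.

    The unit of permutation is the cross-type mean; labels are shuffled
    respecting the diallel design (k within-labels among the k^2 cross
    types). When the number of distinct assignments C(k^2, k) does not
    exceed ``n_perm`` the null is enumerated completely, so with 3
    populations the smallest attainable p is 1/84.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    means = cross_type_means(sheet).per_cross
    vals = means["mean"].to_numpy()
    is_within = (means["sire_pop"] == means["dam_pop"]).to_numpy()
    k = int(is_within.sum())
    m = len(vals)

    def diff(mask: np.ndarray) -> float:
        return vals[mask].mean() - vals[~mask].mean()

    obs = diff(is_within)
    n_total = comb(m, k)
    if n_total <= n_perm:
        count = 0
        for idx in itertools.combinations(range(m), k):
            mask = np.zeros(m, dtype=bool)
            mask[list(idx)] = True
            if diff(mask) >= obs - 1e-12:
                count += 1
        return count / n_total
    rng = rng or np.random.default_rng()
    count = 1  # observed assignment counts itself
    for _ in range(n_perm):
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=k, replace=False)] = True
        if diff(mask) >= obs - 1e-12:
            count += 1
    return count / (n_perm + 1)
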