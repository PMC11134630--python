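"""Premating-isolation statistics.

Chasing-time comparisons across assay setups (Kruskal-Wallis with a
compact-letter post-hoc display) and assortative-mating quantification
from 2x2 mating-pair count tables (Yule's index, Fisher's exact test).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stats import bh_adjust

ASSAY_DURATION_S = 900.0  # 15-minute film


@dataclass
class ChasingRecord:
    """Per-male (or per-trial) chasing time for one assay setup."""
    trial_id: str
    setup: str
    chasing_time: float

    def __post_init__(self) -> None:
        if not 0 <= self.chasing_time <= ASSAY_DURATION_S:
            raise ValueError(
                f"chasing_time must lie in [0, {ASSAY_DURATION_S}] s")


@dataclass
class MatingCountTable:
    """2x2 mating-pair counts, rows = female population, cols = male population.

    The homotypic cells are (0,0) and (1,1); heterotypic are off-diagonal.
    """
    pops: tuple[str, str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def homotypic(self) -> tuple[float, float]:
        return float(self.counts[0, 0]), float(self.counts[1, 1])

    @property
    def heterotypic(self) -> tuple[float, float]:
        return float(self.counts[0, 1]), float(self.counts[1, 0])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction.

    Returns (H, p) with p from chi-square on k-1 df. A fully degenerate
    input (all values identical across all groups) gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _pairwise_mannwhitney(groups: list[np.ndarray]) -> np.ndarray:
    """BH-adjusted two-sided Mann-Whitney p for every group pair."""
    k = len(groups)
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        gi, gj = np.asarray(groups[i], float), np.asarray(groups[j], float)
        if np.all(np.concatenate([gi, gj]) == gi.flat[0]):
            raw.append(1.0)
        else:
            raw.append(float(stats.mannwhitneyu(gi, gj,
                                                alternative="two-sided").pvalue))
    adj = bh_adjust(np.array(raw))
    mat = np.ones((k, k))
    for (i, j), q in zip(pairs, adj):
        mat[i, j] = mat[j, i] = q
    return mat


def posthoc_letters(groups: list[np.ndarray], alpha: float = 0.05) -> list[str]:
    """Compact letter display from all pairwise Mann-Whitney tests.

    Two groups share a letter iff their BH-adjusted two-sided p exceeds
    ``alpha``. Uses the classic insert-and-absorb algorithm; letters are
    ordered by group median so 'a' labels the lowest cluster.
    """
    k = len(groups)
    if k == 1:
        return ["a"]
    q = _pairwise_mannwhitney(groups)
    # insert-absorb: start from one all-group letter, split on each
    # significant pair, drop letter sets contained in another
    letters: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if q[i, j] <= alpha:
            for s in [s for s in letters if i in s and j in s]:
                letters.remove(s)
                for cand in (s - {i}, s - {j}):
                    if cand and not any(cand <= o for o in letters):
                        letters.append(cand)
            letters = [s for s in letters
                       if not any(s < o for o in letters)]
    medians = [np.median(g) for g in groups]
    letters.sort(key=lambda s: min(medians[i] for i in s))
    out = ["" for _ in range(k)]
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letters):
        for i in s:
            out[i] += letter
    return out


def yules_index(table: MatingCountTable, variant: str = "Y") -> float:
    """Yule's association index for a 2x2 mating table.

    With homotypic counts a, d and heterotypic b, c:
    Q = (ad - bc)/(ad + bc) (Yule's Q) and
    Y = (sqrt(ad) - sqrt(bc))/(sqrt(ad) + sqrt(bc)) (coefficient of
    colligation). Positive values indicate assortative mating.
    """
    a, d = table.homotypic
    b, c = table.heterotypic
    if table.total == 0:
        raise ValueError("degenerate table: no pairs")
    ad, bc = a * d, b * c
    if ad + bc == 0:
        raise ValueError("degenerate table: ad + bc = 0")
    if variant == "Q":
        return (ad - bc) / (ad + bc)
    if variant == "Y":
        sad, sbc = np.sqrt(ad), np.sqrt(bc)
        return float((sad - sbc) / (sad + sbc))
    raise ValueError("variant must be 'Q' or 'Y'")


@dataclass
class FisherResult:
    odds_ratio: float  # sample OR = ad/bc; nan when undefined
    p: float
    degenerate: bool = False


def fisher_exact_2x2(table: MatingCountTable,
                     alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on the mating table.

    Exact hypergeometric p conditioning on both margins; the reported
    odds ratio is the unconditional sample OR (a*d)/(b*c). A zero margin
    makes the table degenerate: p = 1, OR undefined.
    """
    c = table.counts.astype(np.int64)
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=float("nan"), p=1.0, degenerate=True)
    res = stats.fisher_exact(c, alternative=alternative)
    return FisherResult(odds_ratio=float(res.statistic), p=float(res.pvalue))
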