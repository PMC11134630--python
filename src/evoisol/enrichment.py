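"""Gene-set over-representation and tissue-specificity classification.

Plain per-set Fisher's exact tests with BH FDR across the tested sets;
annotation comes from generic GMT-like files, so the module is agnostic
about whether a set is a GO term, a tissue-specific list or a curated
pathway. Tissue-specific sets are derived from a gene x tissue expression
table by the "more than twofold above whole-body" rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set '{self.name}' is empty")

    @classmethod
    def of(cls, name: str, genes) -> "GeneSet":
        return cls(name=name, genes=frozenset(genes))


def overrep_test(hits: GeneSet, annotations: list[GeneSet],
                 universe: set[str],
                 haldane_anscombe: bool = False) -> pd.DataFrame:
    """Fisher over-representation of ``hits`` in each annotation set.

    2x2 cells: (hits ∩ anno, hits \\ anno, anno \\ hits, neither), all
    within ``universe``. Reports the sample odds ratio (optionally with
    the Haldane-Anscombe +0.5 correction when a cell is zero), the exact
    hypergeometric p (alternative: greater, i.e., over-representation)
    and BH q across the annotation sets tested.
    """
    if not universe:
        raise ValueError("empty universe")
    hit = hits.genes & universe
    rows = []
    for anno in annotations:
        a = anno.genes & universe
        k11 = len(hit & a)
        k12 = len(hit - a)
        k21 = len(a - hit)
        k22 = len(universe) - k11 - k12 - k21
        if 0 in (k11, k12, k21, k22) and haldane_anscombe:
            oddsr = ((k11 + 0.5) * (k22 + 0.5)) / ((k12 + 0.5) * (k21 + 0.5))
        else:
            num, den = k11 * k22, k12 * k21
            oddsr = num / den if den else (np.inf if num else np.nan)
        p = float(stats.fisher_exact([[k11, k12], [k21, k22]],
                                     alternative="greater").pvalue)
        rows.append({"set": anno.name, "n_set": len(a), "overlap": k11,
                     "hit_only": k12, "set_only": k21, "neither": k22,
                     "odds_ratio": float(oddsr), "p": p})
    tab = pd.DataFrame(rows)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    return tab


def tissue_specific_genes(tissue_expr: pd.DataFrame,
                          whole_body_col: str = "whole_body",
                          fold: float = 2.0) -> dict[str, GeneSet]:
    """Per-tissue gene sets by the strict > ``fold`` x whole-body rule.

    ``tissue_expr`` is a gene x tissue table that must include the
    whole-body reference column; a gene joins a tissue's set iff its
    expression there strictly exceeds fold x its whole-body expression.
    """
    if whole_body_col not in tissue_expr.columns:
        raise ValueError(f"missing whole-body column '{whole_body_col}'")
    wb = tissue_expr[whole_body_col]
    out = {}
    for tissue in tissue_expr.columns:
        if tissue == whole_body_col:
            continue
        members = tissue_expr.index[tissue_expr[tissue] > fold * wb]
        if len(members):
            out[tissue] = GeneSet.of(tissue, members)
    return out
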