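"""Compositional analysis of cuticular-hydrocarbon (CHC) profiles.

CHC abundances from GC/MS are relative (they carry only ratio
information), so the analysis works in the Aitchison geometry: closure to
the simplex, centered log-ratio (CLR) transform, PCA on CLR values, and a
per-compound two-way ANOVA for sex, evolution and their interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust


@dataclass
class CompositionProfile:
    """One sample's relative-abundance vector with its design labels."""
    sample_id: str
    sex: str          # "female" | "male"
    group: str        # "ancestral" | "evolved"
    replicate: str
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")


def profiles_to_frame(profiles: list[CompositionProfile],
                      compound_names: list[str] | None = None) -> pd.DataFrame:
    """Stack profiles into a samples x compounds DataFrame with a
    (sex, group, replicate) metadata index."""
    k = len(profiles[0].abundances)
    names = compound_names or [f"c{i+1}" for i in range(k)]
    idx = pd.MultiIndex.from_tuples(
        [(p.sample_id, p.sex, p.group, p.replicate) for p in profiles],
        names=["sample_id", "sex", "group", "replicate"])
    return pd.DataFrame([p.abundances for p in profiles], index=idx,
                        columns=names)


def closure(v: np.ndarray) -> np.ndarray:
    """Project a nonnegative vector (or rows of a matrix) onto the simplex."""
    v = np.asarray(v, dtype=float)
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s == 0):
        raise ValueError("cannot close a vector summing to 0")
    return v / s


def clr(c: np.ndarray, zero_strategy: str = "multiplicative") -> np.ndarray:
    """Centered log-ratio transform: clr_i = ln c_i - mean(ln c).

    Zeros are handled by the multiplicative replacement of Martín-
    Fernández: each zero is set to delta = 0.65 x the smallest positive
    fraction in that sample and the vector re-closed. With
    ``zero_strategy='error'`` zeros raise instead. Output rows sum to 0.
    """
    was_1d = np.asarray(c).ndim == 1
    c = closure(np.atleast_2d(np.asarray(c, dtype=float)))
    if (c == 0).any():
        if zero_strategy == "error":
            raise ValueError("composition contains zeros")
        if zero_strategy != "multiplicative":
            raise ValueError("zero_strategy must be 'multiplicative' or 'error'")
        out = c.copy()
        for row in out:
            z = row == 0
            if z.any():
                delta = 0.65 * row[row > 0].min()
                row[z] = delta
        c = closure(out)
    logc = np.log(c)
    res = logc - logc.mean(axis=-1, keepdims=True)
    return res[0] if was_1d else res


def completeness_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only compounds with nonzero abundance in every sample
    (the 'detected in all samples' rule)."""
    keep = (table > 0).all(axis=0)
    return table.loc[:, keep]


@dataclass
class PCAResult:
    scores: np.ndarray          # samples x components
    loadings: np.ndarray        # variables x components
    variance_explained: np.ndarray  # fractions, sum to 1 at full rank
    degenerate: bool = False


def pca(x: np.ndarray) -> PCAResult:
    """PCA of a samples x variables matrix via SVD of the column-centered
    data (covariance PCA, no rescaling).

    Sign convention: within each component the loading entry of largest
    magnitude is made positive, so results are deterministic. A constant
    matrix is flagged degenerate with all variance fractions zero.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=0)
    total = (xc ** 2).sum()
    if total == 0:
        k = min(x.shape)
        return PCAResult(np.zeros((x.shape[0], k)),
                         np.zeros((x.shape[1], k)),
                         np.zeros(k), degenerate=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    flip = np.where(vt[np.arange(len(s)),
                       np.abs(vt).argmax(axis=1)] < 0, -1.0, 1.0)
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    return PCAResult(scores=u * s, loadings=vt.T,
                     variance_explained=s ** 2 / (s ** 2).sum())


@dataclass
class AnovaResult:
    """Two-way ANOVA p-values (and F, SS) for one response variable."""
    p_sex: float
    p_evolution: float
    p_interaction: float
    f_sex: float
    f_evolution: float
    f_interaction: float
    ss: dict


def _rss(y: np.ndarray, design: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(design))


def two_way_anova(values: np.ndarray, sex: np.ndarray,
                  evolution: np.ndarray) -> AnovaResult:
    """Type-II two-way ANOVA of one response on two two-level factors.

    Sums of squares by model comparison: SS(sex | evolution),
    SS(evolution | sex) and SS(interaction | main effects), each tested
    against the residual mean square of the full interaction model. A
    factor with a single observed level yields NaN for its effects.
    """
    y = np.asarray(values, dtype=float)
    s = (np.asarray(sex) == np.asarray(sex)[0]).astype(float)
    e = (np.asarray(evolution) == np.asarray(evolution)[0]).astype(float)
    if len(set(map(str, sex))) < 2 or len(set(map(str, evolution))) < 2:
        return AnovaResult(*(float("nan"),) * 6, ss={})
    one = np.ones_like(y)
    d_s = np.column_stack([one, s])
    d_e = np.column_stack([one, e])
    d_se = np.column_stack([one, s, e])
    d_full = np.column_stack([one, s, e, s * e])
    rss_s, _ = _rss(y, d_s)
    rss_e, _ = _rss(y, d_e)
    rss_se, _ = _rss(y, d_se)
    rss_full, rank_full = _rss(y, d_full)
    n = len(y)
    df_resid = n - rank_full
    ss = {"sex": rss_e - rss_se, "evolution": rss_s - rss_se,
          "interaction": rss_se - rss_full, "residual": rss_full}
    if df_resid <= 0:
        return AnovaResult(*(float("nan"),) * 6, ss=ss)
    mse = rss_full / df_resid
    out_f, out_p = [], []
    for key in ("sex", "evolution", "interaction"):
        if mse == 0:
            f = np.inf if ss[key] > 0 else 0.0
            p = 0.0 if ss[key] > 0 else 1.0
        else:
            f = max(ss[key], 0.0) / mse
            p = float(stats.f.sf(f, 1, df_resid))
        out_f.append(float(f))
        out_p.append(p)
    return AnovaResult(p_sex=out_p[0], p_evolution=out_p[1],
                       p_interaction=out_p[2], f_sex=out_f[0],
                       f_evolution=out_f[1], f_interaction=out_f[2], ss=ss)


def anova_table(clr_values: pd.DataFrame, sex: np.ndarray,
                evolution: np.ndarray, bh: bool = False) -> pd.DataFrame:
    """Per-compound two-way ANOVA on CLR values (or raw percentages if a
    raw table is passed); optionally BH-correct each effect's p-values
    across compounds."""
    rows = {}
    for comp in clr_values.columns:
        r = two_way_anova(clr_values[comp].to_numpy(), sex, evolution)
        rows[comp] = {"p_sex": r.p_sex, "p_evolution": r.p_evolution,
                      "p_interaction": r.p_interaction}
    tab = pd.DataFrame(rows).T
    if bh:
        for col in tab.columns:
            tab[col.replace("p_", "q_")] = bh_adjust(tab[col].to_numpy())
    return tab
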