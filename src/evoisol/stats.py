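"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values. NaN entries are passed through
    and excluded from the effective number of tests."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
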