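"""Shared statistical primitives: BH adjustment, Mann-Whitney-Wilcoxon, star bands.

These are thin, contract-pinning wrappers around scipy/statsmodels so that
every module in the pipeline applies exactly the same multiple-testing and
rank-test conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "mann_whitney", "p_stars"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN inputs propagate to NaN outputs and are excluded from the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Uses the exact null distribution when both samples have n <= 8 and the
    pooled data is tie-free; otherwise the normal approximation with tie and
    continuity corrections. Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence of a shift
        return float(x.size * y.size / 2), 1.0
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def p_stars(p: float) -> str:
    """Significance bands: **** <1e-4, *** <1e-3, ** <0.01, * <0.05."""
    if np.isnan(p):
        return ""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return mark
    return ""


def run_contrasts(values: pd.Series, comparisons) -> pd.DataFrame:
    """MWW over a family of named contrasts, BH-adjusted jointly.

    ``comparisons`` is a list of ``(name, ids_a, ids_b)`` triples of sample-id
    sequences indexing into ``values``.
    """
    rows = []
    for name, ids_a, ids_b in comparisons:
        a = values.loc[list(ids_a)].to_numpy(dtype=float)
        b = values.loc[list(ids_b)].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"contrast {name!r}: each cell needs >=2 samples")
        u, p = mann_whitney(a, b)
        rows.append({"contrast": name, "n_a": a.size, "n_b": b.size,
                     "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                     "U": u, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    out["stars"] = [p_stars(p) for p in out["p_adj"]]
    return out
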