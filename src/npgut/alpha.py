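"""SRS library-size normalization, Shannon-Weiner diversity, MWW+BH contrasts.

SRS (scaling with ranked subsampling) normalizes every sample to a common
depth Cmin by scaling counts to sum Cmin, keeping integer parts, and handing
the remaining reads one each to the taxa with the largest fractional parts
(fractional-part ties broken uniformly at random with a recorded seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import run_contrasts  # noqa: F401  (re-exported for callers)


@dataclass
class SrsResult:
    counts: pd.DataFrame
    c_min: int
    seed: int | None


def srs_normalize(counts: pd.DataFrame, c_min: int | str = "auto",
                  seed: int | None = None) -> SrsResult:
    """Normalize each sample to exactly ``c_min`` total reads by SRS."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(f"all-zero samples: {totals[totals <= 0].index.tolist()}")
    if c_min == "auto":
        c_min = int(totals.min())
    c_min = int(c_min)
    if c_min < 1:
        raise ValueError("c_min must be >= 1")
    too_small = totals[totals < c_min].index.tolist()
    if too_small:
        raise ValueError(f"samples with fewer than c_min={c_min} reads: {too_small}")
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy(dtype=float)
    out = np.zeros_like(mat, dtype=np.int64)
    for i in range(mat.shape[0]):
        scaled = mat[i] * (c_min / totals.iloc[i])
        ints = np.floor(scaled).astype(np.int64)
        frac = scaled - ints
        remaining = c_min - int(ints.sum())
        if remaining:
            # rank by descending fractional part; ties uniformly at random
            order = np.lexsort((rng.random(frac.size), -frac))
            ints[order[:remaining]] += 1
        out[i] = ints
    return SrsResult(pd.DataFrame(out, index=counts.index, columns=counts.columns),
                     c_min, seed)


def shannon(counts: pd.DataFrame) -> pd.Series:
    """Shannon-Weiner index H = -sum p ln p (nats) per sample."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(f"all-zero samples: {totals[totals <= 0].index.tolist()}")
    p = counts.div(totals, axis=0).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=counts.index, name="shannon")


def compare_alpha(alpha: pd.Series, metadata: pd.DataFrame, comparisons) -> pd.DataFrame:
    """MWW + BH over a family of named contrasts on per-sample alpha values.

    Each comparison is ``(name, selector_a, selector_b)`` where a selector is
    either an explicit sample-id sequence or a dict of metadata column ->
    level used to select samples.
    """
    resolved = []
    for name, sel_a, sel_b in comparisons:
        resolved.append((name, _resolve(metadata, sel_a, alpha.index),
                         _resolve(metadata, sel_b, alpha.index)))
    return run_contrasts(alpha, resolved)


def _resolve(metadata: pd.DataFrame, selector, available) -> list:
    if isinstance(selector, dict):
        mask = pd.Series(True, index=metadata.index)
        for col, level in selector.items():
            mask &= metadata[col] == level
        ids = metadata.index[mask]
    else:
        ids = pd.Index(selector)
    ids = ids.intersection(available)
    if len(ids) == 0:
        raise ValueError(f"selector {selector!r} matches no samples with alpha values")
    return list(ids)
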