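"""Independent brute-force oracles used to pin the statistical machinery.

Everything here is written from first principles (enumeration, exact
rational arithmetic, nested loops) and never calls the code paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup_reject(pvalues, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions: sort p, find the largest i with
    p_(i) <= i*alpha/m, reject hypotheses 1..i."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def fisher_greater_p(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (greater) Fisher p for [[a, b], [c, d]] by exhaustive
    hypergeometric enumeration in exact rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if k >= a:
            total += Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
    return total


def mww_exact_two_sided_p(x, y) -> float:
    """Two-sided exact MWW p by enumerating every assignment of the pooled
    ranks to the two groups (tie-free data only)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)

    def u_of(ranks_x):
        return sum(ranks_x) - n1 * (n1 + 1) / 2

    u_obs = u_of([rank[v] for v in x])
    us = [u_of(combo) for combo in
          itertools.combinations(range(1, n1 + n2 + 1), n1)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(p_le, p_ge))


def pooled_t(x, y) -> tuple[float, float]:
    """Hand-computed pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * t_dist.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def bray_curtis_direct(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.abs(u - v).sum() / (u + v).sum())


def content_bruteforce(matches, reactions_by_model, reaction_ids) -> dict:
    """Nested-loop reaction-content oracle: dict (asv, reaction) -> fraction."""
    out = {}
    for asv, model_ids in matches.items():
        for r in reaction_ids:
            n_with = sum(1 for mid in model_ids if r in reactions_by_model[mid])
            out[(asv, r)] = n_with / len(model_ids)
    return out


def reaction_abundance_bruteforce(ra, content) -> np.ndarray:
    """Double-loop abundance oracle over pandas inputs (samples x reactions)."""
    out = np.zeros((ra.shape[0], content.shape[1]))
    for i, s in enumerate(ra.index):
        for j, r in enumerate(content.columns):
            acc = 0.0
            for asv in content.index:
                if asv in ra.columns:
                    acc += ra.at[s, asv] * content.at[asv, r]
            out[i, j] = acc
    return out
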