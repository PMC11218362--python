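"""Sample-level reaction abundances, differential testing, pathway enrichment, PCA.

Reaction abundance in a sample is the abundance-weighted model content:
abundance(s, j) = sum over mapped ASVs a of RA(s, a) * content(a, j).
Group differences are assessed per reaction with a two-sample t-test
(pooled-variance by default, Welch by flag) and BH correction; pathways are
tested for enrichment among significant reactions with a one-sided Fisher's
exact test, again BH-corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .stats import bh_adjust


def reaction_abundances(ra_table: pd.DataFrame, content: pd.DataFrame) -> pd.DataFrame:
    """Samples x reactions matrix: RA (restricted to mapped ASVs) @ content."""
    shared = ra_table.columns.intersection(content.index)
    if len(shared) == 0:
        raise ValueError("no overlap between RA-table ASVs and mapped ASVs")
    return ra_table[shared] @ content.loc[shared]


def reaction_prevalence(abundances: pd.DataFrame, min_fraction: float = 0.99) -> dict:
    """Presence (= strictly positive abundance) summaries across samples."""
    if abundances.shape[0] == 0:
        raise ValueError("need at least one sample")
    present = abundances.to_numpy() > 0
    n_samples, n_reactions = present.shape
    per_sample = present.sum(axis=1) / max(n_reactions, 1)
    return {
        "n_reactions": int(n_reactions),
        "frac_reactions_in_all_samples": float(present.all(axis=0).mean()),
        "per_sample_fraction": pd.Series(per_sample, index=abundances.index),
        "min_per_sample_fraction": float(per_sample.min()),
        "frac_samples_above": float((per_sample > min_fraction).mean()),
    }


def differential_reactions(abundances: pd.DataFrame, metadata: pd.DataFrame,
                           contrast, welch: bool = False,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-reaction two-sample t-test between the two levels of ``contrast``.

    ``contrast`` is ``(factor, level_a, level_b)`` over metadata columns.
    Reactions with zero variance in both groups and equal means carry NaN
    statistics and ``excluded_reason``; BH runs over the tested reactions.
    """
    factor, lvl_a, lvl_b = contrast
    ids_a = metadata.index[(metadata[factor] == lvl_a)].intersection(abundances.index)
    ids_b = metadata.index[(metadata[factor] == lvl_b)].intersection(abundances.index)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"contrast {lvl_a} vs {lvl_b} on {factor!r}: both levels need >=2 samples "
            f"(got {len(ids_a)}, {len(ids_b)})")
    a = abundances.loc[ids_a].to_numpy(dtype=float)
    b = abundances.loc[ids_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0) & (mean_a == mean_b)
    t = np.full(abundances.shape[1], np.nan)
    p = np.full(abundances.shape[1], np.nan)
    ok = ~degenerate
    if ok.any():
        res = sps.ttest_ind(a[:, ok], b[:, ok], equal_var=not welch, axis=0)
        t[ok], p[ok] = res.statistic, res.pvalue
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "t": t, "p": p,
    }, index=abundances.columns)
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] <= alpha
    out["excluded_reason"] = pd.array(
        np.where(degenerate, "zero variance in both groups, equal means", None),
        dtype="string")
    out.index.name = "reaction"
    return out


def pathway_t_summary(differentials: pd.DataFrame, catalog: pd.Series) -> pd.DataFrame:
    """Mean t per pathway with a normal-theory 95% CI over member reactions."""
    tested = differentials.dropna(subset=["t"])
    groups = tested.groupby(catalog.reindex(tested.index))["t"]
    rows = []
    for pathway, tvals in groups:
        k = len(tvals)
        mean = float(tvals.mean())
        half = 1.959963984540054 * float(tvals.std(ddof=1)) / np.sqrt(k) if k > 1 else np.nan
        rows.append({"pathway": pathway, "n_reactions": k, "mean_t": mean,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows).set_index("pathway")


def pathway_enrichment(differentials: pd.DataFrame, catalog: pd.Series,
                       alpha: float = 0.05,
                       alternative: str = "greater") -> pd.DataFrame:
    """Fisher's exact enrichment of significant reactions within each pathway.

    2x2 per pathway: {significant, not} x {in pathway, not}; BH over pathways;
    enriched iff adjusted p <= ``alpha``. Pathways with no tested reaction are
    skipped.
    """
    tested = differentials.dropna(subset=["p"])
    missing = tested.index.difference(catalog.index).tolist()
    if missing:
        raise ValueError(f"tested reactions missing from catalog: {missing[:10]}")
    sig = tested["significant"].to_numpy(dtype=bool)
    pathways = catalog.reindex(tested.index)
    m = len(tested)
    n_sig = int(sig.sum())
    rows = []
    for pathway in pd.unique(pathways):
        in_path = (pathways == pathway).to_numpy()
        k = int(in_path.sum())
        if k == 0:
            continue
        a = int((sig & in_path).sum())          # significant, in pathway
        table = [[a, n_sig - a], [k - a, (m - n_sig) - (k - a)]]
        odds, p = sps.fisher_exact(table, alternative=alternative)
        rows.append({"pathway": pathway, "n_in_pathway": k,
                     "n_significant_in_pathway": a, "n_significant_total": n_sig,
                     "n_tested_total": m, "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["p_adj"] = bh_adjust(out["p"])
    out["enriched"] = out["p_adj"] <= alpha
    return out


def pca_embed(matrix: pd.DataFrame, standardize: bool = True):
    """Exact (full-SVD) PCA of samples; z-scores columns when ``standardize``.

    Returns ``(scores, explained_fractions, dropped_columns)``; zero-variance
    columns are dropped (with a report) before standardization.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    variances = X.var(axis=0)
    dropped = list(matrix.columns[variances == 0]) if standardize else []
    if standardize:
        keep = variances > 0
        if keep.sum() < 2:
            raise ValueError("fewer than 2 non-degenerate columns")
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        raise ValueError("fewer than 2 non-degenerate columns")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            pd.Series(frac, index=cols), dropped)
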