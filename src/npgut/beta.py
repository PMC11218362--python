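"""Beta diversity: Bray-Curtis and robust Aitchison distances, PCoA, and the
permutation-test battery (PERMANOVA with sequential two-factor partitioning,
PERMDISP, pairwise PERMANOVA with BH).

PERMANOVA follows the distance-matrix partitioning of McArdle & Anderson:
with G the Gower-centered matrix of squared dissimilarities and H a model
projection ("hat") matrix, a model's explained sum of squares is tr(HG);
sequential (Type I) term sums of squares are differences of nested-model
traces, and significance comes from free permutation of sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stats import bh_adjust

_EIG_TOL = 1e-10


# ---------------------------------------------------------------- distances

def bray_curtis(abundances: pd.DataFrame, transform: str = "log1p") -> pd.DataFrame:
    """Bray-Curtis dissimilarity, optionally on log1p-transformed entries.

    The log transform is applied to the abundance entries *before* computing
    distances (transforming a distance matrix itself would break the [0, 1]
    and non-negativity contracts).
    """
    if (abundances.to_numpy() < 0).any():
        raise ValueError("Bray-Curtis requires non-negative input")
    zero = abundances.index[abundances.sum(axis=1) == 0].tolist()
    if len(zero) >= 2:
        raise ValueError(f"distance undefined between all-zero samples: {zero}")
    if transform == "log1p":
        X = np.log1p(abundances.to_numpy(dtype=float))
    elif transform == "none":
        X = abundances.to_numpy(dtype=float)
    else:
        raise ValueError("transform must be 'log1p' or 'none'")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=abundances.index, columns=abundances.index)


def rclr_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Robust centered log-ratio: log of each nonzero entry minus the mean log
    over that sample's nonzero entries; zeros stay zero."""
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("rclr requires non-negative input")
    if (X.sum(axis=1) == 0).any():
        zero = counts.index[X.sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with no nonzero entries: {zero}")
    out = np.zeros_like(X)
    with np.errstate(divide="ignore"):
        logs = np.log(X, where=X > 0, out=np.full_like(X, np.nan))
    for i in range(X.shape[0]):
        nz = X[i] > 0
        out[i, nz] = logs[i, nz] - logs[i, nz].mean()
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def robust_aitchison(counts: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between rclr-transformed samples."""
    Z = rclr_transform(counts).to_numpy()
    d = squareform(pdist(Z, metric="euclidean"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


# ------------------------------------------------------------------- PCoA

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame       # samples x positive-eigenvalue axes
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_coordinates: pd.DataFrame  # axes for negative eigenvalues


def _gower_center(distances: np.ndarray) -> np.ndarray:
    A = -0.5 * distances ** 2
    row = A.mean(axis=1, keepdims=True)
    return A - row - row.T + A.mean()


def pcoa(distances: pd.DataFrame) -> PcoaResult:
    """Classical metric scaling by double-centering and eigendecomposition.

    Negative eigenvalues are reported (and their axes kept, imaginary part
    stored as real coordinates) rather than silently dropped.
    """
    n = distances.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    D = distances.to_numpy(dtype=float)
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("input is not a valid distance matrix")
    G = _gower_center(D)
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > _EIG_TOL * max(abs(eigvals[0]), 1.0)
    neg = eigvals < -_EIG_TOL * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    ncoords = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    naxes = [f"PCoNeg{i + 1}" for i in range(ncoords.shape[1])]
    return PcoaResult(
        pd.DataFrame(coords, index=distances.index, columns=axes),
        eigvals,
        prop,
        pd.DataFrame(ncoords, index=distances.index, columns=naxes),
    )


# --------------------------------------------------------------- PERMANOVA

def _parse_formula(formula: str) -> list[str]:
    formula = formula.strip()
    if "*" in formula:
        a, b = (t.strip() for t in formula.split("*"))
        return [a, b, f"{a}:{b}"]
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    if not 1 <= len(terms) <= 3:
        raise ValueError(f"cannot parse formula {formula!r}")
    return terms


def _indicator(metadata: pd.DataFrame, factor: str) -> np.ndarray:
    levels = pd.unique(metadata[factor])
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if len(levels) == len(metadata):
        raise ValueError(f"factor {factor!r} is confounded with samples "
                         "(one sample per level)")
    return (metadata[factor].to_numpy()[:, None] == np.asarray(levels)[None, :]).astype(float)


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        Za, Zb = _indicator(metadata, a.strip()), _indicator(metadata, b.strip())
        return np.einsum("ni,nj->nij", Za, Zb).reshape(len(metadata), -1)
    return _indicator(metadata, term)


def _projector(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank (SVD-based)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def permanova(distances: pd.DataFrame, metadata: pd.DataFrame, formula: str,
              n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA on a distance matrix.

    ``formula`` is one or two factor names joined by ``+`` or ``*`` (``*``
    adds the interaction after the main effects, in the order written).
    Returns a vegan-style table with term, Residual and Total rows.
    """
    metadata = metadata.loc[distances.index]
    terms = _parse_formula(formula)
    n = len(metadata)
    G = _gower_center(distances.to_numpy(dtype=float))
    total_ss = float(np.trace(G))

    # nested model projectors: intercept, +term1, +term1+term2, ...
    X = np.ones((n, 1))
    projectors, ranks = [], []
    for term in terms:
        X = np.hstack([X, _term_columns(metadata, term)])
        H, r = _projector(X)
        projectors.append(H)
        ranks.append(r)
    df_terms = np.diff([1] + ranks).astype(int)
    if (df_terms <= 0).any():
        bad = [t for t, d in zip(terms, df_terms) if d <= 0]
        raise ValueError(f"terms add no degrees of freedom (aliased): {bad}")
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(Gmat):
        model_ss = np.array([np.sum(H * Gmat) for H in projectors])
        ss = np.diff(np.concatenate([[0.0], model_ss]))
        res = np.trace(Gmat) - model_ss[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_terms) / (res / df_res)
        return ss, res, F

    ss, res_ss, F_obs = term_stats(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    # relative tolerance so permutations reproducing the observed statistic
    # (e.g. relabelings of a perfect separation) count as exceedances
    with np.errstate(invalid="ignore"):
        thresh = np.where(np.isfinite(F_obs),
                          F_obs - 1e-9 * np.maximum(np.abs(F_obs), 1.0), F_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, F_perm = term_stats(G[np.ix_(perm, perm)])
        exceed += F_perm >= thresh
    pvals = (exceed + 1) / (n_perm + 1)

    rows = [{"term": t, "df": int(d), "SumsOfSqs": float(s), "F": float(f),
             "R2": float(s / total_ss), "p": float(p), "n_perm": n_perm}
            for t, d, s, f, p in zip(terms, df_terms, ss, F_obs, pvals)]
    rows.append({"term": "Residual", "df": int(df_res), "SumsOfSqs": float(res_ss),
                 "F": np.nan, "R2": float(res_ss / total_ss), "p": np.nan,
                 "n_perm": n_perm})
    rows.append({"term": "Total", "df": n - 1, "SumsOfSqs": total_ss, "F": np.nan,
                 "R2": 1.0, "p": np.nan, "n_perm": n_perm})
    return pd.DataFrame(rows).set_index("term")


def pairwise_permanova(distances: pd.DataFrame, metadata: pd.DataFrame,
                       group_factor: str, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """One PERMANOVA per level pair of ``group_factor``; BH across pairs.

    Pairs containing a single-sample level are skipped with a note.
    """
    metadata = metadata.loc[distances.index]
    levels = list(pd.unique(metadata[group_factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {group_factor!r} has fewer than 2 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            la, lb = levels[i], levels[j]
            ids = metadata.index[metadata[group_factor].isin([la, lb])]
            counts = metadata.loc[ids, group_factor].value_counts()
            if counts.min() < 2:
                rows.append({"pair": f"{la} vs {lb}", "df": np.nan,
                             "SumsOfSqs": np.nan, "F": np.nan, "R2": np.nan,
                             "p": np.nan, "note": "skipped: single-sample level"})
                continue
            sub = permanova(distances.loc[ids, ids], metadata.loc[ids],
                            group_factor, n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            rec = sub.loc[group_factor]
            rows.append({"pair": f"{la} vs {lb}", "df": rec["df"],
                         "SumsOfSqs": rec["SumsOfSqs"], "F": rec["F"],
                         "R2": rec["R2"], "p": rec["p"], "note": ""})
    out = pd.DataFrame(rows).set_index("pair")
    out["p_adj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------- PERMDISP

def _spatial_median(points: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 500) -> np.ndarray:
    """Weiszfeld's algorithm for the geometric (spatial) median."""
    if points.shape[0] == 1 or points.shape[1] == 0:
        return points.mean(axis=0)
    c = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - c, axis=1)
        if (d < tol).any():
            # median coincides with a data point
            return points[d.argmin()].copy()
        w = 1.0 / d
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - c) < tol:
            return new
        c = new
    return c


@dataclass
class PermdispResult:
    dispersions: pd.Series       # group -> mean distance to center
    sample_distances: pd.Series  # per-sample distance to own group center
    F: float
    p: float
    n_perm: int


def permdisp(distances: pd.DataFrame, metadata: pd.DataFrame, group_factor: str,
             n_perm: int = 999, center: str = "median",
             seed: int | None = None) -> PermdispResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Samples are embedded by PCoA keeping negative-eigenvalue axes; each
    sample's distance to its group center (spatial median by default,
    centroid optionally) uses the imaginary-axis correction
    d^2 = d_real^2 - d_imag^2. A one-way F on these distances is assessed by
    permuting group labels over the fixed distance vector.
    """
    metadata = metadata.loc[distances.index]
    groups = metadata[group_factor]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if sizes.min() < 2:
        raise ValueError(f"groups with <2 samples: {sizes[sizes < 2].index.tolist()}")
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    emb = pcoa(distances)
    pos = emb.coordinates.to_numpy()
    neg = emb.negative_coordinates.to_numpy()
    dists = np.zeros(len(groups))
    for level in levels:
        mask = (groups == level).to_numpy()
        if center == "median":
            cp = _spatial_median(pos[mask])
            cn = _spatial_median(neg[mask]) if neg.shape[1] else np.zeros(0)
        else:
            cp = pos[mask].mean(axis=0)
            cn = neg[mask].mean(axis=0) if neg.shape[1] else np.zeros(0)
        d2 = ((pos[mask] - cp) ** 2).sum(axis=1)
        if neg.shape[1]:
            d2 = d2 - ((neg[mask] - cn) ** 2).sum(axis=1)
        dists[mask] = np.sqrt(np.clip(d2, 0.0, None))

    codes = pd.Categorical(groups).codes
    k = len(levels)

    def anova_F(vals, labels):
        grand = vals.mean()
        ss_between = ss_within = 0.0
        for g in range(k):
            sub = vals[labels == g]
            ss_between += sub.size * (sub.mean() - grand) ** 2
            ss_within += ((sub - sub.mean()) ** 2).sum()
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / (k - 1)) / (ss_within / (vals.size - k))

    F_obs = anova_F(dists, codes)
    rng = np.random.default_rng(seed)
    thresh = (F_obs - 1e-9 * max(abs(F_obs), 1.0)) if np.isfinite(F_obs) else F_obs
    exceed = 0
    for _ in range(n_perm):
        if anova_F(dists, rng.permutation(codes)) >= thresh:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    disp = pd.Series({lvl: dists[(groups == lvl).to_numpy()].mean() for lvl in levels})
    return PermdispResult(disp, pd.Series(dists, index=distances.index),
                          float(F_obs), float(p), n_perm)
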