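"""Relative-abundance composition summaries, per-taxon group tests, shared ASVs.

Aggregation works at any rank from phylum to genus; ASVs whose label is
unassigned at the requested rank fall back to the lowest assigned higher rank
("undefined genera of family Ruminococcaceae"), the convention used for
stacked-bar composition figures. Top-k taxa are ranked by mean relative
abundance within each displayed cell and the remainder pooled into OTHERS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RANKS
from .stats import run_contrasts

_PLURAL = {"phylum": "phyla", "class": "classes", "order": "orders",
           "family": "families", "genus": "genera", "species": "species"}

OTHERS = "OTHERS"


def taxon_labels(taxonomy: pd.DataFrame, rank: str) -> pd.Series:
    """Label each ASV at ``rank``, falling back to the lowest assigned higher
    rank as e.g. "undefined genera of family Ruminococcaceae"."""
    if rank not in RANKS[1:]:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS[1:]}")
    idx = RANKS.index(rank)
    labels = {}
    for asv in taxonomy.index:
        val = taxonomy.at[asv, rank] if rank in taxonomy.columns else pd.NA
        if pd.notna(val):
            labels[asv] = str(val)
            continue
        for higher in range(idx - 1, -1, -1):
            hval = taxonomy.at[asv, RANKS[higher]] if RANKS[higher] in taxonomy.columns else pd.NA
            if pd.notna(hval):
                labels[asv] = (f"undefined {_PLURAL.get(rank, rank)} of "
                               f"{RANKS[higher]} {hval}")
                break
        else:
            labels[asv] = f"undefined {_PLURAL.get(rank, rank)}"
    return pd.Series(labels, name=rank).reindex(taxonomy.index)


def collapse_to_rank(ra_table: pd.DataFrame, taxonomy: pd.DataFrame,
                     rank: str) -> pd.DataFrame:
    """Sum ASV relative abundances into rank-level labels (samples x taxa)."""
    labels = taxon_labels(taxonomy.loc[ra_table.columns], rank)
    return ra_table.T.groupby(labels).sum().T


def aggregate_taxa(ra_table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str,
                   top_k: int = 15,
                   metadata: pd.DataFrame | None = None,
                   cell_factors=("group", "phase", "sample_type")) -> pd.DataFrame:
    """Mean RA of the top-k taxa (+ OTHERS) at ``rank`` per metadata cell.

    With no metadata, all samples form a single cell. Total RA is conserved
    exactly: within each cell the means over top taxa and OTHERS sum to the
    cell's mean sample total.
    """
    by_rank = collapse_to_rank(ra_table, taxonomy, rank)
    if metadata is None:
        cells = {"all": list(by_rank.index)}
    else:
        meta = metadata.loc[by_rank.index]
        factors = [f for f in cell_factors if f in meta.columns]
        grouped = meta.groupby(factors, dropna=False, observed=True)
        cells = {
            " / ".join("NA" if pd.isna(v) else str(v)
                       for v in (key if isinstance(key, tuple) else (key,))): list(ids)
            for key, ids in grouped.groups.items()
        }
    rows = []
    for cell, ids in cells.items():
        means = by_rank.loc[ids].mean(axis=0).sort_values(ascending=False)
        top = means.iloc[:top_k]
        rest = means.iloc[top_k:]
        for taxon, mean_ra in top.items():
            rows.append({"cell": cell, "taxon": taxon, "mean_ra": float(mean_ra),
                         "n_samples": len(ids)})
        if len(rest):
            rows.append({"cell": cell, "taxon": OTHERS, "mean_ra": float(rest.sum()),
                         "n_samples": len(ids)})
    return pd.DataFrame(rows)


def compare_taxa(ra_table: pd.DataFrame, taxonomy: pd.DataFrame,
                 metadata: pd.DataFrame, rank: str, contrasts) -> pd.DataFrame:
    """Per-taxon MWW across a family of contrasts, BH over taxon x contrast.

    ``contrasts`` is a list of ``(name, ids_a, ids_b)``. Taxa absent from all
    involved samples are excluded with a note column.
    """
    by_rank = collapse_to_rank(ra_table, taxonomy, rank)
    all_rows = []
    for taxon in by_rank.columns:
        values = by_rank[taxon]
        if (values == 0).all():
            all_rows.append(pd.DataFrame([{
                "contrast": c[0], "taxon": taxon, "p": np.nan,
                "note": "absent from all samples"} for c in contrasts]))
            continue
        res = run_contrasts(values, contrasts).drop(columns=["p_adj", "stars"])
        res.insert(1, "taxon", taxon)
        res["note"] = ""
        all_rows.append(res)
    out = pd.concat(all_rows, ignore_index=True)
    from .stats import bh_adjust, p_stars
    out["p_adj"] = bh_adjust(out["p"])
    out["stars"] = [p_stars(p) for p in out["p_adj"]]
    return out


@dataclass
class SharedAsvReport:
    shared: int
    unique_a: int
    unique_b: int
    shared_asvs: tuple
    shared_ra_a: float  # mean over set-a samples of summed RA of shared ASVs
    shared_ra_b: float

    @property
    def union(self) -> int:
        return self.shared + self.unique_a + self.unique_b


def shared_asvs(ra_table: pd.DataFrame, metadata: pd.DataFrame, set_a, set_b,
                min_ra: float = 0.0005) -> SharedAsvReport:
    """Shared/unique ASVs between two disjoint sample sets at an RA floor.

    An ASV belongs to a set iff its RA reaches ``min_ra`` in at least one
    sample of that set (default 0.05%).
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both sample sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("sample sets must be disjoint")
    in_a = set(ra_table.columns[(ra_table.loc[set_a] >= min_ra).any(axis=0)])
    in_b = set(ra_table.columns[(ra_table.loc[set_b] >= min_ra).any(axis=0)])
    shared = in_a & in_b
    if not in_a or not in_b:
        import warnings
        warnings.warn("a sample set has no ASVs above the RA floor")
    shared_cols = sorted(shared)
    ra_a = float(ra_table.loc[set_a, shared_cols].sum(axis=1).mean()) if shared_cols else 0.0
    ra_b = float(ra_table.loc[set_b, shared_cols].sum(axis=1).mean()) if shared_cols else 0.0
    return SharedAsvReport(len(shared), len(in_a - in_b), len(in_b - in_a),
                           tuple(shared_cols), ra_a, ra_b)
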