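"""ASV-to-GSMM mapping and model-averaged reaction content.

Each genome-scale metabolic model (GSMM) is used purely as a taxon-labelled
reaction set. An ASV is matched to models at the lowest taxonomic rank
(species > genus > family) at which at least one model label equals the ASV's
label after normalization, and its reaction content is the unweighted mean of
binary reaction presence across all matched models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATCH_RANKS = ("species", "genus", "family")


def normalize_label(label) -> str | None:
    """Lowercase, strip, and collapse underscore/whitespace runs so SILVA and
    model-collection label dialects compare equal."""
    if label is None or (isinstance(label, float) and np.isnan(label)) or pd.isna(label):
        return None
    s = " ".join(str(label).replace("_", " ").split()).lower()
    return s or None


def label_components(label, split_composites: bool = True):
    """Composite labels like 'Methylobacterium-Methylorubrum' match on any
    hyphen-separated component when ``split_composites`` is on."""
    norm = normalize_label(label)
    if norm is None:
        return []
    if split_composites and "-" in norm:
        return [c for c in (p.strip() for p in norm.split("-")) if c] or [norm]
    return [norm]


@dataclass
class ModelCollection:
    """Taxon-labelled reaction sets: one row of ``models`` per GSMM (family
    required, genus/species optional) and ``reactions`` mapping model id to
    its reaction-id set."""

    models: pd.DataFrame  # index: model id; columns family, genus, species
    reactions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.models.index.duplicated().any():
            raise ValueError("model ids must be unique")
        if self.models["family"].isna().any():
            bad = self.models.index[self.models["family"].isna()].tolist()
            raise ValueError(f"models missing a family label: {bad}")
        for mid in self.models.index:
            rset = self.reactions.get(mid)
            if not rset:
                raise ValueError(f"model {mid} has an empty reaction set")
            self.reactions[mid] = frozenset(rset)

    def __len__(self) -> int:
        return len(self.models)

    def all_reactions(self) -> set:
        out: set = set()
        for rset in self.reactions.values():
            out |= rset
        return out

    def to_json(self, path) -> None:
        payload = {
            mid: {
                "family": self.models.at[mid, "family"],
                "genus": None if pd.isna(self.models.at[mid, "genus"]) else self.models.at[mid, "genus"],
                "species": None if pd.isna(self.models.at[mid, "species"]) else self.models.at[mid, "species"],
                "reactions": sorted(self.reactions[mid]),
            }
            for mid in self.models.index
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelCollection":
        with open(path) as fh:
            payload = json.load(fh)
        rows, reactions = {}, {}
        for mid, rec in payload.items():
            rows[mid] = {
                "family": rec["family"],
                "genus": rec.get("genus") or pd.NA,
                "species": rec.get("species") or pd.NA,
            }
            reactions[mid] = frozenset(rec["reactions"])
        return cls(pd.DataFrame.from_dict(rows, orient="index"), reactions)


def read_catalog(path) -> pd.Series:
    """Reaction catalog TSV (reaction, pathway) -> Series reaction -> pathway."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def _rank_lookup(collection: ModelCollection, split_composites: bool) -> dict:
    lookup: dict = {rank: {} for rank in MATCH_RANKS}
    for mid in collection.models.index:
        for rank in MATCH_RANKS:
            for comp in label_components(collection.models.at[mid, rank], split_composites):
                lookup[rank].setdefault(comp, []).append(mid)
    return lookup


def match_asv_to_models(taxonomy: pd.DataFrame, collection: ModelCollection,
                        split_composites: bool = True) -> pd.DataFrame:
    """Match each ASV at the lowest resolvable rank.

    Returns a frame indexed by ASV with columns ``rank`` (species/genus/family
    or NA when unmapped), ``n_models`` and ``model_ids`` (tuple).
    """
    lookup = _rank_lookup(collection, split_composites)
    records = []
    for asv in taxonomy.index:
        rank_used, model_ids = pd.NA, ()
        for rank in MATCH_RANKS:  # species first: tier precedence
            hits: list = []
            for comp in label_components(taxonomy.at[asv, rank] if rank in taxonomy else None,
                                         split_composites):
                hits.extend(lookup[rank].get(comp, []))
            if hits:
                rank_used = rank
                model_ids = tuple(dict.fromkeys(hits))  # dedupe, keep order
                break
        records.append({"asv": asv, "rank": rank_used,
                        "n_models": len(model_ids), "model_ids": model_ids})
    return pd.DataFrame(records).set_index("asv")


def asv_reaction_content(matches: pd.DataFrame, collection: ModelCollection,
                         catalog: pd.Series) -> pd.DataFrame:
    """Mean binary reaction presence over each ASV's matched models.

    Entry (a, j) = (#matched models of a containing reaction j) / (#matched
    models of a); only mapped ASVs appear as rows.
    """
    mapped = matches[matches["n_models"] > 0]
    known = set(catalog.index)
    missing = collection.all_reactions() - known
    if missing:
        raise ValueError(f"reactions absent from catalog: {sorted(missing)[:10]}")
    reaction_ids = list(catalog.index)
    col_of = {r: i for i, r in enumerate(reaction_ids)}
    mat = np.zeros((len(mapped), len(reaction_ids)))
    for i, asv in enumerate(mapped.index):
        mids = mapped.at[asv, "model_ids"]
        for mid in mids:
            for r in collection.reactions[mid]:
                mat[i, col_of[r]] += 1.0
        mat[i] /= len(mids)
    return pd.DataFrame(mat, index=mapped.index, columns=reaction_ids)


def mapping_summary(matches: pd.DataFrame) -> dict:
    """Per-tier ASV counts and mean models-per-ASV, plus mapped/unmapped totals."""
    out = {"n_total": int(len(matches))}
    mapped = matches[matches["n_models"] > 0]
    out["n_mapped"] = int(len(mapped))
    out["n_unmapped"] = int(len(matches) - len(mapped))
    for rank in MATCH_RANKS:
        sub = mapped[mapped["rank"] == rank]
        out[f"n_{rank}"] = int(len(sub))
        out[f"mean_models_{rank}"] = float(sub["n_models"].mean()) if len(sub) else 0.0
    return out
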