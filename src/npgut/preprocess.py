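"""Input parsing, taxon/contaminant pruning, sample exclusion, relative abundance.

The cleaning rules mirror standard 16S amplicon practice downstream of
denoising: keep kingdom Bacteria only, prune organellar and cyanobacterial
sequences, drop blocklisted genera (known reagent contaminants such as
Methylobacterium-Methylorubrum), drop singleton ASVs, and exclude samples
with fewer than 1000 reads.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

_SILVA_PREFIXES = {
    "d": "kingdom", "k": "kingdom", "p": "phylum", "c": "class",
    "o": "order", "f": "family", "g": "genus", "s": "species",
}


def parse_silva_label(label: str) -> dict:
    """Split a SILVA-style lineage string ("k__Bacteria;p__Firmicutes;...")
    into the seven canonical rank columns; missing ranks become NA."""
    out: dict = {r: pd.NA for r in RANKS}
    if not isinstance(label, str):
        return out
    for i, part in enumerate(label.split(";")):
        part = part.strip()
        if not part:
            continue
        if "__" in part:
            prefix, _, name = part.partition("__")
            rank = _SILVA_PREFIXES.get(prefix.strip().lower())
        else:
            rank = RANKS[i] if i < len(RANKS) else None
            name = part
        name = name.strip()
        if rank is not None and name:
            out[rank] = name
    return out


def _normalize_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower().strip(): c for c in taxonomy.columns}
    if all(r in cols for r in ("kingdom", "phylum")) or all(
        r in cols for r in ("domain", "phylum")
    ):
        renames = {cols[k]: k for k in cols if k in RANKS}
        if "domain" in cols:
            renames[cols["domain"]] = "kingdom"
        tax = taxonomy.rename(columns=renames)
        for r in RANKS:
            if r not in tax.columns:
                tax[r] = pd.NA
        tax = tax[RANKS].copy()
    elif taxonomy.shape[1] == 1:
        # single SILVA lineage-string column
        col = taxonomy.columns[0]
        tax = pd.DataFrame(
            [parse_silva_label(v) for v in taxonomy[col]], index=taxonomy.index
        )[RANKS]
    else:
        raise ValueError(
            "taxonomy must have per-rank columns (kingdom..species) or a single "
            "SILVA lineage-string column"
        )
    tax = tax.astype("string")
    stripped = tax.apply(lambda col: col.str.strip())
    return stripped.where(stripped.notna() & (stripped != ""), pd.NA)


def read_inputs(count_path, taxonomy_path, metadata_path):
    """Read and cross-validate the count, taxonomy and metadata TSV tables.

    Returns ``(counts, taxonomy, metadata)`` where counts is samples x ASVs.
    Raises ``ValueError`` naming the offending ids on any mismatch.
    """
    counts = pd.read_csv(count_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype="string")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype="string")
    return validate_inputs(counts, taxonomy, metadata)


def validate_inputs(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                    metadata: pd.DataFrame):
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in counts: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated ASV ids in counts: {dups}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative entries in count table")
    taxonomy = _normalize_taxonomy(taxonomy)
    if taxonomy.index.duplicated().any():
        dups = taxonomy.index[taxonomy.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated ASV ids in taxonomy: {dups}")
    missing_tax = counts.columns.difference(taxonomy.index).tolist()
    if missing_tax:
        raise ValueError(f"ASVs missing from taxonomy: {missing_tax}")
    missing_meta = counts.index.difference(metadata.index).tolist()
    if missing_meta:
        raise ValueError(f"samples missing from metadata: {missing_meta}")
    extra = metadata.index.difference(counts.index).tolist()
    if extra:
        warnings.warn(f"metadata rows without counts (ignored): {extra}")
    return counts, taxonomy.loc[counts.columns], metadata.loc[counts.index]


def _matches_contaminant(row) -> bool:
    """Organellar/cyanobacterial contaminant rule: substring 'mitochondria' in
    family, 'chloroplast' in order (SILVA places them there), or phylum equal
    to 'Cyanobacteria' — all case-insensitive, checked at every rank to be
    robust to label-placement differences between database releases."""
    for rank in RANKS:
        val = row.get(rank)
        if pd.isna(val):
            continue
        low = str(val).lower()
        if "mitochondria" in low or "chloroplast" in low:
            return True
        if low == "cyanobacteria":
            return True
    return False


def filter_taxa(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                blocklist=()) -> pd.DataFrame:
    """Prune non-bacterial, contaminant, blocklisted-genus and singleton ASVs.

    Singleton = total count of exactly 1 across all samples. Idempotent.
    """
    taxonomy = _normalize_taxonomy(taxonomy).loc[counts.columns]
    kingdom = taxonomy["kingdom"].astype("string").str.strip().str.lower()
    keep = kingdom == "bacteria"
    contaminated = taxonomy.apply(_matches_contaminant, axis=1)
    keep &= ~contaminated
    if blocklist:
        blocked = {str(b).strip().lower() for b in blocklist}
        genus = taxonomy["genus"].astype("string").str.strip().str.lower()
        keep &= ~genus.isin(blocked).fillna(False)
    keep = keep.fillna(False).astype(bool) & (counts.sum(axis=0) != 1)
    out = counts.loc[:, keep.to_numpy(dtype=bool)]
    if out.shape[1] == 0:
        warnings.warn("all ASVs removed by taxon filtering")
    return out


def filter_samples(counts: pd.DataFrame, min_reads: int = 1000) -> pd.DataFrame:
    """Exclude samples whose total read count is strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = counts.sum(axis=1)
    out = counts.loc[totals >= min_reads]
    if out.shape[0] == 0:
        raise ValueError(f"all samples have fewer than {min_reads} reads")
    return out


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample closure to relative abundances (rows sum to 1)."""
    totals = counts.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")
    return counts.div(totals, axis=0)


def summarize_reads(counts: pd.DataFrame, taxonomy: pd.DataFrame | None = None) -> dict:
    """Per-sample read-depth summary (type-7 linear-interpolation quartiles)
    plus taxonomy-assignment fractions when a taxonomy is supplied."""
    if counts.shape[0] == 0:
        raise ValueError("need at least one sample")
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    out = {
        "n_samples": int(counts.shape[0]),
        "n_asvs": int(counts.shape[1]),
        "total_reads": float(totals.sum()),
        "median_reads": float(np.median(totals)),
        "lower_quartile": float(np.quantile(totals, 0.25)),
        "upper_quartile": float(np.quantile(totals, 0.75)),
    }
    if taxonomy is not None:
        tax = _normalize_taxonomy(taxonomy).loc[counts.columns]
        n = max(counts.shape[1], 1)
        out["frac_genus_assigned"] = float(tax["genus"].notna().sum() / n)
        out["frac_species_assigned"] = float(tax["species"].notna().sum() / n)
    return out
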