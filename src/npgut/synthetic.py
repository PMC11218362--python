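"""Synthetic study-design data: model collections, taxonomies, communities.

Emulates a two-diet (M = marine, V = plant), three-phase (stimulus /
intermediate / challenge) salmon feeding trial: 18 intestinal samples per
group x phase, 3 water samples per group x phase, 3 feed samples per diet.
Counts are Dirichlet-multinomial with per-taxon base concentrations drawn
log-normally (a few dominant taxa, Firmicutes/Proteobacteria-heavy), library
sizes uniform over the study's observed quartile span, and optional planted
effects that multiply the expected relative abundance of chosen taxa in
chosen (group, phase) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gsmm import ModelCollection
from .preprocess import RANKS

DEFAULT_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteriota",
                 "Bacteroidota", "Verrucomicrobiota")
DEFAULT_PHYLUM_PROBS = (0.45, 0.30, 0.12, 0.08, 0.05)
# concentration boosts making expected intestinal composition ~67% Firmicutes
# and ~24% Proteobacteria, as in early-phase salmon gut communities
DEFAULT_PHYLUM_BOOST = {"Firmicutes": 2.2, "Proteobacteria": 1.2}
# water communities are Proteobacteria/Bacteroidota-dominated; feed is
# Firmicutes-heavy (lactic-acid bacteria in the pellets)
SAMPLE_TYPE_BOOST = {
    "intestine": {},
    "water": {"Firmicutes": 0.1, "Proteobacteria": 3.0, "Bacteroidota": 8.0},
    "feed": {"Firmicutes": 2.0, "Proteobacteria": 0.5, "Bacteroidota": 0.2},
}

DEFAULT_MATCH_FRACTIONS = {"species": 0.097, "genus": 0.688,
                           "family": 0.215, "none": 0.0}


@dataclass
class SyntheticDesign:
    """Sampling design of the simulated trial."""

    group_labels: tuple = ("M", "V")
    phase_labels: tuple = ("stimulus", "intermediate", "challenge")
    n_per_cell: int = 18
    n_water_per_cell: int = 3
    n_feed_per_diet: int = 3
    library_size_range: tuple = (7633, 76326)

    def __post_init__(self):
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library sizes must be >= 1 and range non-empty")
        for labels in (self.group_labels, self.phase_labels):
            if len(set(labels)) != len(labels):
                raise ValueError(f"labels must be unique: {labels}")
        if self.n_water_per_cell < 0 or self.n_feed_per_diet < 0:
            raise ValueError("water/feed counts must be >= 0")


@dataclass
class EffectSpec:
    """A planted multiplicative shift of expected relative abundance."""

    affected_taxa: tuple
    affected_cells: tuple  # of (group, phase) pairs
    log_fold_change: float
    affected_pathway: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.log_fold_change):
            raise ValueError("log_fold_change must be finite")
        self.affected_taxa = tuple(self.affected_taxa)
        self.affected_cells = tuple((g, p) for g, p in self.affected_cells)


def generate_model_collection(n_models: int, n_reactions: int, n_pathways: int,
                              seed: int | None = None, genus_prob: float = 0.8,
                              species_prob: float = 0.3,
                              reaction_prob: float = 0.5):
    """Random taxon-labelled reaction sets plus a reaction -> pathway catalog.

    Every model carries a family label; genus and species labels are present
    with the given probabilities. Every reaction belongs to exactly one
    pathway and every model's reaction set is non-empty.
    """
    if n_models < 1 or n_reactions < 1 or n_pathways < 1:
        raise ValueError("n_models, n_reactions and n_pathways must be positive")
    if n_pathways > n_reactions:
        raise ValueError("n_pathways cannot exceed n_reactions")
    rng = np.random.default_rng(seed)
    n_families = max(1, n_models // 3)
    n_genera = max(1, (2 * n_models) // 3)
    rows, reactions = {}, {}
    reaction_ids = [f"R{i + 1:04d}" for i in range(n_reactions)]
    for i in range(n_models):
        fam = f"Family{rng.integers(n_families) + 1}"
        genus = f"Genus{rng.integers(n_genera) + 1}" if rng.random() < genus_prob else pd.NA
        species = (f"{genus} sp{i + 1}"
                   if (pd.notna(genus) and rng.random() < species_prob) else pd.NA)
        rows[f"model_{i + 1:03d}"] = {"family": fam, "genus": genus, "species": species}
        mask = rng.random(n_reactions) < reaction_prob
        if not mask.any():
            mask[rng.integers(n_reactions)] = True
        reactions[f"model_{i + 1:03d}"] = frozenset(
            r for r, m in zip(reaction_ids, mask) if m)
    # first n_pathways reactions pin one pathway each, rest assigned randomly
    pathway_ids = [f"pathway_{i + 1:02d}" for i in range(n_pathways)]
    assignment = list(pathway_ids) + [pathway_ids[rng.integers(n_pathways)]
                                      for _ in range(n_reactions - n_pathways)]
    catalog = pd.Series(assignment, index=reaction_ids, name="pathway")
    catalog.index.name = "reaction"
    collection = ModelCollection(pd.DataFrame.from_dict(rows, orient="index"),
                                 reactions)
    return collection, catalog


def _make_taxonomy(n_taxa: int, rng, match_fractions, collection):
    fracs = dict(match_fractions)
    total = sum(fracs.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"match fractions must sum to 1 (got {total})")
    levels = rng.choice(list(fracs), size=n_taxa, p=list(fracs.values()))
    phyla = rng.choice(DEFAULT_PHYLA, size=n_taxa, p=DEFAULT_PHYLUM_PROBS)
    if collection is not None:
        with_species = collection.models.index[collection.models["species"].notna()]
        with_genus = collection.models.index[collection.models["genus"].notna()]
        if "species" in fracs and fracs["species"] > 0 and len(with_species) == 0:
            raise ValueError("collection has no species-labelled models")
        if "genus" in fracs and fracs["genus"] > 0 and len(with_genus) == 0:
            raise ValueError("collection has no genus-labelled models")
    rows = {}
    for i, (level, phylum) in enumerate(zip(levels, phyla)):
        asv = f"ASV_{i + 1:04d}"
        row = {r: pd.NA for r in RANKS}
        row["kingdom"], row["phylum"] = "Bacteria", phylum
        if collection is None:
            row["family"] = f"Family{i % 40 + 1}"
            if level in ("genus", "species"):
                row["genus"] = f"Genus{i % 120 + 1}"
            if level == "species":
                row["species"] = f"Genus{i % 120 + 1} sp{i + 1}"
            if level == "none":
                row["family"] = f"NovelFamily{i + 1}"
        else:
            if level == "species":
                mid = rng.choice(with_species)
            elif level == "genus":
                mid = rng.choice(with_genus)
            elif level == "family":
                mid = rng.choice(collection.models.index)
            else:
                mid = None
            if mid is None:
                row["family"] = f"NovelFamily{i + 1}"
            else:
                row["family"] = collection.models.at[mid, "family"]
                if level in ("genus", "species"):
                    row["genus"] = collection.models.at[mid, "genus"]
                if level == "species":
                    row["species"] = collection.models.at[mid, "species"]
        rows[asv] = row
    return pd.DataFrame.from_dict(rows, orient="index")[RANKS]


def generate_community(design: SyntheticDesign,
                       match_fractions: dict | None = None,
                       effects=(), seed: int | None = None,
                       collection: ModelCollection | None = None,
                       n_taxa: int = 300, concentration: float = 60.0,
                       lognormal_sigma: float = 1.0,
                       taxonomy: pd.DataFrame | None = None,
                       base_concentrations: np.ndarray | None = None):
    """Dirichlet-multinomial community for the full sampling design.

    Returns ``(counts, taxonomy, metadata)``. Effects multiply the Dirichlet
    concentration (hence expected RA, before renormalization) of their taxa
    in intestinal samples of their (group, phase) cells by exp(lfc).
    A pre-built ``taxonomy`` and/or ``base_concentrations`` may be supplied to
    pin the community structure exactly (used by planted-effect scenarios).
    """
    rng = np.random.default_rng(seed)
    if taxonomy is None:
        taxonomy = _make_taxonomy(n_taxa, rng,
                                  match_fractions or DEFAULT_MATCH_FRACTIONS,
                                  collection)
    asvs = list(taxonomy.index)
    n_taxa = len(asvs)
    phyla = taxonomy["phylum"].astype(object).to_numpy()

    if base_concentrations is None:
        alpha = rng.lognormal(0.0, lognormal_sigma, size=n_taxa)
        boost = np.array([DEFAULT_PHYLUM_BOOST.get(p, 0.5) for p in phyla])
        alpha = alpha * boost
        alpha = alpha / alpha.sum() * concentration
    else:
        alpha = np.asarray(base_concentrations, dtype=float)
        if alpha.shape != (n_taxa,):
            raise ValueError("base_concentrations must have one entry per taxon")

    cells = {(g, p) for g in design.group_labels for p in design.phase_labels}
    asv_pos = {a: i for i, a in enumerate(asvs)}
    for eff in effects:
        unknown = [t for t in eff.affected_taxa if t not in asv_pos]
        if unknown:
            raise ValueError(f"effect names unknown taxa: {unknown}")
        bad = [c for c in eff.affected_cells if c not in cells]
        if bad:
            raise ValueError(f"effect names unknown (group, phase) cells: {bad}")

    lo, hi = design.library_size_range
    meta_rows, count_rows, ids = [], [], []

    def draw(alpha_vec):
        depth = int(rng.integers(lo, hi + 1))
        return rng.multinomial(depth, rng.dirichlet(alpha_vec))

    def type_alpha(sample_type):
        boost = SAMPLE_TYPE_BOOST.get(sample_type, {})
        if not boost:
            return alpha
        return alpha * np.array([boost.get(p, 1.0) for p in phyla])

    for group in design.group_labels:
        for phase in design.phase_labels:
            cell_alpha = type_alpha("intestine").copy()
            for eff in effects:
                if (group, phase) in eff.affected_cells:
                    idx = [asv_pos[t] for t in eff.affected_taxa]
                    cell_alpha[idx] *= np.exp(eff.log_fold_change)
            for k in range(design.n_per_cell):
                ids.append(f"I_{group}_{phase}_{k + 1:02d}")
                meta_rows.append({"group": group, "phase": phase,
                                  "sample_type": "intestine"})
                count_rows.append(draw(cell_alpha))
            water_alpha = type_alpha("water")
            for k in range(design.n_water_per_cell):
                ids.append(f"W_{group}_{phase}_{k + 1:02d}")
                meta_rows.append({"group": group, "phase": phase,
                                  "sample_type": "water"})
                count_rows.append(draw(water_alpha))
    for group in design.group_labels:
        feed_alpha = type_alpha("feed")
        for k in range(design.n_feed_per_diet):
            ids.append(f"F_{group}_{k + 1:02d}")
            meta_rows.append({"group": group, "phase": pd.NA,
                              "sample_type": "feed"})
            count_rows.append(draw(feed_alpha))

    counts = pd.DataFrame(np.asarray(count_rows, dtype=np.int64),
                          index=ids, columns=asvs)
    metadata = pd.DataFrame(meta_rows, index=ids).astype("string")
    return counts, taxonomy, metadata


@dataclass
class PlantedScenario:
    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    collection: ModelCollection
    catalog: pd.Series
    planted_reactions: tuple
    target_pathway: str
    effect: EffectSpec | None
    affected_taxa: tuple = field(default_factory=tuple)


def planted_scenario(seed: int | None = None, n_taxa: int = 200,
                     n_affected: int = 40, n_reactions: int = 500,
                     n_planted: int = 50, affected_share: float = 0.02,
                     concentration: float = 100.0, lfc: float = 1.0,
                     n_per_group: int = 18, null: bool = False,
                     carriage_prob: float = 0.8) -> PlantedScenario:
    """Two-group, one-phase community with reaction-level planted signal.

    One model per taxon (matched at species level). Planted reactions are
    carried only by models of the affected taxa (each with probability
    ``carriage_prob``); null reactions are carried by any model independently
    with probability 0.5. The target pathway holds 80% of the planted
    reactions plus a small null complement; null reactions fill the other
    pathways. With ``null=True`` no effect is planted (calibration runs).
    """
    rng = np.random.default_rng(seed)
    asvs = [f"ASV_{i + 1:04d}" for i in range(n_taxa)]
    reaction_ids = [f"R{i + 1:04d}" for i in range(n_reactions)]
    planted = reaction_ids[:n_planted]
    nulls = reaction_ids[n_planted:]
    affected = tuple(asvs[:n_affected])

    tax_rows, model_rows, model_reactions = {}, {}, {}
    phyla = rng.choice(DEFAULT_PHYLA, size=n_taxa, p=DEFAULT_PHYLUM_PROBS)
    for i, asv in enumerate(asvs):
        fam, gen, spc = f"Fam{i % 20 + 1}", f"Gen{i + 1}", f"Gen{i + 1} sp{i + 1}"
        tax_rows[asv] = {"kingdom": "Bacteria", "phylum": phyla[i],
                         "class": pd.NA, "order": pd.NA,
                         "family": fam, "genus": gen, "species": spc}
        model_rows[f"model_{i + 1:03d}"] = {"family": fam, "genus": gen, "species": spc}
        rset = {r for r in nulls if rng.random() < 0.5}
        if asv in affected:
            rset |= {r for r in planted if rng.random() < carriage_prob}
        if not rset:
            rset = {nulls[int(rng.integers(len(nulls)))]}
        model_reactions[f"model_{i + 1:03d}"] = frozenset(rset)
    # make sure every planted reaction is carried by at least one affected model
    for j, r in enumerate(planted):
        mid = f"model_{(j % n_affected) + 1:03d}"
        model_reactions[mid] = model_reactions[mid] | {r}

    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")[RANKS]
    collection = ModelCollection(pd.DataFrame.from_dict(model_rows, orient="index"),
                                 model_reactions)
    target = "pathway_target"
    n_in_target = int(round(0.8 * n_planted))
    assignment = {}
    for r in planted[:n_in_target]:
        assignment[r] = target
    null_background = [f"pathway_{i + 1:02d}" for i in range(9)]
    for r in planted[n_in_target:]:
        assignment[r] = null_background[int(rng.integers(9))]
    for j, r in enumerate(nulls):
        assignment[r] = target if j < 10 else null_background[j % 9]
    catalog = pd.Series([assignment[r] for r in reaction_ids],
                        index=reaction_ids, name="pathway")
    catalog.index.name = "reaction"

    base = rng.lognormal(0.0, 1.0, size=n_taxa)
    # pin the affected block to exactly `affected_share` of total concentration
    s_unaffected = base[n_affected:].sum()
    base[:n_affected] *= (affected_share / (1.0 - affected_share)
                          * s_unaffected / base[:n_affected].sum())
    base = base / base.sum() * concentration

    design = SyntheticDesign(phase_labels=("stimulus",), n_per_cell=n_per_group,
                             n_water_per_cell=0, n_feed_per_diet=0)
    effect = None if null else EffectSpec(affected, (("V", "stimulus"),), lfc)
    counts, taxonomy, metadata = generate_community(
        design, effects=() if null else (effect,),
        seed=int(rng.integers(2 ** 31)), taxonomy=taxonomy,
        base_concentrations=base)
    return PlantedScenario(counts, taxonomy, metadata, collection, catalog,
                           tuple(planted), target, effect, affected)


def write_dataset(outdir, counts, taxonomy, metadata,
                  collection=None, catalog=None) -> None:
    """Write the generated tables in the same formats the pipeline reads."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    if collection is not None:
        collection.to_json(outdir / "models.json")
    if catalog is not None:
        catalog.to_frame().to_csv(outdir / "reactions.tsv", sep="\t")
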