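# Methods

This note documents the models, conventions and design choices behind
`npgut`, in the spirit of the methods documentation of statsmodels or
scanpy: what each procedure assumes, which knobs matter, and where the
implementation had to make a call that the underlying methodology leaves
open.

## Preprocessing

Taxon filtering keeps ASVs whose kingdom is Bacteria and removes
organellar/cyanobacterial contaminants. Contaminant matching is
case-insensitive: a substring match on "mitochondria" or "chloroplast" at
any rank (SILVA places these at family and order, but database releases
move them), plus exact phylum equality with "Cyanobacteria". A user-supplied
genus blocklist covers reagent contaminants curated by hand (e.g.
*Methylobacterium-Methylorubrum*); a statistical contaminant classifier is
deliberately out of scope. A **singleton** is an ASV with total count
exactly 1 across all samples — the standard frequency-based reading; the
boundary is sharp (total 2 is kept).

Samples with fewer than 1000 reads are excluded, strictly ("less than"),
and *after* taxon filtering. The methodology does not dictate an order;
taxa-then-samples is used and matters only for samples near the cutoff.
Read-depth quartiles use linear interpolation (type 7, the numpy/R default)
so summaries are reproducible elsewhere.

## SRS normalization and alpha diversity

SRS scales each sample's counts to a common total C_min (by default the
minimum sample total), keeps integer parts, and assigns the remaining
C_min − Σ⌊scaled⌋ reads one each to the taxa with the largest fractional
parts. Fractional-part ties are broken uniformly at random with a recorded
seed; the published procedure permits any tie rule and the seed is stored
in the result object so a run is exactly repeatable. Two invariants are
enforced by tests: every sample sums to exactly C_min, and a taxon with a
strictly larger count never receives fewer normalized reads than a smaller
one in the same sample.

Shannon–Weiner diversity uses natural logarithms (nats), the
`estimate_richness` convention. When different sample types (gut, water,
feed) are compared, normalization is done within the subset being compared,
since a shared C_min across types would be dominated by the shallowest type.

Mann–Whitney–Wilcoxon tests are two-sided; the exact null distribution is
used when both groups have n ≤ 8 and the pooled data is tie-free, otherwise
the normal approximation with tie and continuity corrections. All contrasts
submitted together form one BH family.

## Distances, ordination and permutation tests

Bray–Curtis is computed after a per-entry log1p transform by default
("natural-log-transformed Bray–Curtis"); transforming the distance matrix
itself would break the [0, 1] and non-negativity contracts, so the
transform is applied to abundances, with `transform="none"` available.

The robust Aitchison distance is the Euclidean distance between rclr
vectors: within each sample, log of each nonzero count minus the mean log
over that sample's nonzero counts, zeros left at zero. No phylogenetic
information enters the distance; tree-aware variants are out of scope.

PCoA is classical metric scaling: Gower double-centering of −½d², exact
eigendecomposition, coordinates scaled by √λ. Negative eigenvalues are
reported, and their axes retained separately rather than dropped.

PERMANOVA follows the McArdle–Anderson trace formulation: the explained sum
of squares of a model with hat matrix H is tr(HG) where G is the
Gower-centered matrix; two-factor formulas use sequential (Type I) sums of
squares in the order written, with the interaction after the main effects.
Permutation is free relabeling of samples (no strata), p = (#{F* ≥ F} + 1) /
(n_perm + 1) with a relative tolerance of 1e-9 on the comparison so that
permutations reproducing the observed statistic (exact relabelings of a
perfect separation) count as exceedances — without it, floating-point jitter
halves the p-value in degenerate cases. The one-factor statistic is
cross-checked against scikit-bio in the test suite.

PERMDISP embeds samples by PCoA (keeping negative-eigenvalue axes),
computes each sample's distance to its group center with the imaginary-axis
correction d² = d²₊ − d²₋ (clamped at 0), and applies a one-way F test.
The center is the spatial median (Weiszfeld's algorithm) by default,
centroid optionally; bias adjustment is off. The permutation p shuffles
group labels over the fixed distance-to-center vector (the
`permutest.betadisper` behaviour) rather than recomputing centers per
permutation — cheaper and, for the homogeneity null, equivalent in spirit.

Pairwise PERMANOVA runs one test per level pair on the subset of samples,
skips pairs containing a single-sample level, and BH-adjusts across pairs.
Whether the omnibus tests should join that family is left to the caller;
by default only the pairwise set is corrected.

## Composition summaries

Taxa are aggregated at a chosen rank; ASVs unassigned at that rank fall
back to the lowest assigned higher rank and are labelled e.g. "undefined
genera of family Ruminococcaceae". Top-k ranking uses the mean RA within
the displayed cell (the ranking statistic is otherwise arbitrary); the
remainder is pooled into OTHERS, so total RA is conserved exactly.

Shared-ASV reports use a per-sample RA floor (default 0.05%): an ASV
belongs to a sample set iff its RA reaches the floor in at least one sample
of that set. The "shared relative abundance" of a set is the per-sample sum
of shared-ASV RAs averaged over that set's samples — one of several
defensible readings, stated here so the numbers are interpretable.

## GSMM mapping and reaction statistics

Models are taxon-labelled reaction sets; stoichiometry and flux are
ignored. An ASV is matched at the lowest rank (species, then genus, then
family) at which at least one model label equals the ASV's label after
normalization (lowercase, trimmed, underscores = spaces). Composite genus
labels ("A-B") match on any hyphen component; this is configurable. Exact
equality after normalization — rather than fuzzy matching — is a deliberate,
conservative choice.

Reaction content is the unweighted mean of binary reaction presence over
matched models, so content ∈ [0, 1] and equals 1 iff the reaction is
universal among matched models. Duplicating matched models or adding models
that match nothing cannot change content (tested invariants). Sample-level
reaction abundance is the RA-weighted sum of content over mapped ASVs;
unmapped ASVs contribute nothing and the abundances are therefore on the
same (dimensionless, relative) scale across samples — which is also why the
per-reaction t-statistics are invariant to sequencing depth.

Differential reactions use the pooled-variance two-sample t-test by default
(the historical default of the standard two-sample routine), Welch by flag;
reactions with zero variance in both groups and equal means are excluded
with a recorded reason. BH runs within each contrast, never pooled across
contrasts. Pathway enrichment is a one-sided ("greater") Fisher exact test
on {significant, not} × {in pathway, not}, BH over pathways, enriched at
adjusted p ≤ 0.05; enrichment, not depletion, is the question being asked,
and the two-sided variant is a flag. A per-pathway mean t with a
normal-theory 95% CI over member reactions is provided as a display
summary; it is an interpretation, not a test.

PCA standardizes columns to z-scores (dropping zero-variance columns with a
report) and uses a full SVD; all retainable components are kept, so
explained-variance fractions sum to 1.

## Synthetic data

The generator emulates the feeding-trial design: 2 diet groups × 3 phases
× 18 intestinal samples, 3 water samples per group × phase, 3 feed samples
per diet; library sizes uniform over [7,633, 76,326] (the observed
quartile span of such runs). Counts are Dirichlet-multinomial: per-taxon
concentrations drawn log-normally (σ = 1), scaled by phylum factors so the
expected intestinal composition is ~67% Firmicutes / ~24% Proteobacteria,
with water shifted toward Proteobacteria/Bacteroidota and feed toward
Firmicutes; total concentration 60 gives realistic overdispersion. Planted
effects multiply the Dirichlet concentration (hence expected RA before
renormalization) of chosen taxa in chosen (group, phase) cells by exp(lfc)
— the multiplicative form matches how diet-driven RA shifts are described.
Taxonomies link configurable fractions of ASVs to the model collection at
species/genus/family, or to no model at all. Feed samples carry no phase
(they predate the trial), stored as NA.

What the generator does *not* emulate: sequencing error, chimeras,
phylogenetic structure, taxon-taxon interaction networks, or zero
inflation beyond what the Dirichlet-multinomial produces. Passing tests
therefore demonstrate statistical correctness of the pipeline under a
well-specified overdispersed compositional model, not robustness to every
artefact of real amplicon data.

The planted-reaction scenario used for calibration and recovery places a
guild of 40 rare taxa (2% of total concentration, total concentration 100,
one species-matched model each) behind 50 of 500 reactions (carriage
probability 0.8 within the guild; null reactions carried by any model with
probability 0.5; a target pathway holds 80% of the planted reactions plus
10 null ones). The geometry matters: because null reactions are carried
broadly, the renormalization shift induced by the guild largely cancels in
their abundances, keeping them honestly null; a power analysis for this
design gives per-planted-reaction effect sizes around 1.5 SD at n = 18 per
group. Under the null variant the per-reaction t-test rejects 5.0% at
α = 0.05 and PERMANOVA/PERMDISP hold their nominal type-I error — all
recomputed by the test suite and `scripts/acceptance.py`, never asserted
from memory.

## Problem sizes

Defaults were chosen so the whole test suite and the acceptance script each
run in about a minute on one CPU: communities of 150–300 taxa, 400–500
reactions, 999 permutations for single permutation tests, 100–200 replicate
datasets for calibration experiments, and 20–100 seeds for recovery
experiments. All of these scale up linearly if heavier validation is
wanted.

## Known limitations

- Matching is label-based; it inherits whatever disagreements exist between
  the taxonomy's and the model collection's nomenclature.
- Reaction content ignores model quality, genome completeness and copy
  number; an ASV matched to many models is averaged, not curated.
- The PERMDISP permutation scheme fixes distances to centers; with very
  unbalanced groups the full recomputation variant can differ.
- Sequential PERMANOVA sums of squares depend on term order in unbalanced
  designs, as in any Type I decomposition.
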