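# Methods

## Scope and assumptions

`myxotax` operates on a pre-aligned collection of near-full-length 16S
rRNA gene sequences with per-sequence isolation metadata.  Alignment
(e.g. MAFFT) and tree inference (e.g. FastTree) are upstream concerns:
the pipeline consumes an aligned FASTA and, optionally, a rooted Newick
tree.  Taxonomic pre-screening against a reference classifier and
chimera removal are likewise assumed to have happened upstream; the QC
stage only enforces length and ambiguity criteria and records that
assumption in its interface.

## Quality control

Two filters, applied in order:

* **Minimum length** — default 1200 ungapped bases, the conventional
  near-full-length cutoff for 16S surveys.  Length is measured on
  ungapped residues so a record passes or fails identically whether it
  arrives aligned or unaligned.
* **Ambiguity ratio** — the fraction of non-gap residues that are not
  unambiguous A/C/G/T must be *strictly* below 0.002 (the equivalent of
  fewer than three ambiguous bases per 1500); a sequence at exactly
  3/1500 is rejected.  All IUPAC ambiguity codes count; U is normalised
  to T on ingest.

Duplicate deposits of one strain (shared `strain_key`) are collapsed to
the longest high-quality sequence; length ties are broken by the
lexicographically smallest id, a convention chosen purely to make the
result deterministic.  A record failing both filters is reported once,
as `too_short`, because length is checked first.

## Distances

All pairwise comparisons use **pairwise deletion**: for each pair, only
columns in which both residues are unambiguous A/C/G/T are compared.
This preserves per-pair information relative to complete deletion and
matches the behaviour of common identity tools.  Identity is matches
over compared sites.  The Kimura two-parameter distance

d = −½·ln((1 − 2P − Q)·√(1 − 2Q))

distinguishes transitions (proportion P) from transversions (Q).  When
a log argument is non-positive the pair is saturated and the distance
is undefined; the default is to raise, and callers may instead supply a
cap.  A pair with no compared sites is always an error.

Matrix computation is vectorised through one-hot matrix products
(float32 matmuls are exact for these integer counts and are promoted to
float64 before division), and tested against the scalar per-pair
implementation.

## Rank delineation

Two sequences at or below 97.0% identity are treated as distinct
species; 94.5%, 89.0% and 85.0% play the same role for genera,
families and suborders.  Three choices are deliberate:

* **Complete linkage.** No clustering algorithm is implied by a bare
  threshold criterion; complete-linkage agglomeration is used because
  it is the only standard linkage under which membership of a cluster
  *guarantees* the pairwise statement — every within-taxon pair has
  identity strictly greater than the rank threshold.  The guarantee is
  asserted by the test suite on every clustering run.
* **Strict boundary.** Identity exactly equal to a threshold separates
  ("97.0% or lower" means distinct), so co-membership requires identity
  strictly greater than the cutoff.
* **Top-down nesting.** Suborders are clustered first on the full
  matrix; each suborder is then re-clustered at the family cutoff, and
  so on.  Nesting of the four partitions holds by construction, with no
  reconciliation step.

Agglomeration merges, at each step, the pair of clusters with the
highest complete-linkage identity; ties are broken by the smallest
member id of the pair (then the other cluster's smallest id).  This
makes the partition deterministic and independent of input order, and
is validated against a brute-force enumerator that explores every tie
order on small instances.

**Tree refinement** (optional): working from species upward, any taxon
whose members are not exactly the leaf set of a clade in the rooted
guide tree is split into its maximal monophyletic member groups.
Refinement only ever splits — merging could violate the within-taxon
identity guarantee — and the split of a deeper rank always lands inside
a single refined parent, so nesting survives.

**Naming.** Suborders containing a user-supplied anchor id take the
anchor's name (the classical suborders *Sorangiineae*,
*Cystobacterineae* and *Nannocystaceae* are the intended use);
remaining suborders are numbered `Suborder_N` by decreasing size, ties
by smallest member id, with anchored suborders skipped by the
numbering.  Families, genera and species are numbered within their
parent in the same order, giving hierarchical names such as
`Sorangiineae_Family_2_Genus_5_Species_1`.

The per-suborder summary table reports family/genus/species counts,
sequence counts and percentages (two decimals, round half to even) with
a totals row; the same builder accepts externally supplied per-suborder
counts, which is how the bundled published census is summarised.

## Biogeography

Ten fixed environmental categories are used (M_organism, M_sediment,
Seawater, Soil, T_sediment, Activated_sludge, T_organism, Freshwater,
Human, The_unknown).  All boundary comparisons are inclusive, following
the wording of the criteria:

* **Abundance** — a suborder with sequence share ≥ 0.5% is abundant.
* **Specificity** — a taxon with ≥ 5 observations, of which ≥ 80% fall
  in a single category, is a specialist; anything else — including taxa
  with fewer than five observations — is cosmopolitan (no third class).
  `The_unknown` counts toward both the observation total and dominance
  by default; a flag excludes it from both when unknown-origin records
  should not influence the call.

Distribution matrices (taxon × category counts per rank), the per-rank
specialist/cosmopolitan profile, and culturability breakdowns
(percentages per environment, global counts, per-suborder counts) are
all plain tables; geographic coordinates pass through to output only.

## Rarefaction

Expected richness in a uniform subsample of size *n* from a group with
species abundances N₁..N_S is the analytic hypergeometric form
E[Sₙ] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)), evaluated with log-gamma
arithmetic so large binomials never overflow.  The analytic curve is
deterministic; a seeded Monte-Carlo subsampler exists solely as an
independent oracle in the tests, where the two are required to agree
within three standard errors.  Species identity for rarefaction is the
pipeline's own species partition (the 97% rank), not a separate
clustering.  Good's coverage is 1 − F₁/N.

## Synthetic communities

The generator exists to make every stage testable with known truth.
Default shape: 4 suborders × 2 families × 2 genera × 2 species × 7
sequences = 224 sequences of length 1400 — large enough to exercise
every stage, small enough that the whole pipeline and test suite run in
seconds on one CPU.  A root sequence is mutated top-down; each edge
applies a fixed, calibrated number of substitutions (transition:
transversion weight κ = 2) at sites chosen without replacement.

* **Identity bands.**  Target pairwise-identity intervals per pair
  class: within species [0.985, 1.0]; between species within a genus
  [0.950, 0.965]; between genera [0.905, 0.935]; between families
  [0.860, 0.882]; between suborders [0.70, 0.84].  Every band is
  separated from every delineation threshold by at least 0.005
  identity, and edge substitution counts are solved from the band
  centres given the expected contribution of deeper levels.
* **Within-suborder additivity.**  All edges below one suborder draw
  from disjoint site sets, so pairwise differences inside a suborder
  are exactly additive and realized identities sit inside their bands
  by construction.  Across suborders, independent subtrees may mutate
  the same site; the wide between-suborder band absorbs the resulting
  slack.  Realized identities are audited after generation and a
  violating community is regenerated from a derived seed (the audit is
  also exported with the truth).
* **Environments.**  At one rank (species by default) each taxon is
  flagged specialist with probability `specialist_fraction` (default
  0.5).  Specialist taxa place ≥ 90% of members in one home category
  (drawn from the global weights); cosmopolitan taxa draw members from
  the global weights and are redrawn if they accidentally satisfy the
  specificity criterion, so the planted class is exactly what the
  classifier recovers.  The global weights mirror the published
  composition of the real collection (soil-dominated at ~59%, ~9%
  marine organisms, ~7% marine sediments, …), and culturability is
  drawn from its global proportions (~22% cultured, ~78% uncultured).
* **Determinism.**  Everything derives from the spec's seed; the same
  seed gives byte-identical FASTA, metadata, truth JSON and Newick.

What the generator does **not** emulate: rate heterogeneity across
sites, indels and alignment error (gap/ambiguity injection is off by
default), intra-genomic 16S copy variation, geographic structure, and
any correlation between habitat and phylogeny.  Passing the recovery
tests therefore shows that the delineation machinery is correct under
clean band-separated divergence — not that real, noisy data will be
partitioned with the same fidelity near the thresholds.

## Numerical and degenerate-input conventions

Percentages are rounded half-to-even to two decimals.  A single
sequence is one taxon at every rank.  An empty input to the QC filter
yields empty outputs; an all-gap sequence, a pair with no compared
sites, an all-zero environment vector and a zero total are all explicit
errors rather than silent defaults.  Clustering tie-breaks and dedupe
tie-breaks are by smallest id, everywhere, so reruns and input
permutations give identical partitions.

## Known limitations

* Complete linkage is order-independent but threshold-sharp: real
  datasets with pairs lying exactly on a cutoff will split, which is
  the documented boundary semantics but may surprise users of
  average-linkage OTU tools.
* Tree refinement formalises one reading of manual, tree-guided
  curation (split non-monophyletic taxa, never merge); other curation
  styles are out of scope.
* The K2P distance is reported for audit but the rank thresholds apply
  to raw identity; users whose thresholds are defined on corrected
  distances should transform before clustering.
* Rarefaction assumes exchangeable sequences within a group; no
  extrapolation (Chao1 and relatives) is provided.
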