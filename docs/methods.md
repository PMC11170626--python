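# Methods

## Problem and data model

The package analyses a curated library of food chemicals and natural
products, each annotated with a binary *epigenetic activity profile*: one bit
per target in a fixed panel of 46 epigenetic proteins (8 writers — DNMTs,
HATs, EZH2, PRMT1; 37 erasers — HDACs, sirtuins, LSD1/KDMs; 1 reader —
BET/BRD4). A set bit records that activity against that target has been
reported in the literature; a zero bit means *no report*, which may be
"untested" rather than "inactive". This asymmetry drives two design choices:

* compounds with an all-zero specific profile are retained (flagged
  `profile_incomplete`), because absence of annotation is information about
  the literature, not the molecule;
* pairs of compounds that look like activity cliffs are reported as
  **pseudo**-activity cliffs, and any pair involving a profile-incomplete
  compound is carried in a separate annex.

Family-level "general activity" flags (activity reported only against, e.g.,
"HDACs") are stored separately and excluded from all per-protein statistics;
the populations are reported side by side instead.

## Similarity

One metric is used throughout: the Jaccard–Tanimoto coefficient
`|A∩B| / |A∪B|` on bit vectors — structural fingerprints and activity
profiles share a single implementation. Four fingerprints are computed:
MACCS keys (RDKit's 167-bit layout; bit 0 is unused, so the 166 dictionary
keys are intact), Morgan radius 2 (ECFP4) and radius 3 (ECFP6) hashed to
2048 bits, and the RDKit path-based topological fingerprint (paths 1–7,
2048 bits). 2048 bits is the ecosystem default; at a few hundred compounds
hash collisions are negligible.

`Tanimoto(∅, ∅)` is defined as 0.0 and flagged `undefined`. A defined value
is required because all compound pairs are classified, including pairs of
unannotated compounds; 0 is the conservative choice for cliff detection
(it can only create *pseudo* cliffs, which the annex mechanism exposes).

For `n` compounds there are `n(n+1)/2` pairs including self-comparisons and
`n(n−1)/2` excluding them; all distributions and thresholds below use the
without-self convention (self-pairs are not comparisons), with sample
(n−1 denominator) standard deviations.

## Scaffold diversity

Scaffolds follow the Bemis–Murcko definition (ring systems plus linkers,
side chains removed), via RDKit's MurckoScaffold. Acyclic molecules map to
the EMPTY scaffold and are excluded from the cyclic-system-recovery (CSR)
curve and, by default, from frequency denominators (`ring_bearing_only`);
the `all_compounds` convention is available and reported.

The CSR curve accumulates scaffolds in descending frequency (ties broken by
ascending canonical SMILES for determinism) and plots the fraction of
scaffolds consumed against the fraction of compounds recovered. The AUC is
the trapezoidal rule on the uniform scaffold grid, evaluated in exact
integer arithmetic as `(2·ΣCᵢ + N) / (2MN)` (Cᵢ = cumulative compound
counts), so the maximally diverse library yields exactly 0.5. The
single-scaffold library (M = 1) is assigned AUC = 1.0 by convention — the
curve degenerates to a vertical line. AUC lies in [0.5, 1.0] and is 0.5 iff
every scaffold occurs once.

A caution established by the property tests: AUC is monotone under
*concentration* (moving a compound from a poorer to a richer scaffold at
fixed M, N — a majorization step) but **not** under *merging* two scaffolds,
which shrinks the scaffold axis and can lower the AUC (counts [5,1,1] →
[6,1] drops 29/42 → 19/28). AUC comparisons across libraries with different
scaffold counts should be read accordingly.

## SAS maps and consensus pseudo-cliffs

For every pair, activity-profile similarity (y) is plotted against
structural similarity (x), one map per fingerprint. Thresholds partition the
map into four regions: the structural threshold is `mean + 2·SD` of that
fingerprint's without-self pairwise distribution (capped at 1.0 with a
warning; a zero-variance distribution is an error), the activity threshold
is fixed at 0.1. Region II (smooth SAR) requires strictly greater structural
similarity and activity similarity > 0.1; region IV (pseudo-cliffs) requires
strictly greater structural similarity and activity ≤ 0.1; regions I/III are
the low-structural-similarity counterparts. Because the structural threshold
is recomputed per fingerprint, the four maps are comparable in spirit but
not in threshold value; *consensus* pairs — assigned the same region under
all four fingerprints — are the robust output, sorted by mean structural
similarity.

Raising the activity threshold can only move pairs II→IV and I→III
(monotone reclassification), and region counts always partition the
`n(n−1)/2` pairs; both are property-tested.

## Chemical space

Descriptors are the full canonical RDKit descriptor list (~210 in current
releases; the count is recorded per run since it varies with the backend
version). Failed or non-finite descriptor values are imputed by column
median and logged; constant columns are dropped and logged. Columns are
z-scored before embedding — descriptor units are heterogeneous and would
otherwise dominate Euclidean distances. The 2-D embedding is t-SNE with PCA
initialisation, default perplexity 30 (reduced automatically for small
inputs), 1000 iterations, fixed default seed 42; an optional PCA
pre-reduction is available for speed. t-SNE coordinates are meaningful only
topologically, so the embedding is validated by properties — fixed-seed
determinism and preservation of coarse cluster structure (k-NN label purity
on well-separated synthetic clusters) — not by coordinate reproduction. An
optional reference SMILES set is overlaid by standardising on the union and
carrying a set label.

## Synthetic library generator

The generator emulates the structure of a curated natural-product library
without reproducing its chemistry:

* **Scaffolds.** Compounds are built by decorating ring-system templates
  (28 common ring systems, extended deterministically with linked two-ring
  variants when more scaffolds are requested) with small inert substituents
  (methyl, hydroxyl, fluoro, methoxy) on ring carbons, each anchor used at
  most once. Every product's Bemis–Murcko scaffold is verified to equal its
  template at generation time, so scaffold assignments are exact by
  construction.
* **Scaffold sizes** follow Zipf weights `k^−s` (`s` =
  `scaffold_concentration`, 0 = uniform) through a deterministic
  largest-remainder allocation after guaranteeing one compound per scaffold;
  counts are assigned, never sampled.
* **Profiles.** Each scaffold draws a base profile (Bernoulli
  `base_profile_density` per target); each compound flips each base bit
  independently with probability `noise_rate`. Profile similarity is thereby
  coupled to scaffold membership.
* **Reproducibility.** One seed is split (`SeedSequence.spawn`) into
  independent structure and profile streams; generation is a pure function
  of the spec.

Defaults: 46 targets, density 0.1 (≈4–5 targets per scaffold profile,
matching the sparse multi-target annotation of real epigenetic food-chemical
data), noise 0.05, concentration 1.0 (mid-range CSR AUC, comparable to a
real curated library), `n_scaffolds = n_compounds/2` (the real library's
scaffold-to-compound ratio is close to 1:2).

`expected_profile_similarity` gives the exact expected Jaccard similarity of
two profiles under this model, by enumeration over the per-bit joint
distribution and the (intersection, union) counting law, *conditional on the
pair being defined* (non-empty union) — consistent with how empirical means
treat the flagged convention. A property worth knowing: for sparse profiles
the expectation is **not** monotone in the flip rate — at `ε = 0.5` both
profiles are dense coin flips and the expected Jaccard rebounds toward 1/3,
above its `ε = 0.3` value whenever density ≲ 0.3. Monotonicity checks of the
noise mechanism are therefore run at density 0.5, where monotonicity
provably holds; the rebound itself is unit-tested against the closed form.

What a green synthetic test does **not** establish: the generator makes no
attempt at drug-likeness, realistic property distributions, or the real
panel's target correlations; real scaffold tables also contain acyclic
compounds and far more heterogeneous decoration than the four inert
substituents used here.

## Numerical and degenerate-input choices

* Thresholds: sample SD everywhere; structural thresholds capped at 1.0 with
  a warning; constant distributions raise instead of producing a vacuous
  threshold.
* Ties: scaffold ordering by descending count then ascending SMILES;
  target-frequency ties keep panel order; multi-target ranking ties are
  alphabetical by compound name.
* Degenerate inputs: a library with no ring-bearing compound has no CSR
  curve (error); Tanimoto of two empty vectors is 0.0 + flag; empty activity
  cells read as 0 but are counted in the data-quality report (a 0 here means
  "no reported activity").
* Validation is total: every CSV row becomes either a record or a reported
  row-level issue; malformed InChIKeys are warnings (structures are compared
  by canonical SMILES, not InChIKey).

## Known limitations

* The activity model is strictly binary presence-of-report; no potencies.
* No tautomer/charge standardisation beyond SMILES canonicalisation.
* The SAS consensus depends on per-fingerprint thresholds and therefore on
  the library composition; it is a within-library screen, not a portable
  cliff definition.
* t-SNE coordinates are not comparable across runs with different inputs
  even at a fixed seed.
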