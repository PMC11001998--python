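# Methods

This note documents the models and procedures implemented in `structpcm`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Protein structural fingerprint

For a protein chain with atoms *a₁…a_N* and a radius *r* (default
**5.0 Å**), the neighborhood of atom *a* is the set of residues
(one-letter code, sequence position) having **any** atom within Euclidean
distance ≤ *r* of *a*; the atom's own residue is always a member (distance
0). After sweeping all atoms, neighborhoods with identical member sets are
collapsed — deduplication acts on the position-annotated sets, *before*
letters are sorted. Each surviving pattern is encoded as its residue
letters sorted lexicographically with multiplicity (two distinct
phenylalanines contribute `FF`), and the key is hashed to one bit of a
binary array of **16,381** bits, the largest prime below 2¹⁴ (a prime
modulus spreads collisions of structured keys).

Numerical and design choices:

* **Hash.** SHA-1 of the ASCII key reduced modulo the array length. Any
  stable digest would do; what matters is that it is seedless and
  byte-stable, so fingerprints agree across runs, processes and platforms.
  A per-process randomized hash would silently break persisted
  fingerprints. Collisions are tolerated by design; the measured collision
  rate on random keys matches the uniform-occupancy expectation
  m − n(1 − (1 − 1/n)^m) (tested within 3σ).
* **Cutoff.** The distance test is inclusive (≤ r). The choice only
  matters on a measure-zero boundary but is fixed for bit-exactness.
* **Neighbor search.** A k-d tree (`scipy.spatial.cKDTree`); the
  brute-force all-pairs scan is kept in the test suite as an oracle and
  the contract is *exact* set equality, so the index is purely an
  optimization.
* **All atoms are swept**, as centers and as neighbor candidates. For
  AlphaFold-style inputs this means heavy atoms; a `heavy_only` parse flag
  exists for experimental files with modeled hydrogens.
* The encoding uses distances only, so it is invariant to rigid motion
  and atom order; no superposition step exists anywhere.
* **Similarity** between targets is the Jaccard index of on-bit sets
  (post-hash, hence marginally collision-lossy). A pre-hash variant over
  pattern-key sets is available (`pattern_keys` / `jaccard_sets`) for
  collision-free comparisons.

## Structure input

PDB files are read with gemmi. Only polymer ATOM records are used:
HETATM, waters and non-polymer residues are excluded, common nonstandard
residues (MSE, SEP, …) are mapped to their parent one-letter code, and
truly unknown residue names are skipped with a warning rather than
inventing alphabet letters. Multi-model files contribute model 1 only.
Alternate conformations resolve to the highest-occupancy conformer (ties
prefer altloc `A`). Multi-chain files are reduced by the **largest-chain
policy**: keep the chain with the most distinct resolved residues, ties
broken by the lexicographically smallest chain id; "largest" is measured
in residues, not atoms, because the fingerprint is residue-level.

## Ligand fingerprint

2048-bit binary Morgan fingerprints of bond radius 3 (**ECFP6**) via
RDKit, used as raw 0/1 features. No standardization or salt stripping is
applied; multi-fragment SMILES are fingerprinted as given and logged. The
descriptor choice is deliberately fixed — the package is about the protein
side.

## Activity curation and the spKi scale

Raw Ki records are processed per (molecule, target) pair:

1. Units: only molar concentrations (M, mM, µM, nM, pM) are accepted and
   converted to nM; anything else (%, mass concentrations, blanks) is
   excluded with a logged reason.
2. `=` records without a value, records with neither relation nor
   comment, and "active"-style comments without a number are excluded.
3. Exact measurements win. Multiple values within one order of magnitude
   (max/min ≤ 10) resolve to the geometric mean; beyond that, the most
   recent year wins (recency ties fall back to the geometric mean of the
   tied values).
4. Without exact measurements, `<`/`≤` bounds yield one upper-bound label
   at the **highest** reported threshold (the least informative bound).
5. `>`/`≥` records mark the pair inactive (spKi 0). When they conflict
   with exact measurements or bounds, the more informative record wins and
   the conflict is logged.

Every excluded raw row appears exactly once in the exclusion report, so
used + excluded = input (conservation, asserted in tests). The resolved
Ki maps to spKi = 0 for Ki ≥ 10⁴ nM or inactive, 1 for Ki ≤ 1 nM, else
(4 − log₁₀ Ki)/4 — continuous at both knots. Targets with fewer than
**40** curated activities are dropped; so are targets whose spKi standard
deviation falls below **0.01** (the variability threshold is a package
choice; it is configurable and only guards against degenerate all-equal
labels).

## Feature assembly

Protein fingerprints are far wider (16,381) than the number of targets in
any study and are repeated identically across every activity row of a
target, so they are reduced by **centered PCA fitted on the target ×
n_bits fingerprint matrix**. Components: either one per target (truncated
to matrix rank, with a warning) or the smallest k reaching 99% explained
variance. Each component's sign is fixed by making its largest-|loading|
entry positive, so fits are deterministic. PCA is *unsupervised* — it
never sees activity labels — so it is fitted on all targets' fingerprints
including blind-validation targets; held-out targets therefore have
well-defined projections while contributing zero label information. When
the target set itself changes (e.g. comparing structure sources), the
projection is refitted. A feature row is [2048 molecule bits ∥ k protein
components] labeled with the pair's spKi; rows whose molecule or target
key is missing are reported, never silently dropped.

## Models, regimes and metrics

The regressor is a scikit-learn random forest with **200 trees** and
library defaults otherwise (a 5-fold CV helper exists for informational
hyperparameter checks but defaults are fixed). Regimes:

* **baseline_per_target** — one forest per target on its own rows,
  molecule bits only, random 80/20 split per target.
* **unified_random** — one joint forest on the full feature rows, random
  80/20 split, repeated over fresh splits (seeds seed+0 … seed+n−1) and
  averaged, since the per-target composition of a random validation set
  varies between draws.
* **blind_random_targets / semi_blind_similar_targets** — all rows of the
  held-out targets form the validation set; leakage is asserted, not
  assumed. Semi-blind targets are chosen from the closest Jaccard pairs,
  greedily in descending similarity with pairs kept disjoint; from each
  pair the member with fewer activities goes to validation (keeps training
  large; without counts the tie-break is lexicographic). Whether the
  closest pairs must be disjoint, and which member is held out, are
  genuinely open choices; both rules are fixed here and surfaced in the
  pairing table.

Metrics: RMSE, and RVE defined in the coefficient-of-determination form
1 − SSres/SStot — unbounded below, 0 for the mean predictor — because
bounded-below alternatives cannot represent worse-than-mean blind
performance. Overall statistics are test-size-weighted plain averages of
per-target statistics. A target whose validation labels have zero
variance has undefined RVE; it keeps its RMSE weight and is dropped from
the RVE average with a warning. Predictions are scored raw (no [0, 1]
clipping) by default; clipping is available as an option.

## Synthetic benchmark

The generator emulates the study's three inputs without any downloads:

* **Structures**: Cα-trace random walks, step 3.8 Å, confined to a sphere
  of radius 3.2·n^⅓ Å (protein-like packing density), giving genuine
  sequence-nonlocal contacts at r = 5 Å. Cα-only keeps fixtures tiny; the
  fingerprint itself is atom-agnostic and the all-atom path is covered by
  PDB-format fixtures. Targets in the same *motif family* share a pendant
  residue cluster placed 10 Å outside the sphere, so family members share
  exactly the motif's neighborhood bits — family Jaccard ≈ 0.1–0.2 against
  a near-zero background, the hook for semi-blind pairing.
* **Molecules**: sparse random 2048-bit vectors (density 0.03 ≈ a typical
  ECFP6 popcount); a small bundled SMILES set exercises the real RDKit
  path.
* **Activities**: a planted linear model sets the true spKi of a
  (molecule, target) pair: a per-family baseline potency (uniform
  0.15–0.45 — real panels have visibly different label means per target,
  and without that asymmetry no greedy tree can enter the interaction) plus
  **effect_size = 0.2** for each of 4 family-specific signal bits the
  molecule carries (carrier frequency 0.4), plus Gaussian noise
  **noise_sd = 0.05** on the spKi scale, clamped to [0, 1]. The resulting
  label spread (sd ≈ 0.2) and noise floor are chosen to resemble curated
  Ki panels, where assay-to-assay scatter is a few tenths of a log unit.
  Scores convert to Ki through the inverse transform 10^(4−4·spKi);
  clamped scores map to the representative values 20,000 nM and 0.5 nM.
  Records are emitted with unit variety (20% in µM), censored relations
  (5%), duplicated measurements within one order of magnitude (10%), and
  junk units (2%) to exercise every curation rule. With all corruption
  rates at zero, curation recovers the planted spKi exactly.

Benchmark sizes are the package's own desk-scale choices: the signal-
recovery run uses the default study (20 targets in 10 families × 200
activities, 200 trees); the blind/semi-blind contrast uses ten studies of
12 targets (three 3-member families + three orphans) × 80 activities with
60-tree forests, compared by a one-sided sign test. Three-member families
matter: with a single training exemplar the learned family region in
feature space is often too narrow to capture an unseen relative, which is
also why real semi-blind transfer benefits from densely populated
subfamilies.

**What passing does and does not show.** The synthetic studies prove the
pipeline's bookkeeping (exact neighborhoods, curation rules, leak-free
splits) and that the modeling chain can recover a planted
structure-coupled signal and reproduce the blind/semi-blind contrast. They
do not show that real SAR landscapes are linear in fingerprint bits, that
real paralogs share bits the way pendant motifs do, or anything about
binding physics; transfer on real panels depends on data density and true
structural conservation.

## Known limitations

* mmCIF, structure repair and NMR multi-model handling beyond model 1 are
  out of scope; AlphaFold-style single-chain PDB files are the primary
  input.
* The hash is fixed (SHA-1 mod n); fingerprints from other hash choices
  are not comparable bit-for-bit, only through pre-hash pattern keys.
* PCA projections depend on the fitted target set; fingerprints projected
  with different fits live in different coordinate systems.
* Random-forest scaling is O(n_features · n log n) per tree with
  scikit-learn defaults; very large studies may want `max_features`
  tuning, exposed on `ModelSpec`.
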