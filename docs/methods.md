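# Methods

This note records how the package's models and procedures are defined,
which parameters matter, and where genuinely open design choices were
made.

## Interfaces and contacts

An interface is the pair of residue sets (fragments A and B, one per
binding partner) with at least one inter-chain contact, together with the
boolean inter-fragment contact map.  Two contact criteria are supported:

* **atomic** — at least one heavy-atom pair (one atom from each residue)
  within 4.5 Å.  "Heavy" means non-hydrogen; hydrogens and waters are
  removed at parse time.  Distance boundaries are inclusive (≤).
* **Cα-only** — Cα–Cα distance within `mean(i,j) + ξ·sd(i,j)` for the
  unordered amino-acid-type pair (i,j), default ξ = 0.5.  The
  type-dependent cutoff compensates for side chains of different sizes
  contacting at different backbone separations.

The per-pair statistics are computed with `compute_cutoff_table` from any
user-supplied set of atomic complexes: every inter-chain residue pair in
heavy-atom contact contributes its Cα–Cα distance; sample statistics use
ddof = 1; pairs with fewer than two observations fall back to the global
mean/sd (logged).  When no table is given, the package uses a uniform
fallback table (mean 8.0 Å, sd 0), a common single-cutoff choice at Cα
resolution.  Tables serialize to plain text (`AA1 AA2 mean sd` lines with
a `# xi` header).

A structure is classified `ca_only` when fewer than half of its
non-glycine residues carry a side-chain heavy atom (glycine is excluded
from the denominator because it has no side chain); mode can always be
forced.  Multi-model files use the first model; alternate locations
resolve to the highest-occupancy conformer (ties prefer altloc 'A');
MSE/SEC/PYL map to M/C/K and other nonstandard residues are dropped with
a warning.  Residues keep their author numbering and are identified by
(chain, seq_id, icode).

## Chemical classes

The 20 amino acids reduce to six classes by prominent side-chain
functional group (donor; acceptor; mixed donor/acceptor; aromatic;
aliphatic; mixed donor/acceptor-or-aromatic).  Two matching notions are
used deliberately:

* **hashing-stage compatibility** — classes match when their group sets
  intersect (Asn can match Arg through the donor group, or Asp through
  the acceptor group);
* **scoring-stage identity** — the indicator I in the equivalence score
  is 1 only for identical class labels.

Both stages accept the rule as a parameter, so either reading can be
toggled; the defaults above are used throughout.

## Geometric hashing

Each interface is a labeled Cα point cloud.  Local reference frames are
built from residue triplets within one fragment with pairwise distances
in [3, 13] Å and triangle area ≥ 1 Å² (origin at the first vertex, x-axis
toward the second, z along the normal).  Triplet vertices are ordered
canonically by the length of the opposite side — a rigid-invariant
labeling — so corresponding triplets on two interfaces yield
corresponding frames at one sixth the frame count of all orderings.

All points of interface 1 are recorded in every interface-1 frame, binned
at 2.0 Å and keyed by (bin, fragment label, functional group); bins are
offset by half a width so the frame-defining points (frame coordinates
exactly 0) sit mid-bin, which keeps voting exactly invariant under rigid
motion of either interface.  Probing with interface-2 frames scans the 27
neighboring bins to absorb boundary effects; a vote is one distinct
interface-2 point matched per frame pair.  Candidates are ranked by
votes, with ties broken by exact-bin votes (which keeps the top
candidate's transform at floating-point accuracy for noise-free copies,
where the neighbor-bin tolerance lets many slightly-off transforms also
reach full votes), then by rotation angle and frame order for
determinism.  Both fragment mappings are always attempted by swapping
interface 2's labels.

Near-degenerate transforms are merged by greedy leader clustering
(relative rotation ≤ 15°, translation difference ≤ 3 Å, computed from the
candidate composed with the representative's inverse); a representative
accumulates its cluster's votes, and the top 100 representatives go to
refinement.  Defaults: vote threshold max(4, 25 % of the smaller
interface's residue count), at most 200 frames per interface
(deterministic stride over the canonical triplet list) and 1000 raw
candidates per fragment mapping — the frame and candidate caps bound the
memory and runtime of the vectorized voting stage and leave
self-alignment and rigid-recovery behaviour unchanged.  All knobs live in
`HashParams`.

## Refinement and scoring

Refinement alternates (a) Hungarian maximum-weight matching of residues,
weighted by the equivalence score `1/(1 + 0.25(1−I) + d²/16)` and solved
separately inside each fragment pairing so fragments never cross, with
(b) Kabsch superposition over all currently matched pairs (unweighted;
proper rotation enforced by the determinant correction).  The objective
tracked is the summed equivalence score of matched pairs; the matching
under the incoming candidate transform counts as an iterate, so
refinement can never end below its starting point.  Iteration stops when
the matched set repeats, the objective improves by < 1e-6, or after 100
iterations; the best iterate seen is returned.  If matching collapses
below three pairs the candidate is flagged degenerate.  Pairs below the
0.20 inclusion threshold are pruned only at scoring time by default
(`prune_during_refine` enables in-loop pruning).

Scoring filters pairs to equivalence score ≥ 0.20 (a same-class pair at
exactly 8 Å scores exactly 0.20), computes the common-contact fraction
f_c over the aligned subsets (0 when both aligned maps are empty), the
raw score (f_c/L_ave)·Σeq, and the size-scaled
PC-score = raw^(ln 0.3 / ln(0.14 + 0.29·0.97^L_ave)).  L_ave counts all
interfacial residues of both fragments, averaged over the two
interfaces.  The candidate with the highest PC-score wins; coverage
(L_ali/L_ave) and Cα RMSD are reported over the retained pairs.  The
scaling exponent is positive for every L_ave > 0 and tends to
ln 0.3/ln 0.14 ≈ 0.612 for large interfaces; with f_c ≤ 1 and
Σeq ≤ L_ali ≤ L_ave the PC-score always lies in [0, 1] and equals 1 for
identical interfaces.

Significance: `empirical_pvalue` is the add-one tail frequency
(1 + #{b ≥ s})/(n + 1) against a background of PC-scores of unrelated
pairs, by default 1000 seeded synthetic pairs with fragment sizes drawn
uniformly from 10–30 residues (typical real interface sizes).

## Q-score

For capsid-type interfaces formed by two copies of one protein, contact
maps are N×N boolean matrices over residue positions of the shared
sequence (built with the same contact criteria as extraction, indexed by
residue number; sequence identity at shared positions is verified first)
and Q = 2⟨Nᵃ,Nᵇ⟩/(⟨Nᵃ,Nᵃ⟩+⟨Nᵇ,Nᵇ⟩).  The maps need not be symmetric —
the two subunits are distinct molecules.

## Synthetic data

The generator emulates what the pipeline actually consumes: two shells of
Cα positions facing each other across a ~5 Å gap with ±3 Å depth, residues
laid along gently curling strand segments (3.8 Å virtual bonds, minimum
lateral separation 1.1× the step) the way interfacial residues sit on
secondary-structure fragments, on a per-seed random quadratic surface
with per-seed footprint elongation and packing-density variation.
Chemistry is sampled from class weights (default: uniform over the 20
residues).  The patch extent is set so that approximately the requested
fraction of cross-fragment pairs falls within the 8 Å Cα contact radius
(default target ≈ 4.9/n, i.e. about five contacts per residue); residues
left without a contact are pulled toward their nearest partner, so every
generated interface satisfies the no-orphan invariant by construction.
Everything is reproducible from (spec, seed).

The strand-and-curvature geometry is deliberate: uniformly dense patches
of equal size are trivially superposable, which makes every unrelated
pair look alike.  With this generator the mean raw score of unrelated
same-size pairs tracks the size-scaling law's random-pair curve
0.14 + 0.29·0.97^L (measured ≈ 0.20 vs 0.19 at L = 60), which is the
calibration the PC-score's exponent is built from; consequently a typical
unrelated pair scores near PC ≈ 0.3–0.4 and perturbed copies of a real
interface score ≈ 0.95, far above the background's 99th percentile
(≈ 0.46).  What the synthetic data does *not* model: real side-chain
packing, sequence-correlated chemistry, secondary-structure hydrogen-bond
geometry, and size/shape distributions of real complexes — so passing
tests demonstrate the correctness and calibration of the algorithm, not
performance on any particular biological benchmark.

Backbone corruption (`perturb_backbone`) drops all non-Cα atoms and
displaces each Cα along an independent uniform random direction by a
half-normal magnitude |N(0, σ²)|, σ = 1 Å by default — a literal reading
of "perturbed in a random direction by a Gaussian-distributed magnitude",
rather than i.i.d. per-coordinate noise.  On an Interface the contact map
(defined before corruption) is kept.

## Numerical choices and degenerate inputs

* All distances inclusive at boundaries; coordinates in Å, right-handed.
* Rotations validated to 1e-6 orthonormality, det +1; only proper
  rotations anywhere (mirror matches are unreachable by construction).
* Hungarian assignment via `scipy.optimize.linear_sum_assignment`
  (deterministic); matched pairs reported sorted by (idx1, idx2).
* Kabsch via SVD with reflection guard
  (`scipy.spatial.transform.Rotation.align_vectors`); requires ≥ 3
  non-collinear pairs, else the degenerate-geometry error.
* Fragments need ≥ 3 non-collinear points for hashing; interfaces that
  cannot form a frame raise the degenerate-geometry error (CLI exit 2).
* Empty candidate sets yield an empty result with PC-score 0.
* f_c uses the 0/0 → 0 convention (no shared contacts ⇒ no evidence).

## Problem sizes used in the test suite

Self-comparison exactness is checked for 20 interfaces of 5–60 residues
per fragment; rigid recovery on 50 random transforms of 8–25-residue
interfaces; the Hungarian oracle on 200 instances of ≤ 6 residues per
fragment; extraction against brute force on 50 synthetic complexes; noise
robustness with 50 perturbed pairs against a 1000-pair background.  These
sizes span the realistic interface range while keeping the default test
run fast.

## Known limitations

* The hashing parameters (bin width, frame caps, vote threshold,
  clustering tolerances) are engineering choices surfaced in `HashParams`,
  not fitted constants; very large interfaces rely on the deterministic
  frame subsample.
* Partial-motif search is out of scope: the score rewards global overlap
  of whole interfaces.
* The Cα cutoff table ships only as the uniform fallback; deriving a
  statistics-based table requires a user-supplied atomic structure set.
* The empirical p-value is relative to the synthetic background unless a
  user-provided background is supplied.
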