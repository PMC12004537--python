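# Methods

## The minimum-distance matrix representation

A protein conformation with *n* residues is embedded as the symmetric
*n* × *n* matrix **D** with

    D[i, j] = min over heavy atoms a ∈ residue i, b ∈ residue j of |a − b|,

the minimum inter-residue heavy-atom distance in Å, and zero diagonal. A
bound ligand is embedded as the length-*n* vector of minimum residue–ligand
heavy-atom distances. The representation is superposition-free (invariant
under rigid motion of the whole structure) and sensitive to both backbone
and side-chain rearrangements, which is what distinguishes it from
Cα-only distance matrices or binarized contact maps. Distances are never
thresholded; the matrix is a distance map, not a contact map.

Residues are identified by `(chain, author residue number, insertion
code)`. Author numbering is the public coordinate system because it is the
only identifier stable across crystal structures of the same protein.
Before embedding an ensemble, residues not resolved in *every* structure
are dropped (intersection of residue keys), so all matrices share one
index. Matrices flatten to the n(n−1)/2 upper-triangle features in
lexicographic key order with explicit column labels.

Hydrogens are parsed but excluded from distances by default: most X-ray
models lack them, and the nSMD normalization offset α exists precisely to
compensate for that (below). A flag includes them for hydrogen-complete or
NMR models, in which case α should be set to 0.

## Dimension reduction and clustering

Feature matrices are mean-centered and decomposed by PCA. The retained
component count *m* is the smallest for which the cumulative
explained-variance ratio reaches the retention fraction (default 0.75).
Features are *not* standardized before PCA — all features share Å units,
and the cluster-selection threshold ϵ̂ is only meaningful on an unscaled
Å-derived axis. Component signs follow a fixed convention (the
largest-magnitude loading of each component is positive) so scores are
reproducible run to run.

Retained scores are clustered with HDBSCAN: `min_samples` k = 5,
`cluster_selection_epsilon` ϵ̂ = 10.0 by default. The mutual-reachability
construction underneath is

    d_mreach(i, j) = max(κ(i), κ(j), d(i, j)),

with core distance κ(i) the Euclidean distance from point i to its kth
nearest neighbor; clusters are selected by excess of mass over the
resulting hierarchy, and unassigned points are noise (label −1). ϵ̂ acts
as a floor that keeps spatially close microclusters from splitting one
conformational state into several clusters.

Implementation note: excess-of-mass selection is delegated to
scikit-learn's HDBSCAN. Its `cluster_selection_epsilon` code path raises a
`TypeError` under the numpy version this package targets whenever ϵ̂
actually forces a merge, so the floor is applied here as a post-processing
step instead: the fitted mutual-reachability single-linkage dendrogram is
cut at ϵ̂; all selected clusters falling in one component are merged; and
noise points of a cluster-bearing component whose core distance is ≤ ϵ̂
(density-reachable at that level) join the merged cluster. Components
containing no selected cluster stay noise. This reproduces the documented
"prevents clusters below the threshold from splitting further" behavior;
a characterization test pins it on a microcluster fixture. The per-cluster
stability score S(C) = Σ_p (λ_p − λ_birth) with λ = 1/d is exposed as a
diagnostic on a given partition (λ_p taken as 1/κ(p), λ_birth as the
reciprocal of the largest within-cluster mutual-reachability distance); it
is not the production selection criterion.

The ϵ̂ = 10.0 default is calibrated to the PC-score spread of large
real-protein ensembles (hundreds of structures, scores spanning hundreds
of Å). The synthetic fixtures in this repository are far smaller — their
PC1 inter-state separation is ~10–30 Å — so tests and the acceptance
script pass a fixture-scaled ϵ̂ of 2.0; the library default is unchanged.

## Normalized standardized mean difference (nSMD)

Given two clusters x and y, each residue pair (i, j) has per-cluster
distance samples with means d̄ˣ, d̄ʸ and sample SDs σˣ, σʸ. The effect
size is the standardized mean difference with Cohen's pooled SD:

    SMD = (d̄ˣ − d̄ʸ) / σ_pooled,
    σ_pooled = sqrt(((Nx−1)σx² + (Ny−1)σy²) / (Nx+Ny−2)).

An unweighted-average-of-variances pooling is available behind a switch
for auditability. The SMD is then normalized to bias pairs that can
actually form an interaction:

    nSMD = SMD / (min(d_ij) − α),

where min(d_ij) is the minimum of that pair's distance over the union of
the two compared clusters' structures, and α = 1.5 Å allows for unseen
hydrogens (α = 0 for NMR/hydrogen-complete models). Pairs with
min(d_ij) ≤ α + 0.1 Å are flagged near-covalent and excluded from
selection — sequence-adjacent residues joined by the ~1.33 Å peptide bond
would otherwise produce sign-flipped values from a non-positive
denominator. Zero pooled SD yields 0 for equal means and a signed-infinity
sentinel (excluded from selection) otherwise.

With the orientation x = inactive-like, y = active-like, pairs with
nSMD > 5 and 1.8 Å < min(d_ij) < 3.5 Å form in cluster y (set **R3**);
pairs with nSMD < −5 in the same window form in cluster x (set **R1**).
All inequalities are strict. Swapping the cluster orientation exchanges
the two sets exactly. Summing each structure's R1 and R3 distances places
it on a two-axis conformational coordinate; per-pair histograms (0.25 Å
bins) visualize the underlying bimodality.

## Conformation-based loop templates

Missing-residue runs are detected against a full-length reference
numbering; runs touching either terminus are excluded from modeling. For
each internal segment, candidate templates are the other ensemble members
resolving every residue of the segment, ranked lexicographically:
same conformational cluster as the target first, then ascending Euclidean
distance in retained PC space, then ascending crystallographic resolution
(unknown resolution last), with structure id as the deterministic final
tie-break. The combination order is this package's design choice — cluster
identity leads because conformational matching is the platform's central
claim. The emitted job bundle (PIR alignment + JSON manifest) declares the
external-engine protocol: rebuild missing segments only, revert
noncanonical residues to the reference amino acid, generate five models,
keep the lowest-DOPE one. The engine itself is out of scope.

## Docking-pose evaluation

*Self-docking*: a pose succeeds when its heavy-atom symmetry-corrected
RMSD to the crystal ligand is < 2 Å, computed in the shared frame with no
realignment. Symmetry correction minimizes RMSD over element-preserving
automorphisms of the reference bond graph (bonds perceived from covalent
radii + 0.45 Å; enumeration truncated at 10⁴ mappings with a warning);
a naive atom-order mode is retained for audit.

*Cross-docking*: the docked receptor is superposed onto the reference over
the intersection of their Cα keys (Kabsch least squares, proper rotation
enforced), the transform carries the pose, and success is a heavy-atom
ligand-centroid distance < 5 Å from the crystal ligand centroid. The
looser criterion reflects that a rigid receptor in a different
conformation cannot reproduce contacts atom-for-atom yet can still
identify the right pocket. A warning is attached when fewer than half the
reference Cα are shared.

A complex succeeds when any considered pose passes (optionally only the
top-k ranked); success fractions are reported per binding-mode group with
group sizes, and empty groups are absent rather than zero. ΔPop/ΔRank
diagnostics cluster poses by pairwise symmetry-corrected RMSD (complete
linkage, 2 Å cut): ΔPop is the population of the correct cluster (the one
holding the best-ranked passing pose) minus the largest incorrect-cluster
population; ΔRank is the best incorrect rank minus the best correct rank,
so positive ΔRank means the correct pose outranks all false positives.
Conformer deduplication uses Butina sphere exclusion at 2 Å on the
pairwise aligned-RMSD matrix, ties on neighbor count broken by lowest
index.

## Synthetic ground truth

The ensemble generator emulates exactly the feature the statistics
consume: designated residue pairs toggling between a formed minimum
distance (default μ_f = 2.8 Å, hydrogen-bond/salt-bridge range) and a
broken one (μ_b = 8.0 Å) across states, with Gaussian noise σ (default
0.26 Å, giving separation ratio (μ_b − μ_f)/σ = 20) on realized distances
and a small (0.02 Å) jitter on backbone pseudo-atoms. Backbone CA atoms
sit on a ring with 6 Å spacing so untoggled pairs keep large, nearly
constant separations; each planted pair is realized by a side-chain
pseudo-atom placed along the partner's outward normal. Planted pairs must
be ≥ 4 residues apart in sequence and vertex-disjoint so each realized
distance is controlled by exactly one atom. State fractions allocate
structures deterministically (largest remainders), and every random draw
flows from the single spec seed, so identical specs are byte-identical.

What the generator does *not* emulate: real protein geometry, correlated
backbone motion, crystallographic artifacts (altlocs, partial occupancy,
lattice contacts), resolution-dependent coordinate error, or continuous
conformational gradients between states. Passing tests therefore
demonstrate correctness of the statistical machinery on cleanly separable
states, not robustness to the messiness of real ensembles.

The benchmark generator builds complexes whose poses are pure rigid
translations of the reference ligand (the designated true pose by 0 Å),
so the self-RMSD and cross-centroid metrics of every pose equal its
planted displacement exactly and success fractions are analytic.

## Numerical choices and edge cases

- Minimum distances take the min over squared distances with a single
  final square root, making entries bit-identical to a brute-force
  min-over-norms evaluation.
- Altloc handling keeps the highest-occupancy conformation per atom name,
  ties broken alphabetically.
- PCA on rank-0 (all rows identical) data is a hard error; fewer than 2k
  points yield an all-noise assignment with a warning rather than a crash.
- The Kabsch step rejects < 3 or collinear points; reflections are
  corrected to proper rotations via the SVD determinant.
- A residue–ligand distance of exactly 0 (clash) is retained but warned
  about.
- Problem sizes throughout the test suite (40-residue / 40-structure
  ensembles, 8-complex benchmarks, 50-point mutual-reachability sets) are
  chosen so the full suite and the acceptance script run in seconds on one
  CPU while still exercising every code path at the study's planted
  parameter values.

## Known limitations

- The ϵ̂ floor is a faithful but independent re-implementation of the
  epsilon-selection semantics; exotic hierarchies could differ from the
  reference library in corner cases (single cluster born above ϵ̂ with
  nearby noise).
- Bond perception for symmetry RMSD is distance-based; exotic ligands with
  unusual bond lengths may gain or lose automorphisms.
- NMR multi-model entries are reduced to records per an explicit per-model
  switch; no automatic model averaging is attempted.
- The loop-modeling module emits jobs for an external engine; it does not
  validate that the engine accepts them beyond the PIR/JSON contract.
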