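# Methods

## Scope and data model

The package post-processes molecular-dynamics output: multi-frame XYZ
trajectories (Å) with per-path reactive/unreactive labels supplied by a
CSV manifest, or derived by segmenting one long trajectory with the
order parameter. A `Frame` holds element symbols, coordinates, and
(optionally) velocities; velocities are parsed when present but never
enter the default feature set, since distance features carry the
discriminating information and velocity features add little. A
`PathRecord` adds the label and a `generation_order` — the sampling-time
ordinal on which the block-error analysis relies.

## The proton-transfer order parameter

s(r) is deliberately discontinuous. Given the acid's two oxygens and
the set of *reactive* hydrogens (every hydrogen except the acid's
C-bound one):

- If the minimum acid-O/reactive-H distance r_min is below the
  protonation threshold (1.4 Å), the acid is protonated and
  s = r_min.
- Otherwise each reactive hydrogen is assigned to its nearest oxygen
  (ties to the lowest oxygen index — deterministic and documented).
  Water oxygens holding exactly three hydrogens mark the hydronium;
  s is the minimum distance from the acid oxygens to the hydrogens of
  any such oxygen. If several oxygens are triply coordinated at once
  the global minimum over all of them is used.
- If the proton has left but no oxygen is triply coordinated (a
  transient assignment gap), s falls back to r_min. This keeps the
  series defined and continuous through the gap; the case is logged at
  debug level.

State A is s < `stateA_bound` (1.05 Å for four-water clusters, 1.07 Å
for six-water ones), state B is s > `stateB_bound` (3.0 Å). The jump of
s when the hydronium identity changes is the feature that separates
contact ion pairs from Zundel-like product structures.

Segmentation of an unlabeled trajectory emits maximal excursions out of
state A: a segment starts at the last A frame before departure and ends
at the first frame inside whichever state is touched next (B →
reactive, A → unreactive). Incomplete leading/trailing stretches are
dropped. A symmetric B-origin mode exists behind a flag.

## Index-invariant distance matrix

Rows of the atom–atom distance matrix are grouped per element and
sorted within each group by distance to a reference atom; each row's
columns are grouped and sorted the same way by distance to that row's
atom. Design choices the construction leaves open:

- **Element-group order**: reference element first, remaining elements
  by descending atomic number (C, O, H for these systems). The order is
  configurable and recorded in the `InvariantMatrix`, so labels are
  reproducible.
- **Self-distances** (the zero diagonal) are retained. This makes the
  flattened vector exactly M² long (23 atoms → 529 features) and puts
  each row's own atom at column rank 0 of its own element group.
- **Ties**: exact distance ties are broken by original atom index
  (stable sort). Tied geometries make the representation formally
  non-unique; the invariance test suite uses generic (jittered)
  geometries where ties have probability zero.

The recorded permutations make the transform reversible without
arithmetic (`unsort`), and any feature label resolves to a concrete
atom pair, which is how split features are visualized: dummy `X` atoms
are appended at the two real-atom positions of each split's pair.

Back-mapping a symmetric distance matrix to coordinates is classical
multidimensional scaling: double-centre the squared distances into a
Gram matrix, take the three leading eigenpairs, coordinates are
V·sqrt(Λ). Eigenvalues below 1e-9 of the largest are treated as zero;
negative eigenvalues are clamped with a warning; more than three
significant eigenvalues (non-3D-embeddable input, e.g. a hand-edited
matrix) produce a rank-3 approximation with a warning. The result is
unique up to translation, rotation and reflection, so tests compare
realized pairwise distances, not raw coordinates.

## Dataset assembly

The three hyper-parameters are the selection window's location and
width and the frames drawn per path; defaults 1.1 < s < 1.25 Å
(strict inequalities) and one frame per path. Paths with fewer
in-window frames than requested contribute what they have; paths with
none contribute nothing. Sampling is a seeded choice without
replacement, so a run is reproducible from its config. Rows are ordered
by `generation_order`, which is what makes contiguous blocks meaningful
as time blocks downstream.

## Trees, the main decision path, and the error model

The classifier is a depth-3 decision tree with the information-gain
(entropy) criterion, fitted by scikit-learn and exported into a plain
`TreeNode` structure carrying the split feature label, threshold, and
per-node (unreactive, reactive) counts. The main decision path leads to
the leaf maximizing n_r·n_r/(n_r+n_u); exact score ties (measure-zero
for continuous features) break toward the shallower leaf, then the
earlier leaf in preorder. The leaf fraction n_r/(n_r+n_u) is reported
as the probability that a path satisfying the splits is reactive.

First-split reliability uses random forests of depth-1 trees: with a
single split per tree, the forest's per-feature importance reduces to
the frequency-weighted importance of the first split alone. Choices the
procedure leaves open, and what this package does:

- **Forest size**: 1000 trees by default, configurable.
- **Feature subsampling**: 25% of features per tree. With M² feature
  vectors, square-root subsampling admits a dominant feature into too
  few trees for its importance to accumulate against its many partial
  geometric correlates; a fixed fraction keeps the estimator
  informative while still decorrelating trees.
- **Blocks**: rows are cut into 10 contiguous, near-equal blocks in
  generation order (sizes differ by at most one, larger blocks first),
  shuffled within each block. One forest per block yields an importance
  series whose per-feature sample standard deviation (ddof = 1) is σ;
  the mean comes from a forest on the full data. All block forests
  share the seed and the within-block shuffle stream, so copied-row
  blocks give exactly σ = 0 — a property the tests use as a sanity
  check. Single-class blocks contribute zero importance with a
  warning.
- **p(most important)**: each feature's importance is modelled as an
  independent Gaussian with its (mean, σ); 10⁵ Monte-Carlo joint draws
  are taken and argmax frequencies reported. The two-feature case has
  the closed form Φ(Δμ/(σ√2)), used as the test oracle. If every σ is
  zero the distribution is degenerate: probability 1 on the max-mean
  feature, split uniformly over exact ties.

## Synthetic data: what it emulates and what it does not

The generator emulates clusters of one formic acid plus n waters (ideal
monomer geometries: C=O 1.22 Å, C–O 1.34 Å, O–H 0.97/0.96 Å, C–H
1.09 Å, H–O–H 104.5°) producing both unreactive excursions (the acid
O–H stretches to ~1.3 Å and relaxes) and reactive paths (scripted
transfer of the acid proton to the nearest water, then a hydronium-
identity hop to a distant water that takes s past 3 Å). The hops are
kinematic scripts, not dynamics: the analysis pipeline, not an MD
engine, is under test.

The recoverable ground truth is a rigid-subcluster displacement: two
waters sit outside the solvation ring, and the O–O distance between
them is drawn below the planted threshold (3.0 Å) for reactive paths
and above it for unreactive ones, with a 0.25 Å guard band on either
side. Because the outer water is always the farthest oxygen from the
reference carbon and its partner is always its nearest other oxygen,
the planted entry has the stable label `O(n+1)-O1'` (`O7-O1'` for six
waters — column rank 0 being the row atom's own zero self-distance).
Every other distance touching the pair is scrambled by class-
independent randomness — random rigid orientations of both outlier
waters, a broadly distributed partner-to-ring distance, and a large
out-of-plane tilt of the outer water's placement direction — so that
exactly one feature separates the classes cleanly. Default conditions:
six waters, 50% reactive paths (count exact by rounding, labels spread
evenly over generation order), coordinate jitter σ = 0.02 Å per frame.

What passing tests therefore do show: the full pipeline (window
selection → invariant featurization → tree/forest analysis) rediscovers
a known geometric signature from raw labeled trajectories, at realistic
cluster sizes and feature counts (529 features). What they do not show:
recovery under physically realistic dynamics, thermal noise structure,
or correlated path-sampling ensembles — real trajectory collections are
noisier and their discriminating features less cleanly separated, so
importance probabilities on real data will be far from the near-
certainty seen on the fixtures.

## Problem sizes

The recovery suite runs the end-to-end pipeline on 100 independent
200-path collections (decision-tree root check) and two collections for
the blocked-forest check at 300 trees per forest; these sizes give
stable pass/fail behaviour while keeping the default test run fast.
The forest default of 1000 trees is unchanged.

## Known limitations

- The feature count scales as M²; systems beyond a few hundred atoms
  need feature pruning or the index-variant matrix (not shipped).
- Exact distance ties (ideal lattices, symmetric minima) make the
  sorted representation non-unique; any jitter resolves them.
- Fitted trees are not transferable between systems; the analysis is
  descriptive, per collection.
- The Gaussian block model treats feature importances as independent,
  which over-resolves strongly correlated features; the reported
  probabilities are a ranking heuristic, not calibrated inference.
- The manifest format assumes one trajectory file per path and
  pre-deduplicated paths; ensemble re-weighting across path-sampling
  interfaces is out of scope.
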