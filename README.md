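# trajtree

Data-driven identification of the geometric features that distinguish
**reactive** from **unreactive** molecular-dynamics trajectories, with
decision trees on an atom-index/rotation/translation-invariant
distance-matrix representation. The method is demonstrated on proton
transfer in small formic-acid/water clusters, but the machinery is
generic: it post-processes any collection of labeled trajectories
(e.g. the output of transition-interface path sampling, or a long
trajectory segmented by an order parameter).

## Who this is for

Simulators who have generated rare-event trajectories and want an
unbiased answer to: *what must a configuration near the initial state
look like for its trajectory to end up reactive, and with what
probability?* Instead of guessing a reaction coordinate, the package
lets a shallow decision tree pick the discriminating inter-atomic
distances, then maps them back onto the 3D structure.

## Method in brief

1. **Order parameter.** For acid-to-water proton transfer, s(r) is the
   minimum acid-oxygen/reactive-hydrogen distance while the acid is
   protonated (r < 1.4 Å); once the proton has left, hydrogens are
   assigned to their nearest oxygen, any water oxygen holding three
   hydrogens marks the hydronium, and s(r) becomes the minimum distance
   from the acid oxygens to the hydronium hydrogens. State A
   (protonated) is s < 1.05–1.07 Å; state B (separated, Zundel-like)
   is s > 3.0 Å. A change in hydronium identity makes s jump
   discontinuously — by design.
2. **Selection window.** One frame per trajectory is drawn at random
   from a narrow window near state A (default 1.1 < s < 1.25 Å) to
   limit inter-sample correlation. Window location, width, and
   frames-per-path are the method's three hyper-parameters.
3. **Invariant featurization.** The frame's atom–atom distance matrix
   is grouped per element and sorted by distance to a reference atom
   (rows) and to each row's atom (columns). Entry labels read
   `O2-H5'`: the distance from the third-closest oxygen to the
   reference, to that oxygen's sixth-closest hydrogen (0-based ranks;
   the prime marks the per-row column index). Flattened row-major, an
   M-atom frame gives an M² feature vector; the sort permutations are
   recorded, so every feature can be resolved back to a concrete atom
   pair, and a symmetric distance matrix can be back-mapped to 3D
   coordinates by classical multidimensional scaling
   (Young–Householder).
4. **Learning.** A depth-3 decision tree (entropy criterion) separates
   frames of reactive from unreactive paths. The *main decision path*
   leads to the leaf maximizing n_r·n_r/(n_r+n_u); its leaf fraction
   n_r/(n_r+n_u) estimates the probability that a path satisfying the
   splits is reactive.
5. **First-split reliability.** Depth-1 random forests (whose feature
   importance is exactly the importance of the first split) are fitted
   to 10 contiguous generation-time blocks to get a per-feature σ; a
   Gaussian Monte-Carlo argmax over (mean, σ) yields the probability
   that each feature truly is the most important first split.

## Worked example

The package ships a synthetic-trajectory generator with a known ground
truth: clusters of one formic acid and n waters in which two "outlier"
waters sit outside the solvation shell, and the O–O distance between
them is below 3.0 Å exactly for the reactive paths.

```
$ trajtree synth --n-waters 6 --n-paths 200 --seed 1 --out-dir data
$ trajtree analyze config.yaml
main path leaf P(reactive) = 1.000
most probable first split: O7-O1' (p = 0.92)
analysis complete in out
```

with `config.yaml`:

```yaml
manifest: data/manifest.csv
out_dir: out
acid_oxygen_indices: [1, 2]
reactive_hydrogen_indices: [4, 6, 7, 9, 10, 12, 13, 15, 16, 18, 19, 21, 22]
stateA_bound: 1.07
```

The main-path report (`out/main_path.txt`):

```
O7-O1' <= 3  (u, r) = (100, 100)
leaf: (u, r) = (0, 100); score = 100.000; P(reactive) = 1.000
```

reads: of 200 sampled frames (100 from unreactive, 100 from reactive
paths), those whose eighth-ranked oxygen (the farthest from the
reference carbon, `O7`) lies within 3 Å of its nearest other oxygen
(`O1'`) all belong to reactive paths — the planted signature,
rediscovered. `out/importance.tsv` ranks the same feature first with
p = 0.92 probability of truly being the best first split, the
remainder spread over geometrically correlated neighbours:

```
feature  mean_importance  sigma     p_most_important
O7-O1'   0.238000         0.035914  0.917280
O6-O2'   0.158000         0.043416  0.078920
```

`out/tree.dot` (Graphviz) draws the tree with per-node split
inequalities and (unreactive, reactive) counts, and
`out/main_path_markers.xyz` contains a representative in-window frame
with dummy `X` atoms on the split's atom pairs, ready for VMD.

The same stages are available individually (`trajtree cv`,
`features`, `tree`, `importance`, `backmap`, `synth`) and as library
functions (`trajtree.colvar`, `.invrep`, `.select`, `.treelearn`,
`.synthfix`, `.trajio`).

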