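# Methods

`omicnet` reconstructs association networks between pairs of omics blocks
("internal phenotypes": e.g. intestinal transcriptomics, gut microbiota
composition, serum cytokines, serum and urine metabolomics) measured on
the same dietary-intervention experiment, validates the network thresholds
against a permutation null, and merges the pairwise networks into a single
typed graph in which cross-layer connectivity hubs are identified. This
note records the model, its assumptions, the defaults, and the choices
made where the procedure is genuinely open.

## Differential screen

Each block is log2-transformed (configurable pseudo-offset, default 0 for
strictly positive assays; use 1 for count-like data) and fitted per feature
with a cell-means OLS model over the diet groups. Contrasts are each
treatment group's mean minus the reference group's mean. Residual
variances are pooled within groups over `n − G` degrees of freedom.

Variances are then moderated by the standard empirical-Bayes squeeze: a
scaled inverse-chi-square prior `(d0, s0²)` is fitted by method of moments
on `log s²` (prior df via the inverse trigamma; infinite `d0` when the
observed spread of log-variances does not exceed chi-square sampling
noise), and each posterior variance is `(d0·s0² + d·s²)/(d0 + d)`.
Moderated t statistics use `d + d0` degrees of freedom. This reproduces
limma's `lmFit`/`eBayes` to 8+ digits on a fixed fixture (see
`tests/test_screen.py`). The assumed proportion of changed features
(default 0.01) is carried for reporting; it would enter only the log-odds
ranking, which the screen does not use because selection is FDR-based.

P-values are Benjamini–Hochberg adjusted within each contrast, and a
feature is selected when its minimum FDR over the five
treatment-vs-reference contrasts is at or below the per-block threshold
(default 0.05; typical practice ranges from 0.001 to 0.1 depending on the
block's size and signal density). An empty selection is a warning at the
screen stage and an error when the block tries to enter integration.

## Sparse PLS and the association matrix

For a block pair, sPLS in regression mode is fitted in both orientations.
Columns are centered and scaled to unit variance (default; it makes blocks
with different units comparable). Each component is a soft-thresholded
power iteration on the current cross-product matrix `M = XᵀY`: the
predictor loading is `soft(Mv, λ_u)` with `λ_u` chosen as the (k+1)-th
largest magnitude so exactly `keep_x` entries survive (ties broken toward
the lower index; an exact tie that would annihilate the vector retains the
top k unshrunk), normalized to unit length, and symmetrically for the
response loading; iterated to `tol = 1e−9` or `max_iter = 500`. Deflation
is asymmetric: both blocks are deflated by the projection onto the
predictor scores, which makes the predictor scores mutually orthogonal and
the response block modeled by regression on the predictor's latent
variables. Loading vectors are sign-fixed (largest-magnitude entry
positive) purely for reproducibility.

Defaults: `ncomp = 5`, no sparsity (`keep = all`). With full keep the
dependency structure is vacuous and every feature pair is "dependent";
sparsity levels are exposed per component because no single default suits
all block sizes.

A feature pair (i, j) is *dependent* when some single component selects
both sides; pairs selected only on different components are not. The
association matrix `Ma(X,Y)` holds the Pearson correlation over the shared
samples for dependent pairs and an exact structural zero otherwise.

## Pairwise network and dynamic dual thresholds

The two orientations are combined as `M = Ma + Mbᵀ`, so a pair detected in
both directions with correlation r has weight ≈ 2r (the weight scale is
[−2, 2]). Dual thresholds retain the extreme tails, separately per sign:
`th_h` is the value such that the entries ≥ `th_h` are the top `fraction`
(default 5%) of the *positive nonzero* entries, inclusive at the boundary
(ties kept); `th_l` symmetrically for negative entries. The quantile is
taken over nonzero entries rather than all matrix cells so that the
threshold reflects the correlation population, not the matrix size. The
binary adjacency is `1` where `m ≥ th_h` or `m ≤ th_l`; its nonzero cells,
weighted by `m`, form a strictly bipartite network (every node with at
least one retained edge; within-block correlations are deliberately out of
scope, so each node's clustering coefficient in a pairwise network is
exactly 0).

Sample alignment intersects the two blocks' sample IDs (≥3 required) and
orders the response block to match the predictor block.

## Permutation null model

Each iteration shuffles every feature's values independently across
samples in both blocks — the strongest null: each variable keeps its exact
value distribution while all within- and between-block correlation is
destroyed — then reruns the full pairwise integration and records the
dynamic cut-offs `(th_lk, th_hk)`. Permuting one block would suffice to
break cross-block association; both are permuted because the null should
contain no correlation structure at all, and a single-block option is
available. The default iteration count is 200 at desk scale; 1,000
reproduces the full-scale setting (`--iterations 1000`).

Tail significance is the add-one-smoothed exceedance
`p = (1 + #{null thresholds at least as extreme}) / (N_it + 1)`, which
cannot reach 0 at finite `N_it` and equals `1/(N_it+1)` when the real
threshold is the most extreme value seen. A tail "overlaps" when a
retained real edge weight lies inside the null threshold range; overlap
calls for caution in interpreting that sign's edges. Failed null
iterations (degenerate fits) are recorded as missing and tolerated up to
10%.

## Merging, topology, hubs

The C(B,2) pairwise networks are merged into one simple undirected typed
graph. Provenance (which networks contributed each node and edge) is kept;
duplicate edges — impossible among type-distinct pairwise networks, but
possible with user-supplied inputs — collapse to the larger-|weight|
contribution. Nodes present in fewer than `min_networks = 2` of the
original networks are dropped in a single pass (membership counts are not
re-derived from the filtered graph, so the filter is idempotent). The
membership count is over contributing *networks*; for the ten
type-distinct networks this coincides with the number of partner data
types.

Topology metrics: degree; per-node clustering coefficient (realized links
among neighbors over possible links, 0 when degree < 2) averaged over
nodes; density `2E/(N(N−1))`; connected components; and the
characteristic path length defined as the **median** over nodes of each
node's mean shortest-path distance to the others — a deliberate
convention of the analysis this package reproduces, which differs from the
usual mean-over-pairs definition (they coincide on vertex-transitive
graphs, which the tests exploit). Unreachable pairs are excluded from a
node's average; the filter typically leaves one or two components, so this
choice is rarely active.

A **connectivity hub** is a node whose neighbor set covers every data type
other than its own (with five types: all four others).

## Synthetic data generator

The generator emulates a six-diet mouse trial (default groups: soy
(reference), casein, whey, plasma, gluten, mealworm; 6 animals per group)
with per-block quality-control dropout to `n_samples_retained`, chosen
uniformly without replacement. Values are built on the log2 scale and
exponentiated on output so the pipeline's own log transform is exercised:

`log2 x = baseline + diet effect + noise_sd · (Σ a_p Z_p + b ε)`

* Baselines are N(7, 2) per feature (microarray-intensity-like).
* A *responsive* feature (fraction per block) shifts by ±`effect_size`
  (default 2 log2 units at `noise_sd = 1`, a realistic magnitude for
  features that pass a small-n differential screen) in a random non-empty
  subset of treatment groups.
* Each planted cross-block pair has its own unit-variance latent factor
  `Z_p`; both members load `a = sqrt(|r|)` (one side sign-flipped for
  negative targets) and the residual scale is `b = sqrt(1 − Σ|r|)`, so the
  population correlation is exactly the target `r` — the closed form the
  oracle tests rely on. Requesting loadings with `Σ|r| > 1` on a single
  feature raises an infeasibility error rather than clipping.
* Latent factors are partially diet-coupled (`diet_coupling = 0.6` as the
  loading of a standardized per-group shift pattern), so planted features
  are themselves diet-responsive without disturbing the planted
  correlation.

What the generator does **not** emulate: microarray/16S/MS noise physics,
compositionality of microbiota counts, cell-level missingness, or
feature-feature correlation beyond the diet effects and planted latents.
Passing tests therefore demonstrate the pipeline's statistical behavior
under its own assumptions, not robustness to real assay artifacts.

## Study conditions used by the tests and the acceptance script

* Five-block end-to-end runs use Table-1-like shapes scaled to desk size
  (120/50/23/41/16 features; 33/33/36/36/28 samples); the full microarray
  dimensionality is available through the config but is not needed to
  exercise any code path.
* The planted-structure scenario (edge recovery, null separation) uses two
  blocks of 24 and 30 features on 30 samples with 10 planted edges at
  |r| = 0.85 (5 positive, 5 negative) and `responsive_fraction = 0.8`,
  emulating the *post-screen* stage of the analysis: by construction,
  features entering the real integration passed the differential screen,
  so nearly all of them respond to diet. That diet-driven background
  correlation is precisely what the permutation null destroys, and is what
  separates the real thresholds from the null distribution.
* Null models run at `N_it = 200` per replicate in the tests and the
  acceptance script, with 20 outer replicates for the separation check.

## Numerical choices and degenerate inputs

* sPLS convergence `tol = 1e−9` on the loading change, `max_iter = 500`;
  components are initialized from the dominant singular pair of `M`.
* Zero-variance features among dependent pairs, all-zero cross-products,
  constant columns under scaling, empty groups, zero residual df, and
  all-zero residual variances raise named errors rather than propagating
  NaNs.
* Floating-point TSV fields are written at 10 significant digits, making
  output bundles byte-stable across runs with a fixed seed.
* One master seed is split into independent spawned streams per pair and
  per null iteration, so adding a block pair does not perturb another
  pair's randomness.

## Known limitations

* With the default no-sparsity sPLS the dependency filter never excludes a
  pair, so the association matrix is a plain (thresholded) correlation
  matrix; sparsity is where the method's variable selection becomes
  active, and the appropriate keep counts are data-dependent.
* The screen controls FDR within each contrast; the min-over-contrasts
  union selection is not itself an FDR-controlled quantity (the pure-null
  suite checks the average selected fraction stays below the threshold).
* The characteristic-path-length convention (median of per-node means)
  is nonstandard; comparisons with other tools' "average shortest path"
  should expect small differences.
* Literature mining of the retained edges is out of scope.
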