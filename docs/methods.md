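# Methods

`neogenet` implements a generative-growth analysis of neonatal structural
connectomes: binary networks on a fixed spatial parcellation are grown edge
by edge under an economic trade-off between wiring cost and topological
value, the trade-off exponents are fitted to observed networks by grid
search, and the fitted models are interrogated for what they imply about
wiring constraints in term- and preterm-born infants.

## The growth model

Networks live on N nodes with fixed 3D coordinates (mm); `d_ij` is the
Euclidean distance matrix derived once from those coordinates.  Growth
starts from a seed network and adds one edge per iteration.  The
probability that an absent pair (i, j) wires is

    p_ij ∝ d_ij^eta * (k_ij + eps)^gamma

* `eta` (dimensionless, typically in [-8, 0]) weights the distance cost;
  negative values favour short connections.
* `gamma` (dimensionless) weights the topological value `k_ij`, recomputed
  from the current adjacency after every addition.
* `eps` (default 1e-5) keeps zero-value pairs reachable: homophily value is
  0 for most pairs early in growth and 0^gamma would otherwise freeze the
  process.  Its exact magnitude is immaterial as long as it is small
  against typical nonzero values (the smallest nonzero matching index on a
  90-node, 10%-dense network is ~1e-2).

Thirteen value rules are registered: `spatial` (k ≡ 1, pure distance
penalty), the homophily pair `neighbors` (count of shared neighbours) and
`matching` (shared neighbours over the union of both neighbourhoods,
excluding the pair itself — the normalised form of `neighbors`), and
avg/min/max/diff/prod combinations of the endpoints' clustering
coefficients (`clu-*`) or degrees (`deg-*`).  One matching-index
implementation is shared between the growth engine and the graph-measure
module so the two can never drift apart.

Sampling uses inverse-CDF over a fixed upper-triangular edge ordering, so a
run is bit-reproducible from its generator state on any platform.  The
value term is recomputed in full each iteration (dense matrix products;
~0.1 ms per iteration at N = 90), which keeps the engine simple and
obviously correct; an incremental update was not needed at this scale.

## Model fitting

A candidate (eta, gamma) is scored by growing one simulation to the
observed network's edge count and computing the energy

    E = max(KS_k, KS_c, KS_b, KS_e)

over the nodal distributions of degree, clustering coefficient,
betweenness centrality, and edge length.  "Edge length" of a node is the
sum of the Euclidean lengths of its connections; a per-edge-length
convention (`edge_length_mode="edge"`) is also provided because usage in
the literature varies.  The grid search uses one simulation per grid point
(a replicate count is exposed); each point draws from its own rng stream so
the landscape does not depend on evaluation order.  Best fit is the energy
argmin, with ties broken towards smaller |eta|, then smaller gamma.  The
half-grid-step is reported as the resolution limit of the estimates.

Default grids mirror the neonatal analysis: a wide sweep (-8 ≤ eta ≤ 0,
-8 ≤ gamma ≤ 8) for value-rule selection and a narrow per-subject grid
(-3 ≤ eta ≤ 0, 0.1 ≤ gamma ≤ 0.6); 100 × 100 points on the narrow bounds
reproduce the 10,000-simulation search, and the default `fit()` grid is a
20 × 20 thinning of it.

Two further diagnostics qualify a fit beyond energy: the topological
fingerprint (the 6 × 6 correlation matrix of the local measures across
nodes; dissimilarity between two fingerprints is the Frobenius norm of
their difference; zero-variance measures get correlation 0, logged) and
spatial embedding (node-wise Pearson correlation of each local measure
between simulation and observation; cohort-level summaries are means with
bootstrap CIs — mixed-effects inference is deliberately left to external
statistics on the emitted tidy tables).

## Network construction

Weighted streamline-count cohorts become binary networks in the order the
neonatal analysis uses: a 60% group consensus mask (edge kept iff present
in ≥ 60% of subjects; presence means weight > 0; the comparison is ≥, with
a `strict` flag), then either an absolute count threshold (default 325,
inclusive ≥; a search routine returns the smallest integer threshold whose
cohort-mean density is ≤ a 10% target) or a per-subject proportional
threshold retaining the strongest edges up to an exact 10% density.
Fractional edge targets round half away from zero; cutoff ties break by
higher weight, then lexicographic node pair — deterministic and tested.

The group consensus network preserves the subjects' connection-length
distribution: candidate edges are binned by length (default 10 equal-count
bins; intra- and inter-hemispheric edges binned separately) and each bin
receives its rounded mean per-subject edge count, filled with the most
prevalent edges.  A plain prevalence ranking at equal density is biased
towards short edges; the test suite checks the binned construction beats it
in KS distance to the pooled subject length distribution.

## Graph measures

All measures operate on binary networks.  Local: degree, clustering,
unnormalised betweenness (Brandes, vectorised over sources), nodal edge
length, local efficiency (efficiency of the open-neighbourhood subgraph),
mean matching index.  Global: density, characteristic path length (mean
over *connected* pairs; NaN when none), global efficiency (mean inverse
shortest path; disconnected pairs contribute 0), and maximum modularity by
Newman spectral bisection with Kernighan–Lin refinement (deterministic:
`eigh` leading eigenvector, fixed sign convention, greedy single-node
flips).  The disconnected-pair conventions matter because 10%-dense
networks need not be connected; they are stated here and in the emitted
reports so cross-study comparisons are explicit.

Rich-club analysis: phi(k) = 2 E_k / (N_k (N_k - 1)) over nodes with degree
strictly greater than k, normalised by the mean of degree-preserving
rewired nulls (double-edge swap, default 10 successful swaps per edge, 1000
nulls).  A level is significant when the one-sided empirical p (fraction of
nulls with phi ≥ observed) is below alpha = 0.05; no multiple-k correction
is applied (flags exposed).  Each significant level defines a candidate
club (nodes with degree > k); the selected club is the largest one
comprising at most half the network — mirroring the choice of a large
(27-of-90-node) club over a trivial 2-node one, while refusing
majority-of-the-network "clubs".  The minority restriction is needed
because at low k the null phi is almost fully determined by the degree
sequence: its variance collapses and excesses of a fraction of a percent
come out "significant" without describing any elite.  Edges are classed
rich (both endpoints in the club), feeder (one), local (neither).

## The term/preterm representative experiment

Two batches of growth runs are launched at the representative exponents
(preterm eta = -1.85, gamma = 0.34; term eta = -1.74, gamma = 0.32; 1000
runs per group by default), with every addition recorded.  Edges are
classified against a rich-node set frozen from the consensus network
*before* any simulation, shared by both groups.  Per iteration the
experiment reports cumulative class counts (seed edges included, so the
classes always sum to the current edge count) and cumulative mean lengths
over all present edges, per class and overall; per-iteration added-edge
lengths are also emitted since the cumulative-vs-instantaneous convention
is a genuine choice.  Group contrasts use run-level permutation of the
final summaries rather than model-based curve inference: the smooth-curve
effect sizes reported for the real cohort depend on the real atlas
geometry and seed network and are not reproduction targets here.

On real data the frozen hub set is the consensus network's rich club.  On
fully synthetic cohorts that derivation is available but comes with a
caveat established empirically during development: growth-model-generated
cohorts place their emergent hubs too centrally (generative models are
known to embed hubs imperfectly in space), so a consensus-derived club on
synthetic data is mildly clumped and its hub-hub edges are not the longest
class.  Experiments that need an anatomically realistic hub set — one
spread over both hemispheres, as real rich clubs are — should instead
treat hub placement as an input via `cohort.planted_hub_set`
(farthest-point sampling over one hemisphere, mirrored), which restores
the rich > feeder/local edge-length structure that real hub dispersion
produces.  With hub placement fixed this way, the two parameter regimes
reproduce the qualitative contrasts: the tighter preterm regime wires
shorter connections overall while the rich-edge count is the least
affected class — the cost/value trade-off (stronger distance penalty,
stronger value weighting) cancels most nearly for long, high-value
hub-hub pairs.

## The synthetic cohort

The generator states a world with the features the analysis assumes:

* **Geometry** — 90 nodes, two mirror-image hemispheric point clouds on
  half-ellipsoid *shells* (semi-axes 30/60/45 mm, 5% radial jitter),
  clamped so no node comes within 5 mm of the midline.  The shell matters:
  cortical parcels lie on a folded sheet, not in a filled volume.  In a
  volume-filling cloud, distance-penalised growth piles high-degree nodes
  at the geometric centre and hub-hub edges come out *short*; on a shell,
  hubs are spatially distributed and hub-hub edges are long, reproducing
  the rich > feeder > local edge-length ordering real connectomes show.
  Mirroring makes non-mirror cross-hemisphere pairs provably farther apart
  than the matching intra-hemisphere pairs.
* **Covariates** — ~29% preterm (birth age uniform 24–36.9 wk; term
  37–42 wk); scan delay ~ N(1 + 0.55·(40 − GA), 1.2) clipped positive, so
  delay averages ~1–2 weeks and correlates negatively with birth age, as in
  the real cohort; PMA = GA + delay, capped at 45 wk.
* **Ground truth** — each subject's binary scaffold is grown by the engine
  itself at the group's parameters (defaults: the representative term and
  preterm exponents above).  All subjects share a common partial network
  (75% of the smallest subject's edge count, grown once at the term
  parameters): the stereotyped core of real cohorts, without which a 60%
  consensus mask would strand synthetic subjects below any realistic
  density target and the 95%-prevalence seed would be empty.
* **Density** — raw binary density 0.20 at 40 wk PMA, +0.005/week, so the
  post-mask cohort supports both a 10% mean-density absolute threshold and
  exact 10% per-subject thresholding.
* **Weights** — counts on present edges are 1 plus a negative binomial
  with mean 600·exp(-d/60 mm) − 1 and shape 20 (coefficient of variation
  ~0.2 on strong edges); no quantitative count distribution is published
  for this kind of data, so any positive, distance-decaying count model is
  defensible — this one makes absolute thresholding sparsify long edges
  first, as real tractography does, while keeping edge survival consistent
  enough across subjects that a realistic share of edges reaches the 95%
  prevalence the seed rule assumes.  (A geometric count model, CoV ≈ 1,
  leaves the 95%-prevalence seed empty — no edge survives thresholding
  that reliably.)

What the generator does *not* emulate: tractography error structure,
motion, hemispheric asymmetries, lobar anatomy, or any biological process
of connection formation.  A green test on synthetic cohorts therefore
establishes internal correctness of the pipeline (estimator consistency,
invariants, direction-of-effect logic), not anything about real neonatal
data.

Parameter-recovery experiments deliberately use a different rng stream for
fitting simulations than for generation, so a recovery success reflects the
estimator rather than shared noise.

## Numerical choices and degenerate cases

* Rounding of fractional edge targets: half away from zero (so a 0.10
  target on N = 90 gives 401 of 4005 pairs).
* Empty networks: efficiency 0, path length NaN, modularity 0.
* Star-like graphs admit no degree-preserving swap; the rewirer returns
  after exhausting its retry budget (40× the requested swap count), logging
  the shortfall.
* Empty edge classes report count 0 and NaN mean length.
* An empty seed network is legal: growth starts from nothing.
* All randomness flows through `numpy.random.Generator`; cohort generation
  and pipeline runs spawn child streams from a single root `SeedSequence`,
  so every artifact is reproducible from one integer.

## Known limitations

* One simulation per grid point makes the energy landscape noisy at fine
  grid resolution; the argmin inherits that noise.  The replicate knob
  trades compute for variance.
* The spectral modularity maximiser is a deterministic heuristic; it can
  return a slightly sub-optimal partition on adversarial graphs (the suite
  checks it against greedy agglomeration on planted-module graphs).
* Growth cost is O(N² · m) per run from the full value-matrix recompute;
  fine at N = 90, not designed for N in the thousands.
* The pipeline emits tidy tables for external inferential statistics; no
  spline/mixed-model fitting is performed in-package.
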