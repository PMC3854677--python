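# Methods

## Model

A typed interaction network records, for unordered drug pairs, an
interaction type x_ij drawn from an alphabet of K ≥ 2 labels.  The model
family is the stochastic block model with typed edges: a partition P of the
drugs into groups, together with, for every group pair (α, β), a probability
vector q_{αβ} on the K-simplex giving the chance that a pair of drugs in
those groups interacts with each type.  The generative assumption is that
x_ij depends on (i, j) only through their groups.

Given the observed part of the network, the probability of a type for an
unobserved pair is obtained by Bayesian model averaging: sum over partitions
and integrate over the q matrices with a uniform ("no prior knowledge")
prior.  The q integrals factorize over group pairs and have the closed form

    ∫_simplex Π_k q_k^{n^k} · (K−1)! dq  =  (K−1)! Π_k n^k! / (n + K − 1)!

— the mean of Π_k q_k^{n^k} under Dirichlet(1, …, 1), where n^k = n^k_{αβ}
counts observed type-k interactions between the groups and n their total.
Collecting logs over group pairs defines the partition weight H(P)
(`compute_H`), and the posterior for a pair reduces to the exp(−H)-weighted
average of the Laplace-smoothed rate (n^k + 1)/(n + K) between the pair's
groups.  The (K−1)! prior-density constant is kept in every factor (it does
not cancel between partitions with different numbers of occupied groups); a
switch (`include_prior_constant`) exposes the bare-integral variant.

## Sampling

The partition sum is estimated with a Metropolis chain over assignments of
the N drugs to N *labeled* groups: propose moving a uniformly chosen drug to
one of the N−1 other groups (a symmetric proposal under which every
partition is reachable) and accept with probability min(1, e^{H−H'}).  The
stationary distribution is exp(−H)/Z over labeled assignments; a partition
with g occupied groups is represented by N!/(N−g)! labeled states, and all
exhaustive small-network checks in the test suite enumerate that same
labeled space, so the sampler is validated against exactly the measure it
samples.

Protocol (defaults in `SamplerConfig`):

- **Chains** — 50 independent chains of 200 recorded partitions each,
  pooled; each chain starts from an independent uniformly random
  assignment.  Chains run sequentially but own disjoint RNG streams spawned
  from one seed sequence, so results do not depend on execution order.
- **Thermalization** — a chain is declared equilibrated when the means of H
  over two consecutive windows of 20 sweeps (1 sweep = N elementary moves)
  differ by at most one pooled standard error, with a hard cap of 10,000
  sweeps (warning, or error in strict mode, when the cap is hit).
- **Thinning** — automatic by default: after burn-in, the decorrelation
  time of H is estimated from a 50-sweep calibration stretch as the first
  lag at which its autocorrelation drops below 1/e, clipped to [1, 25]
  sweeps.  A fixed integer thinning can be supplied instead; the heavier
  verification studies fix it to 3 sweeps to keep runtimes predictable.
- **Arithmetic** — all factorials via log-gamma lookup tables; H is updated
  incrementally per move (only the group-pair blocks touching the source
  and destination groups change) and agrees with from-scratch recomputation
  to ~1e−13 per move (tested).  The move loop is a compiled (numba) kernel;
  each batch of proposals consumes pre-drawn uniform variates, so a chain
  is a deterministic function of its seed.

Observation semantics: in **heldout** mode only the network's explicit
observations enter the counts (unobserved pairs are missing data — used for
exhaustive-screen validation); in **fully-observed** mode every pair of a
binary network is an observation, absence meaning "no interaction" (used
for database snapshots).  When a scored pair is itself observed, its own
contribution is removed from the counts before evaluating the estimator
(leave-self-out), so fully-observed scoring is not contaminated by the edge
being scored.  Arbitrary pairs can additionally be masked, which the
discovery simulation uses for a target drug's untested pairs.

## Benchmark predictors

- **Baseline** — the overall rate of each type among observed interactions;
  the same vector for every query.
- **Neighbor** — similarity S_ij = fraction of commonly reported partners
  with equal interaction type (undefined without common partners; a drug's
  similarity to itself is 1).  Candidate pairs (k, l) with known type are
  ranked by S_ik·S_jl; the top candidate's type is transferred.  Ties break
  by the larger min(S_ik, S_jl), then lexicographically; with no
  positive-product candidate the baseline vector is returned.  Undefined
  similarities are excluded from the ranking rather than treated as zero,
  keeping "defined but zero" distinguishable from "no evidence".
- **Prism II** — agglomerative clustering from singletons: at each step
  merge the two groups minimizing (mean cross-group profile distance) +
  w·ΔS, where the profile distance is 1 − S_ij (1 when undefined) and ΔS is
  the increase in total monochromaticity entropy, S(v) = n·[−f₋ln f₋ −
  f₊ln f₊] summed over group pairs, computed from the counts of
  synergistic-like (−) and antagonistic-like (+) interactions.  For K > 2
  alphabets only polarized types enter the entropy (additive is neutral;
  suppressing counts as antagonistic-like); the mapping lives on the
  alphabet and can be overridden.  The tree is cut at the fewest-groups
  nested partition whose total entropy is ≤ t times the single-group
  entropy; predictions then use the same Laplace estimator as the block
  model, restricted to that one partition (the two coincide exactly on a
  single-partition sample set — tested).

  Free parameters default to w = 1 and t = 0.1, calibrated on synthetic
  perfectly-monochromatic fixtures: t must be small enough that such a
  network is cut at its zero-entropy partition rather than at a coarser
  merge whose entropy merely dips below the bound.  Performance is not
  sensitive to w on those fixtures (block structure is recovered for any
  positive weight when profiles are clean).

## Evaluation protocols

- **Sub-sampling validation** — keep a uniformly random ⌈f·M⌉ subset of the
  M observed pairs, fit, predict the complement; report exact accuracy and,
  for ordered alphabets, the ±1-level accuracy (a prediction one step off
  on the synergistic < additive < antagonistic < suppressing scale counts
  as correct), with standard errors over repetitions.  Sub-sampling is
  uniform over pairs, not stratified by type.
- **Relative improvement** — (F_SBM − F_X)/(F_X − F_B): the accuracy gain
  over method X in units of X's own gain over the baseline.  Undefined
  (NaN + warning) when X ties the baseline; when X is below the baseline
  the sign flips, flagging a comparison against a method that underperforms
  the trivial rate.
- **Snapshot detection** — diff two snapshots over their shared drugs into
  persistent / novel / spurious / never-added pairs, score every pair of
  the earlier snapshot in fully-observed mode, then: novel ROC = added
  pairs vs never-added pairs on p(interaction); spurious ROC = removed
  pairs vs persistent pairs on −p(interaction) (removed edges should score
  low; negation keeps one AUROC implementation).  AUROC is the rank-based
  Mann–Whitney estimator with ties counted ½, identical to the trapezoid
  area under the sensitivity/(1−specificity) curve (tested to 1e−9).
- **Discovery simulation** — all pairs of a target drug start unknown
  except one seed interaction; each iteration masks the remaining unknown
  pairs, runs the sampler, queries the highest-scoring candidate, reveals
  the truth and iterates.  The feasible region is bounded above by
  min(queries, degree) (oracle) and below by the uniform-random expectation
  q·d/C for d true partners among C candidates.  The sampler is re-run
  every iteration by default (a reuse switch trades staleness for speed).

## Synthetic data

Generators draw every pair's type from the planted group-pair distribution
θ_{αβ}, so ground truth is exact.  Defaults mirror the two data regimes the
method targets: exhaustive matrices (13 drugs / K=3 and 21 drugs / K=4,
dominant-type probability 0.8 — strong but imperfect monochromaticity, as
in real combination screens) and sparse binary databases (assortative
planted partition, e.g. 100 drugs, 4 groups, within-group edge probability
0.45, between 0.02 — a mean degree of ~12, the typical-drug degree of the
large interaction databases scaled to 100 drugs, so that a degree-10
discovery target is an ordinary group member rather than an anomaly the
model would rightly refuse to co-classify).  Snapshot fixtures are built by *degrading* the planted
network: hidden true edges become the later snapshot's novel interactions
(and therefore carry block structure, as real database additions do), while
injected random non-edges become its spurious ones.

What these fixtures do not emulate: degree heterogeneity within groups,
overlapping mechanisms, reporting bias, and drug-name noise of real
databases.  Passing the planted-recovery tests shows the inference machinery
is correct and well-calibrated on its own model class, not that real-world
AUROC values will match.

## Verification scales and numerical choices

Exhaustive oracles are feasible at 6 drugs (6^6 labeled assignments) for
posterior agreement (tolerance 0.02, the Monte-Carlo error of the 50×200
protocol) and at 5 drugs for stationarity (χ² against the exact Boltzmann
distribution over all 52 set partitions, 10^5 sweeps recorded every 5th —
thinning respects the χ² independence assumption).  The planted studies use
60 drugs (typed, 3 groups) and 100 drugs (binary, 4 groups) with reduced
chain counts (4–6 chains × 100–150 samples), sizes at which one CPU
completes the full suite in minutes while leaving comfortable margins on
every bound.  Ties in argmax classification break to the lowest type index;
candidate ties in discovery break alphabetically; both make seeded runs
bit-reproducible.

## Known limitations

- The Prism II free parameters are fixture-calibrated defaults, not values
  fitted to any published screen.
- Group-pair counts are dense (G = N potential groups), so memory is
  O(N²K); fine for hundreds to a few thousand drugs, beyond which both the
  count table and the full 50×200 protocol become expensive.
- Only pairwise interactions are modeled; no degree correction, hierarchy,
  or three-way interaction tensors.
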