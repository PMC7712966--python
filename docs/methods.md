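# Methods

## Model

A frame of a trajectory is reduced to a bit-vector x<sub>i</sub> ∈ {0,1}<sup>M</sup>
of pairwise contacts (d(u, v) < cutoff, strict inequality; plain Euclidean
distances, no periodic boundaries).  Columns constant across all frames are
removed before modelling; M always denotes the pruned count.  The data are
modeled as a Bernoulli mixture: state k emits contact j with probability
μ<sub>kj</sub>, independently across j, and states are drawn with weights π.

Priors:

* π ~ Dirichlet(α, …, α) with **α = M + 1**.  This choice makes the
  collapsed likelihood ratio for dividing a state into two parts
  asymptotically insensitive to M, so refining the structural detail (more
  points, more contacts) does not by itself change the inferred number of
  states.  α is computed from the pruned M — the feature count the
  algorithm actually sees — and is recomputed per dataset.
* μ<sub>kj</sub> ~ Beta(1, 1) independently.  The flat choice yields the
  conjugate Beta(N<sub>kj</sub>+1, N<sub>k</sub>−N<sub>kj</sub>+1)
  posterior used throughout and makes all collapsed marginals analytic.
* Uniqueness factor ∏<sub>k&lt;l</sub>(1 − B<sub>kl</sub>), with B the
  Bhattacharyya coefficient between prototype rows (with square roots:
  B(p, q) = ∏<sub>j</sub>[√(p<sub>j</sub>q<sub>j</sub>) +
  √((1−p<sub>j</sub>)(1−q<sub>j</sub>))], so B(p, p) = 1 holds exactly).
  Parameter sets containing two identical prototypes get zero prior
  density, removing the redundant-component degeneracy that plagues
  maximum-likelihood mixture fitting.

Classification responsibilities include the mixture-weight factor:
P(z<sub>i</sub>=k | x<sub>i</sub>, θ) ∝ π<sub>k</sub>
∏<sub>j</sub> μ<sub>kj</sub><sup>x<sub>ij</sub></sup>(1−μ<sub>kj</sub>)<sup>1−x<sub>ij</sub></sup>.
A `--no-pi` option drops π<sub>k</sub> for comparison (prototype-only
classification); the default includes it, as consistency with the joint
model requires.

All probability arithmetic is in log space; −∞ is a representable value
(impossible event), not an error.

## Collapsed marginal

Integrating π and μ out of P(x, z | θ) P(θ | U) gives

log P(x, z | K) = log Γ(Kα) − log Γ(N + Kα)
  + Σ<sub>k</sub> [log Γ(N<sub>k</sub> + α) − log Γ(α)]
  + Σ<sub>k,j</sub> log Beta(N<sub>kj</sub> + 1, N<sub>k</sub> − N<sub>kj</sub> + 1).

This quantity drives split/join acceptance and is validated in the tests
against analytic micro-integrals and Monte-Carlo integration.

## Sampler

Each sweep: one recategorization, one reclassification, one split-or-join
attempt (50/50 when both are available; an unavailable move counts as a
rejection).  The composition of one of each per step is a convention.

* **Recategorization** redraws every z<sub>i</sub> from its
  responsibilities.  The chain is restricted to *surjective* labelings
  (every category occupied): a joint draw that would empty a category is
  rejected and the previous z kept.  Because the unrestricted conditional
  is an independence proposal, this accept/reject rule is exact
  Metropolis–Hastings on the restricted support.  Consequently K always
  equals the number of occupied categories and 1 ≤ K ≤ N.
* **Reclassification** proposes θ′ from the conjugate posterior under the
  Dirichlet/Beta prior and accepts with probability ∏(1 − B′<sub>kl</sub>).
  Proposal density × acceptance weight is symmetric in (θ, θ′), so the
  move leaves the uniqueness-weighted posterior over θ invariant.
* **Split** picks a splittable category k uniformly (one with some
  0 < N<sub>kj</sub> < N<sub>k</sub>), one of its varying features j
  uniformly, and routes each member to the new set L with probability
  η<sup>x<sub>ij</sub></sup>(1−η)<sup>1−x<sub>ij</sub></sup> (default
  η = 0.9); an all-L or all-R outcome is redrawn.  The L part keeps label
  k, the R part becomes k+1 and higher labels shift up.  The generation
  probability of the outcome sums over every feature that could have
  produced the same partition, each term renormalized by
  (1 − P(all-L) − P(all-R)) for the redraw rule.
* **Join** merges the adjacent label pair (k+1 into k), k uniform on the
  K−1 choices.  With this labeling convention every join is the exact
  inverse of exactly one split, so the Metropolis ratio —
  collapsed-marginal ratio times generation-probability ratio — satisfies
  detailed balance on labeled states.  Label mixing across non-adjacent
  pairs is supplied by recategorization, which has full support at fixed
  K.  An accepted dimension change is followed immediately by a fresh
  conjugate θ draw at the new K and a standard reclassification (if the
  reclassification is rejected, the fresh draw is kept — the old θ has the
  wrong dimension).

Earlier designs that retained empty categories as bookkeeping were
abandoned: the degenerate-partition redraw means no split can recreate an
empty category, so joins absorbing one are unbalanced (or must always be
rejected), and K drifts upward without bound.  The surjectivity
restriction removes the problem exactly.

### Exactness

With the uniqueness factor disabled, all three move families leave the
same distribution invariant — the collapsed posterior
P(z | x, U) ∝ P(x, z | K) over surjective labelings — and the test suite
verifies the sampled partition posterior against exhaustive enumeration
(weight b!·P(x, z | K=b) for a partition with b blocks) on a tiny
instance, within Monte-Carlo standard errors.

With the uniqueness factor active (the default), reclassification targets
the uniqueness-weighted posterior while split/join ratios use the plain
collapsed marginal, as the method prescribes; the exact stationary law of
the mixed chain then has no closed form.  Its intended effect is checked
by invariants instead: no retained sample contains two categories with
B = 1, and the K distributions behave as described below.

### Dimension-move acceptance rate

At protocol scale (N = 1000) the generation probability of a specific
partition of an n-member category is of order e<sup>−cn</sup> while the
reverse join generation probability is ~1/K, so the Metropolis log-ratios
of dimension moves have magnitudes of tens to hundreds of nats: splits
that pay for themselves are accepted essentially deterministically during
burn-in, and at equilibrium both directions almost never fire (measured
0.2–0.4% over a run).  The K posterior is correspondingly concentrated
(often a point mass or two adjacent values).  This is an intrinsic
property of using collapsed marginals in the acceptance ratio at large N,
not a convergence failure — the categorizations themselves equilibrate
through the per-frame Gibbs moves.

## Synthetic benchmark systems

Three geometric systems emulate slow conformational transitions; each is a
time series of N frames (default 1000) whose contact map changes
monotonically, so classification quality is measurable as grouping in
time.  Gaussian noise of width σ = 0.1 is added to every coordinate after
the deterministic motion; contacts use cutoff 2 (distance units).

* **chomp** — two unit-spaced arms of ⌈P/2⌉ and ⌊P/2⌋ points hinged at the
  origin (2-D); the inter-arm angle closes linearly from 150° to 1°.  A
  cross-arm pair at matching arc length s enters contact near angle 2/s
  rad, so contacts zip up progressively from the hinge outward and —
  because the hinge closes almost completely — the contact front traverses
  arms hundreds of points long.  (Stopping at ~10° would freeze the front
  ~11 points out and leave all more distal points inert, making the
  benchmark's structure collapse as P grows.)
* **heli** — a unit-spaced line of P points rotating rigidly by 180° about
  its midpoint (3-D), plus a static reference line of ⌊P/3⌋ points offset
  0.5 out of plane.  The reference is logically necessary: a lone rigid
  rotation preserves every internal distance and would yield zero varying
  features.
* **glob** — three ⌊P/3⌋-point spheres of radius 1.5 (golden-angle point
  placement) at mutual separation 5.5, chosen so initial surface gaps
  (2.5) exceed the cutoff and no cross-sphere contact exists at frame 0.
  The right sphere swings 90° behind the plane and back
  (ψ(t) = 90°·sin πt/T); the top sphere descends 2 units linearly,
  closing its gaps below the cutoff late in the trajectory.

Because points sit at unit-ish spacings, some pairs lie almost exactly at
the cutoff and flip stochastically under noise; they survive pruning as
uninformative near-Bernoulli(½) columns.  This is a deliberate property of
the benchmark: the classifier must tolerate a substantial fraction of
noise features (they acquire μ ≈ ½ in every state and cancel out of the
classification).

What the generators do **not** emulate: real protein features such as
correlated contact formation, secondary-structure constraints, or recrossing
dynamics (the motions are monotone in time).  Passing these benchmarks
demonstrates correct inference on slowly varying, time-ordered contact
data; it does not by itself validate state decomposition of equilibrium
trajectories that revisit states, although nothing in the model assumes
time ordering — only the *scoring* does.

## Evaluation metrics

For a categorization z of time-ordered frames with T adjacent label
changes and k distinct labels:

* **left score** = 100·(1 − (T − (k−1))/N): every transition beyond the
  k−1 required ones marks a miscategorized frame.
* **right score** excuses boundary oscillation: adjacent-transition counts
  form a weighted graph over labels; transitions along the maximum-weight
  simple path visiting every label are excused, and only the remainder
  count as errors.  The maximum-weight path is found exactly by
  Held–Karp subset DP up to 12 labels, greedily (heaviest edges first,
  degree ≤ 2, acyclic) beyond — the exact regime covers everything the
  benchmarks produce.

Both scores are label-permutation invariant.  Across pooled posterior
samples the summary statistic is the mean, reported with the
interquartile range.  K histograms count occupied categories per retained
sample.  Per-K maximum-posterior parameters and representative frames
(the frame maximizing each category's responsibility; ties to the lowest
index) support structural inspection of the inferred states.

## Protocol defaults and problem sizes

5 independent chains × 1000 sweeps, burn-in 500, thinning 10 (250 pooled
samples), started from all frames in one category; η = 0.9 (any value in
(0.5, 1) is admissible); α = M + 1.  An 8-chain × 1250-step variant used
for protein work is available by configuration.  The packaged benchmark
scripts run the three systems at P ≈ 222 and N = 1000, with reduced-size
variants (P = 18, N = 125…2000) for scaling studies; these sizes keep a
full reproduction on one CPU in the minutes range while matching the
benchmark conditions.

## Numerical choices

* Conjugate Beta draws are clipped to [10⁻¹⁵, 1−10⁻¹⁵] so log-space
  matrix products never meet exact 0/1 prototypes; user-supplied boundary
  prototypes take a slower exact path with the 0·log 0 = 0 convention.
* Responsibilities are computed via one N×M×K BLAS product per sweep;
  sufficient statistics via a one-hot product; split/join marginal ratios
  via O(M) deltas of the collapsed marginal.
* Per-chain RNG streams are seeded from (seed, chain_id), so ensembles are
  bit-reproducible under any execution order.
* Ties in representative frames and best-θ-per-K resolve to the lowest
  frame index / earliest (chain, step).

## Known limitations

* No periodic-boundary distance handling.
* The uniqueness-weighted stationary law is approximate in the sense
  described under *Exactness*; only the U-prior chain is exactly
  characterized.
* Dimension-move acceptance is rare at large N (see above), so the K
  posterior should be read as a point estimate with limited spread rather
  than a fully mixed distribution over K.
* The greedy path fallback beyond 12 labels is a heuristic; all shipped
  benchmarks stay within the exact regime.
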