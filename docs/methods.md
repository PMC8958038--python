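# Methods

This note documents the models implemented in `netrepurpose`, their
assumptions, the numerical choices that affect results, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Scoring models

### Proximity

The raw statistic is the closest-distance average
`d(T,S) = (1/‖T‖) Σ_{t∈T} min_{s∈S} d(t,s)` with unweighted hop
distances. Edges are treated as unweighted everywhere: the confidence
column of the input network is used only to threshold which edges exist
(default 0.8), after which the graph is purely topological.

The null resamples **both** the target-like and the disease-like set,
degree-matched, and recomputes `d` per permutation (default
`n_perm = 1000`); `z = (d_obs − μ_R)/σ_R` with the population (ddof 0)
standard deviation of the permutation distances. Degree matching uses
degree-contiguous bins of 100 nodes (nodes sorted by degree with
lexicographic tie-break; a final remainder bin smaller than half the bin
size is merged into its predecessor, so no bin is degenerately small).
A one-sided lower-tail normal p is reported alongside an empirical
permutation p with the `(1 + #{d_null ≤ d_obs})/(n_perm + 1)` correction,
since a normal tail on a discrete, bounded distance is an approximation.
Targets that cannot reach any disease gene are excluded from the mean
with a warning; a pair whose targets reach nothing is reported as
unscored rather than imputed.

Because the null resamples the disease set as well, the z of a fixed
disease set against many random target sets shares a common offset
driven by that particular disease draw (how reachable the set happens to
be relative to degree-matched resamples). This matters for calibration
experiments — see "Validation protocols" below.

### NEAT

Crosstalk `x` is the number of distinct edges with one endpoint in each
set; an edge inside the intersection of overlapping sets counts once,
which keeps the count symmetric and bounded by the maximum possible
crosstalk `n_x = |T|·|S| − o − o(o−1)/2`, `o = |T∩S|`. The null is a
hypergeometric in **node counts**: `μ_H = nK/N` and
`σ_H = sqrt(μ_H·(N−K)/N·(N−n)/(N−1))` — exactly the mean and standard
deviation of `Hypergeom(N, K, n)` (the test suite verifies this against
`scipy.stats.hypergeom`). This parameterization ignores node degrees
entirely. On a network with mean degree `k̄`, the expected crosstalk of
random sets is roughly `k̄·μ_H`, so NEAT's z is systematically positive
on any realistically dense network and grows with degree heterogeneity.
We implement it in this form deliberately and document the consequence:
in the calibration protocol NEAT is the one method whose null z is far
from centered (mean ≈ +1.4 on the 2000-node test network), consistent
with its known propensity for false positives. Treat NEAT z values as a
ranking signal, not as calibrated significance.

### BinoX

The null is `Bin(n_x, p_x)` with `p_x` estimated as the mean fraction
`x_i/n_x` of crosstalk over `M` degree-preserving randomizations of the
network (default `M = 100`, configurable; larger M stabilizes `p_x`).
Randomization is by attempted double-edge swaps: `⌈swap_factor·|E|⌉`
attempts (default `swap_factor = 10`), each picking two edges
{a,b},{c,d} and rewiring to {a,d},{c,b} unless a self-loop or duplicate
would result; failed attempts are skipped and counted. Ten attempts per
edge is a standard burn-in for approximate uniformity over the
degree-fixed graph ensemble. `p_x ∈ {0, 1}` cannot be normalized and
raises a typed error suggesting a larger M. When many pairs are scored
at once the M randomized networks are generated once and reused for all
pairs, which is how the batch estimation is defined in the first place.

### ANUBIX

The null holds the disease set fixed and samples `n_samples = 100`
degree-matched target-like sets, recording their crosstalk with the
disease set. A beta-binomial `BetaBin(n_x, α, β)` is fitted to these
counts by maximum likelihood (Nelder–Mead in log-parameter space,
method-of-moments start, never accepted if worse than the start). The
fitted mean `n_x α/(α+β)` and standard deviation normalize the observed
crosstalk. When the sample variance does not exceed the binomial
variance the beta-binomial MLE diverges (α+β → ∞); the fit then falls
back to a near-binomial with `α+β = 10⁶` at the sample-mean proportion
(with a half-count pseudo-observation so all-zero samples stay off the
boundary). This fallback is common for drugs with very few targets on a
sparse network, where the 100 sampled crosstalk counts are mostly 0–2;
it is logged and harmless — the null simply reduces to the binomial.
No correction for non-random intra-set interactions is applied.

### Orientation, p-values, similarity

Proximity associates through *small* distances, the crosstalk methods
through *large* counts; `oriented_score` maps every method onto a common
"higher = stronger" scale (z for crosstalk methods, −z for proximity),
and p-values are one-sided normal tails in the direction of association.
Drug–drug similarity computes the method's z between a candidate's
targets and each approved drug's target set, combined as `e^(−min z)`
(proximity) or `max z` (crosstalk). Approved sets identical to the
candidate's are excluded by default (leave-one-out): without it, a
candidate that *is* an approved drug matches itself perfectly and
inflates benchmark performance.

## Benchmark construction

Order of operations: (1) restrict all sets to network nodes; (2) drop
drugs with zero in-network targets and diseases with fewer than 20
in-network genes; (3) approved/off_label → positive, contraindicated and
clinical_trial → excluded (a sensitivity flag reassigns them to
positive), unknown → negative, with unlisted combinations materialized
as unknown; (4) exclude negatives with target–gene overlap. The overlap
filter touches only negatives, so the positive count is invariant to it.
Provenance counts are recorded at every stage and conserve
(positive + negative + excluded = all combinations). Time-stamped
relabeling flips listed negatives to positives (flagged `new_positive`);
relabeling an excluded or absent pair is an error, an already-positive
pair a logged no-op. Identifier matching is exact-string; ontology
mapping is out of scope.

## Evaluation

All evaluation consumes oriented scores, so one code path serves every
method. AUROC is the Mann–Whitney probability (ties = 1/2); AUPR uses
step-wise, non-interpolated precision (interpolation choices change AUPR
and are a known source of disagreement between tools). The
classification threshold is the score minimizing |sensitivity −
specificity| over midpoints between consecutive distinct scores (±∞
included), ties broken toward higher sensitivity; recall is the fraction
of positives at or above it. Balanced AUROC keeps all positives and
draws equally many negatives without replacement, 100 times; the same
negative index draws are reused across methods so the default Wilcoxon
signed-rank comparison is paired (rank-sum is available unpaired).
The prediction cutoff is `μ_z + 2σ_z` with the population standard
deviation — a descriptive cutoff, not an inference, chosen so reruns
reproduce it exactly. Degenerate or unscored pairs are excluded from
evaluation with logged counts, never imputed. MCC and F1 at the chosen
threshold are computed and exported but gate nothing.

## Synthetic data

The generator emulates the *shape* of the real inputs: a
preferential-attachment network (heavy-tailed degrees — the feature the
degree-aware nulls exist to handle; an Erdős–Rényi graph would not
exercise them), diseases as connected neighborhood-grown modules of
20–60 nodes, and drugs with 1–5 uniform targets (median 3, matching the
few-targets regime of approved drugs). Defaults: 2000 nodes, attachment
parameter 3 (mean degree ≈ 6), 5 diseases, 30 drugs, half the drugs
given one "approved" disease. Signal is planted for each positive pair
by rewiring each target's edges onto uniformly chosen disease genes with
probability `signal_rewire_prob = 0.5` per edge — degree-preserving for
the target, so planted positives do not confound degree-based nulls —
plus target–gene overlap planted at class-conditional rates 0.3
(positives) vs 0.02 (negatives), reproducing the qualitative overlap
enrichment of real positives. Negatives get uniform targets and no
rewiring.

What the generator does **not** emulate: confidence-score structure,
correlated multi-disease drugs, and — importantly — target-set
similarity among drugs approved for the same disease. Real
same-indication drugs hit the same pathways; here each positive drug's
targets are independent uniform draws that are only connected *through*
the disease module. Consequently drug–drug similarity on synthetic data
lacks the direct target–target channel it enjoys in real data, while
direct drug–disease association measures the planted signal itself and
sits near AUROC 1. The real-world finding that similarity-based
repurposing outperforms association-based repurposing therefore does
*not* reproduce on this generator, and passing or failing that ordering
here says nothing about real networks. Passing pipeline tests shows the
machinery separates planted signal from degree-matched background; it
does not validate biological performance.

## Validation protocols (`netrepurpose.protocols`)

* **Calibration**: on one 2000-node preferential-attachment network, 8
  uniformly drawn 40-gene disease sets are each scored against 25
  uniformly drawn 5-node target sets (200 null scores per method); a
  calibrated null gives pooled mean z ≈ 0 and ≈5% |z| > 1.96. Several
  disease sets are used because the proximity null's shared
  disease-set offset (above) dominates the pooled mean when a single
  disease set is used; batching averages that nuisance out. NEAT fails
  this check by design of its printed null (see above); proximity,
  BinoX and ANUBIX pass.
* **Planted pipeline**: simulate at defaults (30 drugs × 5 diseases,
  rewire 0.5), score all four methods, balanced AUROC per method —
  all well above 0.8. The zero-signal control (rewire 0, equal overlap
  rates 0.02) is run at 150 drugs × 5 diseases: the sampling standard
  deviation of a null AUROC scales with the number of positives
  (≈0.035 at 75 positives vs ≈0.09 at 15), and the larger control keeps
  the [0.4, 0.6] window a ≈3σ check rather than a coin flip.
* **Parameter recovery**: beta-binomial MLE on 1000 draws from
  `BetaBin(100, α=2, β=5)` recovers both parameters within ~20%.

Problem sizes were chosen so the full protocol suite runs in a few
minutes on one CPU; all randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning.

## Numerical and engineering choices

* Multi-source hop distances are computed in C via
  `scipy.sparse.csgraph.dijkstra(unweighted=True, min_only=True)` on a
  cached CSR adjacency; node ordering is sorted-by-identifier so every
  array is deterministic.
* Crosstalk is counted via adjacency-set intersections with an explicit
  correction for edges inside the overlap of the two sets; a brute-force
  edge scan serves as the oracle in tests.
* Degree-matched sampling draws without replacement within each bin
  (vectorized top-k-of-uniform in the batch path); per-bin composition
  of a sample always equals the reference set's exactly.
* In `score_all_pairs`, proximity reuses each permutation's sampled
  disease-like set across the drugs of one disease. The per-pair null is
  marginally identical to independent sampling; it induces correlation
  between the null statistics of different drugs for the same disease,
  which affects no per-pair quantity and is irrelevant for rank-based
  evaluation.
* All stochastic operations take an explicit `numpy.random.Generator`;
  nothing reads global random state, and omitting the generator is an
  error rather than a silent time-based seed.

## Limitations

* NEAT's printed node-count null is uncalibrated on dense or
  heavy-tailed networks (by construction; documented above).
* The normal-tail p-values are approximations; for proximity the
  empirical permutation p is the safer quantity at small `n_perm`.
* Beta-binomial fits on tiny `n_x` (drugs with one target against small
  diseases) frequently take the near-binomial fallback; their z-scores
  are then binomial-calibrated, not over-dispersion-corrected.
* Exact-string identifiers only; no ontology mapping, no weighted
  shortest paths, no directed edges, no network inference.
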