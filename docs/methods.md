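# Methods

## Model

The posterior over phylogenies is p(T | Y) ∝ p(Y | T) p(T) for an alignment
Y of nucleotide sequences and an unrooted binary tree T with branch lengths
l_e ≥ 0 in expected substitutions per site.

**Likelihood.** Jukes-Cantor (JC69): uniform base frequencies (1/4 each)
and a single exchange rate, so the transition probabilities along a branch
of length t are p_same = 1/4 + (3/4)e^(−4t/3) and
p_diff = 1/4 − (1/4)e^(−4t/3). Site likelihoods are computed by Felsenstein
pruning over compressed site patterns, with per-node rescaling against
underflow. Gaps and ambiguity codes are fully missing data (all-ones tip
partials); any non-ACGT symbol is treated this way. The likelihood is
invariant to the internal node chosen as traversal root (tested).

**Prior.** Uniform over unrooted topologies (constant, dropped from the
unnormalised density) and Gamma-Dirichlet on branch lengths: total length
TL ~ Gamma(shape α = 1, rate β = 0.1), proportions p_e = l_e/TL ~
symmetric Dirichlet(1). The density is evaluated on the branch-length
vector, which requires the change-of-variables factor TL^−(K−1) for K
edges; omitting it would make Metropolis ratios target a different
distribution. TL = 0 has density zero (log prior −∞); individual zero
branch lengths are allowed under Dirichlet(1). An alternative mode places
independent standard Normals on every embedding coordinate and no tree
term at all; it is unconventional for phylogenetics but removes the
length-inflation tendency discussed below.

## Geometry

Hyperbolic space is represented by the upper hyperboloid sheet
{x ∈ R^(d+1) : ⟨x,x⟩ = −1, x₀ > 0} under the Lorentz form
⟨x,y⟩ = −x₀y₀ + Σ x_i y_i. Only the d spatial ("tangent") coordinates are
stored; projection x₀ = √(1 + |x|²) puts every stored state exactly
on-sheet. The sheet is fixed for all curvatures; κ < 0 enters only through
the metric d_κ(x,y) = arcosh(−⟨x,y⟩)/√(−κ). Consequences used throughout:

* distances are homogeneous in 1/√(−κ), and so is the four-point-condition
  violation δ (the δ-scaling law), which the diagnostics verify to 1e−9;
* κ = 0 cannot be reached as a limit of the formula; Euclidean mode is a
  separate code path that measures plain Euclidean distances between the
  stored coordinates.

**Numerical note.** The Gram entries −⟨x_i,x_j⟩ are computed through the
Lorentz interval identity G = 1 + (|Δx_s|² − (Δx₀)²)/2 rather than
x₀ᵢx₀ⱼ − x_sᵢ·x_sⱼ. The naive product form loses all precision for nearby
points far from the origin (at κ = −1000 on-sheet coordinates reach 1e9,
and the two products cancel to below machine precision); the interval form
reduces the error by a factor ≈ x₀/|Δx|. The arcosh argument is clamped to
[1, ∞) with a 1e−12 guard before evaluation. Even with the stable form,
float64 limits embeddings at κ = −1000 to trees whose distance span keeps
arcosh values below ≈ 25–30; the continuity analyses therefore use short
trees (branch mean 0.05, six taxa).

## Encoding (hydra+-style embedding)

A distance matrix D is embedded in two stages:

1. **Strain (eigen) initialisation**: form A = cosh(√(−κ) D); take the d
   spatial coordinate vectors from the eigenvectors of the d most negative
   eigenvalues scaled by √(max(−λ, 0)), then renormalise each point onto
   the sheet by re-projection. For an exactly embeddable D, A is the Gram
   matrix of the solution.
2. **Stress refinement**: minimise σ² = Σ_{i<j} (D_ij − d_κ(x_i,x_j))² over
   all tangent coordinates with L-BFGS-B and the analytic gradient
   (defaults: 1000 iterations, relative tolerance 1e−8). The result is
   never accepted if it is worse than the initialisation.

A requested curvature of exactly zero is embedded at κ = −1e−10 (flat to
machine precision) and the coordinates rescaled by 1/√(−κ) so that plain
Euclidean row distances reproduce D.

Single-taxon placement solves S H z′ = −cosh(√(−κ) d*) for the new point
given q ≥ d+1 on-sheet anchors and target distances d* (exactly at
q = d+1, least squares beyond), then re-projects the spatial part onto the
sheet. The right-hand side carries the minus sign required by
⟨z_i, z′⟩ = −cosh(√(−κ) d*); round-trip recovery of known points to 1e−6
is the arbiter and is tested in d ∈ {2, 3}.

## Decoding

Neighbour joining turns any symmetric distance matrix into an unrooted
binary tree with branch lengths. It is consistent (additive input ⇒ the
generating tree, exactly) and has ℓ∞ robustness radius 1/2: perturbations
below half the minimum edge never change the topology. Ties in the
Q criterion are broken by the lexicographically smallest index pair so the
decoding — and hence the Markov chain — is deterministic; negative
branch-length estimates are clamped to zero, keeping decoded trees inside
the prior's support. Because δ → 0 as κ → −∞, decoded tree length is
continuous in the embedding coordinates in that regime; the test suite
measures the empirical Lipschitz constant at κ = −1000 (≈ 0.01–0.015 per
unit coordinate change on the fixtures used) and verifies per-direction
proportional scaling of the response, which a jump discontinuity would
violate.

## Sampler

Metropolis-coupled MCMC with chains tempered as β_i = 1/(1 + 0.1(i−1))
(four chains by default). Per generation and chain: a joint Gaussian
perturbation of all n·d coordinates using the chain's lower-triangular
scale factor; decode; score; accept with min(1, exp(β Δlog p)). The
proposal is symmetric, and no Jacobian for the embedding→tree map is
applied (the map is non-injective with a singular Jacobian, and NJ is not
differentiable); this makes the sampled distribution an approximation
whose visible signature is mild tree-length overestimation.

* **Warm-up** (default 10⁴ generations): proposal covariance re-estimated
  every 100 generations as 2.38²/(nd) times the empirical covariance of
  the visited states, from an initial 0.01²·I.
* **RAM phase**: robust adaptive Metropolis rank-one updates
  S S′ ← S (I + η (α − α*) zz′/|z|²) S′ with η = min(1, nd·i^(−2/3)) and
  target acceptance α* = 0.234; adaptation diminishes, preserving
  ergodicity. On a mis-scaled Gaussian target the realised acceptance rate
  converges to the target within ±0.05 (tested).
* **Swaps**: ten adjacent-pair swap attempts every 10³ generations with
  probability min(1, exp((β_i − β_j)(log p_j − log p_i))). Only the cold
  chain is recorded; n_samples evenly spaced post-warm-up samples are
  retained. A fixed seed yields a bit-identical trace.

States whose decoded tree has zero total length (density zero) are
rejected automatically; individual zero branches are valid.

## Synthetic data

The generator produces uniformly random unrooted binary topologies
(sequential random attachment: each new tip subdivides a uniformly chosen
edge) with i.i.d. Exponential branch lengths, mean 0.1 substitutions per
site by default — the short-tree regime of curated benchmark alignments —
and evolves alignments under the same JC69 process the likelihood assumes
(root state uniform at an arbitrary internal node; reversibility makes the
choice immaterial). Sampler-fidelity fixtures use five taxa, internal
edges 0.1 and 500 sites; the continuity fixtures use six taxa with branch
mean 0.05 (see the numerical note above).

What this does and does not show: passing tests demonstrate correctness of
the machinery and agreement with an independent tree-space sampler under
the model's own generative process. Real alignments violate JC69 (unequal
base frequencies, rate heterogeneity, indels), so fidelity on data of that
kind is not established by this suite.

## Baseline sampler

`hyperphylo.reference.nni_metropolis` is a deliberately plain tree-space
Metropolis sampler (uniform NNI moves on internal edges; multiplicative
branch-length moves with the log-multiplier Hastings correction) targeting
the same posterior. It never touches the embedding machinery and serves as
the independent comparison: on the synthetic fixtures the embedding
sampler matches its split frequencies within 0.05 and two independent
embedding runs reach ASDSF < 0.05 (the conventional agreement threshold),
with a posterior mean tree-length ratio near 1.01.

## Problem sizes and defaults

Default operating point: dimension d = 3, curvature κ = −1 (quality
saturates for −100 ≤ κ ≤ −1; very flat spaces decode wrong trees, very
curved ones localise the chain). Test-suite and acceptance runs use
5–8-taxon fixtures, 10⁵ generations, 10⁴ warm-up and a single chain for
the long sampler comparisons — on fixtures this small the tempering ladder
is unnecessary and a single chain keeps the suite fast; the multi-chain
machinery is exercised separately.

## Known limitations

* No Jacobian correction (see above): branch lengths, and hence tree
  length, are slightly overestimated relative to tree-space samplers.
* JC69 only; no rate heterogeneity, no model parameters to sample.
* Unrooted trees only; no clock models or rooted decodings.
* Extreme curvature combined with long trees exceeds float64 range for the
  on-sheet coordinates; practical curvature for typical alignments is
  −1000 ≲ κ < 0 with short trees, −100 ≤ κ ≤ −1 generally.
* The four-point-condition diagnostic enumerates all C(n,4) quadruples and
  is intended for n ≲ 64.
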