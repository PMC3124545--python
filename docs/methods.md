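# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `wingshape`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Superimposition

Each specimen is a configuration of k = 19 planar landmarks. Location is
removed by centering, scale by division with centroid size
S = sqrt(Σᵢ ‖xᵢ − x̄‖²), and orientation by the closed-form 2-D
least-squares rotation. Reflections are never applied (determinant +1
only): wings are digitized in one consistent orientation, and allowing an
improper rotation would silently "repair" a flipped specimen instead of
exposing it.

Generalized Procrustes analysis iterates two steps — rotate every
specimen onto the current consensus, re-estimate the consensus as the
normalized mean — until the Procrustes distance between successive
consensuses falls below `tol` (default 1e-10; the metric is scale-free
and cheap). The summed squared residual is non-increasing across
iterations, which the suite verifies. Because the fixed point is only
defined up to a global rotation, the converged consensus is put into a
canonical orientation (principal axis on x, the π ambiguity resolved by
coordinate third moments, rotation only); this makes the output
invariant to input ordering and to arbitrary similarity transforms of
the inputs, to ~1e-8.

Shape distance is the **partial Procrustes distance**: the root summed
squared difference after centering, unit-size scaling and optimal proper
rotation. Tangent-space coordinates are the orthogonal projection
x − (x·c)c at the unit consensus vector c; the consensus maps to zero.
The adequacy check regresses pairwise tangent distance on Procrustes
distance through the origin and reports the uncentered correlation
(Pearson is reported alongside; the uncentered form is the default
because a regression through the origin is the natural null here —
both distances vanish together).

If the cross-covariance in a rotation fit is numerically zero the
rotation is undefined; the identity is returned with a warning rather
than an arbitrary angle.

## Thin-plate splines, partial and relative warps

The bending-energy matrix uses the kernel U(r) = r² log r² on the
consensus landmark distances; it is symmetric positive semi-definite
with exactly three zero eigenvalues (the affine null space), which is
asserted in the suite. Partial-warp scores project each specimen's
tangent deviation onto the nonzero-eigenvalue eigenvectors, separately
in x and y, optionally rescaled by λ^(−α/2). Defaults are **α = 0 with
the uniform component included**: with those defaults the score basis is
an orthonormal rotation of tangent space, total variance is conserved
exactly, and relative warps coincide with a PCA of tangent coordinates.
Both knobs are exposed because published analyses do not always state
them.

The uniform (affine, non-similarity) component is computed by the
complement method: the four affine generators at the consensus are
projected orthogonally to the similarity directions (two translations,
scale, rotation) and orthonormalized, giving a 2-vector basis that is
provably inside tangent space and orthogonal to every nonaffine warp.

Relative warps are the SVD of the column-centered score matrix;
variance fractions are squared singular values over their sum.
Deformation grids evaluate the interpolating TPS on a rectangular grid
(default 20×20, purely cosmetic) spanning the reference with a 10%
margin.

## Metric disparity

For a group of N members, MD = Σᵢ dᵢ² / (N − 1), with dᵢ the member's
distance from the group mean measured in the tangent space referenced to
the grand mean. Because the partial-warp basis is orthonormal, MD from
scores and MD from tangent coordinates agree to machine precision (the
suite checks the identity). Two deliberate choices:

* distances are measured against a **fixed** grand-mean tangent space
  rather than re-running GPA inside every bootstrap replicate — this
  matches computing scores "relative to the total mean", keeps the
  bootstrap cheap, and makes replicates comparable;
* the **group mean is re-estimated inside each replicate**, so the
  bootstrap SE reflects uncertainty in the mean as well as spread.

The SE is the ddof-1 standard deviation over `n_boot` (default 10,000)
seeded resamples. For a two-member group the bootstrap distribution is
fully enumerable (resamples AA/AB/BA/BB) and the suite checks the SE
against that enumeration. Note that MD with the N−1 divisor is *not*
invariant to pooling a group with a copy of itself (the divisor moves
from N−1 to 2N−1); the tests assert the exact value the formula implies.

## UPGMA phenetics

Average-linkage agglomeration with node height = half the merge
distance, so the output is ultrametric and exact on ultrametric input.
Ties are broken by the lexicographically smallest pair of original label
indices — the reference implementations of this clustering leave their
tie rule undocumented, so a fixed deterministic rule was chosen to make
phenograms reproducible across runs and platforms. The implementation is
cross-checked against scipy's average linkage in the suite.

## Maximum parsimony

States 0–9 are bitmasks; '?' contributes the set of states observed for
that character, so missing data never forces a change. Fitch length is
computed by the set algorithm, vectorized across characters, on trees
rooted along the edge adjacent to a fixed anchor leaf (rooted and
unrooted topologies then correspond one-to-one and length is
root-independent).

The search is random-addition Wagner trees followed by branch swapping
(NNI, SPR, or TBR = SPR with rerooting of the pruned subtree), with a
final walk through the island of equal-length neighbors so that multiple
most-parsimonious trees are collected (bounded by `max_trees`). On six
and seven taxa the search is verified against exhaustive enumeration of
all unrooted topologies, including recovering the complete MPT set.

Ensemble CI = ΣM/S and RI = (ΣG − S)/(ΣG − ΣM) with per-character
minima M (distinct observed states − 1) and maxima G (scored taxa −
modal count). The headline CI includes uninformative characters —
whether the classic programs include them is undocumented — and a
variant excluding characters that cannot show homoplasy (M = G) is
reported as `ci_informative`.

Bootstrap support resamples characters with replacement (weight
vectors, so tip encodings are built once per replicate) and searches
with reduced effort (default 10 addition replicates, SPR) — full-effort
searches per pseudoreplicate would dominate runtime for no measurable
change in the frequencies at these matrix sizes. Strict consensus keeps
exactly the splits common to all inputs and reports how many nodes of
the first input were collapsed.

Character changes are mapped by resolving Fitch sets with the classic
backtracking rule — keep the parent's state whenever the child's
preliminary set allows it, lowest state otherwise — which always
realizes the minimum length; a change is non-homoplasious iff its
character's realized steps equal its minimum possible steps. The
ACCTRAN/DELTRAN distinction is not implemented as two behaviours: the
sources this workflow reproduces do not state which optimization they
used, and every quantity reported here (change counts, homoplasy flags)
is identical under both.

## Squared-change ancestral reconstruction

Internal-node values minimize Σ over edges of the squared coordinate
change; the optimum solves a linear system in which every internal node
is the (weighted) average of its neighbors, solved once for all 2k
coordinates. Default is **unweighted** (every branch length 1), because
the input is a cladogram whose branch lengths carry no information;
`weighted=True` uses 1/length weights when meaningful lengths exist and
is the maximum-likelihood Brownian-motion estimator in that case.
Reconstructions are verified against hand-solved normal equations and a
Gauss–Seidel local-averaging oracle, and satisfy the per-coordinate
convex-hull property.

Reconstructed tangent vectors back-project as consensus + deviation
(optionally magnified — published ancestral-shape figures typically
exaggerate, and the factor is a free parameter) and render as TPS
deformations of the consensus.

## Tree comparison and Mantel tests

Trees become distance matrices **cophenetically** (branch-length path
sums; used for the UPGMA phenogram, which has meaningful heights) or
**nodally** (edge counts; used for cladograms). Character sub-matrices
become mismatch proportions over jointly scored characters; taxon pairs
with no jointly scored characters raise by default (silently assigning
a distance would bias the correlation) or take distance 1 by flag.

The Mantel statistic is the Pearson correlation over unordered
off-diagonal pairs; the null comes from joint row/column permutations
of one matrix with p = (count of permuted r ≥ observed + 1) /
(permutations + 1), one-tailed upper, default 9,999 permutations,
deterministic under seed. The statistic matches scikit-bio's, the
p-value matches full enumeration at n = 4, and the empirical type-I
error on independent matrices is within Monte-Carlo error of nominal
(all in the suite). The reported `r > 0.5` flag mirrors the common
1%-significance rule of thumb for matrix correlations; the permutation
p is the primary inference.

## Synthetic data

The generator provides every input the pipeline consumes, with ground
truth:

* **wing template** — 19 fixed hand-placed landmarks (basal cluster,
  leading edge, apex, trailing edge, two vein junctions; ~3:1 aspect),
  centered at unit centroid size. Its bending-energy matrix has exactly
  the 3-dimensional affine null space.
* **tree** — pure-birth with seeded exponential waiting times,
  ultrametric, extended one inter-speciation waiting time past the last
  split.
* **shapes** — independent Brownian motion per coordinate along
  branches, with every increment projected into the tangent space at
  the template so no spurious translation/scale/rotation accumulates;
  i.i.d. Gaussian digitization noise added at the tips only. True
  internal-node shapes are retained. Tip variance follows
  σ²·depth·(2k − 4), verified by Monte-Carlo.
* **characters** — symmetric k-state Mk model via the closed-form
  transition probability; at saturation the pairwise mismatch fraction
  approaches (s−1)/s, verified by simulation.

Defaults mirror the study regime: 81 taxa, 19 landmarks, 119
characters, 9 groups, birth rate 1. σ² = 0.001 per coordinate per unit
time and digitization noise sd 0.005 put the data in the
small-variation regime where tangent-space statistics are valid (the
adequacy correlation on such data exceeds 0.999). The character rate
default is 0.1 per unit time: with mean Yule branch lengths near 0.5
this gives ≈ 0.05 expected changes per branch per character —
informative, far from saturation. Three states per character reflect
that most real morphological characters here are binary or ternary.

What the generator does **not** emulate: correlated landmark
displacements (real wing veins covary), among-character rate variation,
non-neutral/constrained shape evolution, and coding error in discrete
characters. Passing recovery tests therefore show the pipeline is
correct and coherent, not that real data of this size always contain
enough signal.

A limitation worth stating plainly: on 12-taxon pure-birth trees, exact
topology recovery is *not* guaranteed even without digitization noise.
Realized Brownian distances deviate from their clock-like expectation
with relative spread ≈ sqrt(2/(2k−4)) ≈ 24% at k = 19 (independent of
σ², since both signal and spread scale together), and short internal
edges are common under pure birth; measured over 30 seeds, UPGMA
recovers the exact topology in ~1/6 of runs and parsimony in ~1/2,
although the Mantel congruence between the two derived matrices is
detected essentially always. The congruence logic, not exact topology
identity, is the robust property of this design.

## Problem sizes and determinism

The shipped test suite and the acceptance script run at 6–50 specimens,
8–30 taxa and 25–119 characters — sizes chosen so every stochastic
check has a frozen seed and an enumerable or closed-form oracle where
one exists. All randomness flows through `numpy.random.default_rng`
seeds; the pipeline fans one global seed out to per-stage seeds via
`SeedSequence([seed, stage_index])`, records each stage's seed in the
report, and reruns are byte-identical.
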