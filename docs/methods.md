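# Methods

## Model and assumptions

`mdakrls` treats microbe–disease association prediction as bipartite link
prediction with pair-level kernel ridge regression. The working assumption
is the one underlying all interaction-profile methods: entities with similar
association patterns tend to share partners. No information beyond the 0/1
network itself is used — no taxonomy, disease ontology or literature
features — so predictions for an entity with an empty profile are driven
entirely by the other axis's similarities.

Each axis gets two similarities computed from the *training* matrix:

* **GIP kernel**: a Gaussian kernel on profiles whose bandwidth
  `σ = σ′ / mean squared profile norm` self-scales with network density.
  On 0/1 profiles the squared Euclidean distance equals the Hamming
  mismatch count, so distances are accumulated in exact integer arithmetic
  before exponentiation; GIP matrices are symmetric positive definite by
  construction and their entries lie in (0, 1].
* **HIP similarity**: `1 − normalized Hamming distance`, entries in [0, 1].
  HIP matrices can be indefinite; the solver does not assume positive
  semidefiniteness anywhere.

The pair kernel is `K = S_m ⊗ S_d` under **column-major** vectorization, so
`K·vec(Y) = vec(S_d Y S_mᵀ)`. The regularized least squares solution
`vec(F) = K(K+σI)^{-1}vec(Y)` is evaluated through eigendecompositions of
the two small factors and an elementwise filter factor
`λ_d λ_m/(λ_d λ_m + σ)`; the `N×N` kernel is materialized only by the
explicit oracle path (`kronecker_similarity` + `krls_solve_direct`), which
refuses instances above `N = 4000` to keep memory flat. The two branch
scores are fused as `F* = w F_G + (1−w) F_H`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma_G`, `sigma_H` | 30 | Tikhonov regularization per branch. Performance is flat over roughly 5–35; 30 sits safely on the plateau. Unitless (kernel entries are in [0,1]). |
| `w` | 0.8 | Weight of the Gaussian branch in the fused score; 0.8 reflects that the GIP branch is the more informative of the two. |
| `sigma_prime_m`, `sigma_prime_d` | 1 | GIP bandwidth trade-off; 1 leaves the bandwidth entirely to the density normalization. |
| `denom_tol` | 1e−10 | Guard on the eigen-path denominators `λ_d λ_m + σ`. Because HIP matrices may have negative eigenvalues, a pathological combination could cancel σ; the solver then raises rather than amplifying noise. At σ = 30 on realistically sized data this never triggers (similarity eigenvalues are bounded by the matrix dimension). |

Degenerate inputs: an all-zero training matrix gives a zero mean profile
norm; the bandwidth then falls back to `σ = σ′`, which yields a well-defined
all-ones kernel and equal scores everywhere. This keeps every leave-one-out
round total rather than erroring on pathological cases.

## Evaluation protocols

Similarities are recomputed from the current training matrix in every
cross-validation round; nothing is cached across rounds.

* **Global LOOCV**: each known association is zeroed in turn and its score
  compared against all pairs that are zero in the *original* matrix. Rounds
  are aggregated, by default, as the mean per-round normalized rank
  statistic (one AUC per round against the candidate set). Pooling raw
  scores across rounds is also available (`aggregation="pooled"`); it is not
  the default because candidate scores shift between rounds and are not
  directly comparable. With ties, a round contributes half credit per tied
  candidate (midrank convention).
* **Repeated k-fold CV** (defaults k = 5, 100 repeats): positives are
  shuffled per repeat with sub-seed `seed + repeat` and split into k
  near-equal folds; each fold is zeroed, the model retrained, and one AUC
  computed with the fold as positives and the original zero pairs as
  negatives — held-out positives are never counted as negatives. Reported
  as mean ± sample standard deviation (ddof = 1) over repeats.
* **Case study**: a disease's entire row is zeroed before training;
  candidate microbes are ranked by descending score, competition-ranked,
  ties broken lexicographically by microbe identifier for determinism.
* **Parameter sweep**: σ_G and σ_H are swept as a single coupled value with
  w fixed, then w is swept at the best σ.

AUC is the Mann–Whitney rank statistic with midranks, identical to the
trapezoidal area under the threshold-swept ROC curve; ROC point lists come
from scikit-learn's curve sweep while the AUC value itself is computed by
the package and cross-checked in the tests against exhaustive
concordant-pair counting.

## Synthetic data

The generator plants a bipartite stochastic block model: diseases and
microbes are assigned uniformly to `n_blocks` latent blocks and associate
with probability `p_in` within a shared block, `p_out` otherwise. Defaults
(39×292, 8 blocks, `p_in = 0.30`, `p_out = 0.005`, ≈ 470 positives, 20 %
withheld as hidden ground truth) mirror the scale and density of the HMDAD
benchmark, so evaluation runtimes match the real use case. Co-association
blocks are exactly the structure the method's similarity assumption
exploits, which makes hidden-link recovery a meaningful end-to-end check.

What the generator does **not** emulate is the hub-dominated degree
distribution of real curated networks: HMDAD concentrates many associations
on a few well-studied diseases and microbes, whereas the uniform block model
spreads them thinly (mean microbe degree ≈ 1.3 at the default scale). Dense
profiles are much easier to match than near-empty ones, so absolute AUCs on
the synthetic defaults (recovery ≈ 0.74, LOOCV ≈ 0.68, 5-CV ≈ 0.60) sit
well below those published for HMDAD (0.93 / 0.90) — indeed an oracle that
knows the true block memberships cannot exceed ≈ 0.89 here, because ~11 % of
planted positives are pure background noise and many hidden links belong to
microbes with empty observed profiles. Passing the synthetic tests therefore
demonstrates correctness and a genuine structure signal, not the absolute
performance attainable on real, hub-rich data. For the unstructured null
check the common probability `p_in = p_out` is set to 0.05 so the dataset
carries enough positives (≈ 570, ≈ 114 hidden) for a stable null AUC.

## Numerical choices

* Similarity matrices are exactly symmetric by construction (integer
  mismatch counts); the solver additionally symmetrizes inputs as
  `(S + Sᵀ)/2` before `eigh` to wash out any floating-point asymmetry.
* The fused scores are invariant to eigenvector sign flips and eigenpair
  reordering (asserted in tests), so `eigh`'s conventions do not leak into
  results.
* The direct solver refuses systems with condition number above 1e12
  rather than returning noise, and suggests a larger σ.
* All shuffling uses `numpy.random.default_rng` with a single user-visible
  seed; repeat r uses sub-seed `seed + r`, making every protocol
  bit-reproducible.
* Ranked outputs use competition ranking with lexicographic tie-breaks so
  files are byte-stable across runs.

## Problem sizes in the test suite and acceptance script

Oracle-equivalence checks run on random instances up to 6×8 (where the
explicit `N×N` kernel is cheap); end-to-end checks run at the full default
39×292 scale. The acceptance script uses 10 repeats for the 5-fold CV
summary and 5 seeds for the recovery means — enough for stable means at
this scale while keeping the whole run under a minute.

## Known limitations

* Cold-start entities (empty profiles) receive near-uninformative scores;
  the method has no side information to fall back on.
* The closed-form solve is exact but cubic in each axis dimension; very
  large networks (tens of thousands per axis) would need iterative solvers,
  which are deliberately out of scope.
* Scores are relative rankings, not calibrated probabilities.
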