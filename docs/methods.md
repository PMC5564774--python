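# Methods

This note records the models the package implements, the conventions it
fixes where the literature is silent, and the numerical choices that affect
results.

## Target and data model

The response is log₁₀(1/IGC₅₀) with IGC₅₀ in mmol/L, the 50% growth
inhibition concentration for *Tetrahymena pyriformis*; higher values mean
higher toxicity.  A `DescriptorTable` is an n×p matrix of named, finite
descriptor values with unique compound ids and an optional target column
`logIGC50inv`.  Descriptors divide into a graph-computable block the
package calculates itself and externally supplied columns (quantum-chemical
and force-field quantities such as LUMO, ΔE, logP) that enter only through
CSV input.

## Topological descriptors

All indices operate on the hydrogen-suppressed graph; explicit hydrogens in
input files are folded into per-atom implicit counts.

- **Connectivity (χ).** ᵐχ of kind *k* sums Π(δᵥ)^(−1/2) over all connected
  m-edge subgraphs of that kind (path: max internal degree ≤ 2; cluster:
  star; path-cluster: other trees; cyclic subgraphs belong to none of the
  three).  The valence variant replaces the degree δ by
  δᵛ = (Zᵛ − h)/(Z − Zᵛ − 1), which reduces to Zᵛ − h for second-row
  elements and applies the higher-row correction through the denominator.
  Aromatic atoms need no special casing because δᵛ depends only on Zᵛ and
  the hydrogen count.
- **Kappa shape (κ).** ¹κ = A(A−1)²/P₁², ²κ = (A−1)(A−2)²/P₂², and ³κ uses
  the even/odd-A convention ((A−1)(A−3)²/P₃² for even A, (A−3)(A−2)²/P₃²
  for odd).  Pᵢ counts i-edge path subgraphs.  The α correction adds
  Σ(rₓ/r_Csp³ − 1) to both A and Pᵢ, with covalent radii keyed by element
  and hybridization (inferred from bond orders: triple or two doubles → sp,
  any double/aromatic → sp2, else sp3).  Φ = ¹κ_α·²κ_α/A.
- **E-state (S).** Intrinsic state I = ((2/L)²δᵛ + 1)/δ with L the
  principal quantum number; Sᵢ adds the field term Σⱼ(Iᵢ−Iⱼ)/(dᵢⱼ+1)².
  Because the field term is antisymmetric, the molecular sum equals ΣI.
- **Wiener, Randić, Balaban.** W is the half-sum of the BFS distance
  matrix; ¹χ is the Randić index; J = M/(γ+1)·Σ_edges(sᵢsⱼ)^(−1/2) with s
  the distance-row sums and γ the cyclomatic number.
- **Counts.** Donors are heavy O/N atoms carrying ≥ 1 H (counted once per
  heavy atom, not per hydrogen).  Acceptors are O plus N excluding
  pyrrole-type nitrogens (aromatic N bearing H or with three connections)
  and amide nitrogens.  Group matchers (hydroxyl excluding carboxyl, NH₂ on
  carbon, CH=O, nitro in either valence dialect, C≡N, acid anhydride,
  terminal CH₃) are deliberately simple structural rules, stated in the
  docstrings and pinned by tests.  These conventions are declared choices:
  the legacy descriptor software this block mirrors never published its
  exact rules, so we claim consistency with our own definitions, not
  bit-compatibility with that program.

Structure input is parsed with RDKit (MOL/SDF V2000 and SMILES), including
its aromaticity perception; multi-fragment records (salts) are rejected
unless the caller opts to keep the largest fragment.  Atomic masses are
IUPAC standard weights at two decimals (hydrogen kept at 1.008 so methane
and benzene round correctly at the 0.01 level).

Degenerate cases in the batch computation: indices that are undefined for a
molecule (e.g. ³κ when no 3-edge path exists) are emitted as 0.0 in the
descriptor block so the table stays finite; the scalar functions raise
instead, so the convention is visible where it matters.

## ε-SVR engine

The dual problem

min ½(α−α*)ᵀK(α−α*) + εΣ(αᵢ+αᵢ*) − Σyᵢ(αᵢ−αᵢ*),  Σ(αᵢ−αᵢ*) = 0, 0 ≤ α, α* ≤ C

is solved by sequential minimal optimization over the stacked 2n vector
with second-order working-set selection (the pair maximizing the decrease
b²/a among KKT violators), first-index tie-breaking, and exact snapping of
clipped variables onto the box.  This makes the solver deterministic:
identical inputs give bit-identical models, which the serialization tests
exploit.  The stopping rule is the maximal KKT violation gap (default
1e-3 for model fitting, 1e-2 inside GA fitness where only the ranking of
subsets matters, 1e-9 in oracle comparisons).  The iteration cap is
4000·n; the inner loop is numba-compiled when numba is importable and runs
the identical pure-Python code path otherwise.  The bias b is the midpoint
of the KKT interval over free variables.  On rank-deficient kernels the
pair curvature is floored at 1e-12.

Predictions are f(x) = Σβᵢk(xᵢ, x) + b over the stored support vectors
(βᵢ ≠ 0 only).  Kernels: x·y, (x·y + 1)^d (default degree 2), and
exp(−γ‖x−y‖²) with γ defaulting to 1/p.  The bias is always estimated from
the data, never fixed to any dataset-specific constant.

**Standardization.** Features are z-scored on training rows only, inside
every cross-validation fold.  Raw descriptor scales differ by orders of
magnitude (molecular weight vs. orbital energies), which makes unscaled
kernel regression degenerate; scaling is therefore on by default and the
scaling parameters travel with the model.

## Validation metrics

RMSE = √(Σ(pᵢ−eᵢ)²/n); R² = 1 − SS_res/SS_tot on the training partition;
Q² is the same functional applied to the external test set.  Q²'s centring
mean is the test-set mean by default (the formula read literally); the
training-mean convention is available as an argument.  Cross-validation
reports both the pooled RMSE over all held-out residuals (which equals
plain RMSE on the union, and is the quantity optimized everywhere) and the
mean of per-fold RMSEs.  Grid search is exhaustive over
C ∈ {0.1, 0.5, 1, 1.5, 2, 2.3, 3, 5, 10} and ε ∈ {0.01, 0.03, …, 0.25} by
default, with ties broken toward smaller C then smaller ε.

## Two-stage feature selection

**mRMR.** Continuous columns (and the target) are discretized into three
states at mean ± kσ (k = 1, outer bands closed).  Mutual information is the
plug-in estimate on the joint contingency table, in nats.  Ranking is
greedy: first the feature with maximal I(f; y), then repeatedly the
arg-max of I(f; y) − mean_{s∈S} I(f; s) (MID; the MIQ quotient form is
available).  Ties break toward the earlier column, which is what places an
exact duplicate after its original.

**GA wrapper.** Binary masks over the mRMR candidates; size-2 tournament
selection, one-point crossover at 0.75, per-bit mutation at 0.01, elitism 1,
population 50, 100 generations by default.  Fitness is the pooled 5-fold CV
RMSE of an ε-SVR with C = 10 (ε defaults to 0.1) on the masked features;
the fold plan is fixed per run and fitness values are cached per mask, so a
run is bit-reproducible from its seed.  The search-stage C = 10 and the
final tuned (C, ε) are deliberately decoupled: the wrapper only ranks
subsets, the grid search afterwards sets the deployment hyperparameters.
Masks outside the subset-size window (default 3–12) are repaired by
flipping random bits; an empty mask gets one random bit switched on.
Kernel-comparison reports run one GA per kernel over the shared mRMR
candidates.

## PLS comparator

Single-response NIPALS: w ∝ Eᵀf, t = Ew, deflation of both blocks per
component, coefficients collapsed to the original scale via
B = W(PᵀW)⁻¹q.  The component count is chosen by pooled CV RMSE with ties
toward fewer components, since the historical comparison never stated one.
With A = p on full-rank predictors the model provably equals ordinary
least squares, which is the main correctness oracle.

## Interpretation

Ablation retrains the model once per left-out descriptor with the full
model's hyperparameters (no re-tuning per subset — the cost of a
descriptor should be measured under the same settings) and reports train
RMSE/R² and test RMSE/Q² per row.  Sensitivity analysis is one-at-a-time:
a 50-point grid spanning the descriptor's observed range, all other
descriptors held at their training means (medians optional), and the
model's predictions read along the grid; a Spearman rank correlation of
grid vs. prediction summarizes the trend (constant curves report 0).  This
is a local, ceteris-paribus readout: it does not account for descriptor
correlations, and curves for descriptors absent from the underlying
relationship can drift within the model's noise floor.

## Synthetic data

The generator draws informative descriptors i.i.d. standard normal, builds
the target as Σcⱼfⱼ(xⱼ) + N(0, σ²) (fⱼ linear by default; monotone tanh or
cubic tags available), adds redundant descriptors as jittered copies of
informative ones, and independent noise columns.  Defaults mirror the real
benchmark's shape: 581 compounds, 68 descriptors (6 informative, 6
redundant, 56 noise), coefficient ladder 1.0…0.5, and σ calibrated so the
true model's population R² is 0.84 — the regime of the real training fit —
making the synthetic benchmark's difficulty comparable.  Splits are seeded
uniform draws at the benchmark's 500/81 proportion; the historical
partition method was never described, so a random split is the neutral
choice.

What passing the synthetic suites does **not** show: real descriptor
distributions are skewed, discrete and collinear in ways i.i.d. Gaussians
are not, and real structure–toxicity relationships are not exactly linear
in six descriptors.  The synthetic results certify the machinery
(selection finds planted signal, models reach the noise floor, metrics and
solvers are correct), not field performance on new chemistry.

## Problem sizes and runtime choices

The test and acceptance workloads run at reduced-but-representative sizes
chosen as part of the package's design: GA recovery uses population 20 /
30 generations on n = 150 tables over 10 seeds; the end-to-end chain uses
n = 300 tables, mRMR keep-10, GA population 20 / 15 generations and a
3×3 (C, ε) grid; the full-scale acceptance benchmark runs the 581×68 table
with mRMR keep-15 and GA population 20 / 12 generations, using the linear
kernel for wrapper fitness (the synthetic target is linear) and the
degree-2 polynomial kernel for the tuned final model.

## Known limitations

- Aromatic perception and implicit-hydrogen assignment are RDKit's; inputs
  that RDKit cannot sanitize are rejected rather than repaired.
- χ/κ subgraph enumeration is combinatorial over edge subsets; fine for
  drug-sized molecules and m ≤ 4, not meant for macromolecules.
- The SMO solver inherits the slow tail convergence all SMO-type methods
  show on ill-conditioned polynomial-kernel duals with large C; the
  iteration cap then returns the best iterate, whose KKT gap is visible in
  the (documented) tolerance.
- The ANN comparator that sometimes accompanies SVR/PLS benchmarks is
  intentionally absent: no published architecture exists to reproduce.
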