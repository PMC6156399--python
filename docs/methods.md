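# Methods

## Model overview

The predictor treats miRNA–disease association discovery as link
prediction on a bipartite graph. Three ingredients enter: the binary
association matrix `A` (disease × miRNA), a miRNA functional similarity
prior `MFS`, and a disease semantic similarity prior `DSS`. The method's
core idea is that the association matrix itself carries similarity
information that the priors miss: entities with overlapping interaction
profiles are likely functionally related even when the prior says
nothing. That information is extracted by sparse reconstruction, merged
with the priors, and exploited by label propagation.

Orientation is fixed once: `A` is disease × miRNA; score matrices are
miRNA × disease (the miRNA-side propagation acts on `Y = Aᵀ`, and the
disease-side result is transposed before combination). All transposes in
the code are explicit.

## Disease semantic similarity

Diseases are organised in a classification DAG (MeSH-style, child →
parent). The contribution of ancestor `t` to disease `d` decays with
distance: `D_d(d) = 1`, and for any other ancestor
`D_d(t) = max over children t' of t within T(d) of decay · D_d(t')`,
which closes to `decay^(shortest descending path length)`; `decay` is
0.5 by default and configurable (`semantic decay`). The semantic value
`DV(d)` sums contributions over the ancestor closure `T(d)`, and

    S(a, b) = Σ_{t ∈ T(a) ∩ T(b)} (D_a(t) + D_b(t)) / (DV(a) + DV(b)).

S is symmetric, lies in [0, 1], and equals 1 on the diagonal. A
precomputed `DSS` table can be supplied instead, bypassing this module;
if a disease has several DAG placements, the input DAG is assumed
already merged. Contributions are memoised (one BFS per disease), so
building the full matrix is O(n · |DAG|) plus the pairwise sums.

## Sparse-neighbourhood reconstruction

The equality-constrained basis-pursuit program
`min ‖w‖₁ s.t. x = Dw` is infeasible whenever a profile lies outside
the span of the others, so the solver implements the penalized form

    min_w ‖D w − x‖₂² + λ‖w‖₁    (optionally w ≥ 0),

the standard lasso relaxation that dedicated L1 least-squares packages
compute. Numerical choices:

* **Solver.** FISTA (accelerated proximal gradient) on the Gram form,
  step `1/L` with `L = 2·λ_max(DᵀD)`, start `w = 0`, fixed iteration
  order — bit-deterministic for fixed inputs. Convergence: largest
  coordinate change below `tol` (default 1e-10, `max_iter` 20000). The
  test suite verifies optimality against an independent convex solver
  (scikit-learn's coordinate-descent lasso) to 1e-6 relative objective.
* **Batching.** All entities of one side are solved simultaneously on
  the shared Gram matrix; the constraint `W[i,i] = 0` is exactly the
  per-entity program with the self profile removed from the dictionary
  (an entity is never its own neighbour).
* **Penalty.** λ defaults to `0.01 · max|Dᵀx|` per sample. The relative
  scaling keeps shrinkage comparable across profile densities — a dense
  hub and a degree-1 leaf get proportionate penalties; an absolute λ
  can be set instead.
* **Threshold.** Coefficients must exceed ε (default 1e-4) to count as
  sparse neighbours; ε = 0 keeps every strictly positive coefficient.
* **Negative coefficients** are clipped to zero before thresholding: a
  similarity cannot be negative, and the neighbourhood rule `w_j > ε`
  discards them anyway. A `nonneg` option solves the constrained
  program instead; results differ only in degenerate geometries.
* **Symmetrization.** The coefficient matrix is averaged with its
  transpose by default, since fusion and propagation presuppose
  symmetric similarities. The raw asymmetric `W` remains available.
* **Degenerate profiles.** An all-zero profile (an entity with no known
  associations) yields an all-zero similarity row, with a logged
  warning; its propagation scores then come entirely from the
  `(1−α)Y` anchor term.
* No rescaling of `W` to [0, 1] is applied: fusion averages raw values
  and the propagation normalization absorbs overall scale.

## Fusion

`fused(x, y) = reconstructed(x, y)` where the prior is exactly 0.0,
else the mean of the two. The zero test is literal — an exact 0.0 prior
means "no information". Because reconstruction leaves the diagonal at 0
while priors have unit diagonal, fused matrices carry diagonal 0.5;
this is harmless (the diagonal contributes a uniform self-loop that
normalization rescales) and documented rather than patched. Equal
weighting is the method's fixed choice; learned fusion weights are out
of scope.

## Label propagation

The similarity is normalized symmetrically,
`MS = Dg^{−1/2} S Dg^{−1/2}` with `Dg[i,i] = Σ_j S[i,j]`; this is the
normalization under which the iteration
`F(t+1) = α·MS·F(t) + (1−α)·Y` provably converges (spectral radius of
`MS` ≤ 1, so the map contracts at rate ≤ α). Rows with zero sum are
left all-zero rather than divided. Both an iterative mode (max-norm
tolerance 1e-6, max 1000 iterations, error carrying the residual on
exhaustion) and the closed form `(1−α)(I−α·MS)^{−1}Y` are implemented;
they agree to 1e-8 on the test instances, and closed form is the
default at the package's target scale (n ≤ a few thousand). A
precomputed propagation kernel `(1−α)(I−α·MS)^{−1}` serves
cross-validation, where many label matrices hit one fixed network.

Parameters: `α` (neighbour-retention rate, 0 < α < 1) defaults to 0.5;
`β` (miRNA-network weight in `F = β·F_M + (1−β)·F_Dᵀ`, 0 ≤ β ≤ 1)
defaults to 0.5, treating both networks equally. Both propagations use
the raw known associations as initial labels.

## Evaluation protocols

* **Global LOOCV** — each known pair is masked in turn, the pipeline
  rerun, and the held-out score ranked against all unknown pairs.
  Negatives are scored once from the full-data model; each positive
  from its own holdout run. AUC is the tie-aware Mann–Whitney rank
  statistic, identical to trapezoidal ROC integration.
* **Local LOOCV** — the held-out pair is ranked only within its
  disease's unknown pairs; each positive contributes the fraction of
  same-disease negatives it outranks (ties half), and the pooled AUC is
  the mean of these per-disease outcomes. Diseases with no unknown
  pairs are skipped with a warning.
* **Repeated k-fold** — known pairs are split uniformly at random into
  k disjoint folds (no stratification), each fold masked in turn;
  per-repetition AUCs are averaged. With one repetition and k equal to
  the number of positives this reduces exactly to global LOOCV.

By default the *entire* pipeline, sparse reconstruction included, is
rerun per fold — the only fully leakage-free protocol. `fast=True`
reconstructs and fuses once from the full data and redoes only the
propagation per fold (two matrix products via the cached kernel). The
held-out edge then still shapes the similarity graphs, so fast-mode
AUCs are mildly optimistic; the flag exists because per-fold
reconstruction across thousands of folds is expensive, and all
large-fold-count runs in this repository use it with that caveat.

## Synthetic data

The generators define the package's study conditions:

* **Planted-block network** (default 60 diseases × 80 miRNAs, 4 blocks,
  within-block edge rate 0.35, background rate 0.02, prior strength
  0.7): diseases and miRNAs are assigned to matched blocks (sizes
  differing by at most 1); priors interpolate between the exact block
  indicator and symmetric uniform noise, unit diagonal, clipped to
  [0, 1]. The sizes and rates are chosen to mimic a sparse association
  catalogue (~10% density) with recoverable community structure at a
  scale where full LOOCV runs in seconds; the acceptance script reports
  global/local/k-fold AUCs on exactly this configuration.
* **Power-law bipartite network**: degrees from a truncated zeta law
  (discrete sampling), stub totals balanced, configuration-model
  pairing, multi-edges collapsed (realized degrees may fall slightly
  below drawn ones). Emulates the heavy-tailed degree regime of real
  catalogues, where most entities have very few known links.
* **Toy DAGs**: full trees of configurable depth/branching with
  optional extra cross-parents drawn from shallower levels (acyclic by
  construction).

All generators are pure functions of spec + seed. What passing on these
inputs shows — and does not show: the planted model has homogeneous
blocks, independent edges, and priors correlated with the truth by
construction; real catalogues have overlapping disease modules,
curation bias, and priors of uneven quality. Synthetic AUCs therefore
validate the machinery (masking hygiene, ranking, convergence), not the
biological performance on any real dataset; real-data evaluation runs
through the same `eval` entry points on user-supplied files.

## Known limitations

* Per-fold reconstruction (the leakage-free default) is O(folds ×
  lasso); at catalogue scale use `fast` mode and interpret accordingly.
* Entities with no known associations receive only anchor-term scores;
  the method cannot rank candidates for a disease with zero links
  unless its similarity row connects it to linked diseases.
* Fusion weights and the λ, ε, α defaults are fixed engineering
  choices, surfaced in the configs; no hyper-parameter search is
  included.
* Dense matrices throughout: intended scale is at most a few thousand
  entities per side.
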