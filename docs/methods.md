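# Methods

## The model

For one target gene (TG) with centered expression vector `y` over `m`
cells and a column-standardized matrix `X` of `n` candidate transcription
factors (TFs), the regulators are modeled linearly, `y = Xβ + ε`, and
selected under an L0 budget with ridge shrinkage:

    min_{‖β‖₀ ≤ k}  ‖y − Xβ‖² + ρ‖β‖².

Profiling out β turns this into a program over Boolean selector variables
`u ∈ {0,1}ⁿ` with `Σ uᵢ ≤ k`:

    min_u  yᵀ M(u) y,   M(u) = (1/ρ · X D(u) Xᵀ + I)⁻¹,  D(u) = diag(u),

and the biological prior — TFs co-regulating a gene must be in physical
proximity, which we proxy by distance in a physical protein–protein
interaction (PPI) network — enters as a quadratic penalty `λ uᵀ S u`,
where `S[i,j]` is the diffusion state distance (DSD) between TFs i and j.
The Boolean constraint is relaxed to the capped simplex
`{u : Σuᵢ ≤ k, 0 ≤ uᵢ ≤ 1}`, the relaxed problem is solved by a projected
quasi-Newton method, exactness of the relaxation is certified by a
score-separation condition, and fractional solutions are rounded to
Boolean supports.

Assumptions worth keeping in mind: the expression model is linear in TF
expression; proximity in a PPI network is a proxy for co-occupancy at the
locus; and the DSD matrix, though symmetric, non-negative and metric, is
**not** positive semidefinite in general, so for λ > 0 the relaxed
objective can be nonconvex. We do not silently repair S (an optional
eigenvalue diagnostic is easy to add on top of `numpy.linalg.eigvalsh`);
instead the solver only requires descent, and the rounding step never
returns anything worse than deterministic thresholding.

## Diffusion state distance

With row-stochastic transition matrix `P` from the unweighted adjacency,
the t-step diffusion state of node v is `He_t(v) = Σ_{i=0..t} e_vᵀ Pⁱ` and
`D[u,v] = ‖He_t(u) − He_t(v)‖₁`. Defaults: `n_steps = 7`; a converged
variant uses the closed form `‖(e_u − e_v)(I − P + W)⁻¹‖₁` with
`W = 1πᵀ` built from the stationary distribution (degree / 2|E|). The
finite-step matrices converge to the closed form only on non-bipartite
(aperiodic) components; on bipartite graphs the finite sums oscillate and
the closed form is their Cesàro limit — the triangle-inequality and
symmetry properties hold either way. DSD is undefined across connected
components; the package computes it on one component and offers
`component="largest"`, with `missing_policy ∈ {error, max_fill, drop}`
controlling TFs that fall outside.

## Solver

Projected L-BFGS (memory 10) on the capped simplex:

* initialization `u⁰ = (k/n)·1`, a symmetric interior point;
* search direction from the standard two-loop recursion, used only when
  it is a descent direction, otherwise the negative gradient;
* backtracking Armijo line search (c₁ = 1e−4) along the projected arc,
  accepting only genuine-descent steps;
* curvature pairs kept only when `sᵀy > 1e−10`.

Each objective/gradient evaluation solves one n×n system via the
Woodbury identity using cached Gram matrices, so the per-iteration cost
is O(n³) independent of the number of cells.

Stopping: the projected-gradient norm `‖u − proj(u − ∇G)‖` falls below
`grad_tol·max(1, |G|)` (default `grad_tol = 1e−6`), or three consecutive
accepted steps improve G by less than `1e−10·max(1, |G|)`, or the line
search can find no descent step at machine precision. The tolerances are
relative because G scales with the number of cells (G ≈ ‖y‖² ≈ m at the
start); an absolute 1e−6 gradient norm would sit below float64 resolution
for realistic m. The objective trace is recorded and is non-increasing by
construction; an increase raises an error (it indicates an inconsistent
gradient, and is tested for).

The capped-simplex projection is exact: if clipping to the box meets the
budget it is the answer; otherwise the threshold θ solving
`Σ clip(vᵢ − θ, 0, 1) = k` is found from the sorted breakpoints of that
piecewise-linear function (O(n log n)), matching a generic QP solver to
1e−11 and idempotent to 1e−9.

## Exactness certificate and rounding

At the relaxed solution û, each TF gets the score
`vᵢ = (xᵢᵀ M(û) y)² + 2λ (S û)ᵢ`. With support `Θ = {i : ûᵢ > 1e−4}`,
the relaxation is certified exact when `min_{i∈Θ} vᵢ > max_{i∉Θ} vᵢ`
**and** `|Θ| ≤ k`. The second condition matters: when two coordinates tie
exactly across the budget boundary the optimum splits mass between them
(û fractional), yet their scores still separate from the rest; no
feasible Boolean vector can have that support, so separation alone would
over-certify. M is evaluated at û — the certificate is stated at the
optimum of the original program, which is unavailable; this choice is
validated empirically: on 100 random small instances (n ≤ 12, k ≤ 3),
every certified case matched exhaustive enumeration exactly.

Rounding draws `n_samples` (default 100) Boolean vectors with
`P[ũᵢ=1] = ûᵢ`; draws exceeding the budget keep the k drawn coordinates
with largest û; the deterministic top-k-of-û candidate always joins the
pool; the pool minimizer of G is then polished by a deterministic
best-improvement local search over single-coordinate swaps, additions and
removals. The polish step exists because the relaxed optimum can place
exactly zero mass on a coordinate of the best Boolean support, which no
Bernoulli draw can reach; with it, the rounded objective matched
enumeration on every tested small instance.

## Hyper-parameters

| parameter | meaning | default |
|---|---|---|
| ρ | ridge weight (same units as ‖y‖²) | CV over {0.1, 1, 10} |
| λ | proximity weight (units: 1/DSD) | CV over {0, 0.01, 0.1, 1} |
| k | sparsity budget (TF count) | CV over {3, 5, 10} |
| n_steps | DSD walk horizon | 7 |
| n_rounding_samples | Bernoulli pool size | 100 |

Cross-validation is k-fold (default 5): at each grid point the selector
is fit on the training folds, a ridge model restricted to the selected
support is refit, and its held-out MSE is scored; ties break toward
smaller k, then λ, then ρ. The λ grid must include 0 so the no-proximity
ablation is always a candidate.

## Genomic windows

BED-convention 0-based half-open coordinates throughout. A peak
overlapping the 500 bp window immediately upstream of the TSS
(strand-aware) is the gene's promoter peak; any other same-chromosome
peak within 250 kb of the TSS is a distal candidate region; promoter
classification takes precedence, so the two sets partition the in-window
peaks. Candidate TFs are those with ≥1 motif hit (produced upstream by a
motif scanner) overlapping a promoter or distal peak; a flag restricts
candidacy to distal hits.

## Evaluation metrics

* **Held-out MSE** — cells split 90/10 by seeded shuffle; a feed-forward
  network with widths (n_TFs, 20, 1), tanh hidden layer, trained by
  full-batch L-BFGS for ≤200 iterations (deterministic given the seed),
  predicts TG expression from TF expression on the held-out cells. The
  activation, optimizer and epoch budget are this package's choices; only
  the layer widths are fixed by the benchmark design.
* **Average TF distance** — mean pairwise DSD over the inferred TFs.
* **F1_topk** — Ω is the set of unique candidate regions overlapped by a
  motif hit of any top-k TF, Λ the promoter-interaction (PCHiC-style)
  linked regions, Δ their overlap (interval overlap, ≥1 shared base);
  precision |Δ|/|Ω|, recall |Δ|/|Λ|, F1 their harmonic mean (0 when both
  are 0). k = 3 primary, 5 secondary.

## Synthetic study conditions

The generator plants ground truth at desk scale: 30 candidate TFs, 200
cells, 3 true regulators forming a clique in an Erdős–Rényi background
graph (p = 0.15), noise σ = 0.5, effect sizes β* = (1.2, 0.8, 0.3)
(geometric 0.7 decay beyond three). The decoy TF has expression built as
`r·(y/‖y‖)‖z‖ + √(1−r²)·z` with r = 0.9 — correlated with the *realized*
target expression, noise included — and is attached to the graph through
a chain of bridge proteins so its hop distance to every true regulator is
≥ 4.

The effect sizes were set by a power analysis of the decoy mechanism
before any acceptance measurement: because a lone TF pays zero proximity
penalty, a decoy that dominates the fit is selected alone at large λ no
matter how distant it is; β* must keep the true regulators' joint fit
strong enough that the singleton-decoy solution stays suboptimal across
λ ≤ 1 while the weakest regulator's marginal gain remains below the
decoy's at λ = 0. Under these conditions the λ = 0 fit includes the decoy
in essentially every seed, and λ ∈ {0.5, 1} recovers the planted clique.

What the generator does **not** emulate: single-cell count distributions
(dropout, overdispersion, library-size effects), correlated TF–TF
expression, multi-TG structure, or realistic PPI topology. Passing tests
therefore demonstrate the optimization and certification machinery and
the proximity mechanism under the model's own assumptions — not
performance on real multiome data.

## Study sizes

Identity checks: 100 random instances (ridge equivalence), 50 (low-rank
inversion), 200 points (gradient), 200 vectors up to n = 1000
(projection). Exactness: 100 instances with n ≤ 12, k ≤ 3, half in a
strong-signal regime where the certificate typically fires. Proximity
hypothesis: 20 planted and 100 null seeds on 60-node graphs. Decoy
ablation: 50 seeds, λ grid {0, 0.5, 1}, 3-fold CV, plus a
degree-preserving-randomized-network arm (seeded double-edge swaps,
10·|E| swap attempts). Predictive power: 100 noiseless seeds.

## Known limitations

* For λ > 0 the relaxed problem is nonconvex (S indefinite); the solver
  finds a stationary point, and the certificate plus local-search rounding
  are the safeguards. Multi-start is not implemented.
* The certificate evaluates M at û, not at the (unknown) Boolean optimum.
* The Mann–Whitney implementation enumerates the exact null only for
  tie-free pooled samples of size ≤ 12; otherwise it uses the
  tie-corrected normal approximation without continuity correction.
* Each TG is solved independently; there is no joint multi-TG model.
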