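# Methods

## The simulated system

The benchmark is built on the steady-state linear network model
`A·Y + P = 0`. `A` (genes × genes) is the gene regulatory network:
`A[i, j]` is the signed strength with which regulator `j` drives target
`i`, and the diagonal holds selfloops — first-order degradation rates that
keep the dynamical system `dx/dt = A x + p` stable. `P` (genes ×
experiments) records which gene each experiment perturbs (−1 knockdown,
+1 overexpression, 0 none). The noise-free fold-change response is the
equilibrium `X = −A⁻¹P`; observed data add i.i.d. Gaussian measurement
noise. The orientation convention (column = regulator, row = target, so
`A·Y` is conformable with genes × experiments data) is fixed everywhere:
generators, estimators, serialization and evaluation all index
`(target, regulator)`.

### Network generation

Topology comes from preferential attachment (Barabási–Albert skeleton,
adjusted up or down by a few edges to hit the exact budget), which gives
the heavy-tailed degree distribution expected of transcriptional networks.
The default budget is 3 links per gene *including* the selfloop, i.e. ~2
directed off-diagonal links per gene (a 100-gene network carries ~200
off-diagonal edges); every gene may act as a regulator. Each skeleton edge
receives a uniformly random direction, a Bernoulli(1/2) sign (mixed
activation/repression) and a magnitude drawn uniformly from [0.1, 1] —
bounded away from zero because an arbitrarily weak edge is undetectable in
principle and would make support recovery ill-posed rather than merely
hard.

Selfloops are set to −(Σ|incoming off-diagonal weights| + U(0.1, 1)):
degradation outweighs regulation row by row, so the Gershgorin discs lie
strictly in the left half-plane and the system is stable and
well-conditioned by construction. This emulates the comfortably stable
networks of established in-silico generators; an earlier variant with
shallow selfloops left the spectral abscissa pinned at the stability
margin, which inflates indirect effects (`A⁻¹` far from diagonal
dominance) and degrades every estimator in ways the source studies do not
show. A `stabilize` pass (uniform diagonal shift to spectral abscissa
≤ −0.1; pattern- and sign-preserving) remains as a guarantee for
user-supplied weight choices.

### Design, noise, and the scrambling control

The standard design knocks every gene down with 3 replicates
(gene-major, replicate-minor column order; 100 × 300 at the default size).
Replicates share the noise-free column and differ only in their
independent noise draws.

Noise variance λ is calibrated to a target SNR through
`SNR = σ_min(X) / sqrt(χ²_{1−α}(N·M) · λ)` with 1 − α = 0.99: the smallest
singular value of the noise-free data (the weakest signal direction) is
compared to a 99%-confidence bound on the norm of a Gaussian noise matrix.
Inverting for λ is exact, so the round trip λ → SNR reproduces the target
to machine precision. SNR 0.01 / 0.1 / 1 are the high / medium / low noise
study conditions; even "low" noise is not trivial — it equates the noise
bound with the *weakest* signal direction, while typical entries carry far
more signal.

The negative control applies a uniform random derangement (rejection
sampling, ~e draws on average) to the gene labels of the perturbations:
no experiment keeps its true target, every P↔Y link is broken, and the
column structure and entry multiset are untouched.

## Estimators

**Least squares** — `A = −P·Y†` (Moore–Penrose). Exact on noise-free
full-rank data.

**LASSO / ElasticNet / Ridge** — per-target-gene regressions of `−P[i, :]`
on `Yᵀ` with no intercept, predictors scaled by their standard deviation
(not centered — fold changes are zero-referenced by construction and
centering would silently change the no-intercept model). The penalty
vector is 30 values logspaced 10⁻⁶..10⁰ used as given; the objective is
`1/(2M)‖r‖² + pen·(a‖w‖₁ + (1−a)/2‖w‖²)` with mixing weight a = 1 (LASSO),
0.7 (ElasticNet), 0 (Ridge). Each penalty yields one binary network
(support of the fit), ordered densest → sparsest. Two numerical choices
matter:

- *zero tolerance* — standardized coefficients below 10⁻⁴ count as zero.
  Warm-started coordinate descent leaves residue up to ~10⁻⁴ and exact
  ridge leaks ~10⁻⁶ on noise-free data, while the weakest detectable edge
  maps to ≳5·10⁻³ standardized, so the threshold has over a decade of
  margin on each side.
- *ridge support* — pure L2 never produces exact zeros, so the binary
  network at penalty `pen` keeps standardized coefficients with
  `|w| ≥ pen`. The threshold sweeps 10⁻⁶..10⁰ together with the
  shrinkage, mirroring the L1 soft-threshold behaviour and giving the
  required full-to-empty sparsity range.

**Z-score** — for responder `i` and perturbation target `j`, the shift of
gene `i`'s mean expression under the experiments knocking `j` down,
relative to the mean and standard deviation (ddof 1) of gene `i` over all
*other* experiments; `|z|` scores the edge `j → i`. Replicates are
averaged before the distance is taken, and the reference sample excludes
the target's own experiments so a gene's perturbation response never
contaminates its background. Genes with zero reference spread score 0
(logged). Note the method ranks *total* influence (entries of `A⁻¹`), so
even at negligible noise its accuracy saturates below the regression
methods — indirect effects interleave with weak direct edges. That
saturation (~0.83 AUPR at SNR 1 here) alongside its robustness at high
noise (best of all methods at SNR 0.01) is the method's characteristic
trade-off.

**Tree ensemble (GENIE3 recipe)** — per target gene, a random forest
(√ candidates per split, unit-variance response) predicts its expression
from all other genes; the per-predictor score is the average total
variance reduction per tree (unnormalized importances, so uninformative
targets contribute little). On single-knockdown steady-state data the
larger importances empirically point from target to regulator, so the
default output uses that reversed orientation; a flag restores the
textbook direction. Default 1000 trees; the test and acceptance profiles
use 100 (the ranking is already stable there, and the accuracy difference
is well under the between-network spread).

**CLR** — pairwise plug-in mutual information on 10 equal-width bins per
gene (each gene binned over its own range), background-corrected per gene
row: `z_i = max(0, (MI_ij − mean_i)/sd_i)`, score `sqrt(z_i² + z_j²)`.
Symmetric, unsigned, zero diagonal. This is canonical CLR with a normal
background model; the spline/Rayleigh background variants of specific
third-party implementations are not reproduced. MI values below 10⁻¹² are
cleared so constant genes keep an exactly-zero row.

## Evaluation protocol

Direction counts, sign does not (absolute scores). The selfloop policy
makes the two method families comparable: design-based methods estimate
selfloops, so their gold standard keeps the diagonal (N² ordered pairs);
expression-only methods cannot, so the diagonal is removed from both
sides (N² − N pairs) instead of being charged as false negatives. A
`strip_all` mode removes the diagonal everywhere for the sensitivity
analysis. Symmetric (undirected) predictions are evaluated directed: each
undirected edge predicts both directions and pays the corresponding
penalty.

Dense predictions are swept over every unique absolute score (tied scores
enter together); penalty methods contribute their 30 networks. Per level:
recall, precision, FPR, F1, MCC, with the conventions precision = 1 at an
empty prediction, F1 = 0 when precision + recall = 0, MCC = 0 when a
marginal is empty. AUPR is the trapezoidal area over the achieved
(recall, precision) points with the sparsest precision extended
horizontally to recall 0 — no unachieved endpoint is fabricated; AUROC is
trapezoidal with (0,0) and (1,1) anchors. Interpolated (Davis–Goadrich)
PR area is deliberately not used. The maximum-F1 network (ties broken
toward the sparser level) supplies the edge sets for the similarity
analysis: mean pairwise Jaccard per noise level, and the true fraction
|A∩B∩gold|/|A∩B| (undefined and reported missing when the overlap is
empty; Jaccard of two empty sets is 1 by convention, logged). A two-sided
Mann–Whitney U helper is provided for group comparisons.

## Benchmark grid and reproducibility

The standard profile is 5 networks × 100 genes × SNR {0.01, 0.1, 1} ×
7 methods, with the deranged-design control for the 5 design-based
methods. All randomness derives from one master seed through fixed
per-stage `SeedSequence` spawn keys (network k, noise (k, snr), method
(k, snr, m)), so any cell is reproducible in isolation and adding or
removing methods does not shift other cells' draws. Estimator failures
are confined to their grid cell. Report JSON excludes wall times so equal
seeds give byte-identical output; wall times are logged and kept in the
CSV/frame view. 250-gene grids are supported by configuration but are not
part of the default profile (runtime; the qualitative conclusions are
scale-stable).

Problem sizes in the shipped tests and the acceptance script: the full
100-gene 5-network grid with the 100-tree ensemble profile (about 8
minutes for the suite, ~2 minutes for the script on one CPU); unit tests
use 20–40-gene systems.

## The DREAM5-style reader

`grnbench.dream5` extracts known-target perturbation subsets from
chips-by-genes expression plus "chip features" annotation tables:
deletions map to −1, overexpression to +1, fold change is the perturbed
chip minus the per-gene mean of its experiment group's control chips
(subtraction — the compendium scale is already log-like; no re-logging).
Knockdown-only chips (targets unspecified), multi-gene perturbations,
chips listing both a deletion and an overexpression, targets absent from
the expression matrix, and groups without controls are dropped with
logged warnings. A fixture generator emulates the format with
analytically known outputs so the logic is tested entirely offline; the
real compendium and its gold standard are optional external inputs and no
test depends on them.

## What the synthetic data does and does not show

The generator emulates targeted-knockdown steady-state data from a linear,
time-invariant, noise-free-in-dynamics system with additive i.i.d.
Gaussian measurement noise. Real perturbation compendia violate most of
these in some measure: regulation is nonlinear and saturating, knockdowns
have off-target effects, noise is heteroscedastic and correlated across
replicates, and designs are incomplete (only some genes perturbed — the
regime where design-based methods lose much of their edge). Passing tests
therefore demonstrate correctness of the pipeline and the in-silico
conclusions — design-based methods dominate when the design is known,
correct, and covers most genes — not accuracy guarantees on biological
data. The deranged-design control quantifies exactly how much of that
dominance is carried by the design information: all of it.

Other known limitations: the non-design category is represented by two
estimators (tree ensemble, CLR) plus whatever a user plugs into the
common interface; the tree ensemble's reversed-orientation default is an
empirical property of knockdown steady-state data and should be
re-examined on other data types; CLR's equal-width plug-in MI is biased
upward at small sample counts (the background correction absorbs most of
the bias, but fewer than ~100 experiments per 10 bins is not
recommended).
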