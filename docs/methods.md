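# Methods

## The model

`survmod` looks for *active modules*: connected gene sets in a
protein-interaction network whose members are jointly associated with
patient survival and whose internal co-expression differs between
longer- and shorter-survival patients. Both signals are encoded as
weights calibrated to be standard normal under their nulls, which is
what makes a joint score across heterogeneous evidence meaningful.

**Node weights.** For gene *i*, a univariable Cox proportional-hazards
model (partial-likelihood maximisation, Breslow tie handling) of overall
survival on expression yields a two-sided Wald p-value *p*ᵢ. The weight
is wᵢ = Φ⁻¹(1 − *p*ᵢ): standard normal when *p*ᵢ ~ U(0,1), strictly
decreasing in *p*ᵢ. The sign of the association is *not* folded in — a
strongly protective gene receives the same large weight as a strongly
hazardous one. The per-gene Cox solver is a vectorised Newton iteration
written for this package (all genes fitted simultaneously on shared
risk-set cumulative sums), because the pipeline fits it hundreds of times
per network; the multivariate models go through lifelines. Both routes
are checked against a dense-grid partial-likelihood oracle in the tests.

**Edge weights.** Patients are stratified at a survival threshold
(default 37 months, the population median survival used for this
disease); deaths below the threshold form the shorter stratum, patients
surviving past it the longer stratum, and censored patients with
follow-up below the threshold are ambiguous — the default policy
excludes them (`shorter`/`longer` assignments are available, because no
principled assignment exists without follow-up). For edge (*i*, *j*),
Pearson correlations r_L and r_S within each stratum are Fisher-Z
transformed (z = atanh r, variance ≈ 1/(n−3)) and contrasted:

    w_e = |z_L − z_S| / sqrt(1/(n_L − 3) + 1/(n_S − 3)).

The absolute value makes w_e a magnitude of co-expression change,
symmetric under swapping strata; a signed variant is available
(`signed_edge_weights=True`) for sensitivity analysis. Each stratum
needs > 3 patients (Fisher variance) and the stratifier enforces ≥ 4.

**Module score.** A connected set M of n genes with m induced
interactions scores S_M = (Σ wᵢ + Σ w_e)/√(n+m) — the joint sum
normalised by the root of the number of contributing terms so the score
does not grow mechanically with size. The normalisation is a design
choice; it lives in one place (`modules._make_candidate` /
`module_score`) and is straightforward to swap.

## Search and calibration

Finding the maximal-scoring connected subgraph is NP-hard, so the search
is simulated annealing over connected states: moves add a neighbouring
gene or remove a gene whose removal keeps the induced subgraph connected
(checked by BFS per proposal); worsening moves are accepted with
probability exp(ΔS/T) under geometric cooling. Defaults: T 1.0 → 0.01,
10,000 proposals per chain, 20 restarts seeded from random edges, module
size capped at 20. The schedule was chosen to reliably reach the
enumerated optimum on small instances (the exhaustive enumerator,
guarded to ≤ 15 nodes, is part of the package as a test oracle) and to
keep a 500-gene search in seconds; none of it is sacred, and
`AnnealConfig` exposes every knob.

Scores are size-confounded, so each module is standardised against
10,000 random gene sets of its own size — arbitrary node sets scored
with their induced edges, no connectivity requirement (a connected-null
option exists for sensitivity). Adjusted score = (S − μ̂)/σ̂; empirical
p = (1 + #{null ≥ S})/(N+1), never zero by construction. The same
resample set serves both the moments and the empirical p. Modules
overlapping by more than 80% of the smaller one are merged in a single
concurrent pass (meta-graph connected components), then rescored.
Selection keeps the top 1% by adjusted score (ceil of the fraction)
with empirical p < 0.01, reporting the realised score threshold.

## Prognostic evaluation

The module eigengene (EM) is the first principal component of the
standardised module-genes × patients training submatrix; loadings have
unit norm and their sign is fixed so the EM correlates positively with
the module's mean standardised profile, making EM comparable across
cohorts (a first PC is otherwise sign-ambiguous). The phrase "weighted
average of expression by the first PC" is interpreted as this standard
module-eigengene construction. Centring, scaling, loadings and the
training median are frozen; other cohorts are projected, never refitted.

Patients split at the median EM — training and internal test at their
own cohort median, the external cohort at the *training* median (both
configurable) — and the group with the shorter Kaplan-Meier median
survival is labelled high-risk. Association is screened by the training
log-rank p < 0.1, then tested per cohort: log-rank, univariate Cox on
the high-EM indicator, and a multivariate Cox adjusting for age
(dichotomised at the cohort median; continuous available), stage IV vs
III, grade 4 vs 3, and residual tumour > 10 mm vs 0–10 mm. KM, log-rank
and multivariate Cox go through lifelines; CIs are Wald on the log-HR.

## Crosstalk

The interaction universe is the undirected union of the PPI edge list
and the directed RNA→protein edges (RNAs can regulate module proteins
but cannot be module members). For every non-module gene g adjacent to
the module: x = module neighbours of g, n = degree of g, K = module
size, N = universe size − 1; the exact hypergeometric upper tail
P(X ≥ x) is compared to 0.1 (raw, matching the screening convention; a
BH-adjusted column is also emitted). The regulator set's overlap with
the cell-death list is tested the same way with N = universe size. The
choice of universe is the main free parameter here and is recorded in
the output; absolute overlap p-values are only as meaningful as that
choice. Wiring output lists regulator–regulator and regulator–module
edges with their type and the connected components of the overlap genes.

## The synthetic generator

`generate_bundle` emulates the statistical structure the analysis
assumes, with a known truth:

- **Network**: Barabási–Albert background (mean degree 4) over 500 genes
  plus a wired-in connected 12-gene module (random spanning tree +
  Bernoulli(0.25) extra internal edges); all confidences ≥ 0.90 so the
  default filter keeps them.
- **Survival**: per patient a latent module activity f ~ N(0,1); event
  time ~ Exponential(rate = ln2/37 · exp(node_effect · f)) so the null
  median survival equals the 37-month threshold; administrative
  censoring at a horizon solved (Brent) to hit the requested censoring
  fraction (default 0.3) in expectation.
- **Expression**: planted genes follow a one-factor equicorrelation
  model x = √ρ·f + √(1−ρ)·ε with ρ = 0.35 ± edge_effect/2 by the
  patient's (uncensored) survival stratum — the stratum is simulated
  first and expression drawn conditional on it, which guarantees exactly
  the differential co-expression the edge statistic measures, and the
  shared factor routes node_effect into every planted gene. Background
  genes are independent N(0,1). The factor construction requires the
  within-stratum correlations to be non-negative; the config validator
  enforces baseline ± Δr/2 ∈ [0, 0.97].
- **Annotations**: 15 protein regulators each wired to 3 module genes
  plus 4 miRNAs with 2–4 RNA→protein targets; 80% of regulators (100%
  in the crosstalk benchmark) are labelled cell-death and the list is
  padded with non-neighbour genes to 60.
- **Covariates**: age ~ N(60, 10), stage III/IV (0.7/0.3), grade G3/G4
  (0.75/0.25), residual class (0.55/0.45), independent of survival — so
  the adjusted models have null covariates with known truth.

Three cohorts (training/test/external, 200 patients each) share the
truth with independent noise. Everything derives from one seed via
spawned child streams; a bundle is a pure function of its config.

What the generator does **not** emulate: platform/batch effects,
heavy-tailed or count-like expression noise, correlated clinical
covariates, informative censoring, or miRNA expression profiles. Passing
tests therefore demonstrate correctness of the statistical machinery and
recoverability under clean proportional-hazards signal — not robustness
to real microarray artefacts.

## Numerical choices and degenerate inputs

- Cox Newton steps are clipped to ±5 with exp-argument clipping; genes
  with (near-)constant expression are dropped with a logged warning, as
  are genes whose fits are undefined; nothing is imputed, since silent
  imputation would distort the permutation null.
- p-values are clamped to [1e-16, 1−1e-16] before Φ⁻¹; |r| ≥ 1 is
  clamped to 1 − 1e-12 before atanh (both logged).
- Constant-within-stratum genes give edge weight 0 with a warning.
- Ranking ties break lexicographically on the gene set, everywhere, so
  runs are reproducible.
- Empirical p uses the add-one rule; σ̂ = 0 in the null is an error
  (degenerate network), not a silent pass.

## Benchmark problem sizes

The acceptance benchmarks (`scripts/acceptance.py`, mirrored in
`tests/test_acceptance.py`) use: 100 twelve-node graphs for the
search-vs-enumeration comparison (annealing lightened to 2,000
proposals × 5 restarts, ample for these instances); one 500-gene/200-
patient null bundle with 200 ten-gene sets against a 10,000-resample
null; 20 replicates for planted-module recovery, log-rank power and
regulator sensitivity; 100 replicates for the null screening rate; and
200 draws for overlap-p calibration. These sizes give binomial/KS checks
useful resolution while keeping a full run to a few minutes on one CPU.

One calibration subtlety: the discrete hypergeometric overlap test has
p-values supported on few atoms, so its null distribution is
super-uniform rather than uniform; calibration is asserted as
P(p ≤ α) ≤ α + Monte-Carlo slack on a grid of α, the property that
actually holds for exact discrete tests.

## Known limitations

- The annealing search offers no optimality guarantee beyond the small-
  instance benchmarks; on large networks with weak signal the restart
  bests can be local optima.
- The eigengene assumes the first PC captures the module's coherent
  variation; modules assembled from several uncorrelated sub-signals
  will summarise poorly.
- Proportional-hazards diagnostics, multiple-testing correction of the
  per-gene Cox screen, and time-dependent covariates are out of scope.
- Overlap significance depends on the chosen interaction universe (see
  Crosstalk above); compare universes before quoting small p-values.
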