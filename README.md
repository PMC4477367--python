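# survmod

Network-based discovery of survival-associated gene modules, and of their
crosstalk with cell-death genes.

In cancers such as high-grade serous ovarian carcinoma, single-gene
prognostic markers are fragile: the signal lives in connected groups of
interacting genes whose wiring itself changes with outcome. `survmod`
implements a network-module approach to prognostic biomarker discovery:

1. **Weighted network construction.** Each gene *i* in a high-confidence
   protein-interaction network gets a survival weight
   *w<sub>i</sub>* = Φ⁻¹(1 − *p<sub>i</sub>*), where *p<sub>i</sub>* is the
   Wald p-value of a univariable Cox proportional-hazards fit of survival
   on that gene's expression. Each interaction (*i*, *j*) gets a
   differential co-expression weight from the Fisher-Z contrast of the
   pair's Pearson correlation between longer- and shorter-survival
   patients (stratified at 37 months):

   *w<sub>e</sub>* = |z<sub>L</sub> − z<sub>S</sub>| / √(1/(n<sub>L</sub>−3) + 1/(n<sub>S</sub>−3)),  z = atanh(r).

   Under the null both weight types are standard normal (in magnitude).
2. **Module search.** A module *M* with *n* genes and *m* induced
   interactions scores *S<sub>M</sub>* = (Σ w<sub>i</sub> + Σ w<sub>e</sub>) / √(n + m).
   Maximal-scoring connected subgraphs are found by restarted simulated
   annealing; scores are standardised against 10,000 size-matched random
   gene sets, near-duplicate modules (>80% overlap) are merged
   concurrently, and candidates are kept when they rank in the top 1% of
   adjusted scores with empirical p < 0.01.
3. **Prognostic evaluation.** Each candidate module is summarised per
   patient by its eigengene (EM, the first principal component of the
   module submatrix), patients are median-split into risk groups, and
   separation is tested by Kaplan-Meier/log-rank plus univariate and
   covariate-adjusted Cox models (age, stage, grade, residual tumour
   size), on training, internal-test and external cohorts.
4. **Crosstalk analysis.** Genes and miRNAs directly interacting with the
   module are tested for link enrichment (exact hypergeometric upper
   tail, p < 0.1), and the regulator set's overlap with an annotated
   cell-death gene list is itself tested hypergeometrically; the
   overlapping genes' wiring onto the module is exported.

A fully synthetic study generator (`survmod.simulate`) produces cohorts,
networks and annotation sets with a planted ground-truth module, so the
entire pipeline is testable end to end without any external downloads.

## Worked example

```python
from survmod import *
from survmod.simulate import SimulationConfig, generate_bundle
from survmod.modules import AnnealConfig

bundle = generate_bundle(SimulationConfig(seed=1))   # planted 12-gene module
net = build_weighted_network(bundle.cohorts["training"], bundle.network)
mods = simulated_annealing_search(net, AnnealConfig(seed=1))
adjusted = adjust_modules(merge_modules(mods, net), net, n_perm=10_000, seed=2)
selected, _ = select_candidates(adjusted)
rep = evaluate_module(selected[0].genes, bundle.cohorts["training"],
                      bundle.cohorts["test"], bundle.cohorts["external"])
```

Printing the key quantities from these objects gives:

```
network: 500 genes, 1062 interactions (102 longer / 98 shorter survivors)
selected 1 module(s); top: 12 genes, raw score 27.10, adjusted 20.67, empirical p 1.00e-04
planted overlap: 12 / 12
training: log-rank p = 9.91e-17, HR(high EM) = 4.29 (95% CI 2.96-6.20)
test: log-rank p = 2.21e-06, HR(high EM) = 2.21 (95% CI 1.58-3.10)
external: log-rank p = 3.82e-06, HR(high EM) = 2.31 (95% CI 1.60-3.33)
crosstalk: 34 regulators, 15 overlap cell-death genes (p = 8.14e-07); largest cluster 2
```

Reading the numbers: the search recovered exactly the planted 12-gene
module; its score sits ~21 null standard deviations above size-matched
random gene sets. The eigengene split separates survival in all three
cohorts — because the planted effect makes high module expression
hazardous, the high-EM group carries HR > 1. The module's interaction
neighbours are enriched for the planted regulators, and those regulators
overlap the synthetic cell-death list far beyond chance.

The same pipeline is scriptable from the shell:

```bash
survmod simulate --out bundle/ --seed 1
survmod run --config run.yaml          # build-network → find-modules → evaluate → crosstalk
# or stage by stage: survmod build-network / find-modules / evaluate / crosstalk
```

Every run writes `summary.json`, a human-readable `report.txt`, the
weighted network TSVs, module GMT files and crosstalk wiring edge lists,
plus the resolved configuration with a content hash; all randomness
derives from the single `--seed`.

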