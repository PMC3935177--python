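# Methods

## Model

A network is a directed acyclic graph over three kinds of variables: SNP
genotypes `L` (discrete, three levels coded 0/1/2), transcript abundances `E`
and a quantitative phenotype `D` (both continuous).  The joint distribution
factorizes over the graph, `P(X1..Xp | G) = prod_i P(Xi | Pa(Xi))`, with
conditional-Gaussian (CG) local models:

* a discrete node given discrete parents is multinomial per parent
  configuration, with a Dirichlet prior (pseudo-count `dirichlet_alpha` per
  cell, default 1);
* a continuous node given continuous parents `u` and a discrete-parent
  configuration `j` is linear-Gaussian,
  `X | u, j ~ N(m_j + b_j' u, s_j)`, with the conjugate
  normal–inverse-gamma prior `(m_j, b_j) | s_j ~ N(mu_j, s_j / tau_j)` and
  `s_j ~ InvGamma(rho_j / 2, phi_j / 2)`.  `s_j` denotes the residual
  **variance** (the conjugate NIG convention).

Two admissibility rules restrict the structure space.  Genotype is fixed at
conception, so no edge may point into an `L` node; this package extends the
rule to locus→locus edges as well (configurable via
`AdmissibilityRules(allow_l_parents=True)`).  The CG family requires that no
continuous node parent a discrete node.

### Network score

The score of a structure is the log marginal likelihood plus the log
structure prior.  The structure prior is uniform over the admissible space,
so its constant is dropped; natural logarithms are used throughout.  The
score decomposes into per-node terms: the Dirichlet–multinomial marginal for
discrete nodes and, for continuous nodes, the closed-form multivariate
Student-t predictive of Bayesian linear regression, computed per
discrete-parent configuration from sufficient statistics (Gram matrices).
Both closed forms are verified in the test suite against independent
oracles: sequential-predictive (chain-rule) computation for the discrete
case and direct numerical integration over (coefficients, variance) for the
continuous case.

Empty data scores 0 (the empty-product marginal); configurations with no
observations contribute 0 automatically.  Scoring refuses incomplete rows —
missingness is handled upstream (per-triplet complete cases in the partition
stage; filtering/imputation utilities in `npars.io`).

### Priors

Two prior modes exist:

* **Fixed** (`PriorSpec`): data-independent hyperparameters, default
  `dirichlet_alpha = 1`, intercept mean `nig_mu = 0` (regression
  coefficients are always centred at 0), `nig_tau = nig_rho = nig_phi = 1`.
  Fully reproducible across datasets; the default for the low-level scoring
  functions.
* **Empirical** (`prior=None`, the default for the scoring engine and the
  pipelines): per continuous node, the intercept prior mean is the column
  mean and the inverse-gamma scale the column variance, with
  `tau = rho = 1` — one imaginary observation located at the node's marginal
  empirical distribution.  This is the package's reconstruction of the
  conventional data-derived reference prior for CG networks.

The empirical mode matters in practice.  Expression panels sit far from
zero (arrays produce intensities around 8–12 with variance an order of
magnitude above 1); under a zero-located unit-scale prior every
genotype-split model pays a per-configuration penalty for re-learning the
location and scale, which can mask genuine genotype→expression effects.
Centring the prior on the marginal moments removes that artifact while
leaving structure comparison to the data.  Absolute score values are
prior-dependent in either mode; every use in this package compares
structures, where the choice affects only the effective complexity penalty.

### The φ score

Raw scores are not comparable across node sets of different size, and a
network can score well without saying anything about the phenotype.  The
average network improvement score addresses both:

    phi = [lambda * (S - S0) + (1 - lambda) * S] / alpha

`S0` is the score of the null network — the same structure with **every**
edge incident to `D` removed (both directions; the catalog admits D→E
edges, and incident-removal makes the null a D-independent model).  `alpha`
counts all nodes of the candidate's node set, including isolated ones
(3 for triplets, 4–5 for pairwise assemblies).  `lambda` defaults to 0.5,
weighting phenotype improvement and overall fit equally; it is exposed on
every entry point.  The per-node division approximates the roughly linear
growth of the log marginal likelihood with the number of nodes.

## The nPARS pipeline

1. **Partition.**  Every (L, E) pair forms a triplet with `D`.  The 12
   admissible triplet structures are scored and the best *by S* is kept
   (ties go to the lowest catalog index).  The catalog pins index 1 to the
   empty structure and index 2 to {L→E}; the remaining ten follow in
   lexicographic order of their edge lists.  Indices are stable labels
   only — no algorithmic logic depends on them.
2. **Selection.**  Triplets whose best structure has a degree-zero node
   (equivalently fewer than two edges) are discarded; survivors are ranked
   by φ (stable sort, generation order breaks ties) and the top `k1` kept.
   A single survivor is reported directly as the final network.
3. **Reassembly.**  Every unordered pair of selected triplets is merged
   into the union of their nodes (4 nodes when they share the locus or the
   transcript, else 5) and all admissible structures on the union are
   enumerated and scored *from scratch*; the φ-maximizing structure is kept
   (the triplet stage maximizes S, the assembly stage φ; both choices are
   arguments).  Assemblies that coincide on the same node set are
   deduplicated keeping the best φ.  The top `k2` networks are reported.

Defaults: application mode `k1 = 100`, `k2 = 20`; simulation mode keeps all
adequately connected triplets (`k1 = None`) and reports the top 1.  An
optional single growth round (`grow_networks`) unions each reported network
with each remaining triplet and re-searches exhaustively while the union
stays within the enumeration guard (6 nodes by default); exhaustive
re-search grows super-exponentially, so larger assemblies should switch to
a heuristic search.

Enumeration is performed once per role signature (backtracking over
candidate edges with incremental transitive-closure pruning, canonical
order = lexicographic on sorted edge lists) and reused across concrete node
sets; local scores are cached per (node, parent-set), so the 2330 × 3554 =
8,280,820-triplet partition of a real study is linear in the number of
pairs with cheap per-pair work.

## Baseline searches

* **Exhaustive (Exh).**  All C(nL, 2) × C(nE, 2) five-node variable
  combinations, each searched exhaustively; global φ maximizer reported.
  Ties go to the canonically earliest node set.
* **Greedy.**  Hill-climbing over the full variable panel with 10 random
  restarts: start from a random admissible DAG (uniform random topological
  order; each order-consistent admissible edge included with probability
  0.2), repeatedly apply the best strictly-improving single-edge
  modification (add / delete / reverse, admissibility preserved), stop at a
  local optimum or after 100 accepted modifications.  The default objective
  is φ with `alpha` = the number of **connected** (degree ≥ 1) nodes — the
  connected subgraph being the candidate network a greedy search reports.
  Because network scores are large negative numbers, this per-node
  normalization makes absorbing further variables profitable, and
  unconstrained greedy search characteristically connects nearly the whole
  panel — the well-known over-connection pathology this benchmark exists to
  quantify.  The raw score S is available as an alternative objective
  (`SearchConfig.objective="S"`), under which the same climber prunes
  aggressively instead.
* **GreedyE.**  Greedy plus a stopping rule: any move that would raise the
  connected-node count above the cap (default 5) is removed from the move
  set.

Greedy randomness flows exclusively from `SearchConfig.seed`; identical
seeds are bit-reproducible.  "Iteration" means one accepted modification;
"converged" means no strictly-improving move remains (improvement threshold
1e-10).

## Simulation design

Each dataset has five loci (genotypes drawn with probabilities
0.25/0.5/0.25 — Hardy-Weinberg at allele frequency 0.5), five transcripts
and one phenotype.  Noise transcripts are `N(10, 3.6)`; 3.6 is the
**standard deviation** (all dispersion parameters here are standard
deviations, matching the convention of the numerical environment the
scenarios emulate — results are scale-sensitive, so this is configurable on
`ScenarioSpec`).  Linked transcripts follow `E = 8 + beta * (sum of
parents) + eps`, `eps ~ N(0, 3.6)`; the phenotype follows the
scenario-specific linear model documented in `npars.simulate`.  The squared
coefficient `beta^2` in scenarios 1, 2 and 5 is the compounded two-step
effect of a locus acting through a transcript.  Every scenario's true
network spans exactly five of the eleven variables, so six variables are
pure noise and an algorithm that reports everything has node FDR
6/11 ≈ 54.5%.  The wiring registry is package data and can be overridden.

What the generator does *not* emulate: family/pedigree correlation between
samples, linkage disequilibrium between loci, heavy-tailed or heteroscedastic
expression noise, batch effects, and missingness (simulated data are
complete).  Passing benchmarks on these scenarios therefore demonstrates
correct behavior of the search and scoring machinery under the stated
generative model, not robustness to those real-data complications.

Recovery is scored against the generative truth by node and directed-edge
sensitivity `tp / (tp + fn)` and FDR `fp / (tp + fp)`, with `0/0 = 0`.
Edge comparison is exact directed match: a reversed edge counts one false
positive plus one false negative.  No Markov-equivalence credit is given —
equivalence-class reasoning is deliberately out of scope, which also means
some "errors" at strong signal are orientation flips within an equivalence
class.  Reported node sets are: the assembled network's node set for nPARS,
the five chosen variables for Exh, and the degree ≥ 1 nodes for
Greedy/GreedyE.

The comparison harness derives one data seed per (scenario, n, replicate)
and one algorithm seed per cell from a master seed via `SeedSequence`, so
all algorithms see identical data within a replicate and whole tables are
bit-reproducible.

### Problem sizes used in the shipped checks

The packaged tests and the acceptance script use 25 replicates per cell at
n ∈ {100, 200, 500} for the greedy-FDR summary, 25 replicates at n = 200
for the algorithm-ordering comparison, and 10 replicates at n = 500,
beta = 1.2 for full-pipeline recovery — sizes chosen to characterize each
quantity's distribution while keeping a full run in the minutes range on a
single core.  Note that even at beta = 1.2, n = 500 the
genotype→expression link is a moderate effect: the three-way genotype
split pays an Occam cost of the same order as the expected evidence, so
whether a true locus enters the selected triplets — and hence whether the
full five-node set is recovered — varies from replicate to replicate; the
recovery check documents that regime rather than a certainty.

## Data preparation

* `filter_snps`: drops SNPs with missing fraction > 0.3 or minor allele
  frequency < 0.1 (both strict inequalities; MAF from allele counts over
  non-missing genotypes; monomorphic SNPs have MAF 0 and are removed, not
  errors).  Per-SNP decisions, hence order-independent and idempotent.
* `auc_log_dose`: the phenotype summary for cytotoxicity assays is the
  trapezoidal area under viability vs natural-log dose over the observed
  dose range; a larger area means stronger chemo-resistance.  Trapezoids on
  the ln-dose axis are this package's documented quadrature choice.
* `impute_missing_dose`: missing viability readings (typically the lowest
  dose, whose absence would bias the AUC downward) are filled by an
  ordinary least-squares line of viability on ln-dose fitted within
  subject; at least two observed readings are required, imputed values are
  clipped to the [0, 200] viability guard, and a raw-dose axis is available
  by flag.

## Numerical choices and degenerate inputs

* Natural log everywhere; uniform structure prior contributes 0.
* NIG marginals are computed from Gram matrices via batched solves and
  log-determinants; `b_n <= 0` (singular/duplicated design) raises a
  scoring error rather than returning a spurious value.
* Deterministic tie-breaking throughout: canonical (lexicographic)
  structure order, lowest catalog index, earliest node set, first-found
  maximum in enumeration order.
* Capacity guards: exhaustive enumeration refuses > 6 nodes by default;
  oversized growth unions are skipped with a log entry.
* Genotype columns must be integral and within the declared level range;
  violations raise errors naming the offending column (the TSV readers name
  the offending cell).

## Known limitations

* Samples are assumed exchangeable: no pedigree- or kinship-structured
  marginal likelihood, although eQTL panels are often family-based.  Top
  networks from related samples should be re-validated with a
  family-adjusted model.
* The method is built around (L, E, D) triplets; a locus acting on the
  phenotype only through another locus's pathway, or purely L→L structure,
  is outside the search space.
* The φ/α heuristic is a first-order size correction, not a principled
  dimension penalty; comparing 4- and 5-node assemblies with it can favor
  compact networks when phenotype improvement is concentrated on few nodes.
* Exhaustive reassembly is practical only to ~6-node unions; beyond that a
  heuristic edge search should replace enumeration.
* Absolute network scores depend on the prior mode and hyperparameters;
  only comparisons on a fixed dataset are meaningful.
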