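# npars — modular Bayesian-network construction from eQTL data

`npars` builds small causal networks linking SNP genotypes (**L**), transcript
expression (**E**) and a quantitative phenotype (**D**) — the classic eQTL
setting in which a variant perturbs expression which in turn shifts a trait
such as drug cytotoxicity.  Searching the full space of Bayesian networks over
thousands of loci and transcripts is hopeless, and greedy hill-climbing is
notorious for reporting over-connected networks full of false nodes.  nPARS
(network **P**artition **a**nd **R**eassembly **S**earch) takes a middle road:

1. **Partition** — exhaustively score every (L, E, D) triplet.  With loci and
   transcripts admissibility-constrained (no edges into a genotype, no
   continuous parent of a discrete node) there are exactly 12 structures per
   triplet; the best by network score *S* is kept.
2. **Selection** — discard triplets whose best structure leaves a node of
   degree zero, rank survivors by the *average network improvement score*

   φ = [λ·(S − S₀) + (1 − λ)·S] / α,

   where S₀ is the score of the *null network* (all edges incident to D
   removed), λ ∈ [0, 1] weights phenotype relevance against overall fit
   (default 0.5), and α is the node count.  Keep the top *k₁*.
3. **Reassembly** — merge every pair of selected triplets into a 4–5-node
   union, exhaustively re-search all admissible structures on it, and report
   the top *k₂* networks by φ.

Structures are scored with the standard decomposable conditional-Gaussian
marginal likelihood: Dirichlet–multinomial locals for discrete nodes,
normal–inverse-gamma (Student-t predictive) locals for continuous nodes, fitted
per genotype configuration.  Greedy hill-climbing with random restarts
(`greedy_search`), its node-capped variant (`greedy_e`) and the gold-standard
exhaustive 2-locus/2-transcript search (`exhaustive_search`) are included as
baselines, together with a seven-scenario simulation benchmark that measures
node and edge sensitivity/FDR.

Intended users: statistical geneticists and systems biologists analysing
genotype + expression + phenotype panels, and methodologists benchmarking
network-search strategies.

## Worked example

Simulate the first benchmark scenario — two causal paths L1→E1→D and
L2→E2→D hidden among three noise loci and three noise transcripts — and run
the full pipeline:

```python
from npars import ScenarioSpec, simulate_scenario, ScoringEngine, run_npars

sim = simulate_scenario(ScenarioSpec(id=1, beta=1.2, n=500, seed=0))
engine = ScoringEngine(sim.data, sim.nodes)
result = run_npars(None, None, None, k1=None, k2=3, engine=engine)

for t in result.selected:
    print(f"  {t.locus:3s} {t.transcript:3s} {sorted(t.structure.edges)}  phi={t.phi:9.2f}")
for net in result.networks:
    print(f"  {net.node_names}  phi={net.phi:9.2f}")
```

prints

```
  L2  E2  [('E', 'D'), ('L', 'E')]  phi=  -568.86
  L1  E1  [('E', 'D'), ('L', 'E')]  phi=  -571.23
  ('D', 'E1', 'E2', 'L1', 'L2')  phi=  -479.76
```

Exactly the two causal triplets survive selection — each with the
locus→transcript→phenotype structure {L→E, E→D} — and their reassembly
recovers the true five-node set {L1, L2, E1, E2, D}; none of the six noise
variables enters.  φ values are per-node log-marginal quantities (natural
log), so less-negative is better; the assembled network scores higher than
either triplet because the shared phenotype improvement is amortized over
more nodes.  Within the re-searched union some edges may be oriented
differently from the generative wiring (e.g. D→E1 instead of E1→D): directed
conditional-Gaussian structures within an equivalence class can score
identically, and the report keeps the canonically earliest maximizer.

The same pipeline runs from the shell on TSV matrices:

```bash
npars simulate --scenario 1 --beta 1.2 --n 500 --seed 0 --outdir demo/
npars triplets demo/genotypes.tsv demo/expression.tsv demo/phenotype.tsv --outdir demo/
npars assemble demo/genotypes.tsv demo/expression.tsv demo/phenotype.tsv --k1 100 --k2 20 --outdir demo/
npars compare --scenarios 1,2,3 --ns 100,200 --replicates 5 --outdir demo/
npars phenotype doseresponse.tsv --outdir demo/   # log-dose AUC + imputation
```

`filter_snps` implements the usual pre-filters (missingness > 0.3, minor
allele frequency < 0.1), and `auc_log_dose` / `impute_missing_dose` turn
cell-viability dose-response assays into the chemo-resistance phenotype.

## Layout

| module | contents |
| --- | --- |
| `npars.dag` | nodes, DAGs, admissibility, constrained enumeration, 12-structure triplet catalog |
| `npars.scoring` | conditional-Gaussian marginal-likelihood engine, priors |
| `npars.phi` | φ score and null-network construction |
| `npars.search` | the three-stage nPARS pipeline |
| `npars.baselines` | greedy, GreedyE and exhaustive comparators |
| `npars.simulate` | scenario generators, sensitivity/FDR metrics, comparison harness |
| `npars.io` | TSV readers/writers, SNP filters, dose-response utilities |
| `npars.cli` | `npars` command-line interface |

See `docs/methods.md` for the model, priors, simulation design and known
limitations.
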