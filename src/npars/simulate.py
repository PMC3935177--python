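"""Simulation scenarios, recovery metrics and the algorithm-comparison
harness.

Each simulated dataset holds eleven variables: five SNP loci ``L1..L5``
(genotypes 0/1/2 drawn with probabilities 0.25/0.5/0.25), five transcripts
``E1..E5`` and one continuous phenotype ``D``.  Transcripts outside the true
network are independent Normal(10, 3.6) draws (3.6 is the standard
deviation); a transcript with incoming edge effects beta is generated as

    E = 8 + beta * (sum of parent values) + eps,   eps ~ Normal(0, 3.6),

and the phenotype follows the scenario-specific linear model below.  Every
scenario embeds a five-node true network among the eleven variables, so six
variables are pure noise:

1. parallel central-dogma paths: L1→E1, L2→E2, E1→D, E2→D;
   D = b²·E1 + b²·E2 + eps
2. as 1 with pleiotropy, L1 feeding both transcripts: L1→E1, L1→E2, L2→E2;
   D as in 1
3. scenario 1 plus a direct genotype effect L1→D;
   D = b·I(L1=1) + b·I(L1=2) + b·E1 + b·E2 + eps
4. scenario 2 wiring plus L1→D; D as in 3
5. a long chain L1→E1→E2→D with E2's own locus L2→E2;
   E2 = 8 + b·E1 + b·L2 + eps, D = b²·E2 + eps
6. scenario 5 wiring with a strong final link; D = 3·b·E2 + eps
7. genotypes acting directly on the phenotype, no genotype-expression
   edges: L1→D, L2→D, E1→D, E2→D;
   D = b·I(L1=1) + b·I(L1=2) + b·I(L2=1) + b·I(L2=2) + b·E1 + b·E2 + eps

(The squared coefficient in scenarios 1, 2 and 5 is the compounded
two-step effect of a locus acting through a transcript.)

Recovery is scored against the true network by node and directed-edge
sensitivity tp/(tp+fn) and FDR fp/(tp+fp), with the 0/0 convention 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .baselines import SearchConfig, exhaustive_search, greedy_e, greedy_search
from .dag import Node, phenotype as phenotype_node, snp, transcript
from .phi import DEFAULT_LAMBDA
from .scoring import PriorSpec, ScoringEngine
from .search import run_npars

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "TruthNetwork",
    "SimulatedData",
    "Metrics",
    "EvalResult",
    "SCENARIO_IDS",
    "simulate_scenario",
    "node_metrics",
    "edge_metrics",
    "evaluate",
    "run_comparison",
]

LOCI = ("L1", "L2", "L3", "L4", "L5")
TRANSCRIPTS = ("E1", "E2", "E3", "E4", "E5")
PHENOTYPE = "D"
UNIVERSE = LOCI + TRANSCRIPTS + (PHENOTYPE,)
SCENARIO_IDS = (1, 2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class ScenarioSpec:
    """One generative scenario: wiring id, edge effect, sample size, seed."""

    id: int
    beta: float
    n: int
    seed: int = 0
    noise_sd: float = 3.6
    expr_mean: float = 10.0
    expr_sd: float = 3.6
    expr_base: float = 8.0
    genotype_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"scenario id must be 1..7, got {self.id}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TruthNetwork:
    """The generative network: true node subset and directed edges."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]


@dataclass
class SimulatedData:
    data: pd.DataFrame
    nodes: tuple[Node, ...]
    truth: TruthNetwork


# wiring registry: per scenario, parents of each linked transcript and the
# D-model terms ("ind" = per-genotype indicator effect, "lin" = linear with
# the given beta exponent/multiplier)
_E_LINKS: dict[int, dict[str, tuple[str, ...]]] = {
    1: {"E1": ("L1",), "E2": ("L2",)},
    2: {"E1": ("L1",), "E2": ("L1", "L2")},
    3: {"E1": ("L1",), "E2": ("L2",)},
    4: {"E1": ("L1",), "E2": ("L1", "L2")},
    5: {"E1": ("L1",), "E2": ("E1", "L2")},
    6: {"E1": ("L1",), "E2": ("E1", "L2")},
    7: {},
}

# D model: list of (kind, variable, coefficient-function of beta)
_D_TERMS: dict[int, list[tuple[str, str, Callable[[float], float]]]] = {
    1: [("lin", "E1", lambda b: b * b), ("lin", "E2", lambda b: b * b)],
    2: [("lin", "E1", lambda b: b * b), ("lin", "E2", lambda b: b * b)],
    3: [("ind", "L1", lambda b: b), ("lin", "E1", lambda b: b),
        ("lin", "E2", lambda b: b)],
    4: [("ind", "L1", lambda b: b), ("lin", "E1", lambda b: b),
        ("lin", "E2", lambda b: b)],
    5: [("lin", "E2", lambda b: b * b)],
    6: [("lin", "E2", lambda b: 3.0 * b)],
    7: [("ind", "L1", lambda b: b), ("ind", "L2", lambda b: b),
        ("lin", "E1", lambda b: b), ("lin", "E2", lambda b: b)],
}


def truth_network(scenario_id: int) -> TruthNetwork:
    """True edges and nodes of a scenario (each spans five nodes)."""
    edges: set[tuple[str, str]] = set()
    for child, parents in _E_LINKS[scenario_id].items():
        for p in parents:
            edges.add((p, child))
    for kind, var, _coef in _D_TERMS[scenario_id]:
        edges.add((var, PHENOTYPE))
    nodes = {x for e in edges for x in e}
    return TruthNetwork(frozenset(nodes), frozenset(edges))


def simulate_scenario(spec: ScenarioSpec) -> SimulatedData:
    """Draw one dataset (and its truth network) from a scenario."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    for l in LOCI:
        cols[l] = rng.choice(3, size=n, p=spec.genotype_probs).astype(np.int64)
    links = _E_LINKS[spec.id]
    for e in TRANSCRIPTS:  # E1 first: E2 may depend on it (chain scenarios)
        if e in links:
            mean = np.full(n, spec.expr_base)
            for parent in links[e]:
                mean = mean + spec.beta * cols[parent]
            cols[e] = mean + rng.normal(0.0, spec.noise_sd, n)
        else:
            cols[e] = rng.normal(spec.expr_mean, spec.expr_sd, n)
    d = rng.normal(0.0, spec.noise_sd, n)
    for kind, var, coef in _D_TERMS[spec.id]:
        c = coef(spec.beta)
        if kind == "ind":
            d = d + c * (cols[var] == 1) + c * (cols[var] == 2)
        else:
            d = d + c * cols[var]
    cols[PHENOTYPE] = d
    data = pd.DataFrame(cols, columns=list(UNIVERSE))
    nodes = tuple(
        [snp(l) for l in LOCI]
        + [transcript(e) for e in TRANSCRIPTS]
        + [phenotype_node(PHENOTYPE)]
    )
    return SimulatedData(data, nodes, truth_network(spec.id))


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """tp/fp/fn with derived sensitivity and FDR (0/0 -> 0)."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def fdr(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else 0.0


@dataclass(frozen=True)
class EvalResult:
    nodes: Metrics
    edges: Metrics


def _set_metrics(reported: frozenset, truth: frozenset) -> Metrics:
    tp = len(reported & truth)
    return Metrics(tp, len(reported) - tp, len(truth) - tp)


def node_metrics(
    reported: Iterable[str],
    truth: TruthNetwork,
    universe: Iterable[str] = UNIVERSE,
) -> Metrics:
    """Node recovery of a reported node set against the truth network."""
    rep = frozenset(reported)
    uni = frozenset(universe)
    if not rep <= uni:
        raise ValueError(f"reported nodes outside the universe: {rep - uni}")
    return _set_metrics(rep, frozenset(truth.nodes))


def edge_metrics(
    reported: Iterable[tuple[str, str]], truth: TruthNetwork
) -> Metrics:
    """Directed exact-match edge recovery (a reversed edge counts as one
    false positive plus one false negative)."""
    return _set_metrics(
        frozenset((u, v) for u, v in reported), frozenset(truth.edges)
    )


def evaluate(
    reported_nodes: Iterable[str],
    reported_edges: Iterable[tuple[str, str]],
    truth: TruthNetwork,
    universe: Iterable[str] = UNIVERSE,
) -> EvalResult:
    return EvalResult(
        node_metrics(reported_nodes, truth, universe),
        edge_metrics(reported_edges, truth),
    )


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------

def _derive_seed(*keys: int) -> int:
    # deterministic child seed < 2**31
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def _run_algorithm(
    name: str,
    engine: ScoringEngine,
    lam: float,
    seed: int,
    greedy_config: SearchConfig,
) -> tuple[tuple[str, ...], frozenset[tuple[str, str]]]:
    """Reported (nodes, edges) of one algorithm on one dataset."""
    if name == "npars":
        res = run_npars(None, None, None, k1=None, k2=1, lam=lam, engine=engine)
        if not res.networks:
            return (), frozenset()
        net = res.networks[0]
        return net.node_names, frozenset(net.dag.edges)
    if name == "exh":
        net = exhaustive_search(engine, lam=lam)
        return net.node_names, frozenset(net.dag.edges)
    if name in ("greedy", "greedy_e"):
        cfg = SearchConfig(
            restarts=greedy_config.restarts,
            max_iterations=greedy_config.max_iterations,
            node_cap=5 if name == "greedy_e" else greedy_config.node_cap,
            seed=seed,
            objective=greedy_config.objective,
            init_edge_prob=greedy_config.init_edge_prob,
            lam=lam,
        )
        fn = greedy_e if name == "greedy_e" else greedy_search
        res = fn(engine, config=cfg)
        return res.reported_nodes, frozenset(res.dag.edges)
    raise ValueError(f"unknown algorithm {name!r}")


_ALG_OFFSET = {"npars": 1, "exh": 2, "greedy": 3, "greedy_e": 4}


def run_comparison(
    scenarios: Sequence[int] = SCENARIO_IDS,
    algorithms: Sequence[str] = ("npars", "exh", "greedy", "greedy_e"),
    ns: Sequence[int] = (100, 200, 500, 1000),
    beta: float = 0.8,
    replicates: int = 25,
    seed: int = 0,
    prior: PriorSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    greedy_config: SearchConfig = SearchConfig(),
) -> pd.DataFrame:
    """Simulate-run-evaluate every (scenario, n, replicate, algorithm) cell.

    All algorithms see the same dataset within a replicate.  Returns one row
    per run plus one ``replicate="mean"`` summary row per cell, with node and
    edge sensitivity/FDR columns.  Individual failures are logged, counted
    in the ``errors`` attribute of the frame, and excluded from means.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows: list[dict] = []
    errors = 0
    for sid in scenarios:
        for n in ns:
            for rep in range(replicates):
                data_seed = _derive_seed(seed, sid, n, rep)
                sim = simulate_scenario(
                    ScenarioSpec(sid, beta, n, seed=data_seed)
                )
                engine = ScoringEngine(sim.data, sim.nodes, prior)
                for alg in algorithms:
                    alg_seed = _derive_seed(
                        seed, sid, n, rep, _ALG_OFFSET[alg]
                    )
                    try:
                        nodes_rep, edges_rep = _run_algorithm(
                            alg, engine, lam, alg_seed, greedy_config
                        )
                        ev = evaluate(nodes_rep, edges_rep, sim.truth)
                    except Exception:  # pragma: no cover - robustness
                        logger.exception(
                            "replicate failed (scenario=%s n=%s rep=%s alg=%s)",
                            sid, n, rep, alg,
                        )
                        errors += 1
                        continue
                    rows.append(
                        {
                            "scenario": sid,
                            "algorithm": alg,
                            "beta": beta,
                            "n": n,
                            "replicate": rep,
                            "node_sensitivity": ev.nodes.sensitivity,
                            "node_fdr": ev.nodes.fdr,
                            "edge_sensitivity": ev.edges.sensitivity,
                            "edge_fdr": ev.edges.fdr,
                        }
                    )
    df = pd.DataFrame(rows)
    metric_cols = [
        "node_sensitivity", "node_fdr", "edge_sensitivity", "edge_fdr",
    ]
    summaries = []
    if len(df):
        grouped = df.groupby(["scenario", "algorithm", "beta", "n"])[
            metric_cols
        ].mean()
        for (sid, alg, b, n), means in grouped.iterrows():
            summaries.append(
                {
                    "scenario": sid,
                    "algorithm": alg,
                    "beta": b,
                    "n": n,
                    "replicate": "mean",
                    **means.to_dict(),
                }
            )
    out = pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
    out.attrs["errors"] = errors
    if errors:
        logger.warning("%d replicate runs failed and were excluded", errors)
    return out
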