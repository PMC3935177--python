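"""Comparator search algorithms: exhaustive five-node search and greedy
hill-climbing with random restarts.

* :func:`exhaustive_search` (Exh) visits every {L1, L2, E1, E2, D} choice of
  two loci and two transcripts with the phenotype, enumerates all admissible
  structures on each five-node set and returns the global phi maximizer —
  the gold standard, feasible only for small variable panels.
* :func:`greedy_search` (Greedy) hill-climbs over the full variable set:
  from a sparse random admissible DAG it repeatedly applies the best
  strictly-improving single-edge modification (add, delete or reverse,
  admissibility preserved) until a local optimum or the iteration cap, and
  keeps the best of the random restarts.  An iteration is one accepted
  modification; the default objective is the phi score normalized by the
  number of connected nodes (the raw network score S is available via
  ``SearchConfig.objective``).  Because network scores are large negative
  numbers, per-connected-node normalization rewards absorbing additional
  variables, so unconstrained greedy search characteristically connects
  nearly the whole panel — the behavior the node-capped GreedyE variant
  exists to curb.
* :func:`greedy_e` (GreedyE) is Greedy with a node cap: any move that would
  push the number of connected (degree >= 1) nodes above the cap is
  excluded from the move set.

The reported node set of a greedy result is the set of degree >= 1 nodes.
All randomness flows from ``SearchConfig.seed``; identical seeds give
bit-identical results.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dag import (
    AdmissibilityRules,
    DEFAULT_RULES,
    Dag,
    Node,
    admissible_edges,
)
from .phi import DEFAULT_LAMBDA
from .scoring import PriorSpec, ScoringEngine
from .search import AssembledNetwork, search_node_set

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "RestartLog",
    "GreedyResult",
    "exhaustive_search",
    "greedy_search",
    "greedy_e",
]

_EPS = 1e-10  # strict-improvement threshold


@dataclass(frozen=True)
class SearchConfig:
    """Greedy-search settings.

    ``max_iterations`` caps *accepted* edge modifications per restart;
    ``init_edge_prob`` is the inclusion probability of each admissible edge
    (consistent with a random topological order) in the random starting
    DAG.  ``objective`` is ``"phi"`` (default: the phenotype-weighted score
    per connected node, see :meth:`_GreedyState.objective_value`) or
    ``"S"`` (raw network score).
    """

    restarts: int = 10
    max_iterations: int = 100
    node_cap: int | None = None
    seed: int = 0
    objective: str = "phi"
    init_edge_prob: float = 0.2
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.objective not in ("S", "phi"):
            raise ValueError("objective must be 'S' or 'phi'")


@dataclass(frozen=True)
class RestartLog:
    restart: int
    iterations: int
    objective: float


@dataclass
class GreedyResult:
    """Best-restart structure with its scores and reporting."""

    dag: Dag
    objective: float
    S: float
    reported_nodes: tuple[str, ...]
    restart_log: list[RestartLog] = field(default_factory=list)


def _resolve_engine(
    data: pd.DataFrame | ScoringEngine,
    nodes: Sequence[Node] | None,
    prior: PriorSpec,
) -> ScoringEngine:
    if isinstance(data, ScoringEngine):
        return data
    if nodes is None:
        raise ValueError("nodes must be given when data is a DataFrame")
    return ScoringEngine(data, nodes, prior)


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

def exhaustive_search(
    data: pd.DataFrame | ScoringEngine,
    nodes: Sequence[Node] | None = None,
    prior: PriorSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    rules: AdmissibilityRules = DEFAULT_RULES,
) -> AssembledNetwork:
    """Global phi maximizer over all 2-locus/2-transcript five-node sets.

    Ties resolve to the canonically (lexicographically) earliest node set.
    """
    engine = _resolve_engine(data, nodes, prior)
    loci = sorted(n.name for n in engine.nodes if n.role == "L")
    transcripts = sorted(n.name for n in engine.nodes if n.role == "E")
    d_names = [n.name for n in engine.nodes if n.role == "D"]
    if len(loci) < 2 or len(transcripts) < 2 or len(d_names) != 1:
        raise ValueError(
            "exhaustive search needs >= 2 loci, >= 2 transcripts and one "
            "phenotype node"
        )
    node_map = {n.name: n for n in engine.nodes}
    best: AssembledNetwork | None = None
    for lpair in itertools.combinations(loci, 2):
        for epair in itertools.combinations(transcripts, 2):
            members = [node_map[x] for x in (*lpair, *epair, d_names[0])]
            dag, S, S0, phi_val = search_node_set(
                engine, members, lam, "phi", rules
            )
            if best is None or phi_val > best.phi:
                best = AssembledNetwork(
                    tuple(sorted(n.name for n in members)),
                    dag, S, S0, phi_val, (),
                )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Greedy hill-climbing
# ---------------------------------------------------------------------------

class _GreedyState:
    """Mutable hill-climbing state over engine node indices."""

    def __init__(
        self,
        engine: ScoringEngine,
        cand: list[tuple[int, int]],
        lam: float,
        objective: str,
    ) -> None:
        self.engine = engine
        self.p = len(engine.nodes)
        self.cand = cand
        self.cand_set = set(cand)
        self.lam = lam
        self.objective = objective
        self.d_idx = next(
            (i for i, n in enumerate(engine.nodes) if n.role == "D"), None
        )
        self.parents = [0] * self.p
        self.children = [0] * self.p
        self.reach = [0] * self.p

    # -- bookkeeping -------------------------------------------------------
    def set_edges(self, edges: Sequence[tuple[int, int]]) -> None:
        self.parents = [0] * self.p
        self.children = [0] * self.p
        for u, v in edges:
            self.parents[v] |= 1 << u
            self.children[u] |= 1 << v
        self._recompute_reach()

    def _recompute_reach(self) -> None:
        reach = list(self.children)
        changed = True
        while changed:
            changed = False
            for u in range(self.p):
                acc = reach[u]
                m = acc
                while m:
                    b = m & -m
                    acc |= reach[b.bit_length() - 1]
                    m ^= b
                if acc != reach[u]:
                    reach[u] = acc
                    changed = True
        self.reach = reach

    def apply(self, move: tuple[str, int, int]) -> None:
        kind, u, v = move
        if kind == "add":
            self.parents[v] |= 1 << u
            self.children[u] |= 1 << v
        elif kind == "del":
            self.parents[v] &= ~(1 << u)
            self.children[u] &= ~(1 << v)
        else:  # reverse u->v  to  v->u
            self.parents[v] &= ~(1 << u)
            self.children[u] &= ~(1 << v)
            self.parents[u] |= 1 << v
            self.children[v] |= 1 << u
        self._recompute_reach()

    # -- scoring -----------------------------------------------------------
    def local(self, v: int, mask: int) -> float:
        pset = frozenset(b for b in range(self.p) if (mask >> b) & 1)
        return self.engine.local_score_idx(v, pset)

    def totals(self) -> tuple[float, float]:
        """(S, S0) of the current structure."""
        S = 0.0
        S0 = 0.0
        dbit = 1 << self.d_idx if self.d_idx is not None else 0
        for v in range(self.p):
            mask = self.parents[v]
            S += self.local(v, mask)
            if self.d_idx is not None and v == self.d_idx:
                S0 += self.local(v, 0)
            else:
                S0 += self.local(v, mask & ~dbit)
        return S, S0

    def n_active(self) -> int:
        touched = 0
        for v in range(self.p):
            touched |= self.parents[v] | self.children[v]
        return bin(touched).count("1")

    def objective_value(self, S: float, S0: float, n_active: int) -> float:
        """Objective of a candidate state.

        ``"S"`` is the raw network score.  ``"phi"`` normalizes the
        phenotype-weighted score by the size of the *candidate network* —
        the connected (degree >= 1) nodes, since unconnected variables are
        not part of the reported structure.  Scores being large and
        negative, the per-node normalization is what lets greedy search
        absorb additional nodes, the behavior unconstrained hill-climbing
        is known for on this kind of panel.
        """
        if self.objective == "S":
            return S
        return (self.lam * (S - S0) + (1.0 - self.lam) * S) / max(n_active, 1)

    # -- move deltas -------------------------------------------------------
    def _delta(self, v: int, old_mask: int, new_mask: int) -> tuple[float, float]:
        """(dS, dS0) of replacing node v's parent mask."""
        d_s = self.local(v, new_mask) - self.local(v, old_mask)
        if self.d_idx is not None and v == self.d_idx:
            d_s0 = 0.0
        elif self.d_idx is not None:
            dbit = 1 << self.d_idx
            d_s0 = self.local(v, new_mask & ~dbit) - self.local(v, old_mask & ~dbit)
        else:
            d_s0 = d_s
        return d_s, d_s0

    def _path_avoiding(self, src: int, dst: int, skip: tuple[int, int]) -> bool:
        """Directed path src -> dst not using the edge *skip*."""
        su, sv = skip
        seen = 1 << src
        stack = [src]
        while stack:
            x = stack.pop()
            kids = self.children[x]
            if x == su:
                kids &= ~(1 << sv)
            m = kids & ~seen
            while m:
                b = m & -m
                w = b.bit_length() - 1
                if w == dst:
                    return True
                seen |= b
                stack.append(w)
                m ^= b
        return False

    def best_move(
        self, S: float, S0: float, node_cap: int | None
    ) -> tuple[tuple[str, int, int], float, float, float] | None:
        """Best strictly-improving move, or None at a local optimum."""
        touched = 0
        for w in range(self.p):
            touched |= self.parents[w] | self.children[w]
        n_active = bin(touched).count("1")
        cur_obj = self.objective_value(S, S0, n_active)
        best = None
        best_obj = cur_obj + _EPS
        for u, v in self.cand:
            present = (self.parents[v] >> u) & 1
            if not present:
                if (self.reach[v] >> u) & 1:
                    continue  # would create a cycle
                grow = ((touched >> u) & 1 == 0) + ((touched >> v) & 1 == 0)
                if node_cap is not None and n_active + grow > node_cap:
                    continue
                d_s, d_s0 = self._delta(
                    v, self.parents[v], self.parents[v] | (1 << u)
                )
                obj = self.objective_value(S + d_s, S0 + d_s0, n_active + grow)
                if obj > best_obj:
                    best_obj = obj
                    best = (("add", u, v), S + d_s, S0 + d_s0, obj)
            else:
                # delete
                u_stays = bool(
                    self.parents[u] | (self.children[u] & ~(1 << v))
                )
                v_stays = bool(
                    (self.parents[v] & ~(1 << u)) | self.children[v]
                )
                shrink = (not u_stays) + (not v_stays)
                d_s, d_s0 = self._delta(
                    v, self.parents[v], self.parents[v] & ~(1 << u)
                )
                obj = self.objective_value(
                    S + d_s, S0 + d_s0, n_active - shrink
                )
                if obj > best_obj:
                    best_obj = obj
                    best = (("del", u, v), S + d_s, S0 + d_s0, obj)
                # reverse (active set unchanged)
                if (v, u) in self.cand_set and not self._path_avoiding(
                    u, v, (u, v)
                ):
                    d_s1, d_s01 = self._delta(
                        v, self.parents[v], self.parents[v] & ~(1 << u)
                    )
                    d_s2, d_s02 = self._delta(
                        u, self.parents[u], self.parents[u] | (1 << v)
                    )
                    obj = self.objective_value(
                        S + d_s1 + d_s2, S0 + d_s01 + d_s02, n_active
                    )
                    if obj > best_obj:
                        best_obj = obj
                        best = (
                            ("rev", u, v),
                            S + d_s1 + d_s2,
                            S0 + d_s01 + d_s02,
                            obj,
                        )
        return best


def _random_start(
    rng: np.random.Generator,
    cand: list[tuple[int, int]],
    p: int,
    edge_prob: float,
    node_cap: int | None,
) -> list[tuple[int, int]]:
    order = rng.permutation(p)
    pos = np.empty(p, dtype=np.int64)
    pos[order] = np.arange(p)
    edges: list[tuple[int, int]] = []
    touched: set[int] = set()
    for u, v in cand:
        if pos[u] >= pos[v]:
            continue
        if rng.random() >= edge_prob:
            continue
        if node_cap is not None:
            grow = (u not in touched) + (v not in touched)
            if len(touched) + grow > node_cap:
                continue
        edges.append((u, v))
        touched.update((u, v))
    return edges


def greedy_search(
    data: pd.DataFrame | ScoringEngine,
    nodes: Sequence[Node] | None = None,
    prior: PriorSpec | None = None,
    config: SearchConfig = SearchConfig(),
    rules: AdmissibilityRules = DEFAULT_RULES,
) -> GreedyResult:
    """Greedy hill-climbing with random restarts over the full node set."""
    engine = _resolve_engine(data, nodes, prior)
    engine_nodes = engine.nodes
    p = len(engine_nodes)
    index = {n.name: i for i, n in enumerate(engine_nodes)}
    cand = sorted(
        (index[u], index[v]) for u, v in admissible_edges(engine_nodes, rules)
    )
    state = _GreedyState(engine, cand, config.lam, config.objective)
    rng = np.random.default_rng(config.seed)

    best_edges: list[tuple[int, int]] | None = None
    best_obj = -np.inf
    best_S = -np.inf
    log: list[RestartLog] = []
    for r in range(config.restarts):
        state.set_edges(
            _random_start(rng, cand, p, config.init_edge_prob, config.node_cap)
        )
        S, S0 = state.totals()
        iters = 0
        while iters < config.max_iterations:
            move = state.best_move(S, S0, config.node_cap)
            if move is None:
                break
            mv, S, S0, _obj = move
            state.apply(mv)
            iters += 1
        obj = state.objective_value(S, S0, state.n_active())
        log.append(RestartLog(r, iters, obj))
        if obj > best_obj:
            best_obj = obj
            best_S = S
            best_edges = [
                (u, v)
                for v in range(p)
                for u in range(p)
                if (state.parents[v] >> u) & 1
            ]

    assert best_edges is not None
    named = [(engine_nodes[u].name, engine_nodes[v].name) for u, v in best_edges]
    dag = Dag(engine_nodes, named, validate=False)
    reported = tuple(
        sorted(n.name for n in engine_nodes if dag.degree(n.name) > 0)
    )
    return GreedyResult(dag, best_obj, best_S, reported, log)


def greedy_e(
    data: pd.DataFrame | ScoringEngine,
    nodes: Sequence[Node] | None = None,
    prior: PriorSpec | None = None,
    config: SearchConfig = SearchConfig(node_cap=5),
    rules: AdmissibilityRules = DEFAULT_RULES,
) -> GreedyResult:
    """Greedy search with a cap on the number of connected nodes (default 5)."""
    if config.node_cap is None:
        config = replace(config, node_cap=5)
    return greedy_search(data, nodes, prior, config, rules)
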