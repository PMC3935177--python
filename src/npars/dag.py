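"""Directed acyclic graphs over mixed genotype/expression/phenotype nodes.

Nodes carry a *role* — ``L`` for a SNP locus, ``E`` for an expression
transcript, ``D`` for the phenotype — and a *kind* (discrete or continuous).
Genotypes are discrete (three levels: 0/1/2 copies of the minor allele);
expression and phenotype are continuous.  Two admissibility rules restrict
the structure space:

* no edge may point into an ``L`` node — a genotype is fixed at conception,
  so neither expression, phenotype, nor (by default) another locus can be
  its parent;
* no continuous node may be the parent of a discrete node (the conditional
  Gaussian restriction, which keeps the marginal likelihood closed-form).

The module provides acyclicity checking, exhaustive enumeration of the
admissible DAGs on a small node set, and the canonical catalog of the 12
admissible structures on a single (L, E, D) triplet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Node",
    "Dag",
    "TripletStructure",
    "AdmissibilityRules",
    "CapacityError",
    "snp",
    "transcript",
    "phenotype",
    "is_acyclic",
    "admissible_edges",
    "enumerate_dags",
    "enumerate_parent_sets",
    "triplet_catalog",
    "has_isolated_node",
]

#: Node-count guard for exhaustive structure enumeration.
DEFAULT_ENUMERATION_LIMIT = 6


class CapacityError(RuntimeError):
    """Raised when an exhaustive enumeration would exceed the node guard."""


@dataclass(frozen=True)
class Node:
    """A network variable.

    Parameters
    ----------
    name:
        Column identifier in the data.
    role:
        ``"L"`` (SNP locus), ``"E"`` (transcript) or ``"D"`` (phenotype).
    kind:
        ``"discrete"`` or ``"continuous"``; defaults from the role
        (loci are discrete, transcripts and phenotype continuous).
    levels:
        Number of categories for a discrete node (SNP genotypes have 3).
    """

    name: str
    role: str
    kind: str = ""
    levels: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("L", "E", "D"):
            raise ValueError(f"unknown role {self.role!r} for node {self.name!r}")
        kind = self.kind or ("discrete" if self.role == "L" else "continuous")
        object.__setattr__(self, "kind", kind)
        if self.role == "L" and self.kind != "discrete":
            raise ValueError("L nodes must be discrete")
        if self.role in ("E", "D") and self.kind != "continuous":
            raise ValueError("E and D nodes must be continuous")
        if self.kind == "discrete":
            levels = 3 if self.levels is None else self.levels
            if levels < 2:
                raise ValueError("discrete nodes need at least 2 levels")
            object.__setattr__(self, "levels", levels)
        else:
            object.__setattr__(self, "levels", None)


def snp(name: str, levels: int = 3) -> Node:
    """A discrete SNP-locus node (genotype coded 0/1/2)."""
    return Node(name, "L", "discrete", levels)


def transcript(name: str) -> Node:
    """A continuous expression node."""
    return Node(name, "E", "continuous")


def phenotype(name: str = "D") -> Node:
    """The continuous phenotype node."""
    return Node(name, "D", "continuous")


@dataclass(frozen=True)
class AdmissibilityRules:
    """Structural constraints on candidate edges.

    ``allow_l_parents`` permits locus-to-locus edges; by default every edge
    into an ``L`` node is forbidden since genotype is causally upstream of
    everything measured here.
    """

    allow_l_parents: bool = False


DEFAULT_RULES = AdmissibilityRules()


def _node_map(nodes: Sequence[Node]) -> dict[str, Node]:
    by_name: dict[str, Node] = {}
    for node in nodes:
        if node.name in by_name:
            raise ValueError(f"duplicate node name {node.name!r}")
        by_name[node.name] = node
    return by_name


def is_acyclic(edges: Iterable[tuple[str, str]], nodes: Iterable[str]) -> bool:
    """True iff the directed graph given by *edges* on *nodes* has no cycle.

    Raises ``ValueError`` if an edge references a node outside *nodes*.
    """
    names = set(nodes)
    children: dict[str, list[str]] = {n: [] for n in names}
    indeg = {n: 0 for n in names}
    for u, v in edges:
        if u not in names or v not in names:
            raise ValueError(f"edge ({u!r}, {v!r}) references an unknown node")
        children[u].append(v)
        indeg[v] += 1
    # Kahn's algorithm
    queue = [n for n in names if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(names)


class Dag:
    """An admissible DAG over a fixed node set.

    Edges are ordered (parent, child) name pairs.  Construction validates
    membership, acyclicity and (unless ``validate=False``) the role/kind
    admissibility rules.
    """

    __slots__ = ("nodes", "edges", "_by_name")

    def __init__(
        self,
        nodes: Sequence[Node],
        edges: Iterable[tuple[str, str]] = (),
        rules: AdmissibilityRules = DEFAULT_RULES,
        validate: bool = True,
    ) -> None:
        self.nodes: tuple[Node, ...] = tuple(nodes)
        self._by_name = _node_map(self.nodes)
        self.edges: frozenset[tuple[str, str]] = frozenset(
            (str(u), str(v)) for u, v in edges
        )
        if validate:
            allowed = set(admissible_edges(self.nodes, rules))
            for e in self.edges:
                if e[0] not in self._by_name or e[1] not in self._by_name:
                    raise ValueError(f"edge {e} references an unknown node")
                if e not in allowed:
                    raise ValueError(f"edge {e} violates admissibility rules")
            if not is_acyclic(self.edges, self._by_name):
                raise ValueError("edge set contains a directed cycle")

    # -- structure queries -------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> Node:
        return self._by_name[name]

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == name))

    def degree(self, name: str) -> int:
        return sum(1 for u, v in self.edges if name in (u, v))

    def with_edges(self, edges: Iterable[tuple[str, str]]) -> "Dag":
        return Dag(self.nodes, edges, validate=False)

    def canonical_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.edges))

    # -- equality / hashing ------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        edges = ", ".join(f"{u}->{v}" for u, v in self.canonical_edges())
        return f"Dag({list(self.node_names)}, [{edges}])"

    # -- serialization -----------------------------------------------------
    def to_edge_tsv(self) -> str:
        """Tab-separated edge list with a node-annotation header."""
        lines = ["# node\trole\tkind"]
        for n in self.nodes:
            lines.append(f"# {n.name}\t{n.role}\t{n.kind}")
        lines.append("parent\tchild")
        for u, v in self.canonical_edges():
            lines.append(f"{u}\t{v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_edge_tsv(cls, text: str) -> "Dag":
        nodes: list[Node] = []
        edges: list[tuple[str, str]] = []
        header_seen = False
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("# ").split("\t")
                if len(parts) == 3 and parts[0] != "node":
                    name, role, kind = parts
                    nodes.append(Node(name, role, kind))
                continue
            if not header_seen:
                header_seen = True  # "parent\tchild"
                continue
            u, v = line.split("\t")
            edges.append((u, v))
        return cls(nodes, edges)

    def to_dot(self) -> str:
        """Graphviz DOT text; discrete nodes are drawn filled."""
        lines = ["digraph G {"]
        for n in self.nodes:
            style = ' [style=filled, fillcolor=gray]' if n.kind == "discrete" else ""
            lines.append(f'  "{n.name}"{style};')
        for u, v in self.canonical_edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def admissible_edges(
    nodes: Sequence[Node], rules: AdmissibilityRules = DEFAULT_RULES
) -> list[tuple[str, str]]:
    """All ordered (parent, child) pairs permitted by the role/kind rules."""
    out: list[tuple[str, str]] = []
    for u, v in itertools.permutations(nodes, 2):
        if v.role == "L" and not (rules.allow_l_parents and u.role == "L"):
            continue
        if u.kind == "continuous" and v.kind == "discrete":
            continue
        out.append((u.name, v.name))
    out.sort()
    return out


def enumerate_parent_sets(
    n_nodes: int, candidate_edges: Sequence[tuple[int, int]]
) -> list[tuple[int, ...]]:
    """Enumerate acyclic subsets of *candidate_edges* on integer nodes.

    Each result is a tuple of parent bitmasks, one per node.  The list is
    sorted lexicographically by the sorted edge list, so the empty graph is
    first and order is deterministic.  Enumeration proceeds by backtracking
    over the candidate edges while maintaining a transitive-closure bitmask
    so cyclic branches are pruned as soon as they appear.
    """
    results: list[tuple[int, ...]] = []
    edges = sorted(candidate_edges)
    m = len(edges)
    parents = [0] * n_nodes

    def rec(i: int, reach: list[int]) -> None:
        if i == m:
            results.append(tuple(parents))
            return
        rec(i + 1, reach)  # exclude edges[i]
        u, v = edges[i]
        # adding u->v creates a cycle iff u is reachable from v
        if not (reach[v] >> u) & 1:
            parents[v] |= 1 << u
            new_reach = list(reach)
            # every node reaching u (plus u itself) now reaches v's cone
            cone = new_reach[v] | (1 << v)
            for w in range(n_nodes):
                if w == u or (new_reach[w] >> u) & 1:
                    new_reach[w] |= cone
            rec(i + 1, new_reach)
            parents[v] &= ~(1 << u)

    rec(0, [0] * n_nodes)

    def edge_key(ps: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
        return tuple(
            sorted((u, v) for v in range(n_nodes) for u in range(n_nodes)
                   if (ps[v] >> u) & 1)
        )

    results.sort(key=edge_key)
    return results


def enumerate_dags(
    nodes: Sequence[Node],
    rules: AdmissibilityRules = DEFAULT_RULES,
    max_nodes: int = DEFAULT_ENUMERATION_LIMIT,
) -> list[Dag]:
    """Every admissible DAG on *nodes*, exactly once, in canonical order.

    Canonical order is lexicographic on the sorted edge list.  Raises
    :class:`CapacityError` above *max_nodes* nodes (default 6) — the space
    grows super-exponentially.
    """
    if not nodes:
        raise ValueError("node set must be nonempty")
    if len(nodes) > max_nodes:
        raise CapacityError(
            f"exhaustive enumeration limited to {max_nodes} nodes "
            f"(got {len(nodes)})"
        )
    names = [n.name for n in nodes]
    index = {name: i for i, name in enumerate(names)}
    cand = [(index[u], index[v]) for u, v in admissible_edges(nodes, rules)]
    dags = []
    for ps in enumerate_parent_sets(len(nodes), cand):
        edges = [
            (names[u], names[v])
            for v in range(len(nodes))
            for u in range(len(nodes))
            if (ps[v] >> u) & 1
        ]
        dags.append(Dag(nodes, edges, validate=False))
    dags.sort(key=Dag.canonical_edges)
    return dags


# ---------------------------------------------------------------------------
# Triplet catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletStructure:
    """One of the 12 admissible structures on a single (L, E, D) triplet.

    ``index`` runs 1..12.  Index 1 is the empty structure and index 2 is
    {L→E} (the null counterpart of any structure whose only D-edges hang off
    an L→E backbone); the remaining ten follow in lexicographic order of
    their sorted edge lists.  The indices are stable identifiers of this
    package and algorithmic logic never depends on them — selection uses the
    degree-zero predicate.
    """

    index: int
    edges: frozenset[tuple[str, str]] = field(compare=True)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.edges))

    def has_isolated_node(self) -> bool:
        touched = {x for e in self.edges for x in e}
        return len(touched) < 3

    def __repr__(self) -> str:
        edges = ",".join(f"{u}->{v}" for u, v in self.sorted_edges())
        return f"TripletStructure({self.index}, {{{edges}}})"


def _build_catalog() -> tuple[TripletStructure, ...]:
    pool = [("L", "E"), ("L", "D"), ("E", "D"), ("D", "E")]
    sets: list[frozenset[tuple[str, str]]] = []
    for r in range(len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            s = frozenset(combo)
            if ("E", "D") in s and ("D", "E") in s:
                continue  # 2-cycle
            sets.append(s)
    pinned = [frozenset(), frozenset({("L", "E")})]
    rest = sorted(
        (s for s in sets if s not in pinned), key=lambda s: tuple(sorted(s))
    )
    ordered = pinned + rest
    return tuple(
        TripletStructure(i + 1, s) for i, s in enumerate(ordered)
    )


_CATALOG = _build_catalog()


def triplet_catalog() -> tuple[TripletStructure, ...]:
    """The 12 admissible (L, E, D) structures, with stable indices."""
    return _CATALOG


def has_isolated_node(dag: Dag) -> bool:
    """True iff some node of *dag* has total degree zero."""
    touched = {x for e in dag.edges for x in e}
    return any(n.name not in touched for n in dag.nodes)
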