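"""The three-stage nPARS search: partition, selection, reassembly.

nPARS (network Partition and Reassembly Search) builds networks modularly:

1. **Partition** — decompose the variable space into all (locus, transcript,
   phenotype) triplets and, for each, score the 12 admissible three-node
   structures, keeping the structure with the highest network score S.
2. **Selection** — discard triplets whose best structure contains a node of
   degree zero (equivalently, fewer than two edges), rank survivors by the
   phi score and keep the top ``k1``.
3. **Reassembly** — for every unordered pair of selected triplets, take the
   union of their nodes (four nodes if they share the locus or the
   transcript, five otherwise), enumerate every admissible structure on the
   union *from scratch* and keep the phi-maximizing one; rank the resulting
   networks by phi and report the top ``k2``.

Within a triplet the best structure is chosen by S; within a reassembled
node set by phi (both choices are arguments).  All tie-breaks are canonical
(lowest catalog index / lexicographically earliest edge or node set), so
results are deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dag import (
    AdmissibilityRules,
    DEFAULT_RULES,
    Dag,
    Node,
    TripletStructure,
    admissible_edges,
    enumerate_parent_sets,
    phenotype as phenotype_node,
    snp,
    transcript as transcript_node,
    triplet_catalog,
)
from .phi import DEFAULT_LAMBDA, phi as phi_score
from .scoring import PriorSpec, ScoringEngine

logger = logging.getLogger(__name__)

__all__ = [
    "TripletResult",
    "AssembledNetwork",
    "combine_inputs",
    "partition_count",
    "score_all_triplets",
    "select_triplets",
    "pairings",
    "reassemble_pairs",
    "grow_networks",
    "run_npars",
    "NparsResult",
]


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

def combine_inputs(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    phenotype: pd.Series | pd.DataFrame,
    phenotype_name: str = "D",
) -> tuple[pd.DataFrame, list[Node]]:
    """Join the three inputs on their shared sample index.

    Returns the combined frame together with the typed node list (loci
    discrete with 3 levels, transcripts and phenotype continuous).
    """
    if isinstance(phenotype, pd.DataFrame):
        if phenotype.shape[1] != 1:
            raise ValueError("phenotype must be a single column")
        phenotype = phenotype.iloc[:, 0]
    pheno = phenotype.rename(phenotype_name)
    common = genotypes.index.intersection(expression.index).intersection(
        pheno.index
    )
    dropped = (
        len(set(genotypes.index) | set(expression.index) | set(pheno.index))
        - len(common)
    )
    if len(common) == 0:
        raise ValueError("genotype/expression/phenotype share no samples")
    if dropped:
        logger.info("dropped %d samples outside the shared sample set", dropped)
    df = pd.concat(
        [genotypes.loc[common], expression.loc[common], pheno.loc[common]],
        axis=1,
    )
    nodes = (
        [snp(c) for c in genotypes.columns]
        + [transcript_node(c) for c in expression.columns]
        + [phenotype_node(phenotype_name)]
    )
    return df, nodes


def partition_count(n_loci: int, n_transcripts: int) -> int:
    """Number of (L, E, D) triplets the partition stage will visit."""
    if n_loci < 0 or n_transcripts < 0:
        raise ValueError("counts must be nonnegative")
    return n_loci * n_transcripts


# ---------------------------------------------------------------------------
# Stage 1: triplet scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletResult:
    """Best-scoring structure for one (locus, transcript, phenotype) triplet."""

    locus: str
    transcript: str
    structure: TripletStructure
    S: float
    S0: float
    phi: float

    @property
    def node_names(self) -> tuple[str, str]:
        return (self.locus, self.transcript)

    def to_dag(self, phenotype_name: str = "D") -> Dag:
        nodes = [snp(self.locus), transcript_node(self.transcript),
                 phenotype_node(phenotype_name)]
        name = {"L": self.locus, "E": self.transcript, "D": phenotype_name}
        edges = [(name[u], name[v]) for u, v in self.structure.edges]
        return Dag(nodes, edges, validate=False)


# catalog bookkeeping: per structure, the parent roles of E and D and the
# index of its null (phenotype-stripped) counterpart
def _catalog_tables():
    catalog = triplet_catalog()
    by_edges = {s.edges: s.index for s in catalog}
    rows = []
    for s in catalog:
        e_par = frozenset(u for u, v in s.edges if v == "E")
        d_par = frozenset(u for u, v in s.edges if v == "D")
        stripped = frozenset(e for e in s.edges if "D" not in e)
        rows.append((e_par, d_par, by_edges[stripped]))
    return catalog, rows


_CATALOG, _CATALOG_ROWS = _catalog_tables()


def _score_triplet(
    engine: ScoringEngine, locus: str, transcript: str, d_name: str, lam: float
) -> TripletResult:
    """Score all 12 catalog structures for one triplet; pick best by S."""
    li = engine.index(locus)
    ei = engine.index(transcript)
    di = engine.index(d_name)
    by_role = {"L": li, "E": ei, "D": di}
    base = engine.local_score_idx(li, frozenset())

    scores = np.empty(12)
    for k, (e_par, d_par, _null) in enumerate(_CATALOG_ROWS):
        s = base
        s += engine.local_score_idx(ei, frozenset(by_role[r] for r in e_par))
        s += engine.local_score_idx(di, frozenset(by_role[r] for r in d_par))
        scores[k] = s
    best = int(np.argmax(scores))  # first max = lowest catalog index
    s_best = float(scores[best])
    s0 = float(scores[_CATALOG_ROWS[best][2] - 1])
    return TripletResult(
        locus, transcript, _CATALOG[best], s_best, s0,
        phi_score(s_best, s0, lam, 3),
    )


def score_all_triplets(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    phenotype: pd.Series | pd.DataFrame,
    prior: PriorSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    phenotype_name: str = "D",
) -> list[TripletResult]:
    """Stage 1: best structure, S, S0 and phi for every (L, E) pair.

    Rows with a missing value in a triplet's three columns are dropped for
    that triplet only (per-triplet complete-case analysis).  Triplets with
    zero usable samples are logged and omitted.
    """
    df, nodes = combine_inputs(genotypes, expression, phenotype, phenotype_name)
    loci = list(genotypes.columns)
    transcripts = list(expression.columns)
    if not df.isna().any().any():
        engine = ScoringEngine(df, nodes, prior)
        return [
            _score_triplet(engine, l, e, phenotype_name, lam)
            for l in loci
            for e in transcripts
        ]

    node_map = {n.name: n for n in nodes}
    results: list[TripletResult] = []
    for l in loci:
        for e in transcripts:
            sub = df[[l, e, phenotype_name]].dropna()
            if len(sub) == 0:
                logger.warning(
                    "triplet (%s, %s): no complete samples; skipped", l, e
                )
                continue
            engine = ScoringEngine(
                sub, [node_map[l], node_map[e], node_map[phenotype_name]], prior
            )
            results.append(_score_triplet(engine, l, e, phenotype_name, lam))
    return results


# ---------------------------------------------------------------------------
# Stage 2: selection
# ---------------------------------------------------------------------------

def select_triplets(
    results: Sequence[TripletResult], k1: int | None = None
) -> list[TripletResult]:
    """Stage 2: drop structures with an isolated node, rank by phi.

    A triplet structure has no degree-zero node iff it has at least two
    edges; survivors are sorted by phi descending (stable, so ties keep the
    canonical locus-by-transcript generation order).  Returns the top *k1*
    (all survivors when *k1* is ``None`` or exceeds the survivor count).
    """
    if k1 is not None and k1 < 1:
        raise ValueError("k1 must be >= 1")
    if not results:
        logger.warning("select_triplets: empty input")
        return []
    survivors = [r for r in results if not r.structure.has_isolated_node()]
    survivors.sort(key=lambda r: -r.phi)
    return survivors if k1 is None else survivors[:k1]


def pairings(
    selected: Sequence[TripletResult],
) -> Iterator[tuple[TripletResult, TripletResult]]:
    """Every unordered pair of selected triplets, each exactly once."""
    return itertools.combinations(selected, 2)


# ---------------------------------------------------------------------------
# Stage 3: reassembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssembledNetwork:
    """A re-searched network on the node union of two or more triplets."""

    node_names: tuple[str, ...]
    dag: Dag
    S: float
    S0: float
    phi: float
    parent_triplets: tuple[tuple[str, str], ...]


class StructureSpace:
    """Enumerated admissible structures on a role signature, with per-node
    parent-set deduplication and the null-structure index map.

    Instances are cached by signature so the (2 L, 2 E, D) enumeration, for
    example, is performed once and reused across every concrete node set.
    """

    _cache: dict[tuple, "StructureSpace"] = {}

    def __init__(self, signature: tuple[tuple[str, str], ...],
                 rules: AdmissibilityRules) -> None:
        # signature: ((role, kind), ...) in node order
        nodes = [
            Node(f"n{i}", role, kind, 3 if kind == "discrete" else None)
            for i, (role, kind) in enumerate(signature)
        ]
        p = len(nodes)
        index = {n.name: i for i, n in enumerate(nodes)}
        cand = sorted(
            (index[u], index[v]) for u, v in admissible_edges(nodes, rules)
        )
        self.parent_sets = enumerate_parent_sets(p, cand)
        self.n_structures = len(self.parent_sets)
        self.p = p
        arr = np.array(self.parent_sets, dtype=np.int64)  # (n_dags, p)
        self.unique_masks: list[np.ndarray] = []
        self.inverse: list[np.ndarray] = []
        for j in range(p):
            uniq, inv = np.unique(arr[:, j], return_inverse=True)
            self.unique_masks.append(uniq)
            self.inverse.append(inv)
        # null map: strip every edge incident to the role-D node
        d_pos = next(i for i, (role, _) in enumerate(signature) if role == "D")
        lookup = {ps: i for i, ps in enumerate(self.parent_sets)}
        null_idx = np.empty(self.n_structures, dtype=np.int64)
        dbit = 1 << d_pos
        for i, ps in enumerate(self.parent_sets):
            stripped = tuple(
                0 if j == d_pos else (mask & ~dbit)
                for j, mask in enumerate(ps)
            )
            null_idx[i] = lookup[stripped]
        self.null_index = null_idx
        self.d_pos = d_pos

    @classmethod
    def for_signature(
        cls, signature: tuple[tuple[str, str], ...],
        rules: AdmissibilityRules = DEFAULT_RULES,
    ) -> "StructureSpace":
        key = (signature, rules)
        space = cls._cache.get(key)
        if space is None:
            space = cls(signature, rules)
            cls._cache[key] = space
        return space

    def score_all(
        self, engine: ScoringEngine, members: Sequence[int], lam: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """S and phi for every structure, for the concrete node set
        ``members`` (engine indices aligned with the signature order)."""
        S = np.zeros(self.n_structures)
        for j in range(self.p):
            vals = np.empty(len(self.unique_masks[j]))
            for t, mask in enumerate(self.unique_masks[j]):
                pset = frozenset(
                    members[b] for b in range(self.p) if (mask >> b) & 1
                )
                vals[t] = engine.local_score_idx(members[j], pset)
            S += vals[self.inverse[j]]
        S0 = S[self.null_index]
        phi_vec = (lam * (S - S0) + (1.0 - lam) * S) / self.p
        return S, phi_vec

    def to_dag(self, i: int, nodes: Sequence[Node]) -> Dag:
        ps = self.parent_sets[i]
        edges = [
            (nodes[u].name, nodes[v].name)
            for v in range(self.p)
            for u in range(self.p)
            if (ps[v] >> u) & 1
        ]
        return Dag(nodes, edges, validate=False)


def search_node_set(
    engine: ScoringEngine,
    nodes: Sequence[Node],
    lam: float = DEFAULT_LAMBDA,
    objective: str = "phi",
    rules: AdmissibilityRules = DEFAULT_RULES,
) -> tuple[Dag, float, float, float]:
    """Exhaustively search the admissible structures on *nodes*.

    Returns ``(dag, S, S0, phi)`` of the structure maximizing *objective*
    (``"phi"`` or ``"S"``); ties resolve to the canonically earliest edge
    set.  Node order follows sorted names so the enumeration is reusable
    across node sets with the same role pattern.
    """
    ordered = sorted(nodes, key=lambda n: n.name)
    signature = tuple((n.role, n.kind) for n in ordered)
    space = StructureSpace.for_signature(signature, rules)
    members = [engine.index(n.name) for n in ordered]
    S, phi_vec = space.score_all(engine, members, lam)
    crit = phi_vec if objective == "phi" else S
    best = int(np.argmax(crit))
    dag = space.to_dag(best, ordered)
    return dag, float(S[best]), float(S[space.null_index[best]]), float(phi_vec[best])


def _triplet_union(
    a: TripletResult, b: TripletResult, node_map: dict[str, Node]
) -> list[Node]:
    names = sorted({a.locus, a.transcript, b.locus, b.transcript})
    return [node_map[n] for n in names]


def reassemble_pairs(
    selected: Sequence[TripletResult],
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    phenotype: pd.Series | pd.DataFrame,
    prior: PriorSpec | None = None,
    k2: int = 20,
    lam: float = DEFAULT_LAMBDA,
    phenotype_name: str = "D",
) -> list[AssembledNetwork]:
    """Stage 3 over every unordered pair of selected triplets."""
    if len(selected) < 2:
        raise ValueError("reassembly needs at least 2 selected triplets")
    df, nodes = combine_inputs(genotypes, expression, phenotype, phenotype_name)
    if df.isna().any().any():
        raise ValueError(
            "reassembly requires complete data over the selected columns; "
            "drop or impute missing values first"
        )
    engine = ScoringEngine(df, nodes, prior)
    return _reassemble_with_engine(
        engine, selected, k2=k2, lam=lam, phenotype_name=phenotype_name
    )


def _reassemble_with_engine(
    engine: ScoringEngine,
    selected: Sequence[TripletResult],
    k2: int | None,
    lam: float,
    phenotype_name: str,
) -> list[AssembledNetwork]:
    node_map = {n.name: n for n in engine.nodes}
    best_by_nodeset: dict[tuple[str, ...], AssembledNetwork] = {}
    for a, b in pairings(selected):
        union = _triplet_union(a, b, node_map)
        members = [node_map[phenotype_name], *union]
        key = tuple(sorted(n.name for n in members))
        dag, S, S0, phi_val = search_node_set(engine, members, lam, "phi")
        net = AssembledNetwork(
            key, dag, S, S0, phi_val,
            (a.node_names, b.node_names),
        )
        prev = best_by_nodeset.get(key)
        if prev is None:
            best_by_nodeset[key] = net
        else:
            logger.debug("duplicate node set %s from multiple pairs", key)
            if net.phi > prev.phi:
                best_by_nodeset[key] = net
    ranked = sorted(
        best_by_nodeset.values(), key=lambda n: (-n.phi, n.node_names)
    )
    return ranked if k2 is None else ranked[:k2]


def grow_networks(
    bases: Sequence[AssembledNetwork],
    selected: Sequence[TripletResult],
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    phenotype: pd.Series | pd.DataFrame,
    prior: PriorSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    phenotype_name: str = "D",
    max_nodes: int = 6,
) -> list[AssembledNetwork]:
    """One optional growth round: union each base with each remaining
    triplet and re-search exhaustively while within the capacity guard.

    Unions larger than *max_nodes* nodes are skipped with a log entry; a
    union adding nothing new is skipped.  Returns bases and grown networks
    merged, deduplicated by node set and re-ranked by phi.  Exhaustive
    re-search grows super-exponentially with union size, so this round is
    deliberately conservative.
    """
    if not bases:
        raise ValueError("grow_networks needs at least one base network")
    df, nodes = combine_inputs(genotypes, expression, phenotype, phenotype_name)
    engine = ScoringEngine(df, nodes, prior)
    node_map = {n.name: n for n in nodes}
    best: dict[tuple[str, ...], AssembledNetwork] = {
        net.node_names: net for net in bases
    }
    for base in bases:
        for trip in selected:
            extra = {trip.locus, trip.transcript} - set(base.node_names)
            if not extra:
                continue
            names = tuple(sorted(set(base.node_names) | extra))
            if len(names) > max_nodes:
                logger.info(
                    "union %s exceeds the %d-node guard; skipped",
                    names, max_nodes,
                )
                continue
            members = [node_map[n] for n in names]
            dag, S, S0, phi_val = search_node_set(engine, members, lam, "phi")
            net = AssembledNetwork(
                names, dag, S, S0, phi_val,
                base.parent_triplets + (trip.node_names,),
            )
            prev = best.get(names)
            if prev is None or net.phi > prev.phi:
                best[names] = net
    return sorted(best.values(), key=lambda n: (-n.phi, n.node_names))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class NparsResult:
    """Output of the full three-stage pipeline."""

    triplets: list[TripletResult]
    selected: list[TripletResult]
    networks: list[AssembledNetwork]


def run_npars(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    phenotype: pd.Series | pd.DataFrame,
    k1: int | None = 100,
    k2: int | None = 20,
    prior: PriorSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    phenotype_name: str = "D",
    engine: ScoringEngine | None = None,
) -> NparsResult:
    """Run partition, selection and reassembly end to end.

    ``k1=None`` keeps every adequately connected triplet (the simulation
    default); ``k2=None`` returns every assembled network.  If fewer than
    two triplets survive selection, the single survivor (or nothing) is
    reported as the final network.
    """
    if engine is None:
        df, nodes = combine_inputs(
            genotypes, expression, phenotype, phenotype_name
        )
        loci = list(genotypes.columns)
        transcripts = list(expression.columns)
        if df.isna().any().any():
            triplets = score_all_triplets(
                genotypes, expression, phenotype, prior, lam, phenotype_name
            )
            engine = None
        else:
            engine = ScoringEngine(df, nodes, prior)
            triplets = [
                _score_triplet(engine, l, e, phenotype_name, lam)
                for l in loci
                for e in transcripts
            ]
    else:
        loci = [n.name for n in engine.nodes if n.role == "L"]
        transcripts = [n.name for n in engine.nodes if n.role == "E"]
        triplets = [
            _score_triplet(engine, l, e, phenotype_name, lam)
            for l in loci
            for e in transcripts
        ]

    selected = select_triplets(triplets, k1)
    if len(selected) >= 2:
        if engine is None:
            networks = reassemble_pairs(
                selected, genotypes, expression, phenotype, prior, k2, lam,
                phenotype_name,
            )
        else:
            networks = _reassemble_with_engine(
                engine, selected, k2, lam, phenotype_name
            )
    elif len(selected) == 1:
        t = selected[0]
        networks = [
            AssembledNetwork(
                tuple(sorted((t.locus, t.transcript, phenotype_name))),
                t.to_dag(phenotype_name),
                t.S, t.S0, t.phi, (t.node_names,),
            )
        ]
    else:
        logger.info("no triplet survived selection; empty report")
        networks = []
    return NparsResult(triplets, selected, networks)
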