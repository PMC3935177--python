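"""The average network improvement score phi and the null network.

Raw network scores are not comparable across node sets of different sizes,
and a structure can score well through tight molecular associations that
say nothing about the phenotype.  The phi score addresses both: with S the
network score, S0 the score of the *null network* (the same structure with
every edge incident to the phenotype node removed), lambda in [0, 1] and
alpha the number of nodes,

    phi = [lambda * (S - S0) + (1 - lambda) * S] / alpha.

The (S - S0) term measures the improvement contributed by the phenotype
edges; dividing by alpha approximates the linear growth of the log marginal
likelihood in the number of nodes.  lambda = 0.5 weights fit and phenotype
relevance equally and is the default throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dag import Dag

__all__ = ["PhiResult", "phi", "null_network"]

DEFAULT_LAMBDA = 0.5


@dataclass(frozen=True)
class PhiResult:
    """A scored structure: network score, null score and phi."""

    S: float
    S0: float
    lam: float
    alpha: int
    phi: float


def phi(S: float, S0: float, lam: float = DEFAULT_LAMBDA, alpha: int = 1) -> float:
    """Average network improvement score.

    Parameters
    ----------
    S, S0:
        Network score of the structure and of its null network.
    lam:
        Weight in [0, 1] on the phenotype-improvement term (S - S0).
    alpha:
        Node count of the structure (>= 1), including isolated nodes.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    if alpha < 1:
        raise ValueError("alpha must be a positive node count")
    return (lam * (S - S0) + (1.0 - lam) * S) / alpha


def score_phi(S: float, S0: float, lam: float, alpha: int) -> PhiResult:
    """Bundle S, S0 and phi into a :class:`PhiResult`."""
    return PhiResult(S, S0, lam, alpha, phi(S, S0, lam, alpha))


def null_network(dag: Dag, phenotype: str | None = None) -> Dag:
    """The *dag* with every edge incident to the phenotype node removed.

    Both in- and out-edges of the phenotype are dropped, so the null model
    renders the phenotype independent of the rest of the network; all nodes
    are retained.  If *phenotype* is not given, the unique role-``D`` node
    is used.
    """
    if phenotype is None:
        d_nodes = [n.name for n in dag.nodes if n.role == "D"]
        if len(d_nodes) != 1:
            raise ValueError(
                "dag must contain exactly one phenotype (role D) node, "
                f"found {d_nodes}"
            )
        phenotype = d_nodes[0]
    elif phenotype not in dag.node_names:
        raise ValueError(f"phenotype node {phenotype!r} not in dag")
    kept = [(u, v) for u, v in dag.edges if phenotype not in (u, v)]
    return dag.with_edges(kept)
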