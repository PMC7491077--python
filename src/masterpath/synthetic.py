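"""Seeded synthetic interactomes, hit lists and planted pathways.

These generators make every part of the method testable without downloading
any interaction database.  The background graph is a configuration-model
graph with a heavy-tailed (power-law, exponent 2.5 by default) degree
sequence, mimicking the skewed degree structure of real interactomes — the
degree-binned null sampler is only meaningfully exercised on skewed degrees.
Edge types are assigned by a fixed mixture; transcriptional, miRNA-mRNA and
enzymatic edges are directed, a configurable fraction of PPI edges is too.

``plant_backbone`` inserts a directed linear chain between fresh nodes and
wires every designated hit to its head and its tail to every designated
implementer, so that the chain lies on a shortest path for every
(hit, implementer) pair — the convergent-pathway situation the centrality
statistic is designed to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .interactome import EdgeRecord, InteractionNetwork, NodeRecord, merge_networks
from .pathfinding import PairSearcher

logger = logging.getLogger(__name__)

_DEFAULT_MIXTURE = {
    "ppi": 0.70,
    "transcriptional": 0.15,
    "mirna_mrna": 0.05,
    "enzymatic": 0.10,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic interactome.

    ``type_mixture`` gives the sampling proportions of the four interaction
    types (must sum to 1); ``fraction_directed_ppi`` is the fraction of PPI
    edges that are directed (the other three types are always directed, as in
    curated source databases).  ``degree_exponent`` shapes the power-law
    degree sequence fed to the configuration model.
    """

    n_nodes: int = 300
    degree_exponent: float = 2.5
    min_degree: int = 1
    type_mixture: dict = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    fraction_directed_ppi: float = 0.3
    n_mirna: int = 0  # number of nodes given miRNA-style identifiers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mixture proportions must sum to 1 (got {total})")
        if not (0.0 <= self.fraction_directed_ppi <= 1.0):
            raise ValueError("fraction_directed_ppi must lie in [0, 1]")
        if self.degree_exponent <= 1.0:
            raise ValueError("degree_exponent must exceed 1")


def generate_network(spec: FixtureSpec) -> InteractionNetwork:
    """Build a seeded configuration-model interactome from a :class:`FixtureSpec`.

    Deterministic: the same spec (same seed) produces an identical network,
    byte for byte when written back out.  Parallel edges and self-loops from
    the configuration model are discarded; the typed edge list then passes
    through the standard merge, so all network invariants hold.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    max_degree = max(spec.min_degree + 1, n // 10)
    degrees = rng.zipf(spec.degree_exponent, size=n)
    degrees = np.clip(degrees, spec.min_degree, max_degree)
    if degrees.sum() % 2:
        degrees[int(rng.integers(n))] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31 - 1)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))

    ids = _node_ids(n, spec.n_mirna)
    types = list(spec.type_mixture)
    probs = np.array([spec.type_mixture[t] for t in types], dtype=float)
    edge_list = sorted(tuple(sorted(e)) for e in g.edges())
    records: list[EdgeRecord] = []
    for u, v in edge_list:
        itype = types[int(rng.choice(len(types), p=probs))]
        su, sv = ids[u], ids[v]
        if itype == "ppi":
            directed = bool(rng.random() < spec.fraction_directed_ppi)
        else:
            directed = True
        if directed and rng.random() < 0.5:
            su, sv = sv, su
        if itype == "mirna_mrna" and not su.startswith("hsa-"):
            # miRNA-mRNA edges must originate at a miRNA; fall back to ppi
            itype = "ppi"
            directed = bool(rng.random() < spec.fraction_directed_ppi)
        records.append(EdgeRecord(su, sv, directed, itype, "synthetic"))
    if not records:
        raise ValueError("degree sequence produced an empty edge set")
    node_records = [
        NodeRecord(ids[i], "miRNA" if ids[i].startswith("hsa-") else "protein")
        for i in range(n)
    ]
    return merge_networks([records], node_records)


def _node_ids(n: int, n_mirna: int) -> list[str]:
    ids = []
    for i in range(n):
        if i < n_mirna:
            ids.append(f"hsa-mir-{9000 + i}")
        else:
            ids.append(f"N{i:04d}")
    return ids


# ---------------------------------------------------------------------------
# the hand-checkable toy fixture
# ---------------------------------------------------------------------------

#: 10-node / 9-edge undirected PPI toy network (two isolated nodes, TI/TJ).
TOY10_EDGES = (
    ("TB", "TE"),
    ("TE", "TH"),
    ("TC", "TE"),
    ("TB", "TG"),
    ("TD", "TG"),
    ("TD", "TF"),
    ("TA", "TH"),
    ("TC", "TF"),
    ("TA", "TC"),
)
TOY10_HITS = ("TB", "TH")
TOY10_IMPLEMENTERS = ("TF", "TA")
TOY10_ISOLATED = ("TI", "TJ")


def toy10() -> tuple[InteractionNetwork, list[str], list[str]]:
    """The bundled 10-node toy fixture: network, hit list, implementer list.

    Nine undirected PPI edges among eight connected nodes plus two isolated
    nodes; small enough that every path, centrality and subpath score can be
    verified by hand or by exhaustive enumeration.
    """
    edges = [EdgeRecord(u, v, False, "ppi", "toy10") for u, v in TOY10_EDGES]
    nodes = [NodeRecord(x, "protein") for x in TOY10_ISOLATED]
    return merge_networks([edges], nodes), list(TOY10_HITS), list(TOY10_IMPLEMENTERS)


# ---------------------------------------------------------------------------
# planted backbones
# ---------------------------------------------------------------------------


def plant_backbone(
    network: InteractionNetwork,
    k_hits: int,
    n_implementers: int,
    backbone_len: int,
    rng: np.random.Generator | None = None,
    l_max: int = 5,
    max_retries: int = 50,
) -> tuple[InteractionNetwork, list[str], list[str], list[str]]:
    """Insert a directed chain that all (hit, implementer) shortest paths share.

    Adds ``backbone_len + 1`` fresh chain nodes, a directed PPI edge from each
    of ``k_hits`` randomly chosen hits to the chain head, and from the chain
    tail to each of ``n_implementers`` randomly chosen implementers.  The
    resulting hit→implementer route has ``backbone_len + 2`` edges and must be
    a shortest protein-protein path for *every* pair; if the background graph
    provides a shorter bypass the hit/implementer draw is retried, up to
    ``max_retries`` times.

    Returns ``(network', hits, implementers, backbone_nodes)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if backbone_len < 1:
        raise ValueError("backbone_len must be a positive integer")
    if backbone_len + 2 > l_max:
        raise ValueError(
            f"backbone of {backbone_len} edges plus two stubs exceeds l_max={l_max}"
        )
    pool = network.node_ids()
    need = k_hits + n_implementers
    if need > len(pool):
        raise ValueError("not enough network nodes to draw hits and implementers")
    chain = [f"BB{j:02d}" for j in range(backbone_len + 1)]
    if any(network.has_node(b) for b in chain):
        raise ValueError("network already contains backbone node identifiers")

    for attempt in range(max_retries):
        idx = rng.choice(len(pool), size=need, replace=False)
        drawn = [pool[i] for i in idx]
        hits, implementers = drawn[:k_hits], drawn[k_hits:]
        extra = [
            EdgeRecord(chain[j], chain[j + 1], True, "ppi", "backbone")
            for j in range(backbone_len)
        ]
        extra += [EdgeRecord(h, chain[0], True, "ppi", "backbone") for h in hits]
        extra += [EdgeRecord(chain[-1], f, True, "ppi", "backbone") for f in implementers]
        planted = merge_networks(
            [network.edges, extra], list(network.nodes.values())
        )
        if _backbone_is_shortest(planted, hits, implementers, chain, l_max):
            logger.info("backbone planted after %d attempt(s)", attempt + 1)
            return planted, hits, implementers, chain
    raise RuntimeError(
        f"could not plant a shortest backbone in {max_retries} attempts "
        "(background graph keeps providing shorter bypasses)"
    )


def _backbone_is_shortest(
    network: InteractionNetwork,
    hits: list[str],
    implementers: list[str],
    chain: list[str],
    l_max: int,
) -> bool:
    """Post-hoc verification against the pathfinding engine itself."""
    searcher = PairSearcher(network, implementers, l_max)
    for h in hits:
        for f in implementers:
            if h == f:
                return False
            expected = (h, *chain, f)
            found = searcher.typed_paths(h, f)
            if not any(p.nodes == expected for p in found):
                return False
    return True
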