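"""Shared fixtures and the independent brute-force path oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from masterpath.interactome import EdgeRecord, NodeRecord, merge_networks, normalize_id
from masterpath.synthetic import toy10

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


def edge(u, v, directed=False, itype="ppi", prov="t"):
    return EdgeRecord(normalize_id(u), normalize_id(v), directed, itype, prov)


def build_network(edges, nodes=()):
    return merge_networks([list(edges)], [NodeRecord(n) for n in nodes])


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive simple-path enumeration, per-(pair, class)
# minimum filter.  Deliberately independent of the BFS/DFS engine: it builds
# its own adjacency from the raw edge list and classifies by edge-type rank.
# ---------------------------------------------------------------------------

_RANK = {"ppi": 0, "transcriptional": 1, "mirna_mrna": 2, "enzymatic": 3}
_CLASSES = ("protein_protein", "transcriptional", "mirna", "metabolic")


def brute_force_path_set(network, hits, implementers, l_max):
    """Set of (hit, impl, class, node_seq, edge_type_seq) built by exhaustive DFS."""
    adj: dict[str, list] = {}
    for e in network.edges:
        adj.setdefault(e.source, []).append((e.target, e.interaction_type))
        if not e.directed:
            adj.setdefault(e.target, []).append((e.source, e.interaction_type))
    result = set()
    for h in hits:
        for f in implementers:
            if h == f or h not in network.nodes or f not in network.nodes:
                continue
            found: list[tuple] = []

            def dfs(v, nodes, etypes):
                if v == f:
                    found.append((tuple(nodes), tuple(etypes)))
                    return
                if len(etypes) >= l_max:
                    return
                for w, t in adj.get(v, ()):
                    if w not in nodes:
                        dfs(w, nodes + [w], etypes + [t])

            dfs(h, [h], [])
            best: dict[str, tuple] = {}
            for nodes, etypes in found:
                cls = _CLASSES[max(_RANK[t] for t in etypes)]
                L = len(etypes)
                cur = best.get(cls)
                if cur is None or L < cur[0]:
                    best[cls] = (L, {(nodes, etypes)})
                elif L == cur[0]:
                    cur[1].add((nodes, etypes))
            for cls, (_, paths) in best.items():
                for nodes, etypes in paths:
                    result.add((h, f, cls, nodes, etypes))
    return result


def engine_path_set(path_set):
    """The engine's result in the oracle's comparable form."""
    return {
        (p.anchor[0], p.anchor[1], p.type_class, p.nodes, p.edge_types)
        for p in path_set.paths
    }


def random_typed_network(rng: np.random.Generator, n_nodes: int, p_edge: float):
    """A random mixed-direction, all-four-types network for oracle comparisons."""
    names = [f"V{i:02d}" for i in range(n_nodes)]
    types = ["ppi", "transcriptional", "mirna_mrna", "enzymatic"]
    edges = []
    for u, v in itertools.combinations(names, 2):
        if rng.random() >= p_edge:
            continue
        t = types[int(rng.integers(4))]
        directed = True if t in ("transcriptional", "mirna_mrna") else bool(rng.random() < 0.5)
        if directed and rng.random() < 0.5:
            u, v = v, u
        edges.append(EdgeRecord(u, v, directed, t, "rand"))
    if not edges:
        return None
    return merge_networks([edges])


@pytest.fixture(scope="session")
def toy():
    """The bundled 10-node fixture: (network, hits, implementers)."""
    return toy10()
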