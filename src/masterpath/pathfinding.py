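"""Bounded shortest-path search between hits and final implementers.

For every ordered pair ``(h, f)`` of a hit and a final implementer the method
collects *all* shortest simple paths of each of four path type classes whose
length does not exceed ``L_max``.  Edge direction is respected during the
search (undirected edges are traversable both ways); edge *type* only enters
through the class hierarchy:

- ``protein_protein`` — every edge is a protein-protein interaction;
- ``transcriptional`` — at least one transcriptional edge, the rest PPI;
- ``mirna`` — at least one miRNA-mRNA edge, the rest PPI/transcriptional;
- ``metabolic`` — at least one enzymatic edge, any others of the above types.

The minimum length is computed independently per class: a short
protein-protein path does not suppress a longer metabolic path for the same
pair.  Each class corresponds to a cumulative admissible edge-type subset, so
the search runs one distance-bounded BFS/DFS per class with the constraint
that the class's distinguishing edge type occurs at least once.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .interactome import EdgeRecord, InteractionNetwork, MergeReport, NodeRecord

logger = logging.getLogger(__name__)

#: hierarchical order of path type classes (weakest to strongest edge rank)
PATH_TYPE_CLASSES = ("protein_protein", "transcriptional", "mirna", "metabolic")

# per class: (class name, admissible edge types, distinguishing "top" type)
_LEVELS = (
    ("protein_protein", frozenset({"ppi"}), None),
    ("transcriptional", frozenset({"ppi", "transcriptional"}), "transcriptional"),
    ("mirna", frozenset({"ppi", "transcriptional", "mirna_mrna"}), "mirna_mrna"),
    ("metabolic", frozenset({"ppi", "transcriptional", "mirna_mrna", "enzymatic"}), "enzymatic"),
)

_CLASS_INDEX = {name: i for i, (name, _, _) in enumerate(_LEVELS)}

_TYPE_RANK = {"ppi": 0, "transcriptional": 1, "mirna_mrna": 2, "enzymatic": 3}


def classify_path_type(edge_sequence: Sequence) -> str:
    """Classify a path by the strongest-ranked interaction type it contains.

    Accepts a sequence of :class:`EdgeRecord` or of raw interaction-type
    strings.  The hierarchy is enzymatic > miRNA-mRNA > transcriptional > PPI.
    """
    if not edge_sequence:
        raise ValueError("cannot classify an empty edge sequence")
    best = -1
    for e in edge_sequence:
        t = getattr(e, "interaction_type", e)
        try:
            r = _TYPE_RANK[t]
        except KeyError:
            raise ValueError(f"unknown interaction type {t!r}") from None
        if r > best:
            best = r
    return PATH_TYPE_CLASSES[best]


class LinearPath(NamedTuple):
    """An ordered simple path with its typed edge sequence.

    ``nodes`` has one more element than ``edges``; every directed edge is
    traversed source-to-target.  ``anchor`` is the ``(hit, implementer)``
    pair the path connects, when applicable.
    """

    nodes: tuple[str, ...]
    edge_types: tuple[str, ...]
    edges: tuple[EdgeRecord, ...]
    type_class: str
    anchor: tuple[str, str] | None

    @property
    def length(self) -> int:
        return len(self.edge_types)

    @classmethod
    def build(
        cls,
        nodes: Sequence[str],
        edges: Sequence[EdgeRecord],
        anchor: tuple[str, str] | None = None,
    ) -> "LinearPath":
        if len(nodes) != len(edges) + 1:
            raise ValueError("node sequence must have exactly one more element than edges")
        if len(set(nodes)) != len(nodes):
            raise ValueError("path is not simple (repeated node)")
        etypes = tuple(e.interaction_type for e in edges)
        return cls(tuple(nodes), etypes, tuple(edges), classify_path_type(edges), anchor)


def _path_sort_key(p: LinearPath):
    h, f = p.anchor if p.anchor else ("", "")
    return (h, f, _CLASS_INDEX[p.type_class], p.length, p.nodes, p.edge_types)


@dataclass
class ShortestPathSet:
    """All collected shortest typed paths for a (hit list, implementer list) pair."""

    paths: list[LinearPath]
    hits: tuple[str, ...]
    implementers: tuple[str, ...]
    l_max: int

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


class PairSearcher:
    """Reusable per-(network, implementer set, L_max) shortest-path engine.

    Precomputes, for every implementer and class level, reverse BFS distance
    maps on the admissible edge subset: the plain distance-to-implementer and
    the distance of the shortest walk that still has to traverse at least one
    edge of the class's distinguishing type.  Both are lower bounds on the
    remaining simple-path length and drive the pruned depth-first enumeration
    of all minimum-length paths.  Building the searcher once and querying it
    for many hit lists (as the permutation null does) amortizes the BFS cost.
    """

    def __init__(
        self, network: InteractionNetwork, implementers: Iterable[str], l_max: int
    ) -> None:
        if l_max < 1:
            raise ValueError("l_max must be a positive integer")
        self.network = network
        self.l_max = l_max
        self._levels = []
        for cls_name, types, top in _LEVELS:
            out_adj, in_adj = network.adjacency(types)
            self._levels.append((cls_name, out_adj, in_adj, top))
        self._bounds: dict[tuple[str, int], tuple[dict, dict | None]] = {}
        for f in implementers:
            self.add_implementer(f)

    def add_implementer(self, f: str) -> None:
        if not self.network.has_node(f):
            raise KeyError(f"implementer {f!r} not in network")
        for li, (_, _, in_adj, top) in enumerate(self._levels):
            if (f, li) in self._bounds:
                continue
            plain, need = _reverse_bounds(in_adj, f, top)
            self._bounds[(f, li)] = (plain, need)

    def paths(self, hit: str, implementer: str, level_index: int) -> list[tuple]:
        """Shortest class-exact paths for one (hit, implementer, class) triple.

        Returns raw ``(node_tuple, edge_tuple)`` pairs; empty if the class
        minimum exceeds ``l_max`` or no class-exact simple path exists.
        """
        _, out_adj, _, top = self._levels[level_index]
        plain, need = self._bounds[(implementer, level_index)]
        if top is None:
            d = plain.get(hit)
            if d is None or d > self.l_max:
                return []
            return _enumerate_exact(hit, implementer, d, out_adj, plain, None, None)
        lb = need.get(hit)
        if lb is None or lb > self.l_max:
            return []
        for ell in range(max(lb, 1), self.l_max + 1):
            res = _enumerate_exact(hit, implementer, ell, out_adj, plain, need, top)
            if res:
                return res
        return []

    def typed_paths(self, hit: str, implementer: str) -> list[LinearPath]:
        """All four classes' shortest paths for one ordered pair, as LinearPaths."""
        out: list[LinearPath] = []
        anchor = (hit, implementer)
        for li, (cls_name, _, _, _) in enumerate(self._levels):
            for node_seq, edge_seq in self.paths(hit, implementer, li):
                out.append(
                    LinearPath(
                        node_seq,
                        tuple(e.interaction_type for e in edge_seq),
                        edge_seq,
                        cls_name,
                        anchor,
                    )
                )
        return out


def _reverse_bounds(in_adj: dict, f: str, top: str | None) -> tuple[dict, dict | None]:
    """Reverse BFS distance maps toward ``f`` on one admissible edge subset.

    ``plain[v]`` is the shortest-walk distance from ``v`` to ``f``.  When
    ``top`` is given, ``need[v]`` is the shortest walk from ``v`` to ``f``
    containing at least one ``top``-type edge (a layered BFS over states
    ``(node, top-still-needed)``).  Both are admissible lower bounds for the
    pruned enumeration of simple paths.
    """
    plain: dict[str, int] = {f: 0}
    if top is None:
        q = deque([f])
        while q:
            v = q.popleft()
            dv = plain[v] + 1
            for u, _ in in_adj.get(v, ()):
                if u not in plain:
                    plain[u] = dv
                    q.append(u)
        return plain, None
    need: dict[str, int] = {}
    # states: (node, 0) plain layer, (node, 1) "top edge still required" layer
    q = deque([(f, 0)])
    while q:
        v, s = q.popleft()
        dv = (need[v] if s else plain[v]) + 1
        for u, e in in_adj.get(v, ()):
            if s == 0:
                if u not in plain:
                    plain[u] = dv
                    q.append((u, 0))
                if e.interaction_type == top and u not in need:
                    need[u] = dv
                    q.append((u, 1))
            else:
                if u not in need:
                    need[u] = dv
                    q.append((u, 1))
    return plain, need


def _enumerate_exact(
    hit: str,
    f: str,
    ell: int,
    out_adj: dict,
    plain: dict,
    need: dict | None,
    top: str | None,
) -> list[tuple]:
    """Enumerate all simple paths hit→f of exactly ``ell`` edges.

    When ``top`` is given only paths containing at least one ``top`` edge are
    returned.  Branches whose lower-bound completion distance exceeds the
    remaining budget are pruned; the bounds are walk distances, hence always
    admissible.
    """
    INF = float("inf")
    results: list[tuple] = []
    nodes = [hit]
    edges: list[EdgeRecord] = []
    visited = {hit}

    def dfs(v: str, depth: int, used: bool) -> None:
        if v == f:
            if depth == ell and (top is None or used):
                results.append((tuple(nodes), tuple(edges)))
            return
        nd = depth + 1
        budget = ell - nd
        if budget < 0:
            return
        for w, e in out_adj.get(v, ()):
            if w in visited:
                continue
            nu = used or (top is not None and e.interaction_type == top)
            if top is None or nu:
                b = plain.get(w, INF)
            else:
                b = need.get(w, INF)  # type: ignore[union-attr]
            if b > budget:
                continue
            visited.add(w)
            nodes.append(w)
            edges.append(e)
            dfs(w, nd, nu)
            visited.discard(w)
            nodes.pop()
            edges.pop()

    dfs(hit, 0, False)
    return results


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def find_shortest_typed_paths(
    network: InteractionNetwork, hit: str, implementer: str, l_max: int
) -> list[LinearPath]:
    """All per-class shortest simple paths from ``hit`` to ``implementer``.

    Endpoints absent from the network yield an empty result with a warning
    (the pair is skipped, not fatal).  ``hit == implementer`` is rejected.
    """
    if hit == implementer:
        raise ValueError("hit and implementer must differ")
    missing = [n for n in (hit, implementer) if not network.has_node(n)]
    if missing:
        logger.warning("skipping pair (%s, %s): %s not in network", hit, implementer, missing)
        return []
    searcher = PairSearcher(network, [implementer], l_max)
    return sorted(searcher.typed_paths(hit, implementer), key=_path_sort_key)


def collect_shortest_path_set(
    network: InteractionNetwork,
    hits: Sequence[str],
    implementers: Sequence[str],
    l_max: int,
    searcher: PairSearcher | None = None,
) -> ShortestPathSet:
    """Union of shortest typed paths over all ordered (hit, implementer) pairs.

    Identifiers absent from the network are dropped with a warning; identical
    ``(h, h)`` pairs are skipped.  Paths come back in a deterministic order
    (hit, implementer, class, length, node sequence).

    Raises
    ------
    ValueError
        If no hit (or no implementer) remains after dropping absent ids.
    """
    hits_kept = _dedupe([h for h in hits if network.has_node(h)])
    impl_kept = _dedupe([f for f in implementers if network.has_node(f)])
    dropped_h = sorted(set(hits) - set(hits_kept))
    dropped_f = sorted(set(implementers) - set(impl_kept))
    if dropped_h:
        logger.warning("%d hit ids absent from network, skipped: %s", len(dropped_h), dropped_h)
    if dropped_f:
        logger.warning(
            "%d implementer ids absent from network, skipped: %s", len(dropped_f), dropped_f
        )
    if not hits_kept:
        raise ValueError("no hit identifier is present in the network")
    if not impl_kept:
        raise ValueError("no final-implementer identifier is present in the network")
    if searcher is None:
        searcher = PairSearcher(network, impl_kept, l_max)
    paths: list[LinearPath] = []
    for h in hits_kept:
        for f in impl_kept:
            if h == f:
                continue
            paths.extend(searcher.typed_paths(h, f))
    paths.sort(key=_path_sort_key)
    return ShortestPathSet(paths, tuple(hits_kept), tuple(impl_kept), l_max)


def _collect_fast(searcher: PairSearcher, hits: Sequence[str], implementers: Sequence[str]):
    """Unsorted path collection for permutation replicates (ids pre-validated)."""
    paths: list[LinearPath] = []
    for h in hits:
        for f in implementers:
            if h == f:
                continue
            paths.extend(searcher.typed_paths(h, f))
    return paths


def _dedupe(seq: Sequence[str]) -> list[str]:
    seen: set = set()
    out = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def extract_subnetwork(
    path_set: ShortestPathSet, network: InteractionNetwork | None = None
) -> InteractionNetwork:
    """Subnetwork induced by a path set: union of path nodes and deduplicated edges.

    Node classes are copied from ``network`` when provided, otherwise inferred
    from identifiers.  An empty path set yields an empty network with a warning.
    """
    if not path_set.paths:
        logger.warning("extract_subnetwork: empty path set, returning empty network")
        return InteractionNetwork({}, [], merge_report=MergeReport())
    edges: list[EdgeRecord] = []
    seen: set = set()
    node_ids: set[str] = set()
    for p in path_set.paths:
        node_ids.update(p.nodes)
        for e in p.edges:
            k = e.key()
            if k not in seen:
                seen.add(k)
                edges.append(e)
    edges.sort(key=lambda e: e.key())
    if network is not None:
        nodes = {n: network.nodes[n] for n in sorted(node_ids)}
    else:
        from .interactome import _infer_node_class

        nodes = {n: NodeRecord(n, _infer_node_class(n)) for n in sorted(node_ids)}
    return InteractionNetwork(nodes, edges)


def write_path_table(path_set: ShortestPathSet, path: str | Path) -> None:
    """Write the collected paths as TSV (one row per path)."""
    with Path(path).open("w") as fh:
        fh.write("hit\timplementer\tlength\ttype_class\tnode_sequence\tedge_types\n")
        for p in path_set.paths:
            h, f = p.anchor if p.anchor else ("", "")
            fh.write(
                f"{h}\t{f}\t{p.length}\t{p.type_class}\t"
                f"{';'.join(p.nodes)}\t{';'.join(p.edge_types)}\n"
            )
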