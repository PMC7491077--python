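"""Node and subpath centrality scores over a collected shortest-path set.

The centrality of a node ``v`` is the number of collected shortest paths that
pass through it, ``c(v) = |{p : v ∈ p}|``; the centrality of a candidate
subpath ``q`` is the number of collected paths containing ``q`` as a
contiguous, orientation-matching fragment, ``c(q) = |{p : q ⊑ p}|``.  One
degenerate case is collapsed: when every path supporting ``q`` has the same
type class *and* the same (hit, implementer) anchor, ``c(q)`` is set to 1 —
such support reflects a single convergent route through well-connected nodes
rather than independent evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .pathfinding import LinearPath, ShortestPathSet

logger = logging.getLogger(__name__)


class SubpathKey(NamedTuple):
    """Identity of a contiguous path fragment: oriented nodes plus edge types."""

    nodes: tuple[str, ...]
    edge_types: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.edge_types)

    def label(self) -> str:
        return ";".join(self.nodes)


@dataclass(frozen=True)
class CentralityEntry:
    entity: object  # node id (str) or SubpathKey
    kind: str  # "node" | "path"
    centrality: int
    n_supporting: int
    anchors: frozenset  # of (hit, implementer, type_class)


@dataclass
class CentralityTable:
    """Per-entity centrality with the supporting-anchor bookkeeping."""

    entries: dict

    def get(self, entity, default: int = 0) -> int:
        e = self.entries.get(entity)
        return e.centrality if e is not None else default

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entity) -> bool:
        return entity in self.entries

    def __getitem__(self, entity) -> CentralityEntry:
        return self.entries[entity]


def score_nodes(path_set: ShortestPathSet, count_endpoints: bool = True) -> CentralityTable:
    """Centrality ``c(v)`` for every node lying on at least one collected path.

    ``count_endpoints`` controls whether the hit and implementer of a path
    count as lying on it (default: they do); nodes on no path are absent from
    the table (implicit zero).
    """
    if not path_set.paths:
        logger.warning("score_nodes: empty path set")
        return CentralityTable({})
    counts = _node_counts(path_set.paths, count_endpoints)
    anchors: dict[str, set] = {v: set() for v in counts}
    for p in path_set.paths:
        sig = (*p.anchor, p.type_class) if p.anchor else (None, None, p.type_class)
        seq = p.nodes if count_endpoints else p.nodes[1:-1]
        for v in seq:
            anchors[v].add(sig)
    entries = {
        v: CentralityEntry(v, "node", c, c, frozenset(anchors[v])) for v, c in counts.items()
    }
    return CentralityTable(entries)


def enumerate_subpaths(
    path_set: ShortestPathSet, len_min: int, len_max: int
) -> list[SubpathKey]:
    """All distinct contiguous fragments of the collected paths in a length window.

    Fragment identity is the oriented node sequence plus edge types (undirected
    edges are keyed by the orientation in which the supporting path traverses
    them).  The window must satisfy ``1 <= len_min <= len_max <= L_max``.
    """
    _check_window(len_min, len_max, path_set.l_max)
    seen: set[SubpathKey] = set()
    for p in path_set.paths:
        for key in _windows(p, len_min, len_max):
            seen.add(key)
    return sorted(seen)


def score_subpaths(
    path_set: ShortestPathSet, subpaths: Iterable[SubpathKey]
) -> CentralityTable:
    """Centrality ``c(q)`` for candidate subpaths, with the degenerate collapse.

    The raw score counts supporting member paths; if every supporting path
    shares one (hit, implementer) anchor and one type class, the score
    collapses to 1.  Subpaths supported by no path are omitted from the table.
    """
    wanted = set(subpaths)
    if not wanted:
        return CentralityTable({})
    lengths = {q.length for q in wanted}
    len_min, len_max = min(lengths), max(lengths)
    support: dict[SubpathKey, list] = {}
    for p in path_set.paths:
        sig = (*p.anchor, p.type_class) if p.anchor else (None, None, p.type_class)
        for key in _windows(p, len_min, len_max):
            if key not in wanted:
                continue
            ent = support.get(key)
            if ent is None:
                support[key] = [1, {sig}]
            else:
                ent[0] += 1
                ent[1].add(sig)
    entries = {}
    for key, (count, sigs) in support.items():
        collapsed = 1 if len(sigs) == 1 else count
        entries[key] = CentralityEntry(key, "path", collapsed, count, frozenset(sigs))
    return CentralityTable(entries)


def write_centrality_table(table: CentralityTable, path: str | Path) -> None:
    """TSV export: ``entity  kind  centrality  n_supporting_paths  anchors``."""
    with Path(path).open("w") as fh:
        fh.write("entity\tkind\tcentrality\tn_supporting_paths\tanchors\n")
        for entity in sorted(table.entries, key=_entity_sort_key):
            e = table.entries[entity]
            label = entity if isinstance(entity, str) else entity.label()
            anchors = ",".join(
                "|".join(str(x) for x in sig) for sig in sorted(e.anchors)
            )
            fh.write(f"{label}\t{e.kind}\t{e.centrality}\t{e.n_supporting}\t{anchors}\n")


def _entity_sort_key(entity):
    return (0, entity, ()) if isinstance(entity, str) else (1, entity.nodes, entity.edge_types)


# -- internals shared with the permutation null ------------------------------


def _check_window(len_min: int, len_max: int, l_max: int) -> None:
    if not (1 <= len_min <= len_max):
        raise ValueError(f"invalid subpath window [{len_min}, {len_max}]")
    if len_max > l_max:
        raise ValueError(
            f"subpath window upper bound {len_max} exceeds the search bound L_max={l_max}"
        )


def _windows(p: LinearPath, len_min: int, len_max: int):
    """Yield SubpathKeys for all contiguous fragments of ``p`` in the window."""
    L = len(p.edge_types)
    nodes, etypes = p.nodes, p.edge_types
    for wl in range(len_min, min(len_max, L) + 1):
        for i in range(L - wl + 1):
            yield SubpathKey(nodes[i : i + wl + 1], etypes[i : i + wl])


def _node_counts(paths: Sequence[LinearPath], count_endpoints: bool = True) -> dict:
    counts: dict[str, int] = {}
    for p in paths:
        seq = p.nodes if count_endpoints else p.nodes[1:-1]
        for v in seq:
            counts[v] = counts.get(v, 0) + 1
    return counts


def _subpath_scores(
    paths: Sequence[LinearPath],
    len_min: int,
    len_max: int,
    tracked: set | None = None,
) -> dict:
    """Collapsed subpath scores, optionally restricted to a tracked key set.

    Applies the same same-anchor/same-type collapse as :func:`score_subpaths`
    so that observed and null-replicate scores are computed identically.
    """
    support: dict[SubpathKey, list] = {}
    for p in paths:
        sig = (p.anchor, p.type_class)
        for key in _windows(p, len_min, len_max):
            if tracked is not None and key not in tracked:
                continue
            ent = support.get(key)
            if ent is None:
                support[key] = [1, sig, True]
            else:
                ent[0] += 1
                if ent[2] and ent[1] != sig:
                    ent[2] = False
    return {k: (1 if homog else n) for k, (n, _, homog) in support.items()}
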