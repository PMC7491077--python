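"""Typed molecular-interaction networks: loading, merging, adjacency queries.

The integrated interactome is an unweighted graph ``G = (V, E)`` whose nodes
are proteins, genes, miRNAs, small molecules or complexes, and whose edges are
typed molecular interactions drawn from several source databases
(protein-protein, transcription-factor/gene, miRNA-mRNA, enzymatic).  Edges may
be directed or undirected; transcriptional and miRNA-mRNA interactions are
always directed.

Edge tables are plain TSV files with a header row::

    source  target  directed  interaction_type  provenance

where ``directed`` is the literal token ``directed`` or ``undirected`` and
``interaction_type`` is one of ``ppi``, ``transcriptional``, ``mirna_mrna``,
``enzymatic``.  The ``provenance`` column is free-form (typically the source
database name) and may be omitted.

Merging several edge tables applies two rules:

1. duplicate interactions are removed (a directed edge is identified by
   ``(source, target, type)``, an undirected one by ``({u, v}, type)``);
2. if any directed edge exists between a node pair, every undirected edge
   between that pair is suppressed, regardless of interaction type.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

NODE_CLASSES = ("protein", "gene", "miRNA", "small_molecule", "complex")
INTERACTION_TYPES = ("ppi", "transcriptional", "mirna_mrna", "enzymatic")

#: interaction types whose semantics admit no undirected representation
ALWAYS_DIRECTED_TYPES = frozenset({"transcriptional", "mirna_mrna"})

# node-class conflict resolution order (highest priority first)
_CLASS_PRECEDENCE = {"miRNA": 0, "protein": 1, "gene": 2, "complex": 3, "small_molecule": 4}

_MIRNA_PREFIXES = ("hsa-mir-", "hsa-let-")

_DIRECTED_TOKENS = {"directed": True, "undirected": False}


def normalize_id(raw: str) -> str:
    """Normalize a node identifier.

    Gene/protein symbols are upper-cased (HUGO convention); miRNA identifiers
    (``hsa-mir-…`` / ``hsa-let-…``) are lower-cased so that case variants of
    one molecule never split into two nodes.  Surrounding whitespace is
    stripped.
    """
    s = raw.strip()
    low = s.lower()
    if low.startswith(_MIRNA_PREFIXES):
        return low
    return s.upper()


def _infer_node_class(node_id: str) -> str:
    return "miRNA" if node_id.lower().startswith(_MIRNA_PREFIXES) else "protein"


@dataclass(frozen=True)
class NodeRecord:
    """A network node with its molecular class."""

    id: str
    node_class: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.node_class not in NODE_CLASSES:
            raise ValueError(
                f"unknown node_class {self.node_class!r} for node {self.id!r}; "
                f"expected one of {NODE_CLASSES}"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """A typed, optionally directed interaction between two nodes."""

    source: str
    target: str
    directed: bool
    interaction_type: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"unknown interaction_type {self.interaction_type!r}; "
                f"expected one of {INTERACTION_TYPES}"
            )
        if self.source == self.target:
            raise ValueError(f"self-loop edge on {self.source!r} is not allowed")
        if not self.directed and self.interaction_type in ALWAYS_DIRECTED_TYPES:
            raise ValueError(
                f"{self.interaction_type} interactions are always directed "
                f"({self.source}-{self.target})"
            )

    def key(self) -> tuple:
        """Identity used for deduplication (provenance-insensitive)."""
        if self.directed:
            return ("d", self.source, self.target, self.interaction_type)
        u, v = sorted((self.source, self.target))
        return ("u", u, v, self.interaction_type)

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, used by the direction-precedence rule."""
        u, v = sorted((self.source, self.target))
        return (u, v)


@dataclass
class MergeReport:
    """Bookkeeping emitted by :func:`merge_networks`."""

    edges_in: int = 0
    duplicates_removed: int = 0
    undirected_suppressed: int = 0
    edges_kept: int = 0
    n_nodes: int = 0
    class_conflicts: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"edges_in\t{self.edges_in}",
            f"duplicates_removed\t{self.duplicates_removed}",
            f"undirected_suppressed_by_precedence\t{self.undirected_suppressed}",
            f"edges_kept\t{self.edges_kept}",
            f"nodes\t{self.n_nodes}",
        ]
        for node_id, kept, dropped in self.class_conflicts:
            lines.append(f"node_class_conflict\t{node_id}\tkept={kept}\tdropped={dropped}")
        return "\n".join(lines) + "\n"


class InteractionNetwork:
    """The merged interaction graph with adjacency and degree queries.

    Parameters
    ----------
    nodes
        Mapping from node id to :class:`NodeRecord`.
    edges
        Deduplicated edge list satisfying the direction-precedence invariant.
    merge_report
        Optional :class:`MergeReport` describing how the network was built.
    """

    def __init__(
        self,
        nodes: Mapping[str, NodeRecord],
        edges: Sequence[EdgeRecord],
        merge_report: MergeReport | None = None,
    ) -> None:
        self.nodes: dict[str, NodeRecord] = dict(nodes)
        self.edges: list[EdgeRecord] = list(edges)
        self.merge_report = merge_report
        self._degree: dict[str, int] = {n: 0 for n in self.nodes}
        for e in self.edges:
            self._degree[e.source] += 1
            self._degree[e.target] += 1
        self._adj_cache: dict[frozenset | None, tuple[dict, dict]] = {}

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, node_id: str) -> bool:
        return node_id in self.nodes

    def node_ids(self) -> list[str]:
        """Node identifiers in deterministic (sorted) order."""
        return sorted(self.nodes)

    def degree(self, node_id: str) -> int:
        """Number of distinct edges incident to ``node_id`` (direction-agnostic)."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        return self._degree[node_id]

    # -- adjacency -------------------------------------------------------

    def adjacency(self, types: frozenset | None = None) -> tuple[dict, dict]:
        """Traversal adjacency restricted to an interaction-type subset.

        Returns ``(out_adj, in_adj)``: for each node, a tuple of
        ``(neighbor, EdgeRecord)`` pairs.  Undirected edges appear in both
        directions; directed edges only forward (backward in ``in_adj``).
        Results are cached per type subset.
        """
        key = None if types is None else frozenset(types)
        cached = self._adj_cache.get(key)
        if cached is not None:
            return cached
        out_adj: dict[str, list] = {n: [] for n in self.nodes}
        in_adj: dict[str, list] = {n: [] for n in self.nodes}
        for e in self.edges:
            if key is not None and e.interaction_type not in key:
                continue
            out_adj[e.source].append((e.target, e))
            in_adj[e.target].append((e.source, e))
            if not e.directed:
                out_adj[e.target].append((e.source, e))
                in_adj[e.source].append((e.target, e))
        result = (
            {n: tuple(v) for n, v in out_adj.items()},
            {n: tuple(v) for n, v in in_adj.items()},
        )
        self._adj_cache[key] = result
        return result

    # -- invariants (used by the test suite) -----------------------------

    def check_invariants(self) -> None:
        """Assert the no-duplicate, precedence and degree-consistency invariants."""
        keys = [e.key() for e in self.edges]
        if len(keys) != len(set(keys)):
            raise AssertionError("duplicate edges present after merge")
        directed_pairs = {e.pair() for e in self.edges if e.directed}
        for e in self.edges:
            if not e.directed and e.pair() in directed_pairs:
                raise AssertionError(
                    f"undirected edge {e.pair()} coexists with a directed edge"
                )
        total = sum(self._degree.values())
        if total != 2 * len(self.edges):
            raise AssertionError("degree index inconsistent with edge set")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "directed", "interaction_type", "provenance")


def load_id_mapping(path: str | Path) -> dict[str, str]:
    """Load an ``alias → canonical`` TSV mapping (applied before normalization)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"id-mapping file not found: {path}")
    mapping: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [c.strip().lower() for c in header[:2]] != ["alias", "canonical"]:
            raise ValueError(f"{path}: expected header 'alias\\tcanonical'")
        for line in fh:
            if not line.strip():
                continue
            alias, canonical = line.rstrip("\n").split("\t")[:2]
            mapping[alias.strip()] = canonical.strip()
    return mapping


def _map_and_normalize(raw: str, id_map: Mapping[str, str] | None) -> str:
    s = raw.strip()
    if id_map and s in id_map:
        s = id_map[s]
    return normalize_id(s)


def load_edge_table(
    path: str | Path,
    default_provenance: str = "",
    id_map: Mapping[str, str] | None = None,
) -> list[EdgeRecord]:
    """Load one typed edge table.

    Identifiers are normalized (see :func:`normalize_id`); rows whose source
    equals the target are skipped with a warning because self-loops can never
    lie on a simple path.  Exact duplicate rows are retained here (merging is
    responsible for deduplication) but flagged in the log.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On an unrecognized header, directedness token or interaction type,
        naming the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge table not found: {path}")
    records: list[EdgeRecord] = []
    seen: Counter = Counter()
    n_selfloops = 0
    with path.open() as fh:
        header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("\t")]
        if header[: len(_EDGE_COLUMNS) - 1] != list(_EDGE_COLUMNS[:4]):
            raise ValueError(
                f"{path}: header must name columns {_EDGE_COLUMNS[:4]} "
                f"(optionally followed by 'provenance'); got {header}"
            )
        has_provenance = len(header) >= 5 and header[4] == "provenance"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 columns, got {len(fields)}")
            src = _map_and_normalize(fields[0], id_map)
            tgt = _map_and_normalize(fields[1], id_map)
            token = fields[2].strip().lower()
            if token not in _DIRECTED_TOKENS:
                raise ValueError(
                    f"{path}:{lineno}: unrecognized directedness token {fields[2]!r} "
                    "(expected 'directed' or 'undirected')"
                )
            itype = fields[3].strip()
            if itype not in INTERACTION_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown interaction_type {itype!r}; "
                    f"expected one of {INTERACTION_TYPES}"
                )
            if src == tgt:
                n_selfloops += 1
                logger.warning("%s:%d: self-loop on %r skipped", path, lineno, src)
                continue
            prov = fields[4].strip() if has_provenance and len(fields) >= 5 else ""
            rec = EdgeRecord(src, tgt, _DIRECTED_TOKENS[token], itype, prov or default_provenance)
            seen[rec.key()] += 1
            records.append(rec)
    n_dups = sum(c - 1 for c in seen.values() if c > 1)
    if n_dups:
        logger.info("%s: %d duplicate rows (deduplication happens at merge)", path, n_dups)
    if n_selfloops:
        logger.warning("%s: %d self-loop rows skipped", path, n_selfloops)
    return records


def load_node_table(
    path: str | Path, id_map: Mapping[str, str] | None = None
) -> list[NodeRecord]:
    """Load an optional ``id \\t node_class`` table declaring classes/isolated nodes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"node table not found: {path}")
    records: list[NodeRecord] = []
    with path.open() as fh:
        header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("\t")]
        if header[:2] != ["id", "node_class"]:
            raise ValueError(f"{path}: expected header 'id\\tnode_class'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            node_id = _map_and_normalize(fields[0], id_map)
            node_class = fields[1].strip()
            if node_class not in NODE_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown node_class {node_class!r}; "
                    f"expected one of {NODE_CLASSES}"
                )
            records.append(NodeRecord(node_id, node_class))
    return records


def load_hit_list(path: str | Path, id_map: Mapping[str, str] | None = None) -> list[str]:
    """Load a one-identifier-per-line list (hits or final implementers)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"list file not found: {path}")
    ids: list[str] = []
    with path.open() as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                ids.append(_map_and_normalize(s, id_map))
    return ids


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def merge_networks(
    edge_lists: Iterable[Sequence[EdgeRecord]],
    node_records: Iterable[NodeRecord] = (),
) -> InteractionNetwork:
    """Merge validated edge lists into one integrated network.

    Applies duplicate removal and the pair-level direction-precedence rule
    (undirected edges between a pair are dropped whenever any directed edge
    exists between that pair, regardless of interaction type).  Node classes
    come from ``node_records`` where given, otherwise are inferred from the
    identifier; conflicting declarations are resolved by the precedence
    miRNA > protein > gene > complex > small_molecule with a warning.

    Raises
    ------
    ValueError
        If the combined edge input is empty.
    """
    all_edges: list[EdgeRecord] = []
    for lst in edge_lists:
        all_edges.extend(lst)
    if not all_edges:
        raise ValueError("merge_networks: no edges supplied")

    report = MergeReport(edges_in=len(all_edges))

    deduped: list[EdgeRecord] = []
    seen: set = set()
    for e in all_edges:
        k = e.key()
        if k in seen:
            report.duplicates_removed += 1
            continue
        seen.add(k)
        deduped.append(e)

    directed_pairs = {e.pair() for e in deduped if e.directed}
    kept: list[EdgeRecord] = []
    for e in deduped:
        if not e.directed and e.pair() in directed_pairs:
            report.undirected_suppressed += 1
            logger.info(
                "undirected %s edge %s-%s suppressed by a directed edge between the pair",
                e.interaction_type, e.source, e.target,
            )
            continue
        kept.append(e)
    report.edges_kept = len(kept)

    # node classes: explicit declarations win over inference; conflicts by precedence
    classes: dict[str, str] = {}
    for rec in node_records:
        prev = classes.get(rec.id)
        if prev is None:
            classes[rec.id] = rec.node_class
        elif prev != rec.node_class:
            winner = min(prev, rec.node_class, key=_CLASS_PRECEDENCE.__getitem__)
            loser = rec.node_class if winner == prev else prev
            logger.warning(
                "node %r declared both %r and %r; keeping %r", rec.id, prev, rec.node_class, winner
            )
            report.class_conflicts.append((rec.id, winner, loser))
            classes[rec.id] = winner
    nodes: dict[str, NodeRecord] = {}
    for node_id in sorted(
        {e.source for e in kept} | {e.target for e in kept} | set(classes)
    ):
        nodes[node_id] = NodeRecord(node_id, classes.get(node_id, _infer_node_class(node_id)))

    report.n_nodes = len(nodes)
    logger.info(
        "merged network: %d nodes, %d edges (%d in, %d duplicates, %d undirected suppressed)",
        report.n_nodes, report.edges_kept, report.edges_in,
        report.duplicates_removed, report.undirected_suppressed,
    )
    return InteractionNetwork(nodes, kept, merge_report=report)


def write_edge_table(network: InteractionNetwork, path: str | Path) -> None:
    """Write the network back out in the edge-table TSV dialect."""
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tdirected\tinteraction_type\tprovenance\n")
        for e in network.edges:
            token = "directed" if e.directed else "undirected"
            fh.write(f"{e.source}\t{e.target}\t{token}\t{e.interaction_type}\t{e.provenance}\n")


def write_node_table(network: InteractionNetwork, path: str | Path) -> None:
    """Write the node-class table (includes isolated nodes)."""
    with Path(path).open("w") as fh:
        fh.write("id\tnode_class\n")
        for node_id in network.node_ids():
            fh.write(f"{node_id}\t{network.nodes[node_id].node_class}\n")
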