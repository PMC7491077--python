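"""Permutation null model and empirical significance for centrality scores.

Random hit lists of the same size as the observed one are sampled from the
network nodes, either uniformly or preserving the observed hit list's degree
multiset (each hit replaced by a node of approximately equal degree).  For
every sampled list the whole shortest-path collection and centrality scoring
is re-run with identical parameters — including the subpath collapse rule —
and the empirical p-value of an entity is the proportion of replicates whose
centrality for that entity is at least the observed one.  Node and subpath
p-values are then Benjamini-Hochberg adjusted as two separate families.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .centrality import SubpathKey, _node_counts, _subpath_scores
from .config import RunConfig
from .interactome import InteractionNetwork
from .pathfinding import PairSearcher, _collect_fast, collect_shortest_path_set

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# random hit lists
# ---------------------------------------------------------------------------


class DegreeBins:
    """Degree-matched candidate pools for hit-list randomization.

    A hit of degree ``d`` is replaced by a node drawn uniformly from the bin
    of nodes with degree ``d``.  A bin holding fewer than ``min_bin``
    candidates is widened symmetrically in ~10%-of-``d`` increments (at least
    ±1 per step, so small degrees can widen at all) up to five steps (~±50%);
    a bin that is still empty at the cap is a fatal error.
    """

    def __init__(self, network: InteractionNetwork, min_bin: int = 5, max_steps: int = 5):
        pairs = sorted((network.degree(n), n) for n in network.nodes)
        self._degrees = [d for d, _ in pairs]
        self._nodes = [n for _, n in pairs]
        self.min_bin = min_bin
        self.max_steps = max_steps
        self._cache: dict[int, tuple[str, ...]] = {}

    def _range(self, lo: int, hi: int) -> list[str]:
        i = bisect_left(self._degrees, lo)
        j = bisect_right(self._degrees, hi)
        return self._nodes[i:j]

    def candidates(self, degree: int) -> tuple[str, ...]:
        cached = self._cache.get(degree)
        if cached is not None:
            return cached
        cand = self._range(degree, degree)
        step = 0
        while len(cand) < self.min_bin and step < self.max_steps:
            step += 1
            delta = max(step, round(0.1 * step * degree))
            cand = self._range(degree - delta, degree + delta)
        if not cand:
            raise RuntimeError(
                f"degree bin exhausted: no candidate node near degree {degree}"
            )
        result = tuple(cand)
        self._cache[degree] = result
        return result


def sample_random_hitlist(
    network: InteractionNetwork,
    hits: Sequence[str],
    degree_preserving: bool = True,
    rng: np.random.Generator | None = None,
    bins: DegreeBins | None = None,
) -> list[str]:
    """Draw one random hit list of size ``|H|`` (distinct network nodes).

    In degree-preserving mode each hit is replaced by a uniform draw from its
    degree bin (the original hit may be re-drawn); in uniform mode the list is
    a uniform sample without replacement from all nodes.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(hits)
    if n > network.n_nodes:
        raise ValueError("hit list larger than the network")
    if not degree_preserving:
        ids = network.node_ids()
        idx = rng.choice(len(ids), size=n, replace=False)
        return [ids[i] for i in idx]
    if bins is None:
        bins = DegreeBins(network)
    chosen: list[str] = []
    taken: set[str] = set()
    for h in hits:
        cand = bins.candidates(network.degree(h))
        free = [c for c in cand if c not in taken]
        if not free:
            raise RuntimeError(
                f"degree bin exhausted for degree {network.degree(h)} "
                f"after excluding already-drawn nodes"
            )
        pick = free[int(rng.integers(len(free)))]
        chosen.append(pick)
        taken.add(pick)
    return chosen


# ---------------------------------------------------------------------------
# empirical p-values and BH adjustment
# ---------------------------------------------------------------------------


def empirical_pvalue(observed: int, null_scores: Sequence[int]) -> float:
    """Proportion of null replicate scores greater than or equal to ``observed``."""
    if len(null_scores) == 0:
        raise ValueError("empirical_pvalue: empty null score vector")
    arr = np.asarray(null_scores)
    return float(np.count_nonzero(arr >= observed)) / len(arr)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Standard step-up procedure: sort ascending, multiply by m/rank, enforce
    monotonicity from the largest rank down, clip at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = ranked
    # guard against 1-ulp rounding in p*m/rank: dominance holds exactly
    return np.maximum(out, p)


# ---------------------------------------------------------------------------
# the permutation engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignificanceRecord:
    entity: object  # node id or SubpathKey
    kind: str  # "node" | "path"
    centrality: int
    exceedance: int
    p_value: float
    p_adjusted: float
    passes_filters: bool


@dataclass
class SignificanceTable:
    """Per-entity empirical significance of node and subpath centralities."""

    nodes: list[SignificanceRecord]
    subpaths: list[SignificanceRecord]
    n_replicates: int
    n_failed: int

    def record(self, entity) -> SignificanceRecord:
        pool = self.nodes if isinstance(entity, str) else self.subpaths
        for r in pool:
            if r.entity == entity:
                return r
        raise KeyError(entity)


def run_null_model(
    network: InteractionNetwork,
    hits: Sequence[str],
    implementers: Sequence[str],
    config: RunConfig,
    searcher: PairSearcher | None = None,
    extra_tracked_nodes: Iterable[str] = (),
) -> SignificanceTable:
    """Full permutation analysis for one observed hit list.

    Re-runs path collection and centrality scoring for ``config.n_replicates``
    random hit lists (the implementer list is held fixed) and returns, per
    observed entity, the empirical p-value, its BH adjustment and the
    reporting-filter verdict ``centrality >= min_centrality AND adjusted
    p <= fdr_threshold``.  ``extra_tracked_nodes`` adds nodes to track even if
    absent from the observed subnetwork (their observed centrality is 0);
    calibration studies use this to avoid conditioning on being observed.

    Replicate RNG streams derive from ``(config.seed, replicate_index)``, so
    results do not depend on execution order.  A replicate that raises is
    counted as failed; more than 1% failures aborts the run.
    """
    cfg = config
    observed = collect_shortest_path_set(network, hits, implementers, cfg.l_max, searcher=searcher)
    if searcher is None:
        searcher = PairSearcher(network, observed.implementers, cfg.l_max)

    node_obs = _node_counts(observed.paths, cfg.count_endpoints)
    for v in extra_tracked_nodes:
        node_obs.setdefault(v, 0)
    sub_obs = _subpath_scores(observed.paths, cfg.len_min, cfg.len_max)
    tracked_keys = set(sub_obs)

    bins = DegreeBins(network) if cfg.degree_preserving else None
    n_hits = len(observed.hits)
    node_list = network.node_ids()

    r_node = dict.fromkeys(node_obs, 0)
    r_sub = dict.fromkeys(sub_obs, 0)
    n_failed = 0
    for i in range(cfg.n_replicates):
        rng = np.random.default_rng([cfg.seed, i])
        try:
            if cfg.degree_preserving:
                h_i = sample_random_hitlist(network, observed.hits, True, rng, bins)
            else:
                idx = rng.choice(len(node_list), size=n_hits, replace=False)
                h_i = [node_list[j] for j in idx]
            paths_i = _collect_fast(searcher, h_i, observed.implementers)
        except Exception as exc:  # replicate failure, not fatal unless frequent
            n_failed += 1
            logger.warning("replicate %d failed: %s", i, exc)
            continue
        nc = _node_counts(paths_i, cfg.count_endpoints)
        for v, obs in node_obs.items():
            if nc.get(v, 0) >= obs:
                r_node[v] += 1
        sc = _subpath_scores(paths_i, cfg.len_min, cfg.len_max, tracked=tracked_keys)
        for q, obs in sub_obs.items():
            if sc.get(q, 0) >= obs:
                r_sub[q] += 1

    n_ok = cfg.n_replicates - n_failed
    if n_failed > 0.01 * cfg.n_replicates:
        raise RuntimeError(
            f"{n_failed}/{cfg.n_replicates} permutation replicates failed (> 1%)"
        )

    def _pvals(r: dict) -> dict:
        if cfg.pseudocount:
            return {k: (v + 1) / (n_ok + 1) for k, v in r.items()}
        return {k: v / n_ok for k, v in r.items()}

    p_node = _pvals(r_node)
    p_sub = _pvals(r_sub)

    node_keys = sorted(p_node)
    sub_keys = sorted(p_sub)
    if cfg.pool_bh:
        pooled = [p_node[k] for k in node_keys] + [p_sub[k] for k in sub_keys]
        adj = bh_adjust(pooled)
        adj_node = dict(zip(node_keys, adj[: len(node_keys)]))
        adj_sub = dict(zip(sub_keys, adj[len(node_keys):]))
    else:
        adj_node = dict(zip(node_keys, bh_adjust([p_node[k] for k in node_keys])))
        adj_sub = dict(zip(sub_keys, bh_adjust([p_sub[k] for k in sub_keys])))

    def _records(keys, obs, r, p, adj, kind):
        out = []
        for k in keys:
            c = obs[k]
            passes = (c >= cfg.min_centrality) and (adj[k] <= cfg.fdr_threshold)
            out.append(
                SignificanceRecord(k, kind, c, r[k], p[k], float(adj[k]), passes)
            )
        out.sort(key=lambda rec: (-rec.centrality, _label(rec.entity)))
        return out

    return SignificanceTable(
        nodes=_records(node_keys, node_obs, r_node, p_node, adj_node, "node"),
        subpaths=_records(sub_keys, sub_obs, r_sub, p_sub, adj_sub, "path"),
        n_replicates=n_ok,
        n_failed=n_failed,
    )


def _label(entity) -> str:
    return entity if isinstance(entity, str) else ";".join(entity.nodes)


def write_significance_table(
    records: Sequence[SignificanceRecord], path: str | Path
) -> None:
    """TSV export: ``entity kind centrality p_value p_adjusted passes_filters``."""
    with Path(path).open("w") as fh:
        fh.write("entity\tkind\tcentrality\tp_value\tp_adjusted\tpasses_filters\n")
        for r in records:
            fh.write(
                f"{_label(r.entity)}\t{r.kind}\t{r.centrality}\t"
                f"{r.p_value!r}\t{r.p_adjusted!r}\t{r.passes_filters}\n"
            )
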