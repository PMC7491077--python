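"""End-to-end orchestration: load, merge, search, score, permute, export.

A run consumes one or more edge tables, a hit list and (optionally) a
final-implementer list, and writes a reproducible artifact bundle::

    merge_report.txt                how the integrated network was assembled
    paths.tsv                       every collected shortest typed path
    subnetwork.sif                  Cytoscape-readable induced subnetwork
    subnetwork_node_attributes.tsv  node roles and centralities for styling
    node_significance.tsv           per-node permutation significance
    path_significance.tsv           per-subpath permutation significance
    manifest.json                   full configuration + inputs; re-runnable

If the implementer list is absent the hit list doubles as the implementer
list.  Rerunning from the manifest reproduces every table byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .centrality import score_nodes
from .config import RunConfig
from .interactome import (
    InteractionNetwork,
    load_edge_table,
    load_hit_list,
    load_id_mapping,
    load_node_table,
    merge_networks,
)
from .pathfinding import collect_shortest_path_set, extract_subnetwork, write_path_table
from .significance import run_null_model, write_significance_table

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "merge_report.txt",
    "paths.tsv",
    "subnetwork.sif",
    "subnetwork_node_attributes.tsv",
    "node_significance.tsv",
    "path_significance.tsv",
    "manifest.json",
)


def run(
    config: RunConfig,
    network_files: list[str],
    hits_file: str,
    implementers_file: str | None,
    out_dir: str | Path,
    node_table: str | None = None,
    id_mapping: str | None = None,
) -> Path:
    """Execute the full analysis; returns the output directory.

    On any fatal module error the partial outputs written so far are removed
    and the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        id_map = load_id_mapping(id_mapping) if id_mapping else None
        edge_lists = [
            load_edge_table(p, default_provenance=Path(p).stem, id_map=id_map)
            for p in network_files
        ]
        nodes = load_node_table(node_table, id_map=id_map) if node_table else ()
        network = merge_networks(edge_lists, nodes)

        path = out / "merge_report.txt"
        path.write_text(network.merge_report.to_text())
        written.append(path)

        hits = load_hit_list(hits_file, id_map=id_map)
        if implementers_file:
            implementers = load_hit_list(implementers_file, id_map=id_map)
        else:
            logger.info("no implementer list given; reusing the hit list as implementers")
            implementers = list(hits)

        path_set = collect_shortest_path_set(network, hits, implementers, config.l_max)
        skipped = sorted(set(hits) - set(path_set.hits))
        if skipped:
            logger.warning("hit ids not found in the network: %s", skipped)

        path = out / "paths.tsv"
        write_path_table(path_set, path)
        written.append(path)

        sub = extract_subnetwork(path_set, network) if path_set.paths else None
        node_table_obj = score_nodes(path_set, config.count_endpoints)
        centr = {v: node_table_obj.get(v) for v in (sub.nodes if sub else {})}
        written.extend(
            export_cytoscape(sub, path_set.hits, path_set.implementers, centr, out)
        )

        sig = run_null_model(network, list(path_set.hits), list(path_set.implementers), config)
        path = out / "node_significance.tsv"
        write_significance_table(sig.nodes, path)
        written.append(path)
        path = out / "path_significance.tsv"
        write_significance_table(sig.subpaths, path)
        written.append(path)

        manifest = {
            "tool": "masterpath",
            "version": __version__,
            "config": config.to_dict(),
            "network_files": [str(Path(p)) for p in network_files],
            "hits_file": str(Path(hits_file)),
            "implementers_file": str(Path(implementers_file)) if implementers_file else None,
            "node_table": str(Path(node_table)) if node_table else None,
            "id_mapping": str(Path(id_mapping)) if id_mapping else None,
            "skipped_hits": skipped,
            "n_paths": len(path_set),
            "n_failed_replicates": sig.n_failed,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return out


def run_from_manifest(manifest_file: str | Path, out_dir: str | Path) -> Path:
    """Reproduce a run from its manifest alone (byte-identical tables)."""
    with Path(manifest_file).open() as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    return run(
        config,
        manifest["network_files"],
        manifest["hits_file"],
        manifest.get("implementers_file"),
        out_dir,
        node_table=manifest.get("node_table"),
        id_mapping=manifest.get("id_mapping"),
    )


def export_cytoscape(
    subnetwork: InteractionNetwork | None,
    hits,
    implementers,
    node_centrality: dict,
    out_dir: str | Path,
    prefix: str = "subnetwork",
) -> list[Path]:
    """Write a SIF edge file and a node-attribute TSV for Cytoscape.

    The SIF relation is the interaction type suffixed ``_d`` (directed) or
    ``_u`` (undirected); node roles are hit / implementer / both /
    intermediate.  An empty subnetwork produces header-only files with a
    warning.
    """
    out = Path(out_dir)
    sif = out / f"{prefix}.sif"
    attrs = out / f"{prefix}_node_attributes.tsv"
    hit_set, impl_set = set(hits), set(implementers)
    with sif.open("w") as fh:
        if subnetwork is not None:
            for e in subnetwork.edges:
                rel = f"{e.interaction_type}_{'d' if e.directed else 'u'}"
                fh.write(f"{e.source}\t{rel}\t{e.target}\n")
    with attrs.open("w") as fh:
        fh.write("id\trole\tnode_class\tcentrality\n")
        if subnetwork is not None:
            for node_id in subnetwork.node_ids():
                if node_id in hit_set and node_id in impl_set:
                    role = "both"
                elif node_id in hit_set:
                    role = "hit"
                elif node_id in impl_set:
                    role = "implementer"
                else:
                    role = "intermediate"
                cls = subnetwork.nodes[node_id].node_class
                fh.write(f"{node_id}\t{role}\t{cls}\t{node_centrality.get(node_id, 0)}\n")
    if subnetwork is None:
        logger.warning("empty subnetwork: wrote empty Cytoscape files")
    return [sif, attrs]
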