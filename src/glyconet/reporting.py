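"""Module composition, hubs, inter-module interactions, first-neighbor
subnetworks, graph exports and run reports.

Percentages are reported to one decimal; the integer display style rounds
that one-decimal value half-away-from-zero (a 138-gene module with 50
members in its top-3 categories prints 36.2% -> "36%").
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .communities import ModulePartition
from .io import GeneAnnotation
from .netinfer import CoexpressionNetwork

DEFAULT_TOP_HUBS = 23


def percent(count: float, total: float) -> float:
    """Share as a percentage rounded to one decimal (0.0 for empty totals)."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 1)


def display_percent(value_1dp: float) -> str:
    """Integer display of a one-decimal percentage, half away from zero."""
    v = abs(value_1dp)
    i = int(np.floor(v + 0.5))
    return f"{'-' if value_1dp < 0 else ''}{i}%"


def cog_composition(
    module: Sequence[str],
    annotations: Iterable[GeneAnnotation],
    top_k: int = 3,
) -> tuple[dict[str, int], float]:
    """COG category counts of a module and its top-k major-category share.

    Genes without a COG assignment count toward the module size but not the
    category counts; ``major_cog_fraction`` is 100 * (sum of the top_k
    category counts) / module size, to one decimal.
    """
    size = len(module)
    members = set(module)
    counts: Counter[str] = Counter()
    for ann in annotations:
        if ann.gene_id in members and ann.cog is not None:
            counts[ann.cog] += 1
    top = counts.most_common(top_k)
    major = sum(n for _, n in top)
    return dict(counts), percent(major, size)


def cog_percentages(cog_counts: Mapping[str, int], size: int) -> dict[str, float]:
    return {c: percent(n, size) for c, n in sorted(cog_counts.items())}


def hub_ranking(net: CoexpressionNetwork, n_top: int = DEFAULT_TOP_HUBS) -> list[tuple[str, int]]:
    """Genes ranked by number of links, descending; ties by gene id."""
    if net.n_nodes == 0:
        raise ValueError("cannot rank hubs of an empty network")
    ranked = sorted(net.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return [(g, int(d)) for g, d in ranked[:n_top]]


def inter_module_links(net: CoexpressionNetwork, p: ModulePartition) -> pd.DataFrame:
    """Symmetric module x module matrix of cross-module edge counts.

    Only edges between two reported modules are counted (edges touching
    unassigned genes are ignored).  A module interacting with no other
    module is 'standalone'.
    """
    module_of = p.module_of()
    ids = [mid for mid, _ in p.modules]
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for u, v in net.graph.edges:
        mu, mv = module_of.get(u), module_of.get(v)
        if mu is None or mv is None or mu == mv:
            continue
        mat.loc[mu, mv] += 1
        mat.loc[mv, mu] += 1
    return mat


def module_interaction_degrees(links: pd.DataFrame) -> pd.Series:
    """Number of distinct partner modules with >= 1 link, per module."""
    return (links > 0).sum(axis=1).rename("interaction_degree")


def standalone_modules(links: pd.DataFrame) -> list[int]:
    deg = module_interaction_degrees(links)
    return deg.index[deg == 0].tolist()


def first_neighbors(net: CoexpressionNetwork, seeds: Sequence[str]) -> CoexpressionNetwork:
    """Induced subgraph on the seeds and their direct neighbors."""
    known = [s for s in seeds if s in net.graph]
    unknown = [s for s in seeds if s not in net.graph]
    if unknown:
        warnings.warn(f"seeds not in network, skipped: {unknown}", stacklevel=2)
    if not known:
        raise ValueError("none of the seed genes are in the network")
    keep = set(known)
    for s in known:
        keep.update(net.graph.neighbors(s))
    sub = net.graph.subgraph(keep).copy()
    return CoexpressionNetwork(graph=sub, tau=net.tau, mode=net.mode)


# ---------------------------------------------------------------------------
# exports


def write_edge_list(net: CoexpressionNetwork, path: str | Path) -> None:
    net.edges_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_node_attributes(
    net: CoexpressionNetwork,
    p: ModulePartition | None,
    annotations: Iterable[GeneAnnotation] | None,
    path: str | Path,
) -> None:
    module_of = p.module_of() if p is not None else {}
    cog_of = {a.gene_id: a.cog for a in annotations} if annotations is not None else {}
    rows = [
        {
            "gene_id": g,
            "module_id": module_of.get(g, "NA"),
            "degree": d,
            "cog": cog_of.get(g) or "NA",
        }
        for g, d in sorted(net.graph.degree)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sif(net: CoexpressionNetwork, path: str | Path) -> None:
    """Simple interaction format: gene_a <sign> gene_b, one edge per line."""
    lines = []
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((u, v))
        rel = "pos" if d.get("sign", "+") == "+" else "neg"
        lines.append(f"{a}\t{rel}\t{b}")
    Path(path).write_text("\n".join(sorted(lines)) + "\n", encoding="utf-8")


def write_gml(net: CoexpressionNetwork, path: str | Path) -> None:
    nx.write_gml(net.graph, str(path))


# ---------------------------------------------------------------------------
# run report


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_report(
    *,
    n_genes_on_array: int | None = None,
    net: CoexpressionNetwork | None = None,
    partition: ModulePartition | None = None,
    scan=None,
    hub_table: list[tuple[str, int]] | None = None,
    inter_links: pd.DataFrame | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
    timestamp: str | None = None,
) -> dict:
    """Assemble a machine-readable summary of a full pipeline run.

    Missing stages yield explicit nulls.  Two runs with the same seed and
    configuration produce identical reports apart from ``timestamp``.
    """
    from . import __version__

    report: dict = {
        "tool": "glyconet",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "timestamp": timestamp,
        "genes_on_array": n_genes_on_array,
        "selected_tau": None if scan is None else scan.selected_tau,
        "tau_warning": None if scan is None else bool(scan.warning),
        "genes_in_network": None,
        "percent_of_genome_in_network": None,
        "n_edges": None,
        "n_modules": None,
        "module_sizes": None,
        "modularity_q": None,
        "standalone_modules": None,
        "hub_table": None,
        "warnings": [],
    }
    if net is not None:
        report["genes_in_network"] = net.n_nodes
        report["n_edges"] = net.n_edges
        if n_genes_on_array:
            report["percent_of_genome_in_network"] = percent(net.n_nodes, n_genes_on_array)
        if net.n_nodes == 0:
            report["warnings"].append("network is empty")
    if partition is not None:
        report["n_modules"] = partition.n_modules
        report["module_sizes"] = partition.module_sizes()
        report["modularity_q"] = round(partition.modularity_q, 6)
        if partition.n_modules == 0:
            report["warnings"].append("no module passed the size filter")
    if inter_links is not None:
        report["standalone_modules"] = standalone_modules(inter_links)
    if hub_table is not None:
        report["hub_table"] = [[g, d] for g, d in hub_table]
    return report


def write_report(report: Mapping, json_path: str | Path, text_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, default=str) + "\n", encoding="utf-8")
    if text_path is not None:
        Path(text_path).write_text(format_report(report), encoding="utf-8")


def format_report(report: Mapping) -> str:
    lines = [
        f"glyconet {report.get('version')} run summary",
        f"seed: {report.get('seed')}  config: {report.get('config_hash')}",
        f"genes on array: {report.get('genes_on_array')}",
        f"selected cutoff tau: {report.get('selected_tau')}",
        f"genes in network: {report.get('genes_in_network')}"
        + (
            f" ({report['percent_of_genome_in_network']}% of genome)"
            if report.get("percent_of_genome_in_network") is not None
            else ""
        ),
        f"edges: {report.get('n_edges')}",
        f"modules (>=5 genes): {report.get('n_modules')}  Q = {report.get('modularity_q')}",
        f"module sizes: {report.get('module_sizes')}",
        f"standalone modules: {report.get('standalone_modules')}",
    ]
    if report.get("hub_table"):
        lines.append("top hubs (gene, links):")
        for g, d in report["hub_table"][:10]:
            lines.append(f"  {g}\t{d}")
    for w in report.get("warnings", []):
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
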