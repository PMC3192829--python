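"""End-to-end pipeline: simulate (or load) -> correlate -> select cutoff ->
build network -> detect modules -> report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import communities, netinfer, reporting, synthetic
from .io import ExpressionMatrix
from .synthetic import SyntheticSpec, SyntheticTruth


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    truth: SyntheticTruth | None
    corr: netinfer.CorrelationMatrix
    scan: netinfer.ThresholdScan | None
    network: netinfer.CoexpressionNetwork
    partition: communities.ModulePartition
    inter_links: object
    hub_table: list[tuple[str, int]]
    report: dict


def run_synthetic_pipeline(
    spec: SyntheticSpec,
    tau: float | None = None,
    tau_grid: np.ndarray | None = None,
    scan_mode: str = "abs",
    network_mode: str = "positive",
    min_module_size: int = communities.DEFAULT_MIN_MODULE_SIZE,
    n_top_hubs: int = reporting.DEFAULT_TOP_HUBS,
    timestamp: str | None = None,
) -> PipelineResult:
    """Run the full reconstruction on one simulated dataset.

    When ``tau`` is None the cutoff is selected by the RMT scan (absolute
    mode); the reported network is then built in positive mode at that
    cutoff, mirroring the convention that reported links are positive
    co-expression at the selected threshold.
    """
    x, truth = synthetic.simulate(spec)
    corr = netinfer.pearson_matrix(x)
    scan = None
    if tau is None:
        scan = netinfer.rmt_threshold_scan(corr, tau_grid=tau_grid, mode=scan_mode)
        tau = scan.selected_tau
    net = netinfer.build_network(corr, tau, mode=network_mode)
    partition = communities.fast_greedy_modules(net, min_module_size=min_module_size)
    links = reporting.inter_module_links(net, partition)
    hubs = reporting.hub_ranking(net, n_top=n_top_hubs)
    config = {
        "n_genes": spec.n_genes,
        "modules": [
            (m.module_id, m.size, sorted(m.responsive_conditions), m.mean_shift,
             m.within_module_correlation, m.n_hubs)
            for m in spec.modules
        ],
        "noise_sd": spec.noise_sd,
        "snr_dropout_rate": spec.snr_dropout_rate,
        "tau": tau,
        "scan_mode": scan_mode,
        "network_mode": network_mode,
        "min_module_size": min_module_size,
    }
    report = reporting.run_report(
        n_genes_on_array=spec.n_genes,
        net=net,
        partition=partition,
        scan=scan,
        hub_table=hubs,
        inter_links=links,
        seed=spec.seed,
        config=config,
        timestamp=timestamp,
    )
    return PipelineResult(
        matrix=x,
        truth=truth,
        corr=corr,
        scan=scan,
        network=net,
        partition=partition,
        inter_links=links,
        hub_table=hubs,
        report=report,
    )


def export_run(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard artifact set of a run into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "nodes": out / "nodes.tsv",
        "sif": out / "network.sif",
        "gml": out / "network.gml",
        "report_json": out / "report.json",
        "report_txt": out / "report.txt",
    }
    reporting.write_edge_list(result.network, paths["edges"])
    reporting.write_node_attributes(result.network, result.partition, None, paths["nodes"])
    reporting.write_sif(result.network, paths["sif"])
    reporting.write_gml(result.network, paths["gml"])
    reporting.write_report(result.report, paths["report_json"], paths["report_txt"])
    return paths
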