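"""End-to-end orchestration of the network-reconstruction workflow.

Stages run in order — promoter-affinity scoring, TF enrichment calling,
expression preparation, mutual-information inference, coherence analysis,
network intersection and topology — communicating via files in the output
directory so a run is restartable and diffable.  A manifest records every
configuration value, derived seed, output digest and stage timing; an
identical config and seed reproduce the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .enrichment import (
    CutoffScanResult,
    cutoff_scan,
    default_cutoffs,
    enrichment_table,
    select_photosynthesis_tfs,
)
from .expression import filter_experiments, quantile_normalize
from .gsea import CoherenceResult, coherence_table, gsea_nominal_p, merge_target_sets_by_ortholog
from .io import (
    read_expression_tsv,
    read_gene_annotation,
    read_ortholog_map,
    read_promoter_fasta,
    read_transfac_pwm,
    write_expression_tsv,
    write_network,
)
from .mi import MIEdge, dpi_prune, fit_null, infer_edges
from .topology import RegulatoryNetwork, TopologyReport, build_final_network, topology_report
from .trap import affinity_matrix

__all__ = ["PipelineResult", "RunManifest", "run_all", "run_from_bundle"]


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    digests: dict
    timings: dict

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "version": self.version, "seeds": self.seeds,
             "digests": self.digests, "timings": self.timings},
            indent=2, sort_keys=True,
        )


@dataclass
class PipelineResult:
    network: RegulatoryNetwork
    topology: TopologyReport | None
    coherence: list[CoherenceResult]
    manifest: RunManifest
    selected_tfs: list[str]
    scans: list[CutoffScanResult]
    mi_edges: list[MIEdge]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the full workflow from the input files named in ``config``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
        return _T()

    with stage("read_inputs"):
        promoters = read_promoter_fasta(config.promoters)
        pwms = read_transfac_pwm(config.pwms)
        annotation = read_gene_annotation(config.annotation)
        orthologs = read_ortholog_map(config.orthologs)
        expr = read_expression_tsv(config.expression, config.experiments)

    with stage("trap"):
        aff = affinity_matrix(pwms, promoters, lam=config.lam,
                              pseudocount=config.pseudocount)
        aff.to_frame().to_csv(out / "affinity.tsv", sep="\t", float_format="%.10g")

    with stage("enrich"):
        background = [p.gene_id for p in promoters]
        cutoffs = default_cutoffs(config.cutoff_min, config.cutoff_max, config.cutoff_step)
        scans = [
            cutoff_scan(aff.row(pwm.tf_id), annotation.photoset, background,
                        cutoffs, tf_id=pwm.tf_id)
            for pwm in pwms
        ]
        table = enrichment_table(scans)
        selected = select_photosynthesis_tfs(scans, alpha=config.alpha)
        table["selected"] = table["tf_id"].isin(selected)
        table.to_csv(out / "tf_calls.tsv", sep="\t", index=False)

    with stage("prep"):
        tf_genes = sorted({orthologs[tf] for tf in (selected or [p.tf_id for p in pwms])})
        filtered, report = filter_experiments(
            expr, tf_genes, cv_threshold=config.cv_threshold,
            fraction=config.cv_fraction, log2=config.cv_log2,
        )
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        if not filtered.sample_ids:
            raise RuntimeError("no experiment passed the expression-diversity filter")
        norm = quantile_normalize(filtered)
        write_expression_tsv(norm, out / "expr_norm.tsv", out / "experiments_kept.tsv")

    seeds = {"pipeline": config.seed, "null": config.seed,
             "gsea_base": config.seed + 1}
    coherence: list[CoherenceResult] = []
    mi_edges: list[MIEdge] = []
    network = RegulatoryNetwork(edges=[], component_of_gene=dict(annotation.component_of_gene))
    topo: TopologyReport | None = None

    if selected:
        with stage("aracne"):
            null = fit_null(norm, n_permutations=config.n_permutations,
                            seed=seeds["null"], bandwidth_scale=config.bandwidth_scale)
            sel_tf_genes = sorted({orthologs[tf] for tf in selected})
            edges, rankings = infer_edges(
                norm, sel_tf_genes, null, p_threshold=config.p_threshold,
                bandwidth_scale=config.bandwidth_scale,
            )
            if config.dpi:
                edges = dpi_prune(edges, tolerance=config.dpi_tolerance)
            mi_edges = edges
            pd.DataFrame(
                [{"tf_id": e.tf_id, "gene_id": e.gene_id, "mi": e.mi, "p": e.p}
                 for e in edges]
            ).to_csv(out / "mi_edges.tsv", sep="\t", index=False)
            rank_rows = []
            for tf, rt in sorted(rankings.items()):
                for rank, (g, m) in enumerate(zip(rt.targets, rt.mi_values), 1):
                    rank_rows.append({"tf_id": tf, "rank": rank, "gene_id": g, "mi": m})
            pd.DataFrame(rank_rows).to_csv(out / "rankings.tsv", sep="\t", index=False)

        with stage("gsea"):
            target_sets = {
                s.tf_id: s.target_set_at_best for s in scans if s.tf_id in set(selected)
            }
            merged = merge_target_sets_by_ortholog(target_sets, orthologs)
            for i, (gene, (labels, union)) in enumerate(sorted(merged.items())):
                if gene not in rankings:
                    continue
                present = union & set(rankings[gene].targets)
                if not present:
                    continue
                coherence.append(
                    gsea_nominal_p(
                        rankings[gene], union, weight_p=config.gsea_weight,
                        n_permutations=config.gsea_permutations,
                        seed=seeds["gsea_base"] + i, labels=labels,
                    )
                )
            if coherence:
                coherence_table(coherence).to_csv(out / "coherence.tsv", sep="\t", index=False)

        with stage("network"):
            sel_scans = [s for s in scans if s.tf_id in set(selected)]
            network = build_final_network(sel_scans, mi_edges, annotation,
                                          orthologs, affinity=aff)
            write_network(network, out / "network.tsv", "tsv")
            write_network(network, out / "network.sif", "sif")
            from .topology import collapse_to_components
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                collapse_to_components(network).to_csv(
                    out / "components.tsv", sep="\t", index=False
                )
            if network.edges:
                topo = topology_report(network)
                (out / "topology.json").write_text(json.dumps(topo.to_dict(), indent=2))

    digests = {p.name: _digest(p) for p in sorted(out.iterdir()) if p.is_file()
               and p.name != "manifest.json"}
    manifest = RunManifest(
        config=asdict(config), version=__version__, seeds=seeds,
        digests=digests, timings=timings,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return PipelineResult(
        network=network, topology=topo, coherence=coherence, manifest=manifest,
        selected_tfs=selected, scans=scans, mi_edges=mi_edges,
    )


def run_from_bundle(bundle, out_dir: str | Path, **overrides) -> PipelineResult:
    """Write a synthetic bundle to ``out_dir``/inputs and run the pipeline on it."""
    from .simulate import write_bundle

    out = Path(out_dir)
    paths = write_bundle(bundle, out / "inputs")
    cfg = RunConfig(
        promoters=str(paths["promoters"]),
        pwms=str(paths["pwms"]),
        expression=str(paths["expression"]),
        experiments=str(paths["experiments"]),
        annotation=str(paths["annotation"]),
        orthologs=str(paths["orthologs"]),
        out_dir=str(out / "results"),
        **overrides,
    )
    return run_all(cfg)
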