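"""End-to-end orchestration: one run per syndrome-vs-normal comparison plus
cross-comparison reports, with a reproducibility manifest.

Stages communicate only through declared files in the output directory, so
each stage can be re-run or inspected in isolation. One global seed fans out
to per-stage child seeds through a fixed numpy SeedSequence derivation; the
manifest records sha256 hashes of every stage output, and a re-run with the
same config and seed reproduces the hash block exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import build_binary_tree
from .cluster import average_linkage, correlation_distance, to_newick
from .consensus import consensus_targets, read_prediction_tables, write_consensus
from .enrichment import hypergeom_enrich, read_gmt, term_overlap
from .network import (build_weighted_network, compare_networks, extract_hubs,
                      up_subnetwork, write_edge_list, write_graphml)
from .preprocess import (ExpressionMatrix, median_center_patients,
                         read_expression, standardize_samples)
from .rvm import differential_mirnas
from .simulate import NORMAL

__all__ = ["PipelineConfig", "run_all", "stage_seed"]

_STAGES = ("simulate", "de", "cluster", "classify", "consensus",
           "network", "enrich", "compare")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(_STAGES))[idx]
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a run; thresholds default to the
    published analysis values (FC 1.5, P 0.05, alpha 0.01, score 60,
    hub degree 5, min overlap 5, FDR 0.05)."""

    matrix: str = ""
    groups: str = ""
    predictions: str = ""
    validated: str = ""
    gmt: str = ""
    control_group: str = NORMAL
    case_groups: list[str] = field(default_factory=list)
    fc_thresh: float = 1.5
    p_thresh: float = 0.05
    classify_alpha: float = 0.01
    score_threshold: float = 60.0
    hub_min_degree: int = 5
    min_overlap: int = 5
    fdr_thresh: float = 0.05
    n_perm: int = 10000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage for every comparison; returns the manifest dict.

    Per comparison: DE table, dendrogram (Newick + reordered heatmap
    matrix), consensus targets, network + hub + up-expression subnetworks,
    enrichment table. Cross-comparison: miRNA overlaps, rank-similarity and
    retained-term overlaps. A missing GMT skips enrichment with a warning;
    any other stage failure aborts, naming the stage, and partial outputs
    are retained on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "started": time.time(),
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = _sha256(path)

    stage = "load"
    try:
        m = read_expression(config.matrix, config.groups)
        cases = config.case_groups or sorted(
            g for g in set(m.groups) if g != config.control_group)

        ensemble = None
        if config.predictions:
            stage = "consensus-load"
            ensemble = read_prediction_tables(
                config.predictions, config.validated or None)

        collection = None
        if config.gmt:
            universe = None
            if ensemble is not None:
                universe = set()
                for hits in ensemble.binary_programs.values():
                    for gs in hits.values():
                        universe |= gs
                universe |= {g for _, g in ensemble.scored_program}
                universe |= {g for _, g in ensemble.validated}
            collection = read_gmt(config.gmt, universe=universe)
        else:
            warnings.warn("no GMT supplied: enrichment stage skipped", RuntimeWarning)

        m_centered = median_center_patients(m)
        nets = {}
        enrich_results = {}
        for case in cases:
            comp = f"{case}_vs_{config.control_group}"
            stage = f"de[{comp}]"
            de = differential_mirnas(m_centered, case, config.control_group,
                                     fc_thresh=config.fc_thresh,
                                     p_thresh=config.p_thresh)
            de_path = out / f"de_{comp}.tsv"
            de.to_csv(de_path, sep="\t")
            record(f"de_{comp}", de_path)

            stage = f"cluster[{comp}]"
            sig_ids = list(de.index[de["significant"]])
            if len(sig_ids) >= 2:
                cols = m.group_columns(case) + m.group_columns(config.control_group)
                z = standardize_samples(
                    ExpressionMatrix(values=m.values.loc[sig_ids, cols],
                                     groups=m.groups))
                dend = average_linkage(correlation_distance(z, axis="rows"))
                (out / f"dendrogram_{comp}.nwk").write_text(to_newick(dend))
                record(f"dendrogram_{comp}", out / f"dendrogram_{comp}.nwk")
                z.values.loc[dend.leaf_order].to_csv(
                    out / f"heatmap_{comp}.tsv", sep="\t")
                record(f"heatmap_{comp}", out / f"heatmap_{comp}.tsv")

            if ensemble is not None:
                stage = f"consensus[{comp}]"
                cts = consensus_targets(ensemble,
                                        mirnas=sig_ids,
                                        threshold=config.score_threshold)
                cpath = out / f"consensus_{comp}.tsv"
                write_consensus(cts, cpath)
                record(f"consensus_{comp}", cpath)

                stage = f"network[{comp}]"
                net = build_weighted_network(cts, de, comparison=comp)
                nets[case] = net
                write_edge_list(net, out / f"network_{comp}.tsv")
                record(f"network_{comp}", out / f"network_{comp}.tsv")
                write_graphml(net, out / f"network_{comp}.graphml")
                hubs = extract_hubs(net, min_degree=config.hub_min_degree)
                write_edge_list(hubs, out / f"hubs_{comp}.tsv")
                record(f"hubs_{comp}", out / f"hubs_{comp}.tsv")
                up_net, up_frac = up_subnetwork(net)
                write_edge_list(up_net, out / f"upnet_{comp}.tsv")
                record(f"upnet_{comp}", out / f"upnet_{comp}.tsv")
                (out / f"upfrac_{comp}.json").write_text(
                    json.dumps({"up_fraction_percent": up_frac,
                                "n_mirnas_de": len(sig_ids),
                                "n_mirnas_networked": len(net.mirna_nodes)}))
                record(f"upfrac_{comp}", out / f"upfrac_{comp}.json")

                if collection is not None:
                    stage = f"enrich[{comp}]"
                    query = set(up_net.gene_nodes)
                    res = hypergeom_enrich(query, collection,
                                           min_overlap=config.min_overlap,
                                           fdr_thresh=config.fdr_thresh,
                                           p_thresh=config.p_thresh)
                    enrich_results[case] = res
                    epath = out / f"enrichment_{comp}.tsv"
                    res.to_csv(epath, sep="\t")
                    record(f"enrichment_{comp}", epath)

        stage = "classify"
        if len(cases) + 1 >= 2:
            tree = build_binary_tree(m, classes=cases, alpha=config.classify_alpha,
                                     seed=stage_seed(config.seed, "classify"))
            tpath = out / "classification_tree.json"
            tree.write(tpath)
            record("classification_tree", tpath)

        stage = "compare"
        report = {}
        case_list = sorted(nets)
        for i, a in enumerate(case_list):
            for b in case_list[i + 1:]:
                cmp_res = compare_networks(
                    nets[a], nets[b], n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "compare"))
                entry = cmp_res.to_dict()
                if a in enrich_results and b in enrich_results:
                    entry["term_overlap"] = term_overlap(
                        enrich_results[a], enrich_results[b])
                report[f"{a}_vs_{b}"] = entry
        if report:
            rpath = out / "comparison_report.json"
            rpath.write_text(json.dumps(report, indent=1))
            record("comparison_report", rpath)

    except Exception as exc:  # noqa: BLE001 - annotate failing stage, keep partials
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
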