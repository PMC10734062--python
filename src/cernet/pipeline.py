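"""End-to-end orchestration: normalize -> QC -> DE -> Venn -> targets ->
co-expression -> circuits -> filters -> enrichment -> exports.

A run is driven by a single YAML config whose thresholds default to the
conventional printed criteria (fold change 2 / 0.5, P < 0.05, r > 0.2) and
writes a versioned run directory. Identical config + inputs produce
byte-identical outputs (the run log carries no timestamps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna, coexpression, diffexpr, enrichment, preprocess, simulate
from .errors import UserError
from .io import (
    FLOAT_FMT,
    concat_matrices,
    read_expression_matrix,
    read_feature_annotation,
    read_gene_sets,
    read_target_table,
    write_circuits,
    write_expression_matrix,
    write_network,
    write_sankey,
)

SCHEMA_VERSION = "1"

DEFAULT_CONFIG = {
    "thresholds": {
        "fc_hi": 2.0,
        "fc_lo": 0.5,
        "alpha": 0.05,
        "r_min": 0.2,
        "coexpr_alpha": 0.05,
    },
    "circuit_contrasts": ["TS_CM_vs_WT_CM"],
    "min_shared_mirnas": 1,
    "escape_required": True,
    "mrna_filter_set": None,  # gene-set name in the GMT, or null
    "enrichment": True,
}


@dataclass
class PipelineResult:
    """In-memory view of a completed run (the run directory holds the files)."""

    out_dir: Path
    de_results: dict          # (rna_class, contrast) -> DEResult
    venn: "diffexpr.VennPartition"
    edges: dict               # contrast -> list of CoexpressionEdge
    circuits: dict            # contrast -> list of CeRNACircuit (assembled)
    filtered_circuits: dict   # contrast -> list of CeRNACircuit (after filters)
    truth: simulate.TruthManifest | None = None
    log: list = field(default_factory=list)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if key == "thresholds":
            config["thresholds"].update(value or {})
        else:
            config[key] = value
    return config


def _check_input_files(config: dict) -> None:
    """Abort before stage 1 if any referenced input file is missing."""
    inputs = config.get("inputs")
    if inputs is None:
        return
    paths = [inputs.get("sample_sheet"), inputs.get("annotation"), inputs.get("targets")]
    paths += list(inputs.get("expression", {}).values())
    if inputs.get("gene_sets"):
        paths.append(inputs["gene_sets"])
    for p in paths:
        if p is None or not Path(p).exists():
            raise UserError(f"input file missing: {p}")


def _write_tsv(df: pd.DataFrame, path, index=False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FMT, lineterminator="\n")


def run_pipeline(config, out_dir, force: bool = False) -> PipelineResult:
    """Run the full analysis; see module docstring for the stage order."""
    config = load_config(config)
    out = Path(out_dir)
    if (out / "manifest.json").exists() and not force:
        raise UserError(f"{out} holds a completed run; pass force=True to overwrite")
    _check_input_files(config)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []

    def stage(name: str, **sizes) -> None:
        log.append({"stage": name, **sizes})

    # -- stage 0: inputs ------------------------------------------------------
    truth = None
    gene_sets = None
    if "simulate" in config:
        sim_cfg = simulate.SimulationConfig(**(config["simulate"] or {}))
        bundle = simulate.generate_dataset(sim_cfg)
        bundle.write(out / "inputs")
        matrices = bundle.matrices
        annotation = bundle.annotation
        targets = bundle.targets
        truth = bundle.truth
        gene_sets = bundle.gene_sets
        stage("simulate", n_features=sum(m.n_features for m in matrices.values()),
              n_samples=bundle.combined().n_samples)
    elif "inputs" in config:
        inputs = config["inputs"]
        matrices = {
            cls: read_expression_matrix(path, inputs["sample_sheet"])
            for cls, path in inputs["expression"].items()
        }
        annotation = read_feature_annotation(inputs["annotation"])
        targets = read_target_table(inputs["targets"])
        if inputs.get("gene_sets"):
            gene_sets = read_gene_sets(inputs["gene_sets"])
        stage("load", n_features=sum(m.n_features for m in matrices.values()))
    else:
        raise UserError("config needs a 'simulate' or 'inputs' section")

    # -- stage 1: quantile normalization --------------------------------------
    normalized = {cls: preprocess.quantile_normalize(m) for cls, m in matrices.items()}
    combined = concat_matrices([normalized[c] for c in sorted(normalized)])
    write_expression_matrix(combined, out / "normalized_combined.tsv")
    stage("normalize", n_features=combined.n_features, n_samples=combined.n_samples)

    # -- stage 2: QC ------------------------------------------------------------
    log2_combined = combined.to_log2()
    corr = preprocess.sample_correlation_matrix(log2_combined)
    _write_tsv(corr, out / "qc_sample_correlation.tsv", index=True, index_label="sample_id")
    link = preprocess.hierarchical_cluster_samples(log2_combined)
    (out / "qc_dendrogram.nwk").write_text(
        preprocess.dendrogram_newick(link, list(combined.sample_ids)) + "\n"
    )
    k = min(3, combined.n_samples - 1)
    scores, fractions = preprocess.pca_scores(log2_combined, k=k)
    scores = scores.copy()
    scores.loc["variance_fraction"] = fractions
    _write_tsv(scores, out / "qc_pca_scores.tsv", index=True, index_label="sample_id")
    stage("qc", n_samples=combined.n_samples)

    # -- stage 3: DE (3 contrasts x 3 classes) -----------------------------------
    th = config["thresholds"]
    contrasts = diffexpr.standard_contrasts(combined)
    de_results: dict = {}
    for cls in sorted(normalized):
        for label, contrast in contrasts.items():
            de = diffexpr.de_analysis(
                normalized[cls], contrast,
                fc_hi=th["fc_hi"], fc_lo=th["fc_lo"], alpha=th["alpha"],
            )
            de_results[(cls, label)] = de
            _write_tsv(de.table, out / f"de_{cls}_{label}.tsv", index=True)
            _write_tsv(de.volcano_data(), out / f"volcano_{cls}_{label}.tsv", index=True)
            stage(f"de:{cls}:{label}", n_called=len(de.called))

    # -- stage 4: Venn partition of DE mRNAs ----------------------------------
    venn = diffexpr.venn_partition(
        de_results[("mRNA", "WT_CM_vs_WT_iPSC")],
        de_results[("mRNA", "TS_CM_vs_TS_iPSC")],
        de_results[("mRNA", "TS_CM_vs_WT_CM")],
    )
    sizes = venn.sizes()
    _write_tsv(
        pd.DataFrame({"region": list(sizes), "size": list(sizes.values())}),
        out / "venn_sizes.tsv",
    )
    membership = [
        {"feature_id": f, "region": name}
        for name, members in venn.named_regions().items()
        for f in sorted(members)
    ]
    _write_tsv(
        pd.DataFrame(membership, columns=["feature_id", "region"]).sort_values(
            ["region", "feature_id"], ignore_index=True
        ),
        out / "venn_membership.tsv",
    )
    stage("venn", union=len(venn.union()))

    # -- stage 5..7: co-expression, circuits, filters per contrast ----------------
    ann_class = dict(zip(annotation["feature_id"], annotation["rna_class"]))
    filter_set = None
    if config.get("mrna_filter_set"):
        if gene_sets is None:
            raise UserError("mrna_filter_set configured but no gene sets supplied")
        name = config["mrna_filter_set"]
        if name not in gene_sets.sets:
            raise UserError(f"gene set {name!r} not in collection")
        filter_set = set(gene_sets.sets[name])
    edges_by_contrast: dict = {}
    circuits_by_contrast: dict = {}
    filtered_by_contrast: dict = {}
    for label in config["circuit_contrasts"]:
        if label not in contrasts:
            raise UserError(f"unknown circuit contrast {label!r}")
        contrast = contrasts[label]
        de_sponges = sorted(
            de_results[("lncRNA", label)].called | de_results[("circRNA", label)].called
        )
        de_mrnas = sorted(de_results[("mRNA", label)].called)
        edges, graph = coexpression.build_coexpression_network(
            combined, de_sponges, de_mrnas, list(contrast.samples), contrast=label,
            r_min=th["r_min"], alpha=th["coexpr_alpha"], rna_classes=ann_class,
        )
        edges_by_contrast[label] = edges
        _write_tsv(coexpression.edges_to_frame(edges), out / f"coexpression_{label}.tsv")
        write_network(graph, out / f"network_{label}.sif", format="sif")
        write_network(graph, out / f"network_{label}.graphml", format="graphml")
        stage(f"coexpression:{label}", n_pairs_tested=len(de_sponges) * len(de_mrnas),
              n_edges=len(edges))

        circuits = cerna.assemble_circuits(
            edges, targets, min_shared=config["min_shared_mirnas"]
        )
        circuits_by_contrast[label] = circuits
        write_circuits(circuits, out / f"circuits_{label}.tsv")
        stage(f"circuits:{label}", n_circuits=len(circuits))

        filtered = cerna.filter_circuits(
            circuits, annotation,
            escape_required=config["escape_required"],
            mrna_filter_set=filter_set,
        )
        filtered_by_contrast[label] = filtered
        write_circuits(filtered, out / f"circuits_filtered_{label}.tsv")
        write_sankey(filtered, out / f"sankey_{label}.json")
        stage(f"filter:{label}", n_kept=len(filtered))

    # -- stage 8: enrichment ------------------------------------------------------
    if config.get("enrichment") and gene_sets is not None:
        symbol_of = dict(zip(annotation["feature_id"], annotation["gene_symbol"]))
        mrna_ids = annotation.loc[annotation["rna_class"] == "mRNA", "feature_id"]
        universe = {symbol_of[f] for f in mrna_ids}
        for label in contrasts:
            query = {symbol_of[f] for f in de_results[("mRNA", label)].called}
            table = enrichment.enrich_collection(query, gene_sets, universe)
            _write_tsv(table, out / f"enrichment_{label}.tsv")
            stage(f"enrichment:{label}", n_sets=len(table))

    # -- manifest + log -------------------------------------------------------------
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": th,
        "circuit_contrasts": list(config["circuit_contrasts"]),
        "stages": log,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "run.log", "w", newline="\n") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        out_dir=out,
        de_results=de_results,
        venn=venn,
        edges=edges_by_contrast,
        circuits=circuits_by_contrast,
        filtered_circuits=filtered_by_contrast,
        truth=truth,
        log=log,
    )


def recover_circuits(
    sim_cfg: "simulate.SimulationConfig",
    contrast_label: str = "WT_CM_vs_WT_iPSC",
    thresholds: dict | None = None,
    min_shared: int = 1,
):
    """Simulate a bundle, run the analysis in memory, and score recovery.

    The benchmark assembles circuits through the differentiation contrast,
    where planted effect sizes clear the fold-change criteria (a sponge that
    is only dosage-halved sits exactly on the FC = 0.5 boundary and its
    target inherits beta * 1 < 1 in log2, so the genotype contrast cannot
    carry the benchmark; see the methods note).

    Returns (sensitivity, fdp, circuits, bundle).
    """
    th = dict(DEFAULT_CONFIG["thresholds"])
    th.update(thresholds or {})
    bundle = simulate.generate_dataset(sim_cfg)
    normalized = {
        cls: preprocess.quantile_normalize(m) for cls, m in bundle.matrices.items()
    }
    combined = concat_matrices([normalized[c] for c in sorted(normalized)])
    contrast = diffexpr.standard_contrasts(combined)[contrast_label]
    de = {
        cls: diffexpr.de_analysis(
            normalized[cls], contrast, fc_hi=th["fc_hi"], fc_lo=th["fc_lo"],
            alpha=th["alpha"],
        )
        for cls in ("mRNA", "lncRNA", "circRNA")
    }
    de_sponges = sorted(de["lncRNA"].called | de["circRNA"].called)
    de_mrnas = sorted(de["mRNA"].called)
    edges, _ = coexpression.build_coexpression_network(
        combined, de_sponges, de_mrnas, list(contrast.samples), contrast=contrast_label,
        r_min=th["r_min"], alpha=th["coexpr_alpha"],
    )
    circuits = cerna.assemble_circuits(edges, bundle.targets, min_shared=min_shared)
    sensitivity, fdp = simulate.score_recovery(circuits, bundle.truth)
    return sensitivity, fdp, circuits, bundle
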