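"""Linear in-process pipeline runner with a plain-text summary report."""

from __future__ import annotations

import logging
import os

import pandas as pd

from . import annotate as annotate_mod
from . import cluster_diff, integrate_eval, qc as qc_mod, regulators as reg_mod
from .config import RunConfig
from .genome_io import (
    NamedMatrix,
    read_gene_models,
    read_matrix,
    read_peaks,
    read_signatures,
    write_matrix,
)
from .rp_model import gene_activity

logger = logging.getLogger("scregpot")

STAGES = ("qc", "rp", "cluster-rna", "cluster-atac", "markers", "annotate", "integrate")


def _require(path: str | None, stage: str, what: str) -> str:
    if path is None or not os.path.exists(path or ""):
        raise FileNotFoundError(f"stage {stage!r} needs {what}: {path!r} not found")
    return path


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; write per-stage outputs and a report.

    Returns a dict of in-memory artifacts keyed by stage output name.
    """
    stages = list(stages) if stages else list(STAGES)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = config.paths.outdir
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict = {}
    report: list[str] = ["scregpot run summary", "=" * 40]

    rna_counts = atac_binary = None
    if config.paths.rna_matrix:
        rna_counts = read_matrix(config.paths.rna_matrix)
    if config.paths.atac_matrix:
        atac_binary = qc_mod.binarize(read_matrix(config.paths.atac_matrix))

    if "qc" in stages:
        if rna_counts is not None:
            metrics = qc_mod.rna_cell_metrics(rna_counts)
            passing = qc_mod.filter_cells(metrics, config.rna_qc)
            report.append(f"RNA QC: {len(passing)}/{len(metrics)} barcodes pass")
            logger.info("[qc] RNA: %d/%d barcodes pass", len(passing), len(metrics))
            keep = [c for c in rna_counts.col_names if c in passing]
            if not keep:
                raise ValueError(
                    "RNA QC removed every barcode; loosen the thresholds "
                    "(rna_qc) for this input"
                )
            rna_counts = rna_counts.subset_cols(keep)
            _write_lines(sorted(passing), os.path.join(outdir, "rna_barcodes.txt"))
            artifacts["rna_qc_pass"] = passing
        if config.paths.fragments and config.paths.genes:
            frags = qc_mod.read_fragments(config.paths.fragments)
            genes = read_gene_models(config.paths.genes, config.rp.promoter_flank)
            metrics = qc_mod.atac_cell_metrics(frags, genes)
            passing = qc_mod.filter_cells(metrics, config.atac_qc)
            report.append(f"ATAC QC: {len(passing)}/{len(metrics)} barcodes pass")
            logger.info("[qc] ATAC: %d/%d barcodes pass", len(passing), len(metrics))
            _write_lines(sorted(passing), os.path.join(outdir, "atac_barcodes.txt"))
            artifacts["atac_qc_pass"] = passing
            if atac_binary is not None:
                keep = [c for c in atac_binary.col_names if c in passing]
                atac_binary = atac_binary.subset_cols(keep)

    activity = None
    if "rp" in stages:
        peaks = read_peaks(_require(config.paths.peaks, "rp", "a peak BED file"))
        genes = read_gene_models(
            _require(config.paths.genes, "rp", "a gene annotation"), config.rp.promoter_flank
        )
        if atac_binary is None:
            raise FileNotFoundError("stage 'rp' needs an ATAC peak-by-cell matrix")
        activity = gene_activity(peaks, genes, atac_binary, config.rp)
        write_matrix(activity, os.path.join(outdir, "gene_activity.mtx"))
        report.append(
            f"RP model ({config.rp.model}, d0={config.rp.d0:g}): "
            f"{activity.shape[0]} genes x {activity.shape[1]} cells"
        )
        logger.info("[rp] gene activity %s", activity.shape)
        artifacts["activity"] = activity

    rna_labels = atac_labels = None
    rna_normed = atac_activity_normed = None
    if rna_counts is not None:
        rna_normed = cluster_diff.normalize_log(rna_counts)
    if activity is not None:
        atac_activity_normed = cluster_diff.normalize_log(activity)

    if "cluster-rna" in stages and rna_normed is not None:
        hvg = cluster_diff.select_variable_genes(
            rna_normed, min(config.clustering.n_variable_genes, len(rna_normed.row_names))
        )
        emb = cluster_diff.pca_embed(rna_normed, hvg, k=config.clustering.pca_dims)
        rna_labels = cluster_diff.cluster_cells(
            emb, config.clustering.n_neighbors, config.clustering.resolution,
            config.clustering.seed,
        )
        rna_labels.to_frame().to_csv(os.path.join(outdir, "rna_clusters.tsv"), sep="\t")
        sizes = rna_labels.to_frame()["cluster"].value_counts().sort_index()
        report.append("RNA clusters: " + ", ".join(f"{c}:{n}" for c, n in sizes.items()))
        artifacts["rna_labels"] = rna_labels

    if "cluster-atac" in stages and atac_binary is not None:
        k = min(config.clustering.lsi_dims, min(atac_binary.shape) - 1)
        emb = cluster_diff.lsi_embed(atac_binary, k=k, seed=config.clustering.seed)
        atac_labels = cluster_diff.cluster_cells(
            emb, config.clustering.n_neighbors, config.clustering.resolution,
            config.clustering.seed,
        )
        atac_labels.to_frame().to_csv(os.path.join(outdir, "atac_clusters.tsv"), sep="\t")
        sizes = atac_labels.to_frame()["cluster"].value_counts().sort_index()
        report.append("ATAC clusters: " + ", ".join(f"{c}:{n}" for c, n in sizes.items()))
        artifacts["atac_labels"] = atac_labels

    if "markers" in stages and rna_normed is not None and rna_labels is not None:
        thr = {
            "min_logfc": config.markers.gene_min_logfc,
            "min_pct": config.markers.gene_min_pct,
            "max_p": config.markers.max_p,
        }
        records = cluster_diff.wilcoxon_markers(rna_normed, rna_labels, thr)
        cluster_diff.markers_frame(records).to_csv(
            os.path.join(outdir, "rna_markers.tsv"), sep="\t", index=False
        )
        report.append(f"RNA markers: {len(records)} records")
        artifacts["rna_markers"] = records

    if "annotate" in stages and config.paths.signatures:
        signatures = read_signatures(config.paths.signatures)
        for tag, normed, labels in (
            ("rna", rna_normed, rna_labels),
            ("atac", atac_activity_normed, atac_labels),
        ):
            if normed is None or labels is None:
                continue
            annotations = annotate_mod.annotate_clusters(normed, labels, signatures)
            annotate_mod.annotations_frame(annotations).to_csv(
                os.path.join(outdir, f"{tag}_annotations.tsv"), sep="\t"
            )
            report.append(
                f"{tag.upper()} annotations: "
                + ", ".join(f"{a.cluster}={a.cell_type}" for a in annotations)
            )
            artifacts[f"{tag}_annotations"] = annotations

    if "integrate" in stages and rna_normed is not None and atac_activity_normed is not None:
        shared = [g for g in rna_normed.row_names if g in set(atac_activity_normed.row_names)]
        emb = integrate_eval.cca_embed(
            rna_normed.subset_rows(shared),
            atac_activity_normed.subset_rows(shared),
            k=min(config.integration.cca_dims, len(shared) - 1),
        )
        anchors = integrate_eval.find_anchors(emb, config.integration.k_anchor)
        labels_src = artifacts.get("rna_labels") or rna_labels
        if labels_src is not None:
            transfer = integrate_eval.transfer_labels(
                anchors, labels_src, config.integration.k_weight
            )
            transfer.to_frame().to_csv(os.path.join(outdir, "label_transfer.tsv"), sep="\t")
            high = sum(
                1 for s in transfer.max_scores().values()
                if s > config.integration.prediction_score_cutoff
            )
            report.append(
                f"Integration: {len(anchors)} anchors; "
                f"{high}/{len(transfer.predictions)} cells above "
                f"prediction score {config.integration.prediction_score_cutoff}"
            )
            artifacts["transfer"] = transfer

    report_path = os.path.join(outdir, "report.txt")
    with open(report_path, "w") as fh:
        fh.write("\n".join(report) + "\n")
    artifacts["report"] = report_path
    return artifacts


def _write_lines(lines, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(x) for x in lines) + "\n")
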