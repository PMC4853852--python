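"""End-to-end orchestration of the multi-omics key-regulator workflow.

Stage order: per-layer rank-product meta-analysis -> bimodal integration
(miRNA- and methylation-regulated genes, correlation filter, GMCs) ->
global and CGMC network construction -> topology scoring and KR calls ->
PAM partition + GSEA of the KR clusters -> survival validation. Every stage
writes its outputs under the configured output directory and records its
counts, thresholds and seeds in a JSON manifest, so a run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .enrichment import (
    GSEA_P_THRESHOLD,
    GSEA_Q_THRESHOLD,
    gsea,
    pam_partition,
)
from .integration import (
    DEFAULT_CORRELATION_THRESHOLD,
    direction_concordance,
    functional_interactions,
    gmc_set,
    load_target_table,
    methylation_regulated_genes,
    mirna_regulated_genes,
)
from .meta import DEFAULT_N_PERM, DEFAULT_PFP_THRESHOLD, build_meta_signature
from .network import (
    DEFAULT_AR_CUTOFF,
    build_global_network,
    extract_cgmc,
    identify_kr_hubs,
    kr_subnetworks,
    topology_scores,
)
from .preprocess import LAYERS
from .survival import SURVIVAL_P_THRESHOLD, kr_split_survival, logrank_test, som_two_cluster
from .synthetic import MatchedProfiles, SyntheticConfig, generate_all

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_DEGENERATE = 3


class DegenerateResultError(RuntimeError):
    """A stage produced an empty result that makes downstream stages moot."""


@dataclass
class PipelineConfig:
    """Thresholds, permutation counts, seeds and input locations.

    When ``synthetic`` is set the pipeline generates its inputs; otherwise
    the path fields must point at delimited-text inputs (see krnet.io).
    """

    outdir: str = "krnet_out"
    seed: int = 0
    n_perm: int = DEFAULT_N_PERM
    pfp_threshold: float = DEFAULT_PFP_THRESHOLD
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD
    ar_cutoff: float = DEFAULT_AR_CUTOFF
    gsea_n_perm: int = 200
    gsea_p_threshold: float = GSEA_P_THRESHOLD
    gsea_q_threshold: float = GSEA_Q_THRESHOLD
    survival_p_threshold: float = SURVIVAL_P_THRESHOLD
    synthetic: SyntheticConfig | None = None
    # file inputs (used when synthetic is None): per layer a list of
    # (matrix_path, labels_path, study_id) triples, plus the remaining inputs
    studies: dict | None = None
    target_table_path: str | None = None
    matched_gene_path: str | None = None
    matched_mirna_path: str | None = None
    interactome_path: str | None = None
    site_to_gene_path: str | None = None
    survival_path: str | None = None
    expression_for_enrichment: str | None = None  # defaults to first gene study

    def thresholds(self) -> dict:
        return {
            "pfp": self.pfp_threshold,
            "correlation": self.correlation_threshold,
            "ar_cutoff": self.ar_cutoff,
            "gsea_p": self.gsea_p_threshold,
            "gsea_q": self.gsea_q_threshold,
            "survival_p": self.survival_p_threshold,
            "n_perm": self.n_perm,
            "gsea_n_perm": self.gsea_n_perm,
        }


def _load_inputs(config: PipelineConfig) -> dict:
    if config.synthetic is not None:
        bundle = generate_all(config.synthetic)
        bundle["site_to_gene"] = bundle["truth"].site_to_gene
        return bundle
    if not config.studies:
        raise ValueError("either synthetic config or study paths are required")
    bundle: dict = {"studies": {}, "truth": None}
    for layer in LAYERS:
        bundle["studies"][layer] = [
            io.read_study(m, l, sid, layer) for m, l, sid in config.studies.get(layer, [])
        ]
    bundle["targets"] = io.read_edge_list(config.target_table_path)
    bundle["matched"] = MatchedProfiles(
        genes=io.read_matrix(config.matched_gene_path),
        mirnas=io.read_matrix(config.matched_mirna_path),
    )
    edges = io.read_edge_list(config.interactome_path)
    bundle["interactome"] = list(edges.itertuples(index=False, name=None))
    s2g = io.read_edge_list(config.site_to_gene_path)
    bundle["site_to_gene"] = dict(zip(s2g.iloc[:, 0], s2g.iloc[:, 1]))
    bundle["survival"] = io.read_survival_table(config.survival_path)
    return bundle


def run_pipeline(config: PipelineConfig, inputs: dict | None = None) -> dict:
    """Run every stage; returns the manifest (also written as JSON).

    Raises DegenerateResultError when an empty intermediate (e.g. an empty
    meta-signature under a zero pfp threshold) makes the remaining stages
    meaningless; the partial manifest is still written in that case.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages": {},
        "warnings": [],
    }

    def finish(status: str) -> dict:
        manifest["status"] = status
        io.write_json(manifest, outdir / "manifest.json")
        return manifest

    try:
        bundle = inputs if inputs is not None else _load_inputs(config)

        # ---- stage 1: per-layer meta-analysis
        signatures = {}
        stage: dict = {}
        for layer in LAYERS:
            sig = build_meta_signature(
                bundle["studies"][layer],
                n_perm=config.n_perm,
                seed=config.seed,
                pfp_threshold=config.pfp_threshold,
            )
            signatures[layer] = sig
            sig.table.to_csv(outdir / f"meta_signature_{layer}.tsv", sep="\t")
            stage[layer] = {
                "n_features": len(sig.table),
                "n_significant": len(sig.significant_features),
            }
        manifest["stages"]["meta_analysis"] = stage
        if any(not signatures[l].significant_features for l in LAYERS):
            manifest["warnings"].append("a meta-signature is empty; stopping")
            raise DegenerateResultError("empty meta-signature")

        # ---- stage 2: integration
        targets = load_target_table(bundle["targets"])
        mr_genes, active_mirnas = mirna_regulated_genes(
            signatures["gene"], signatures["mirna"], targets
        )
        meth_genes, meth_ann = methylation_regulated_genes(
            signatures["gene"], signatures["methylation"], bundle["site_to_gene"]
        )
        candidates = [
            (m, g)
            for m, g in targets[["mirna", "gene"]].itertuples(index=False, name=None)
            if m in active_mirnas and g in mr_genes
        ]
        func_edges = functional_interactions(
            candidates, bundle["matched"], threshold=config.correlation_threshold
        )
        gmcs = gmc_set(
            mr_genes, meth_genes, func_edges,
            gene_sig=signatures["gene"], meth_annotations=meth_ann,
        )
        gmcs.annotations.to_csv(outdir / "gmc_annotations.tsv", sep="\t")
        func_edges.to_csv(outdir / "functional_edges.tsv", sep="\t", index=False)
        try:
            concord = direction_concordance(gmcs)
        except ValueError:
            concord = float("nan")
        manifest["stages"]["integration"] = {
            "n_mirna_regulated": len(mr_genes),
            "n_active_mirnas": len(active_mirnas),
            "n_meth_regulated": len(meth_genes),
            "n_functional_edges": int(len(func_edges)),
            "n_gmc": len(gmcs.gmcs),
            "direction_concordance_inverse": concord,
        }
        if not gmcs.gmcs:
            manifest["warnings"].append("empty GMC set; stopping")
            raise DegenerateResultError("empty GMC set")

        # ---- stage 3: networks and KR hubs
        G = build_global_network(
            signatures["gene"], signatures["mirna"], bundle["interactome"], func_edges
        )
        cgmc = extract_cgmc(G, gmcs.gmcs)
        io.write_sif(G, outdir / "global_network.sif")
        io.write_sif(cgmc, outdir / "cgmc_network.sif")
        io.write_graphml(cgmc, outdir / "cgmc_network.graphml")
        scores = topology_scores(cgmc)
        scores.to_csv(outdir / "topology_scores.tsv", sep="\t")
        krs = identify_kr_hubs(scores, cutoff=config.ar_cutoff)
        subnets = kr_subnetworks(cgmc, krs)
        manifest["stages"]["network"] = {
            "global_nodes": G.number_of_nodes(),
            "global_edges": G.number_of_edges(),
            "cgmc_nodes": cgmc.number_of_nodes(),
            "cgmc_edges": cgmc.number_of_edges(),
            "kr_hubs": krs,
            "kr_neighbor_counts": {k: sn.number_of_nodes() - 1 for k, sn in subnets.items()},
        }
        if not krs:
            manifest["warnings"].append("no KR hub at the AR cutoff; stopping")
            raise DegenerateResultError("no KR hubs")

        # ---- stage 4: PAM partition + GSEA on a gene expression study
        expr_study = bundle["studies"]["gene"][0]
        kr_genes = [k for k in krs if cgmc.nodes[k].get("type", "gene") == "gene"]
        cgmc_genes = [
            n for n in cgmc.nodes
            if cgmc.nodes[n].get("type", "gene") == "gene" and n in expr_study.matrix.index
        ]
        expr = expr_study.matrix.loc[cgmc_genes]
        kr_genes = [k for k in kr_genes if k in expr.index]
        stage4: dict = {}
        if len(kr_genes) >= 1 and len(expr) > len(kr_genes):
            clustering = pam_partition(expr, kr_genes)
            sets = {f"KR_{m}": members for m, members in clustering.clusters.items()}
            io.write_gmt(sets, outdir / "kr_clusters.gmt")
            gsea_table = gsea(
                expr,
                expr_study.classes,
                sets,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
                p_threshold=config.gsea_p_threshold,
                q_threshold=config.gsea_q_threshold,
            )
            gsea_out = gsea_table.drop(columns=["leading_edge"]).copy()
            gsea_out.to_csv(outdir / "gsea_kr_clusters.tsv", sep="\t")
            stage4 = {
                "n_clusters": len(sets),
                "cluster_sizes": {k: len(v) for k, v in sets.items()},
                "n_significant_sets": int(gsea_table["significant"].sum()),
            }
        else:
            manifest["warnings"].append("PAM/GSEA skipped: too few KR genes in matrix")
        manifest["stages"]["enrichment"] = stage4

        # ---- stage 5: survival validation
        surv = bundle["survival"]
        kr_cols = [k for k in krs if k in surv.columns]
        stage5: dict = {"n_samples": len(surv), "kr_tested": kr_cols}
        if len(kr_cols) >= 2:
            som_labels = som_two_cluster(surv[kr_cols], seed=config.seed)
            if som_labels.nunique() == 2:
                lr = logrank_test(
                    som_labels.to_numpy(), surv["time"].to_numpy(), surv["event"].to_numpy()
                )
                stage5["som_logrank_p"] = lr.p
                stage5["som_significant"] = lr.p <= config.survival_p_threshold
        per_kr = {}
        for k in kr_cols:
            try:
                r = kr_split_survival(surv, k, p_threshold=config.survival_p_threshold)
            except ValueError as e:
                manifest["warnings"].append(f"survival split failed for {k}: {e}")
                continue
            per_kr[k] = {"p": r.p, "significant": r.significant, "direction": r.direction}
        stage5["kr_split"] = per_kr
        manifest["stages"]["survival"] = stage5

        return finish("ok")
    except DegenerateResultError:
        finish("degenerate")
        raise
    except Exception:
        finish("error")
        raise
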