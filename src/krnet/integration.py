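"""Bimodal integration of the three layer meta-signatures.

Combines the gene, miRNA and methylation meta-signatures into the sets the
downstream network is built from: genes targeted by significant miRNAs
(miRNA-regulated), genes owning at least one significant methylation site
(methylation-regulated, direction deliberately ignored), the matched-sample
correlation filter (|R| >= 0.8 by default) that keeps only functional
miRNA-gene interactions, and their intersection — genes under multiple
regulatory controls (GMCs).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .meta import MetaSignature
from .synthetic import MatchedProfiles

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = 0.8

# species prefix (hsa-, mmu-, ...) only when followed by a mir/let stem
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=(?:mir|let))")
_ARM_SUFFIX = re.compile(r"-(5p|3p)$")


def canonicalize_mirna(name: str) -> str:
    """Lowercase and strip a species prefix (e.g. ``hsa-``); arms are kept."""
    return _SPECIES_PREFIX.sub("", name.strip().lower())


def _collapse_arm(name: str) -> str:
    return _ARM_SUFFIX.sub("", name)


def load_target_table(table: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize miRNA ids and drop duplicate (mirna, gene) rows."""
    out = table.copy()
    out["mirna"] = out["mirna"].map(canonicalize_mirna)
    n0 = len(out)
    out = out.drop_duplicates(subset=["mirna", "gene"]).reset_index(drop=True)
    if len(out) < n0:
        logger.info("dropped %d duplicate target rows", n0 - len(out))
    return out


def _match_mirnas(
    prediction_mirnas: pd.Series, signature_ids: set[str]
) -> pd.Series:
    """Map prediction miRNA ids onto signature ids.

    Exact canonical match first; for ids that fail, the -5p/-3p arm suffix is
    collapsed on both sides (logged). Unmatched ids map to NaN.
    """
    sig = {canonicalize_mirna(m): m for m in signature_ids}
    collapsed = {}
    for m in signature_ids:
        collapsed.setdefault(_collapse_arm(canonicalize_mirna(m)), m)
    out = []
    n_collapsed = 0
    for name in prediction_mirnas:
        c = canonicalize_mirna(name)
        if c in sig:
            out.append(sig[c])
        elif _collapse_arm(c) in collapsed:
            out.append(collapsed[_collapse_arm(c)])
            n_collapsed += 1
        else:
            out.append(np.nan)
    if n_collapsed:
        logger.info("matched %d prediction miRNAs after arm collapsing", n_collapsed)
    return pd.Series(out, index=prediction_mirnas.index)


def mirna_regulated_genes(
    gene_sig: MetaSignature,
    mirna_sig: MetaSignature,
    predictions: pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """Significant genes predicted as targets of significant miRNAs.

    Returns (gene set, set of active miRNAs with >= 1 such target). No
    directionality constraint is imposed on either side.
    """
    if predictions.empty:
        logger.warning("empty target-prediction table: no miRNA-regulated genes")
        return set(), set()
    sig_genes = gene_sig.significant_features
    sig_mirnas = mirna_sig.significant_features
    preds = predictions.copy()
    preds["mirna"] = _match_mirnas(preds["mirna"], sig_mirnas)
    hits = preds[preds["mirna"].isin(sig_mirnas) & preds["gene"].isin(sig_genes)]
    return set(hits["gene"]), set(hits["mirna"])


def methylation_regulated_genes(
    gene_sig: MetaSignature,
    meth_sig: MetaSignature,
    site_to_gene: Mapping[str, str],
) -> tuple[set[str], pd.DataFrame]:
    """Genes significant in both the gene and methylation meta-signatures.

    A gene counts as differentially methylated if ANY of its sites is
    significant; its methylation direction is taken from the minimum-pfp
    site. Direction is ignored for membership by design. Returns the gene
    set and a per-gene annotation frame (best_site, meth_direction, pfp).
    """
    mapped = {s for s in meth_sig.table.index if s in site_to_gene}
    if not mapped:
        raise ValueError("no methylation site maps to a gene symbol")
    sig_sites = meth_sig.significant_features & mapped
    rows = []
    for s in sig_sites:
        d = meth_sig.table.loc[s, "direction"]
        pfp = meth_sig.table.loc[s, f"pfp_{d}"]
        rows.append((site_to_gene[s], s, d, float(pfp)))
    if rows:
        ann = pd.DataFrame(rows, columns=["gene", "best_site", "meth_direction", "pfp"])
        ann = ann.sort_values(["gene", "pfp", "best_site"]).drop_duplicates("gene")
        ann = ann.set_index("gene")
    else:
        ann = pd.DataFrame(columns=["best_site", "meth_direction", "pfp"])
    genes = set(ann.index) & gene_sig.significant_features
    return genes, ann.loc[sorted(genes)]


def functional_interactions(
    candidates: Iterable[tuple[str, str]],
    profiles: MatchedProfiles,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> pd.DataFrame:
    """Pearson-filter candidate (miRNA, gene) pairs on matched samples.

    Keeps pairs with |R| >= threshold (signed R reported). Pairs whose gene
    or miRNA is absent from the profiles, or has zero variance, are skipped
    with a warning.
    """
    rows = []
    skipped = 0
    g = profiles.genes
    m = profiles.mirnas
    for mirna, gene in candidates:
        if gene not in g.index or mirna not in m.index:
            skipped += 1
            continue
        x = g.loc[gene].to_numpy(dtype=float)
        y = m.loc[mirna].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= threshold:
            rows.append((mirna, gene, r))
    if skipped:
        logger.warning("skipped %d candidate pairs (missing or zero-variance profiles)", skipped)
    return pd.DataFrame(rows, columns=["mirna", "gene", "r"])


@dataclass
class GmcSet:
    """Integrated regulated-gene sets and the GMC intersection.

    ``annotations`` is indexed by GMC gene with columns gene_direction,
    gene_log2fc (mean across studies), meth_direction, best_site, mirnas
    (sorted list of functionally interacting significant miRNAs).
    """

    mirna_regulated: set[str]
    meth_regulated: set[str]
    gmcs: set[str]
    annotations: pd.DataFrame
    functional_edges: pd.DataFrame  # mirna, gene, r — restricted to GMCs

    def __len__(self) -> int:
        return len(self.gmcs)


def gmc_set(
    mirna_regulated: set[str],
    meth_regulated: set[str],
    functional_edges: pd.DataFrame,
    gene_sig: MetaSignature | None = None,
    meth_annotations: pd.DataFrame | None = None,
) -> GmcSet:
    """Intersect the regulated sets, requiring >= 1 surviving functional edge."""
    with_edge = set(functional_edges["gene"]) if len(functional_edges) else set()
    gmcs = mirna_regulated & meth_regulated & with_edge
    if not gmcs:
        logger.warning("no genes survive the GMC intersection")
    edges = (
        functional_edges[functional_edges["gene"].isin(gmcs)].reset_index(drop=True)
        if len(functional_edges)
        else functional_edges
    )
    ann = pd.DataFrame(index=sorted(gmcs))
    if gene_sig is not None and len(ann):
        ann["gene_direction"] = [gene_sig.direction_of(g) for g in ann.index]
        fc_cols = [c for c in gene_sig.table.columns if c.startswith("log2fc_")]
        ann["gene_log2fc"] = gene_sig.table.loc[ann.index, fc_cols].mean(axis=1)
    if meth_annotations is not None and len(ann):
        ann["meth_direction"] = meth_annotations.reindex(ann.index)["meth_direction"]
        ann["best_site"] = meth_annotations.reindex(ann.index)["best_site"]
    if len(ann):
        by_gene = edges.groupby("gene")["mirna"].apply(lambda s: sorted(set(s)))
        ann["mirnas"] = [by_gene.get(g, []) for g in ann.index]
    return GmcSet(
        mirna_regulated=mirna_regulated,
        meth_regulated=meth_regulated,
        gmcs=gmcs,
        annotations=ann,
        functional_edges=edges,
    )


def direction_concordance(gmc: GmcSet) -> float:
    """Fraction of GMCs whose expression and methylation directions oppose.

    A planted inverse promoter-methylation pattern shows up here as a value
    near the planting probability (~0.7 at the default coupling).
    """
    if not gmc.gmcs:
        raise ValueError("empty GMC set")
    ann = gmc.annotations
    if "gene_direction" not in ann or "meth_direction" not in ann:
        raise ValueError("GMC annotations lack direction columns")
    sign = {"up": 1, "down": -1, 1: 1, -1: -1}
    g = ann["gene_direction"].map(sign)
    m = ann["meth_direction"].map(sign)
    ok = g.notna() & m.notna()
    if not ok.any():
        raise ValueError("no GMC with both direction annotations")
    return float((g[ok] != m[ok]).mean())
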