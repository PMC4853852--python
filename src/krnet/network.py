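"""Molecular network construction, topology scoring and key-regulator calls.

The global network joins the significant genes of the expression
meta-signature (via interactome edges whose endpoints are both significant)
with the significant miRNAs attached through functional correlation edges.
The comprehensive GMC (CGMC) subnetwork is the induced subgraph on the GMCs
plus their first neighbors. Nodes are scored with two topology indices —
stress centrality (number of shortest paths passing through the node) and
neighborhood connectivity (mean neighbor degree) — and ranked; the average
rank (AR) score is the mean of the two ranks and nodes with AR <= 10 are
called key-regulator (KR) hubs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .meta import MetaSignature

logger = logging.getLogger(__name__)

DEFAULT_AR_CUTOFF = 10.0


def build_global_network(
    gene_sig: MetaSignature,
    mirna_sig: MetaSignature,
    interactome_edges,
    functional_edges: pd.DataFrame,
) -> nx.Graph:
    """Simple undirected graph over significant genes and miRNAs.

    Interactome edges are kept only when both endpoints are significant
    genes; functional miRNA-gene edges are kept when both members are
    significant. Self-loops and duplicates are dropped; only nodes incident
    to a retained edge appear.
    """
    sig_genes = gene_sig.significant_features
    sig_mirnas = mirna_sig.significant_features
    G = nx.Graph()
    if isinstance(interactome_edges, nx.Graph):
        interactome_edges = interactome_edges.edges()
    for u, v in interactome_edges:
        if u != v and u in sig_genes and v in sig_genes:
            G.add_edge(u, v, source="interactome")
    for _, row in functional_edges.iterrows():
        m, g = row["mirna"], row["gene"]
        if m != g and m in sig_mirnas and g in sig_genes:
            G.add_edge(m, g, source="mirna_functional")
    if G.number_of_edges() == 0:
        raise ValueError("no retained edges: global network is empty")
    for n in G.nodes:
        G.nodes[n]["type"] = "mirna" if n in sig_mirnas else "gene"
    logger.info(
        "global network: %d nodes, %d edges", G.number_of_nodes(), G.number_of_edges()
    )
    return G


def extract_cgmc(network: nx.Graph, gmcs: set[str]) -> nx.Graph:
    """Induced subgraph on the GMCs present in the network + first neighbors.

    Edges among neighbors are retained (induced subgraph), producing a
    cohesive module rather than a union of stars.
    """
    present = set(gmcs) & set(network.nodes)
    if not present:
        raise ValueError("no GMC present in the network")
    nodes = set(present)
    for g in present:
        nbrs = set(network.neighbors(g))
        if not nbrs:
            logger.warning("GMC %s is isolated in the network", g)
        nodes |= nbrs
    sub = network.subgraph(nodes).copy()
    for n in sub.nodes:
        sub.nodes[n]["is_gmc"] = n in present
    logger.info("CGMC network: %d nodes, %d edges", sub.number_of_nodes(), sub.number_of_edges())
    return sub


def _bfs_sigma(G: nx.Graph, s):
    """BFS from s: returns stack order, predecessor lists, path counts."""
    sigma = {v: 0 for v in G}
    dist = {v: -1 for v in G}
    pred = {v: [] for v in G}
    sigma[s] = 1
    dist[s] = 0
    order = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        for w in G[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return order, pred, sigma


def stress_centrality(network: nx.Graph) -> dict:
    """Number of shortest paths on which each node lies as an interior vertex.

    Unweighted geodesics; every unordered (s, t) pair within a component is
    counted once, and all shortest s-t paths contribute. Uses the
    Brandes-style accumulation for the stress variant:
    delta_s(v) = sigma_sv * sum_{w: v in pred(w)} (1 + delta_s(w) / sigma_sw),
    summed over sources and halved.
    """
    stress = {v: 0.0 for v in network}
    for s in network:
        order, pred, sigma = _bfs_sigma(network, s)
        delta = {v: 0.0 for v in network}
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
            if w != s:
                stress[w] += delta[w]
    return {v: int(round(x / 2.0)) for v, x in stress.items()}


def neighborhood_connectivity(network: nx.Graph) -> dict:
    """Mean degree over each node's neighbors; isolated nodes get 0."""
    deg = dict(network.degree())
    out = {}
    n_isolated = 0
    for v in network:
        nbrs = list(network[v])
        if nbrs:
            out[v] = float(np.mean([deg[w] for w in nbrs]))
        else:
            out[v] = 0.0
            n_isolated += 1
    if n_isolated:
        logger.info("%d isolated nodes assigned neighborhood connectivity 0", n_isolated)
    return out


def topology_scores(network: nx.Graph) -> pd.DataFrame:
    """Stress, neighborhood connectivity, their ranks and the AR score.

    Rank 1 is the highest value of each index; ties receive average ranks;
    AR = (rank_stress + rank_nc) / 2. AR is invariant to monotone
    transformations of the underlying indices.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(network.nodes)
    stress = stress_centrality(network)
    nc = neighborhood_connectivity(network)
    s = np.array([stress[v] for v in nodes], dtype=float)
    c = np.array([nc[v] for v in nodes], dtype=float)
    rank_s = rankdata(-s, method="average")
    rank_c = rankdata(-c, method="average")
    df = pd.DataFrame(
        {
            "stress": s.astype(int),
            "neighborhood_connectivity": c,
            "rank_stress": rank_s,
            "rank_nc": rank_c,
            "ar_score": (rank_s + rank_c) / 2.0,
        },
        index=pd.Index(nodes, name="node"),
    )
    if "type" in next(iter(network.nodes(data=True)))[1]:
        df["type"] = [network.nodes[v].get("type", "gene") for v in nodes]
    return df.sort_values(["ar_score", "rank_stress"]).rename_axis("node")


def identify_kr_hubs(
    scores: pd.DataFrame,
    cutoff: float = DEFAULT_AR_CUTOFF,
    genes_only: bool = False,
) -> list[str]:
    """Nodes with AR score <= cutoff, sorted ascending by AR.

    miRNA nodes are eligible by default; ``genes_only`` restricts the call
    to gene nodes. If the network is smaller than the cutoff every node is
    returned, with a prominent warning.
    """
    if scores.empty:
        raise ValueError("empty score table")
    tab = scores
    if genes_only and "type" in tab.columns:
        tab = tab[tab["type"] == "gene"]
    if len(tab) <= cutoff:
        logger.warning(
            "network has only %d scored nodes (<= AR cutoff %g): every node is a KR",
            len(tab), cutoff,
        )
    krs = tab[tab["ar_score"] <= cutoff].sort_values(["ar_score", "rank_stress"])
    return krs.index.tolist()


def kr_subnetworks(network: nx.Graph, kr_list: list[str]) -> dict[str, nx.Graph]:
    """Induced first-neighbor subgraph around each KR."""
    out = {}
    for kr in kr_list:
        if kr not in network:
            continue
        nbrs = set(network.neighbors(kr))
        if not nbrs:
            logger.warning("KR %s is isolated; singleton subnetwork", kr)
        out[kr] = network.subgraph({kr} | nbrs).copy()
    return out
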