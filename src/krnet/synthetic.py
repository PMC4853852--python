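"""Seeded multi-omics fixture generator with planted ground truth.

Emulates the statistical structure of a multi-study case/control multi-omics
compendium: several heterogeneous studies per layer (gene, miRNA,
methylation) sharing a planted differential signal but carrying
study-specific batch shifts and effect heterogeneity; a miRNA->gene target
table mixing true (co-expressed in matched samples) and decoy pairs; a
scale-free gene interactome whose planted hub genes sit in a rich-club
disease module; and survival times whose hazard depends on the planted
key-regulator expression.

Every generator derives its own random stream from the single config seed
via stable sub-seeding, so stages are reproducible independently of the
order in which they run.

Ground-truth containment invariants: planted GMCs are a subset of both the
planted miRNA-regulated and methylation-regulated gene sets, and planted
hubs are a subset of the planted GMCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import LAYERS, OmicsStudy

logger = logging.getLogger(__name__)

# stable sub-stream ids per generator (order of calls must not matter)
_STREAMS = {
    "truth": 1,
    "gene": 2,
    "mirna": 3,
    "methylation": 4,
    "targets": 5,
    "matched": 6,
    "interactome": 7,
    "survival": 8,
}

#: probability that a planted GMC's methylation direction opposes its
#: expression direction (mirrors the inverse promoter-methylation pattern).
INVERSE_COUPLING_PROB = 0.7


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-omics study collection.

    Defaults describe a desk-scale version of a real compendium: three
    studies per layer, 1000 genes / 150 miRNAs / 1200 methylation sites
    (~1.2 CpG sites per gene), 10 samples per class per study, 10% of
    features differential with a mean |log2FC| of 2 on top of unit residual
    noise, half-unit study batch shifts, 40 doubly-regulated genes of which
    5 are network hubs, 3 decoy target rows per true row, a unit per-risk
    log hazard and 20% independent censoring.
    """

    n_studies_per_layer: int = 3
    n_genes: int = 1000
    n_mirnas: int = 150
    n_meth_sites: int = 1200
    n_samples_per_class: int = 10
    frac_de: float = 0.1
    effect_size: float = 2.0
    batch_sd: float = 0.5
    noise_sd: float = 1.0
    n_gmc: int = 40
    n_hubs: int = 5
    decoy_ratio: int = 3
    hazard_coef: float = 1.0
    censor_rate: float = 0.2
    seed: int = 0
    # secondary knobs (spread of per-study effect heterogeneity, matched-
    # profile residual noise, matched cohort and survival cohort sizes)
    effect_heterogeneity_sd: float = 0.0
    matched_noise_sd: float = 0.2
    n_matched_samples: int = 30
    n_survival_samples: int = 200

    def __post_init__(self) -> None:
        counts = {
            "n_studies_per_layer": self.n_studies_per_layer,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "n_meth_sites": self.n_meth_sites,
            "n_samples_per_class": self.n_samples_per_class,
            "n_gmc": self.n_gmc,
            "n_hubs": self.n_hubs,
            "n_matched_samples": self.n_matched_samples,
            "n_survival_samples": self.n_survival_samples,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0 < self.frac_de < 1:
            raise ValueError("frac_de must lie in (0, 1)")
        if self.n_gmc > self.n_genes:
            raise ValueError("n_gmc cannot exceed n_genes")
        if self.n_hubs > self.n_gmc:
            raise ValueError("n_hubs cannot exceed n_gmc")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.decoy_ratio < 0:
            raise ValueError("decoy_ratio must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted truth shared by all generators for one config."""

    de: dict[str, pd.DataFrame]  # layer -> DataFrame(feature, direction +-1)
    true_pairs: list[tuple[str, str]]  # (mirna_id, gene_id)
    mirna_regulated_genes: set[str]
    meth_regulated_genes: set[str]
    site_to_gene: dict[str, str]
    meth_site_direction: dict[str, int]
    gmcs: set[str]
    hubs: set[str]
    risk_scores: pd.Series | None = None  # filled by generate_survival

    def de_features(self, layer: str) -> set[str]:
        return set(self.de[layer]["feature"])

    def validate(self) -> None:
        assert self.gmcs <= self.mirna_regulated_genes & self.meth_regulated_genes
        assert self.hubs <= self.gmcs


def _ids(prefix: str, n: int, width: int = 5) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def make_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Plant the differential features, regulatory structure, GMCs and hubs.

    Multiplicities mirror real regulatory annotation: each GMC carries 2-3
    differential CpG sites and 1-2 true differential miRNA regulators;
    miRNA-regulated-only and methylation-regulated-only genes pad the funnel.
    """
    rng = config.rng("truth")
    genes = _ids("G", config.n_genes)
    mirnas = [f"mir-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    sites = [f"cg{i:06d}" for i in range(1, config.n_meth_sites + 1)]

    n_de_g = round(config.frac_de * config.n_genes)
    n_de_m = max(2, round(config.frac_de * config.n_mirnas))
    n_de_s = round(config.frac_de * config.n_meth_sites)

    if config.n_gmc > n_de_g:
        raise ValueError(
            f"n_gmc={config.n_gmc} exceeds the {n_de_g} planted DE genes "
            "(raise frac_de or n_genes)"
        )
    de_genes = list(rng.choice(genes, size=n_de_g, replace=False))
    de_mirnas = list(rng.choice(mirnas, size=n_de_m, replace=False))
    de_sites = list(rng.choice(sites, size=n_de_s, replace=False))
    gene_dir = dict(zip(de_genes, rng.choice([-1, 1], size=n_de_g)))
    mirna_dir = dict(zip(de_mirnas, rng.choice([-1, 1], size=n_de_m)))

    gmcs = list(de_genes[: config.n_gmc])
    hubs = set(rng.choice(gmcs, size=config.n_hubs, replace=False))
    rest = de_genes[config.n_gmc:]
    # disjoint single-regulation pads from the remaining planted DE genes
    n_pad = len(rest) // 2
    mirna_only = rest[:n_pad]
    meth_only = rest[n_pad: 2 * n_pad]

    # --- true miRNA->gene pairs: one primary regulator per regulated gene
    true_pairs: list[tuple[str, str]] = []
    for g in gmcs + mirna_only:
        m = de_mirnas[rng.integers(len(de_mirnas))]
        true_pairs.append((m, g))
    # some GMCs get a second regulator (not used for matched-profile coupling)
    for g in gmcs:
        if rng.random() < 0.3:
            m = de_mirnas[rng.integers(len(de_mirnas))]
            if (m, g) not in true_pairs:
                true_pairs.append((m, g))
    mirna_regulated = {g for _, g in true_pairs}

    # --- methylation: map every site to a gene, then point DE sites at the
    # planted methylation-regulated genes (2-3 sites per gene, like real CpGs)
    site_to_gene = {s: genes[rng.integers(config.n_genes)] for s in sites}
    meth_regulated = list(gmcs) + list(meth_only)
    meth_dir_by_gene: dict[str, int] = {}
    for g in meth_regulated:
        if g in gmcs and rng.random() < INVERSE_COUPLING_PROB:
            meth_dir_by_gene[g] = -gene_dir[g]
        else:
            meth_dir_by_gene[g] = int(rng.choice([-1, 1])) if g not in gmcs else gene_dir[g]
    if len(de_sites) < len(meth_regulated):
        raise ValueError(
            f"only {len(de_sites)} planted DE methylation sites for "
            f"{len(meth_regulated)} methylation-regulated genes (raise n_meth_sites)"
        )
    site_dir: dict[str, int] = {}
    site_iter = iter(de_sites)
    # every regulated gene gets one DE site, then extras up to ~2-3 per gene
    # (real genes carry several differential CpGs), leaving a fraction of DE
    # sites on background genes.
    n_extra = max(0, min(len(de_sites) - len(meth_regulated) - len(meth_regulated) // 2,
                         len(meth_regulated)))
    owners = meth_regulated + list(rng.choice(meth_regulated, size=n_extra, replace=True))
    for g in owners:
        s = next(site_iter)
        site_to_gene[s] = g
        site_dir[s] = meth_dir_by_gene[g]
    regulated = mirna_regulated | set(meth_regulated)
    background = [g for g in genes if g not in regulated]
    for s in site_iter:  # leftover DE sites: background genes, random direction
        site_dir[s] = int(rng.choice([-1, 1]))
        if site_to_gene[s] in regulated and background:
            site_to_gene[s] = background[rng.integers(len(background))]

    de = {
        "gene": pd.DataFrame({"feature": de_genes,
                              "direction": [gene_dir[g] for g in de_genes]}),
        "mirna": pd.DataFrame({"feature": de_mirnas,
                               "direction": [mirna_dir[m] for m in de_mirnas]}),
        "methylation": pd.DataFrame({"feature": de_sites,
                                     "direction": [site_dir[s] for s in de_sites]}),
    }
    truth = GroundTruth(
        de=de,
        true_pairs=true_pairs,
        mirna_regulated_genes=mirna_regulated,
        meth_regulated_genes=set(meth_regulated),
        site_to_gene=site_to_gene,
        meth_site_direction=site_dir,
        gmcs=set(gmcs),
        hubs=hubs,
    )
    truth.validate()
    return truth


def _all_features(config: SyntheticConfig, layer: str) -> list[str]:
    if layer == "gene":
        return _ids("G", config.n_genes)
    if layer == "mirna":
        return [f"mir-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    if layer == "methylation":
        return [f"cg{i:06d}" for i in range(1, config.n_meth_sites + 1)]
    raise ValueError(f"unknown layer {layer!r}")


def generate_omics_studies(
    config: SyntheticConfig,
    layer: str,
    truth: GroundTruth | None = None,
) -> tuple[list[OmicsStudy], GroundTruth]:
    """Generate the heterogeneous study collection for one layer.

    Each study draws an independent per-feature batch shift (SD
    ``batch_sd``) and independent residual noise (SD ``noise_sd``); planted
    features shift tumor samples by direction x effect_size x u, where u is
    a per-study, per-feature heterogeneity factor ~ N(1, effect_heterogeneity_sd)
    truncated at 0.2 — this is what makes per-study DE lists overlap poorly
    while the rank product stays consistent. Methylation matrices are the
    logistic transform of the latent signal, so beta values stay in [0, 1].
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng(layer)
    features = _all_features(config, layer)
    n_feat = len(features)
    idx = {f: i for i, f in enumerate(features)}
    de_tab = truth.de[layer]
    de_idx = np.array([idx[f] for f in de_tab["feature"]], dtype=int)
    de_dir = de_tab["direction"].to_numpy(dtype=float)

    n = config.n_samples_per_class
    labels = pd.Series(["normal"] * n + ["tumor"] * n)
    if layer == "methylation":
        # logit-scale baselines; planted differential sites sit in the
        # responsive mid-range (a site saturated at beta ~ 0 or 1 cannot
        # change), matching the variable CpGs real studies select.
        baseline = rng.normal(0.0, 1.5, size=n_feat)
        baseline[de_idx] = rng.normal(0.0, 0.75, size=de_idx.size)
    else:
        baseline = rng.normal(7.0, 2.0, size=n_feat)  # log2 scale

    studies = []
    for k in range(config.n_studies_per_layer):
        study_id = f"SYN-{layer}-{k + 1}"
        batch = rng.normal(0.0, config.batch_sd, size=n_feat)
        mat = baseline[:, None] + batch[:, None] + rng.normal(
            0.0, config.noise_sd, size=(n_feat, 2 * n)
        )
        hetero = np.clip(
            rng.normal(1.0, config.effect_heterogeneity_sd, size=de_idx.size), 0.2, None
        )
        mat[np.ix_(de_idx, np.arange(n, 2 * n))] += (
            de_dir * config.effect_size * hetero
        )[:, None]
        if layer == "methylation":
            mat = 1.0 / (1.0 + np.exp(-mat))
        samples = [f"{study_id}-S{j + 1:03d}" for j in range(2 * n)]
        studies.append(
            OmicsStudy(
                study_id=study_id,
                layer=layer,
                matrix=pd.DataFrame(mat, index=features, columns=samples),
                classes=pd.Series(labels.to_numpy(), index=samples),
            )
        )
    return studies, truth


def generate_target_table(truth: GroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """True miRNA->gene pairs plus ``decoy_ratio`` x as many decoy pairs.

    Decoys are drawn without replacement from (miRNA, gene) combinations not
    planted as true; raises if the decoy pool is exhausted.
    """
    rng = config.rng("targets")
    mirnas = _all_features(config, "mirna")
    genes = _all_features(config, "gene")
    true_set = set(truth.true_pairs)
    n_decoys = int(config.decoy_ratio * len(true_set))
    pool_size = len(mirnas) * len(genes) - len(true_set)
    if n_decoys > pool_size:
        raise ValueError(f"decoy pool exhausted: need {n_decoys}, have {pool_size}")
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        m = mirnas[rng.integers(len(mirnas))]
        g = genes[rng.integers(len(genes))]
        if (m, g) not in true_set:
            decoys.add((m, g))
    rows = [(m, g, "true") for m, g in truth.true_pairs] + [
        (m, g, "decoy") for m, g in sorted(decoys)
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "source"])


@dataclass
class MatchedProfiles:
    """Gene and miRNA matrices over the same, identically ordered samples."""

    genes: pd.DataFrame
    mirnas: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.genes.columns) != list(self.mirnas.columns):
            raise ValueError("matched profiles must share identical sample ids in order")
        if self.genes.shape[1] < 3:
            raise ValueError("matched profiles need >= 3 samples for correlation")


def generate_matched_profiles(
    truth: GroundTruth, config: SyntheticConfig
) -> MatchedProfiles:
    """Matched-sample gene + miRNA expression with latent shared factors.

    Each planted miRNA carries a latent factor; the miRNA profile and its
    primary true targets load on it with weight 1 plus residual noise of SD
    ``matched_noise_sd`` (|R| >= 0.9 in expectation at the default). All
    other features are independent noise, so decoy pairs decorrelate.
    Target signs follow the planted expression directions (a repressing
    miRNA anti-correlates with its target).
    """
    rng = config.rng("matched")
    n = config.n_matched_samples
    samples = [f"MATCH-S{j + 1:03d}" for j in range(n)]
    genes = _all_features(config, "gene")
    mirnas = _all_features(config, "mirna")
    gdir = dict(zip(truth.de["gene"]["feature"], truth.de["gene"]["direction"]))
    mdir = dict(zip(truth.de["mirna"]["feature"], truth.de["mirna"]["direction"]))

    factors = {m: rng.normal(size=n) for m in truth.de_features("mirna")}
    sigma = config.matched_noise_sd
    gmat = rng.normal(size=(len(genes), n))
    mmat = rng.normal(size=(len(mirnas), n))
    m_index = {m: i for i, m in enumerate(mirnas)}
    g_index = {g: i for i, g in enumerate(genes)}
    for m, f in factors.items():
        mmat[m_index[m]] = f + sigma * rng.normal(size=n)
    primary: dict[str, str] = {}
    for m, g in truth.true_pairs:  # first listed pair per gene is primary
        primary.setdefault(g, m)
    for g, m in primary.items():
        sign = float(gdir.get(g, 1) * mdir.get(m, 1))
        gmat[g_index[g]] = sign * factors[m] + sigma * rng.normal(size=n)
    return MatchedProfiles(
        genes=pd.DataFrame(gmat, index=genes, columns=samples),
        mirnas=pd.DataFrame(mmat, index=mirnas, columns=samples),
    )


def generate_interactome(truth: GroundTruth, config: SyntheticConfig) -> nx.Graph:
    """Scale-free gene interactome with a planted rich-club disease module.

    A preferential-attachment (Barabasi-Albert, m=3) graph over all gene ids
    provides the scale-free background. The planted disease module is then
    wired on top of it, the way hubs sit inside dense cores in curated
    interactomes: every non-hub GMC gains edges to other planted DE genes,
    and each planted hub is rewired to the other hubs (rich club) plus all
    non-hub GMCs, with extra DE-gene partners added until its degree exceeds
    both the 99th percentile of non-hub degrees and the non-hub maximum.
    No self-loops or duplicate edges.
    """
    rng = config.rng("interactome")
    genes = _all_features(config, "gene")
    if config.n_genes < 5:
        raise ValueError("interactome needs >= 5 genes")
    m_ba = min(3, config.n_genes - 1)
    base = nx.barabasi_albert_graph(config.n_genes, m_ba, seed=int(rng.integers(2**31)))
    order = rng.permutation(config.n_genes)  # decouple BA hubs from gene ids
    G = nx.relabel_nodes(base, {i: genes[order[i]] for i in range(config.n_genes)})

    de_genes = sorted(truth.de_features("gene"))
    hubs = sorted(truth.hubs)
    core = sorted(truth.gmcs - truth.hubs)
    non_core_de = [g for g in de_genes if g not in truth.gmcs]

    # densify the disease module: non-hub GMCs link to other planted DE genes
    k_partner = min(15, max(2, len(non_core_de) // 4)) if non_core_de else 0
    for g in core:
        if k_partner:
            for p in rng.choice(non_core_de, size=k_partner, replace=False):
                if p != g:
                    G.add_edge(g, p)

    # hub rich club: drop the hubs' background edges and rewire each hub to
    # the other hubs plus every module gene, so hub neighborhoods consist of
    # well-connected nodes (the assortative core wiring of real interactomes);
    # degree fill-up uses background (non-planted) genes.
    for h in hubs:
        G.remove_edges_from(list(G.edges(h)))
    target = 0
    non_hub_deg = np.array([d for g, d in G.degree() if g not in truth.hubs])
    if non_hub_deg.size:
        target = int(max(np.percentile(non_hub_deg, 99), non_hub_deg.max() + 1))
    background = [g for g in genes if g not in truth.de_features("gene")]
    for h in hubs:
        for h2 in hubs:
            if h2 != h:
                G.add_edge(h, h2)
        for g in core:
            G.add_edge(h, g)
        pool = [g for g in background if g != h and not G.has_edge(h, g)]
        rng.shuffle(pool)
        i = 0
        while G.degree(h) < target and i < len(pool):
            G.add_edge(h, pool[i])
            i += 1
        if G.degree(h) < target:
            extra = [g for g in genes if g != h and not G.has_edge(h, g)]
            if len(extra) < target - G.degree(h):
                raise ValueError("requested hub degree impossible for graph size")
            for g in rng.choice(extra, size=target - G.degree(h), replace=False):
                G.add_edge(h, g)
    G.remove_edges_from(nx.selfloop_edges(G))
    return G


def generate_survival(
    truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Survival cohort whose hazard follows planted key-regulator expression.

    Each sample draws unit-normal expression for every planted hub (plus the
    other GMC genes as bystander columns); the true risk score is the sum of
    per-KR standardized expression (so ``hazard_coef`` is the per-unit
    log-hazard effect of each KR), the event time is exponential with
    log-hazard = hazard_coef x risk, and censoring is independent with
    probability ``censor_rate`` (censored times are uniform fractions of the
    latent event time). Returns a table with sample_id, time, event and one
    expression column per planted GMC gene, and stores the per-sample risk
    scores on the ground truth.
    """
    rng = config.rng("survival")
    n = config.n_survival_samples
    hubs = sorted(truth.hubs)
    others = sorted(truth.gmcs - truth.hubs)[:20]
    samples = [f"SURV-S{j + 1:03d}" for j in range(n)]
    expr = pd.DataFrame(
        rng.normal(size=(n, len(hubs) + len(others))),
        index=samples,
        columns=hubs + others,
    )
    z = (expr[hubs] - expr[hubs].mean()) / expr[hubs].std(ddof=0)
    risk = z.sum(axis=1)  # sum of per-KR standardized expression
    log_hazard = config.hazard_coef * risk
    if np.any(np.abs(log_hazard) > 50):
        raise ValueError("hazard overflow: |log-hazard| > 50 for extreme coefficient")
    times = rng.exponential(1.0, size=n) / np.exp(log_hazard.to_numpy())
    event = (rng.random(n) >= config.censor_rate).astype(int)
    censored = event == 0
    times = np.where(censored, times * rng.uniform(0.05, 1.0, size=n), times)
    table = pd.DataFrame({"time": times, "event": event}, index=samples)
    table = pd.concat([table, expr], axis=1)
    table.index.name = "sample_id"
    truth.risk_scores = risk
    return table, truth


def generate_all(config: SyntheticConfig) -> dict:
    """Generate every fixture for one config; returns a keyed bundle."""
    truth = make_ground_truth(config)
    bundle: dict = {"truth": truth, "config": config, "studies": {}}
    for layer in LAYERS:
        bundle["studies"][layer], _ = generate_omics_studies(config, layer, truth)
    bundle["targets"] = generate_target_table(truth, config)
    bundle["matched"] = generate_matched_profiles(truth, config)
    bundle["interactome"] = generate_interactome(truth, config)
    bundle["survival"], _ = generate_survival(truth, config)
    return bundle
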