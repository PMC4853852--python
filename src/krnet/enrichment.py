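"""KR-medoid partitioning, gene set enrichment and over-representation.

The CGMC genes are partitioned around the KR genes with a fixed-medoid
k-medoids assignment (Euclidean distance on expression profiles); each KR
cluster is then scored as a gene set against the phenotype-ranked CGMC gene
list with a weighted Kolmogorov-Smirnov running-sum enrichment statistic
(two-sample t ranking, phenotype-label permutations, NES and FDR q per the
standard procedure); a generic hypergeometric over-representation test
against user-supplied GMT gene sets completes the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_GSEA_WEIGHT = 1.0
DEFAULT_GSEA_N_PERM = 1000
GSEA_P_THRESHOLD = 0.05
GSEA_Q_THRESHOLD = 0.25


# ---------------------------------------------------------------- PAM

@dataclass
class KrClustering:
    """Partition of genes around fixed KR medoids."""

    assignment: pd.Series  # gene -> medoid
    medoids: list[str]

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {m: [] for m in self.medoids}
        for g, m in self.assignment.items():
            out[m].append(g)
        return out


def pam_partition(
    expr: pd.DataFrame,
    medoid_genes: list[str],
    allow_swap: bool = False,
) -> KrClustering:
    """Assign every gene to the nearest KR medoid (Euclidean distance).

    Medoids are fixed by default — the partition is *around* the KR genes,
    so the swap phase of full PAM is disabled; ties go to the medoid listed
    first (callers pass KRs sorted by AR score). ``allow_swap=True`` enables
    a greedy swap phase for comparison, in which medoids may be replaced.
    """
    medoids = list(medoid_genes)
    missing = [m for m in medoids if m not in expr.index]
    if missing:
        raise ValueError(f"medoid genes absent from matrix: {missing}")
    if len(expr) <= len(medoids):
        raise ValueError("need at least one non-medoid gene")

    def assign(meds: list[str]) -> tuple[pd.Series, float]:
        X = expr.to_numpy(dtype=float)
        M = expr.loc[meds].to_numpy(dtype=float)
        d = np.sqrt(((X[:, None, :] - M[None, :, :]) ** 2).sum(axis=2))
        choice = d.argmin(axis=1)  # argmin takes the first minimum: tie rule
        cost = d[np.arange(len(X)), choice].sum()
        return pd.Series([meds[i] for i in choice], index=expr.index), cost

    if allow_swap:
        current = medoids
        _, best_cost = assign(current)
        improved = True
        while improved:
            improved = False
            for i, m in enumerate(current):
                for g in expr.index:
                    if g in current:
                        continue
                    cand = current[:i] + [g] + current[i + 1:]
                    _, cost = assign(cand)
                    if cost + 1e-12 < best_cost:
                        current, best_cost, improved = cand, cost, True
        medoids = current
    assignment, _ = assign(medoids)
    assignment.loc[medoids] = medoids  # each medoid belongs to its own cluster
    return KrClustering(assignment=assignment, medoids=medoids)


# ---------------------------------------------------------------- GSEA

def ranked_gene_list(expr: pd.DataFrame, classes: pd.Series) -> pd.Series:
    """Genes ordered by the two-sample t statistic, tumor vs normal.

    Returns a Series of metric values indexed by gene, sorted descending;
    ties are broken by gene identifier for determinism. Constant genes get
    metric 0.
    """
    labels = classes.reindex(expr.columns)
    t_mask = (labels == "tumor").to_numpy()
    x = expr.to_numpy(dtype=float)
    res = stats.ttest_ind(x[:, t_mask], x[:, ~t_mask], axis=1, equal_var=False)
    metric = np.nan_to_num(np.asarray(res.statistic, dtype=float), nan=0.0,
                           posinf=0.0, neginf=0.0)
    s = pd.Series(metric, index=expr.index)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def gsea_es(
    ranked: pd.Series,
    gene_set,
    weight_p: float = DEFAULT_GSEA_WEIGHT,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running-sum enrichment score of one gene set.

    Hits add |metric|^p normalized by the in-set total; misses subtract
    1/(N - set size). ES is the maximum deviation of the running sum from
    zero (signed); the leading edge is the set members at or before the
    extremum (after it for negative ES).
    """
    genes = list(ranked.index)
    in_set = np.array([g in set(gene_set) for g in genes])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set equals the whole ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-hit metrics exactly zero: fall back to unweighted hits
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    step = hit_w / denom - (~in_set) / float(len(genes) - n_hit)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], in_set[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_max:], in_set[i_max:]) if h]
    return es, running, leading


def _perm_metric(x: np.ndarray, t_mask: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(x[:, t_mask], x[:, ~t_mask], axis=1, equal_var=False)
    return np.nan_to_num(np.asarray(res.statistic, dtype=float), nan=0.0,
                         posinf=0.0, neginf=0.0)


def gsea(
    expr: pd.DataFrame,
    classes: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = DEFAULT_GSEA_N_PERM,
    seed: int = 0,
    weight_p: float = DEFAULT_GSEA_WEIGHT,
    p_threshold: float = GSEA_P_THRESHOLD,
    q_threshold: float = GSEA_Q_THRESHOLD,
) -> pd.DataFrame:
    """Phenotype-permutation GSEA over a collection of gene sets.

    The ranking metric is the per-gene two-sample t statistic; each
    permutation shuffles the class labels, regenerates the ranked list and
    recomputes every set's ES. NES = ES / mean |same-sign null ES|; nominal
    p is the same-sign null tail fraction; FDR q follows the standard
    NES-based procedure (ratio of null to observed tail fractions of the
    normalized scores, made monotone). A set is flagged significant at
    nominal p <= ``p_threshold`` and q <= ``q_threshold``.
    """
    expr = expr[sorted(expr.columns)]  # canonical sample order: results are
    labels = classes.reindex(expr.columns)  # invariant to input arrangement
    t_mask = (labels == "tumor").to_numpy()
    if t_mask.sum() < 3 or (~t_mask).sum() < 3:
        raise ValueError("each class needs >= 3 samples for phenotype permutation")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    sets = {name: [g for g in gs if g in expr.index] for name, gs in gene_sets.items()}

    def es_all(metric: np.ndarray) -> dict[str, float]:
        s = pd.Series(metric, index=genes)
        order = sorted(s.index, key=lambda g: (-s[g], g))
        ranked = s.loc[order]
        return {name: gsea_es(ranked, gs, weight_p)[0] for name, gs in sets.items()}

    obs_metric = _perm_metric(x, t_mask)
    obs = es_all(obs_metric)
    null = {name: np.empty(n_perm) for name in sets}
    for b in range(n_perm):
        perm = rng.permutation(t_mask)
        m = _perm_metric(x, perm)
        for name, e in es_all(m).items():
            null[name][b] = e

    rows = []
    nes_null_all = []
    for name, es in obs.items():
        nn = null[name]
        same = nn[nn >= 0] if es >= 0 else nn[nn < 0]
        mean_abs = np.abs(same).mean() if same.size else np.nan
        nes = es / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        p = float((np.abs(same) >= abs(es)).mean()) if same.size else 1.0
        pos = nn[nn >= 0]
        neg = nn[nn < 0]
        nes_null = np.concatenate([
            pos / pos.mean() if pos.size else pos,
            neg / np.abs(neg).mean() if neg.size else neg,
        ])
        nes_null_all.append(nes_null)
        s_ranked = pd.Series(obs_metric, index=genes)
        order = sorted(s_ranked.index, key=lambda g: (-s_ranked[g], g))
        _, _, leading = gsea_es(s_ranked.loc[order], sets[name], weight_p)
        rows.append((name, len(sets[name]), es, nes, p, leading))
    table = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p", "leading_edge"])
    table = table.set_index("name")

    null_nes = np.concatenate(nes_null_all) if nes_null_all else np.array([])
    qs = []
    for name, row in table.iterrows():
        nes = row["nes"]
        if not np.isfinite(nes):
            qs.append(1.0)
            continue
        if nes >= 0:
            num_pool = null_nes[null_nes >= 0]
            num = (num_pool >= nes).mean() if num_pool.size else 1.0
            obs_pool = table["nes"][table["nes"] >= 0]
            den = (obs_pool >= nes).mean() if len(obs_pool) else 1.0
        else:
            num_pool = null_nes[null_nes < 0]
            num = (num_pool <= nes).mean() if num_pool.size else 1.0
            obs_pool = table["nes"][table["nes"] < 0]
            den = (obs_pool <= nes).mean() if len(obs_pool) else 1.0
        qs.append(min(1.0, num / den) if den > 0 else 1.0)
    table["q"] = qs
    # enforce monotonicity of q in |NES| within each sign
    for sign in (1, -1):
        mask = (table["nes"] >= 0) if sign == 1 else (table["nes"] < 0)
        idx = table.index[mask]
        if len(idx):
            ordered = table.loc[idx, "nes"].abs().sort_values(ascending=False).index
            table.loc[ordered, "q"] = np.minimum.accumulate(table.loc[ordered, "q"].to_numpy())
    table["significant"] = (table["p"] <= p_threshold) & (table["q"] <= q_threshold)
    return table


# ------------------------------------------------- over-representation

def overrepresentation(
    query_set,
    universe,
    annotations: dict[str, list[str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set against GMT terms.

    Terms are intersected with the universe; p is the upper hypergeometric
    tail P(X >= overlap); q is BH across terms; fold enrichment is the
    observed/expected overlap ratio.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set) & universe
    N, n = len(universe), len(query)
    rows = []
    for term, members in annotations.items():
        K = len(set(members) & universe)
        if K == 0:
            continue
        k = len(set(members) & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        expected = K * n / N
        fold = k / expected if expected > 0 else np.nan
        rows.append((term, K, k, p, fold))
    table = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p", "fold"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < q_threshold
        table = table.sort_values("p").reset_index(drop=True)
    return table
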