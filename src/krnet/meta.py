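"""Rank-products meta-analysis across heterogeneous studies of one omics layer.

Individual case/control studies of the same layer rarely agree at strict
per-study significance cutoffs; the rank-product statistic combines them
non-parametrically. Fold changes are converted to within-comparison ranks
across features (descending for the "up" analysis, ascending for "down")
and the rank product RP is the geometric mean of a feature's ranks —
features consistently extreme in the same direction get RP near 1.

Two fold-change modes are supported:

- ``pairwise`` (default): every (tumor, normal) sample pair within a study
  contributes one fold-change vector, the original rank-product scheme for
  unpaired two-class data. Many independent rank draws concentrate the
  geometric mean sharply for genuinely differential features.
- ``per-study``: one fold change per study (difference of class means),
  the cross-study mode of meta-analysis toolkits. With one sample per
  class the two modes coincide.

Significance is assessed by class-label permutations performed
independently within each study: the expected count E(g) of null RPs at
least as extreme as the observed one yields both a per-feature permutation
p-value (E / n_features) and the percentage-of-false-positives measure
pfp = E / rank-position, the rank-product convention for FDR. The pipeline
flags features at pfp <= 0.05 by default.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import OmicsStudy

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")
FC_MODES = ("pairwise", "per-study")
DEFAULT_PFP_THRESHOLD = 0.05
DEFAULT_N_PERM = 1000


def fold_changes(study: OmicsStudy) -> pd.Series:
    """Per-feature log2 fold change, tumor mean minus normal mean."""
    t = study.tumor_mask
    x = study.matrix.to_numpy(dtype=float)
    return pd.Series(x[:, t].mean(axis=1) - x[:, ~t].mean(axis=1), index=study.matrix.index)


def harmonize_features(studies: list[OmicsStudy]) -> list[str]:
    """Shared feature universe: sorted intersection of study feature ids."""
    common = set(studies[0].feature_ids)
    for s in studies[1:]:
        common &= set(s.feature_ids)
    if not common:
        raise ValueError("empty feature intersection across studies")
    dropped = sum(len(s.feature_ids) for s in studies) - len(studies) * len(common)
    if dropped:
        logger.info("feature harmonization dropped %d study-feature entries", dropped)
    return sorted(common)


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def _fc_matrix(x: np.ndarray, tumor: np.ndarray, mode: str) -> np.ndarray:
    """Fold-change vectors for one study: comparisons x features."""
    if mode == "per-study":
        return (x[:, tumor].mean(axis=1) - x[:, ~tumor].mean(axis=1))[None, :]
    if mode == "pairwise":
        t = x[:, tumor]  # features x n_t
        n = x[:, ~tumor]  # features x n_n
        d = t[:, :, None] - n[:, None, :]  # features x n_t x n_n
        return d.reshape(x.shape[0], -1).T
    raise ValueError(f"fc_mode must be one of {FC_MODES}, got {mode!r}")


def _mean_log_ranks(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """(sum log up-ranks, sum log down-ranks, n_comparisons) for one study."""
    n = fc.shape[1]
    r_up = rankdata(-fc, method="average", axis=1)
    r_down = (n + 1.0) - r_up  # average-tie ranks mirror exactly
    return np.log(r_up).sum(axis=0), np.log(r_down).sum(axis=0), fc.shape[0]


def _rp_both(mats, masks, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Rank products (up, down) over all studies' comparison vectors."""
    s_up = s_down = 0.0
    k = 0
    for x, tumor in zip(mats, masks):
        lu, ld, nk = _mean_log_ranks(_fc_matrix(x, tumor, mode))
        s_up, s_down, k = s_up + lu, s_down + ld, k + nk
    return np.exp(s_up / k), np.exp(s_down / k)


def rank_product(
    studies: list[OmicsStudy], direction: str, fc_mode: str = "pairwise"
) -> pd.Series:
    """Observed rank product per feature over the harmonized feature universe."""
    _check_direction(direction)
    if not studies:
        raise ValueError("no studies")
    if len(studies) == 1:
        logger.warning("rank_product called with a single study; RP equals its rank")
    features = harmonize_features(studies)
    mats = [s.matrix.reindex(features).to_numpy(dtype=float) for s in studies]
    masks = [s.tumor_mask for s in studies]
    up, down = _rp_both(mats, masks, fc_mode)
    return pd.Series(up if direction == "up" else down, index=features, name=f"rp_{direction}")


def _study_rng(seed: int, study_id: str) -> np.random.Generator:
    """Stable per-study permutation stream, invariant to study input order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(study_id.encode())])


def _pfp_tables(
    studies: list[OmicsStudy],
    n_perm: int,
    seed: int,
    fc_mode: str,
) -> dict[str, pd.DataFrame]:
    """Both one-sided permutation analyses in a single pass."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    features = harmonize_features(studies)
    n = len(features)
    mats = [s.matrix.reindex(features).to_numpy(dtype=float) for s in studies]
    masks = [s.tumor_mask for s in studies]
    obs = dict(zip(DIRECTIONS, _rp_both(mats, masks, fc_mode)))

    rngs = [_study_rng(seed, s.study_id) for s in studies]
    null = {d: np.empty((n_perm, n)) for d in DIRECTIONS}
    for b in range(n_perm):
        perms = [rng.permutation(mask) for rng, mask in zip(rngs, masks)]
        up, down = _rp_both(mats, perms, fc_mode)
        null["up"][b] = up
        null["down"][b] = down

    out = {}
    for d in DIRECTIONS:
        pool = np.sort(null[d].ravel())
        E = np.searchsorted(pool, obs[d], side="right") / n_perm
        rank_pos = rankdata(obs[d], method="average")
        pfp = E / rank_pos
        out[d] = pd.DataFrame(
            {
                "rp": obs[d],
                "rank": rank_pos,
                "E": E,
                "pval": E / n,
                "pfp": pfp,
                "pfp_capped": np.minimum(pfp, 1.0),
            },
            index=pd.Index(features, name="feature"),
        )
    return out


def permutation_pfp(
    studies: list[OmicsStudy],
    direction: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fc_mode: str = "pairwise",
) -> pd.DataFrame:
    """Permutation-based significance of the observed rank products.

    Class labels are shuffled independently within each study (class sizes
    preserved) and the RPs recomputed. For feature g, E(g) is the average
    number per permutation of null RP values (over all features) at or
    below the observed RP(g):

    - pval(g) = E(g) / n_features  — per-feature permutation p-value
    - pfp(g)  = E(g) / rank-position of g by observed RP — the expected
      proportion of false positives if everything down to g is called.

    Returns a DataFrame with columns rp, rank, E, pval, pfp, pfp_capped.
    """
    _check_direction(direction)
    return _pfp_tables(studies, n_perm, seed, fc_mode)[direction]


@dataclass
class MetaSignature:
    """Layer-level meta-signature from the rank-products analysis.

    ``table`` is indexed by feature with, per direction d in {up, down},
    columns rp_d, rank_d, E_d, pval_d, pfp_d, plus per-study log2fc_<id>
    columns, a consensus ``direction`` and a boolean ``significant`` flag
    at ``pfp_threshold``. A feature significant in both one-sided analyses
    (possible under ties) is resolved to the direction with smaller pfp.
    """

    layer: str
    table: pd.DataFrame
    pfp_threshold: float = DEFAULT_PFP_THRESHOLD
    n_perm: int = DEFAULT_N_PERM
    study_ids: list[str] = field(default_factory=list)

    @property
    def significant_features(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def direction_of(self, feature: str) -> str:
        return str(self.table.loc[feature, "direction"])


def build_meta_signature(
    studies: list[OmicsStudy],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pfp_threshold: float = DEFAULT_PFP_THRESHOLD,
    fc_mode: str = "pairwise",
) -> MetaSignature:
    """Run both one-sided rank-product analyses and merge into a signature."""
    layers = {s.layer for s in studies}
    if len(layers) != 1:
        raise ValueError(f"studies span multiple layers: {layers}")
    layer = layers.pop()
    per_dir = _pfp_tables(studies, n_perm, seed, fc_mode)
    features = per_dir["up"].index
    table = pd.DataFrame(index=features)
    for d in DIRECTIONS:
        for col in ("rp", "rank", "E", "pval", "pfp"):
            table[f"{col}_{d}"] = per_dir[d][col]
    features_list = list(features)
    for s in sorted(studies, key=lambda s: s.study_id):
        table[f"log2fc_{s.study_id}"] = fold_changes(s).reindex(features_list).to_numpy()

    sig_up = table["pfp_up"] <= pfp_threshold
    sig_down = table["pfp_down"] <= pfp_threshold
    # direction: the more extreme one-sided result; both-significant resolved
    # to the smaller pfp (smaller RP breaks exact pfp ties).
    up_wins = (table["pfp_up"] < table["pfp_down"]) | (
        (table["pfp_up"] == table["pfp_down"]) & (table["rp_up"] <= table["rp_down"])
    )
    table["direction"] = np.where(up_wins, "up", "down")
    table["significant"] = np.where(up_wins, sig_up, sig_down)
    n_sig = int(table["significant"].sum())
    logger.info(
        "%s meta-signature: %d/%d features significant at pfp<=%g (%d perms)",
        layer, n_sig, len(table), pfp_threshold, n_perm,
    )
    return MetaSignature(
        layer=layer,
        table=table,
        pfp_threshold=pfp_threshold,
        n_perm=n_perm,
        study_ids=[s.study_id for s in studies],
    )
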