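"""Shared fixtures: toy studies, handmade signatures and a session bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from krnet.meta import MetaSignature, build_meta_signature
from krnet.preprocess import OmicsStudy
from krnet.synthetic import SyntheticConfig, generate_all


def make_study(
    values: np.ndarray,
    study_id: str = "S1",
    layer: str = "gene",
    n_normal: int | None = None,
    feature_ids: list[str] | None = None,
) -> OmicsStudy:
    """Wrap a features x samples array into an OmicsStudy (half/half classes)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    n_normal = n_samp // 2 if n_normal is None else n_normal
    features = feature_ids or [f"F{i:03d}" for i in range(n_feat)]
    samples = [f"{study_id}-{j}" for j in range(n_samp)]
    labels = ["normal"] * n_normal + ["tumor"] * (n_samp - n_normal)
    return OmicsStudy(
        study_id=study_id,
        layer=layer,
        matrix=pd.DataFrame(values, index=features, columns=samples),
        classes=pd.Series(labels, index=samples),
    )


def make_signature(
    significant: dict[str, str],
    other_features: list[str] = (),
    layer: str = "gene",
) -> MetaSignature:
    """Handmade MetaSignature: mapping feature -> direction for significant ones."""
    feats = list(significant) + list(other_features)
    table = pd.DataFrame(index=pd.Index(feats, name="feature"))
    table["direction"] = [significant.get(f, "up") for f in feats]
    table["significant"] = [f in significant for f in feats]
    for d in ("up", "down"):
        table[f"pfp_{d}"] = [
            0.01 if (f in significant and significant[f] == d) else 0.5 for f in feats
        ]
        table[f"rp_{d}"] = 1.0
    table["log2fc_S1"] = [1.0 if significant.get(f) == "up" else -1.0 for f in feats]
    return MetaSignature(layer=layer, table=table, study_ids=["S1"])


@pytest.fixture(scope="session")
def default_bundle():
    """Full synthetic fixture bundle at the default study conditions."""
    return generate_all(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_signatures(default_bundle):
    """Meta-signatures for all three layers on the session bundle."""
    return {
        layer: build_meta_signature(default_bundle["studies"][layer], n_perm=80, seed=11)
        for layer in ("gene", "mirna", "methylation")
    }
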