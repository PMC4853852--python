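"""PAM partitioning, the weighted KS enrichment score, and over-representation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from krnet.enrichment import (
    gsea,
    gsea_es,
    overrepresentation,
    pam_partition,
    ranked_gene_list,
)


def brute_force_running_sum(metric, membership, p=1.0):
    """Plain-python re-derivation of the weighted KS running sum."""
    n = len(metric)
    nh = sum(membership)
    denom = sum(abs(m) ** p for m, h in zip(metric, membership) if h)
    run, cur = [], 0.0
    for m, h in zip(metric, membership):
        if h:
            cur += (abs(m) ** p) / denom if denom else 1.0 / nh
        else:
            cur -= 1.0 / (n - nh)
        run.append(cur)
    i = max(range(n), key=lambda i: abs(run[i]))
    return run[i], run


class TestGseaEs:
    def test_worked_example(self):
        ranked = pd.Series([3.0, 2, 1, -1, -2], index=list("ABCDE"))
        es, running, leading = gsea_es(ranked, {"A", "C"})
        assert es == pytest.approx(0.75, abs=1e-12)
        np.testing.assert_allclose(
            running, [0.75, 0.75 - 1 / 3, 0.75 - 1 / 3 + 0.25, 1 / 3, 0.0], atol=1e-12
        )
        assert leading == ["A"]

    def test_top_gene_set_scores_one(self):
        ranked = pd.Series([5.0, 4, 3, 2, 1], index=list("ABCDE"))
        es, _, _ = gsea_es(ranked, {"A"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_negative_es(self):
        ranked = pd.Series([3.0, 2, 1, -1, -4], index=list("ABCDE"))
        es, _, _ = gsea_es(ranked, {"E"})
        assert es < 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 21))
            metric = rng.normal(size=n)
            metric[::-1].sort()
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            ranked = pd.Series(metric, index=genes)
            es, running, _ = gsea_es(ranked, members)
            exp_es, exp_run = brute_force_running_sum(
                metric, [g in members for g in genes]
            )
            assert es == pytest.approx(exp_es, abs=1e-12)
            np.testing.assert_allclose(running, exp_run, atol=1e-12)

    def test_unweighted_complement_antisymmetry(self):
        # with p=0 and any metric, the complement's running sum is the negative
        rng = np.random.default_rng(1)
        metric = np.sort(rng.normal(size=12))[::-1]
        genes = [f"g{i}" for i in range(12)]
        ranked = pd.Series(metric, index=genes)
        members = set(genes[:5])
        _, run_a, _ = gsea_es(ranked, members, weight_p=0.0)
        _, run_b, _ = gsea_es(ranked, set(genes) - members, weight_p=0.0)
        # unequal set sizes scale the two sums, but sign flips pointwise
        np.testing.assert_allclose(np.sign(run_a[:-1]), -np.sign(run_b[:-1]))

    def test_degenerate_sets_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["A", "B"])
        with pytest.raises(ValueError):
            gsea_es(ranked, {"Z"})
        with pytest.raises(ValueError):
            gsea_es(ranked, {"A", "B"})


class TestGsea:
    def _data(self, seed=0, shift=2.0):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(size=(60, 20)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(20)],
        )
        classes = pd.Series(["normal"] * 10 + ["tumor"] * 10, index=expr.columns)
        expr.iloc[:10, 10:] += shift
        return expr, classes

    def test_planted_up_set_enriched(self):
        hits = 0
        for seed in range(10):
            expr, classes = self._data(seed)
            res = gsea(expr, classes, {"planted": [f"g{i}" for i in range(10)]},
                       n_perm=100, seed=seed)
            row = res.loc["planted"]
            hits += (row["es"] > 0) and (row["p"] <= 0.05)
        assert hits >= 9

    def test_seeded_determinism(self):
        expr, classes = self._data(3)
        sets = {"a": [f"g{i}" for i in range(10)], "b": [f"g{i}" for i in range(30, 45)]}
        r1 = gsea(expr, classes, sets, n_perm=50, seed=9)
        r2 = gsea(expr, classes, sets, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_sample_order_invariance(self):
        expr, classes = self._data(4)
        perm = np.random.default_rng(0).permutation(expr.columns)
        sets = {"a": [f"g{i}" for i in range(10)]}
        r1 = gsea(expr, classes, sets, n_perm=50, seed=2)
        r2 = gsea(expr[perm], classes[perm], sets, n_perm=50, seed=2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_pvalues_calibrated(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(size=(60, 20)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(20)],
        )
        classes = pd.Series(["normal"] * 10 + ["tumor"] * 10, index=expr.columns)
        sets = {f"s{k}": list(rng.choice(expr.index, 10, replace=False)) for k in range(100)}
        res = gsea(expr, classes, sets, n_perm=100, seed=6)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_small_class_rejected(self):
        expr, classes = self._data(6)
        bad = classes.copy()
        bad.iloc[:18] = "normal"
        with pytest.raises(ValueError, match="class"):
            gsea(expr, bad, {"a": ["g1", "g2"]}, n_perm=10)

    def test_ranked_list_strictly_ordered_deterministic_ties(self):
        expr, classes = self._data(7)
        expr.iloc[5] = expr.iloc[4].to_numpy()  # force a metric tie
        r = ranked_gene_list(expr, classes)
        m = r.to_numpy()
        assert all(m[i] > m[i + 1] or (m[i] == m[i + 1] and r.index[i] < r.index[i + 1])
                   for i in range(len(m) - 1))


class TestPamPartition:
    def _expr(self, seed=0):
        rng = np.random.default_rng(seed)
        med = pd.DataFrame(rng.normal(size=(2, 10)), index=["m0", "m1"])
        rows = {}
        for i in range(40):
            rows[f"x{i}"] = med.iloc[i % 2] + 0.1 * rng.normal(size=10)
        return pd.concat([med, pd.DataFrame(rows).T])

    def test_identical_profile_joins_its_medoid(self):
        expr = self._expr()
        expr.loc["twin"] = expr.loc["m1"]
        cl = pam_partition(expr, ["m0", "m1"])
        assert cl.assignment["twin"] == "m1"

    def test_equidistant_tie_goes_to_first_medoid(self):
        expr = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [-1.0, 0.0], "g": [0.0, 0.0]},
        ).T
        cl = pam_partition(expr, ["a", "b"])
        assert cl.assignment["g"] == "a"

    def test_planted_clusters_recovered(self):
        expr = self._expr(1)
        cl = pam_partition(expr, ["m0", "m1"])
        correct = np.mean(
            [cl.assignment[f"x{i}"] == f"m{i % 2}" for i in range(40)]
        )
        assert correct >= 0.95

    def test_deterministic_and_gene_order_invariant(self):
        expr = self._expr(2)
        a = pam_partition(expr, ["m0", "m1"]).assignment
        shuffled = expr.sample(frac=1.0, random_state=3)
        b = pam_partition(shuffled, ["m0", "m1"]).assignment
        assert (a.sort_index() == b.sort_index()).all()

    def test_medoids_partition_the_set(self):
        cl = pam_partition(self._expr(4), ["m0", "m1"])
        members = [g for c in cl.clusters.values() for g in c]
        assert sorted(members) == sorted(cl.assignment.index)
        assert cl.assignment["m0"] == "m0" and cl.assignment["m1"] == "m1"

    def test_missing_medoid_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            pam_partition(self._expr(5), ["nope"])


class TestOverrepresentation:
    def test_worked_hypergeometric_example(self):
        universe = [f"g{i}" for i in range(20)]
        res = overrepresentation(universe[:5], universe, {"t": universe[:4]})
        assert res.iloc[0]["p"] == pytest.approx(16 / 15504, abs=1e-12)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = overrepresentation(universe[:5], universe, {"t": universe[10:14]})
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_term_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = overrepresentation(universe[:3], universe, {"t": universe})
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(set(), set(), {"t": ["a"]})
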