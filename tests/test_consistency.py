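"""Cosine similarity, product diversity, strain consistency and nulls."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from chemovar import consistency as cs
from chemovar.errors import ChemovarError


def brute_cosine(u, v):
    num = sum(a * b for a, b in zip(u, v))
    den = (sum(a * a for a in u) ** 0.5) * (sum(b * b for b in v) ** 0.5)
    return num / den


def product_table(profiles, names, n_samples=5, clusters=None, labels=None):
    df = pd.DataFrame(profiles, columns=[f"t{i}" for i in range(len(profiles[0]))])
    df["strain_name"] = names
    df["producer_id"] = [f"p{i}" for i in range(len(df))]
    df["n_samples"] = n_samples
    if clusters is not None:
        df["cluster"] = clusters
    if labels is not None:
        df["category_label"] = labels
    return df


PROFILE_COLS = ["t0", "t1", "t2"]


class TestCosine:
    def test_identical_vectors(self):
        assert cs.cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cs.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form(self):
        assert cs.cosine_similarity([1, 1], [1, 0]) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_norm_raises(self):
        with pytest.raises(ChemovarError):
            cs.cosine_similarity([0, 0], [1, 0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            u, v = rng.exponential(size=(2, 6))
            assert cs.cosine_similarity(u, v) == pytest.approx(
                brute_cosine(u, v), abs=1e-10
            )

    def test_nonnegative_profiles_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.exponential(size=(2, 5))
            s = cs.cosine_similarity(u, v)
            assert 0.0 <= s <= 1.0 + 1e-12


class TestProductDiversity:
    def test_identical_products_have_zero_diversity(self):
        df = product_table([[1, 2, 3]] * 4, ["a"] * 4)
        df["chemotype"] = "THC-dominant"
        res = cs.product_diversity(df, PROFILE_COLS)
        np.testing.assert_allclose(res.per_product["THC-dominant"], 0.0, atol=1e-12)

    def test_multicluster_chemotype_more_diverse(self):
        rng = np.random.default_rng(2)
        diverse = [
            [1, 0.05, 0.05] if i % 3 == 0 else ([0.05, 1, 0.05] if i % 3 == 1 else [0.05, 0.05, 1])
            for i in range(30)
        ]
        uniform = [[0.05, 1, 0.08]] * 30
        df = product_table(
            np.array(diverse + uniform) + rng.uniform(0, 0.01, (60, 3)),
            [f"s{i}" for i in range(60)],
        )
        df["chemotype"] = ["THC-dominant"] * 30 + ["CBD-dominant"] * 30
        res = cs.product_diversity(df, PROFILE_COLS)
        assert res.per_product["THC-dominant"].mean() > res.per_product["CBD-dominant"].mean()
        assert res.comparisons.loc[0, "significant"]

    def test_two_products_share_their_mutual_distance(self):
        df = product_table([[1, 0, 0], [0, 1, 0]], ["a", "b"])
        df["chemotype"] = "Balanced"
        res = cs.product_diversity(df, PROFILE_COLS)
        np.testing.assert_allclose(res.per_product["Balanced"], 1.0)

    def test_chemotype_with_single_product_excluded_with_warning(self):
        df = product_table([[1, 0, 0], [1, 0.1, 0], [0, 1, 0]], ["a", "b", "c"])
        df["chemotype"] = ["THC-dominant", "THC-dominant", "CBD-dominant"]
        with pytest.warns(UserWarning):
            res = cs.product_diversity(df, PROFILE_COLS)
        assert "CBD-dominant" not in res.per_product


class TestEligibility:
    def _products(self, spec):
        """spec: list of (strain, n_products, n_samples_each)."""
        rows = []
        for strain, n_prod, n_samp in spec:
            for i in range(n_prod):
                rows.append(
                    {"strain_name": strain, "producer_id": f"{strain}-{i}",
                     "n_samples": n_samp}
                )
        return pd.DataFrame(rows)

    def test_five_by_five_is_eligible(self):
        assert cs.eligible_strains(self._products([("a", 5, 5)])) == ["a"]

    def test_four_producers_with_ten_samples_not_eligible(self):
        assert cs.eligible_strains(self._products([("a", 4, 10)])) == []

    def test_one_short_producer_breaks_eligibility(self):
        df = self._products([("a", 4, 5)])
        df = pd.concat(
            [df, pd.DataFrame([{"strain_name": "a", "producer_id": "a-x",
                                "n_samples": 4}])],
            ignore_index=True,
        )
        assert cs.eligible_strains(df) == []


class TestStrainConsistency:
    def test_identical_products_similarity_one(self):
        df = product_table([[1, 2, 3]] * 5, ["a"] * 5)
        res = cs.strain_consistency(df, ["a"], PROFILE_COLS)
        assert res.loc[0, "mean_similarity"] == pytest.approx(1.0)

    def test_two_orthogonal_profile_groups_combinatorial_oracle(self):
        # 4 products: 2 of profile X, 2 of orthogonal profile Y.
        # Each product's mean similarity to the other 3 = 1/3 (one same-
        # profile partner of similarity 1, two orthogonal of 0).
        df = product_table([[1, 0, 0]] * 2 + [[0, 1, 0]] * 2, ["a"] * 4)
        res = cs.strain_consistency(df, ["a"], PROFILE_COLS)
        assert res.loc[0, "mean_similarity"] == pytest.approx(1 / 3)

    def test_two_product_strain_shares_one_value(self):
        df = product_table([[1, 1, 0], [1, 0, 0]], ["a", "a"])
        res = cs.strain_consistency(df, ["a"], PROFILE_COLS)
        assert res.loc[0, "mean_similarity"] == pytest.approx(np.sqrt(2) / 2)

    def test_single_product_strain_raises(self):
        df = product_table([[1, 0, 0]], ["a"])
        with pytest.raises(ChemovarError):
            cs.strain_consistency(df, ["a"], PROFILE_COLS)

    def test_invariant_to_product_order_and_global_scale(self):
        rng = np.random.default_rng(3)
        profiles = rng.exponential(size=(8, 3))
        names = ["a"] * 4 + ["b"] * 4
        df1 = product_table(profiles, names)
        df2 = product_table(profiles[::-1] * 10.0, names[::-1])
        r1 = cs.strain_consistency(df1, ["a", "b"], PROFILE_COLS)
        r2 = cs.strain_consistency(df2, ["a", "b"], PROFILE_COLS)
        pd.testing.assert_frame_equal(r1, r2)


class TestShuffledNameNull:
    def test_identical_products_every_rep_one(self):
        df = product_table([[1, 2, 3]] * 6, ["a"] * 3 + ["b"] * 3)
        null = cs.shuffled_name_null(df, reps=20, seed=0, profile_cols=PROFILE_COLS)
        np.testing.assert_allclose(null.values, 1.0, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        df = product_table(rng.exponential(size=(10, 3)), ["a", "b"] * 5)
        n1 = cs.shuffled_name_null(df, reps=15, seed=7, profile_cols=PROFILE_COLS)
        n2 = cs.shuffled_name_null(df, reps=15, seed=7, profile_cols=PROFILE_COLS)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_matches_exhaustive_permutation_oracle_on_8_products(self):
        """The 200-rep null mean agrees with the exact permutation expectation."""
        rng = np.random.default_rng(5)
        profiles = rng.exponential(size=(8, 3))
        names = ["a"] * 4 + ["b", "b", "c", "c"]
        df = product_table(profiles, names)

        sim = np.array(
            [[brute_cosine(profiles[i], profiles[j]) for j in range(8)]
             for i in range(8)]
        )

        def stat(perm_names):
            scores, weights = [], []
            for name in set(perm_names):
                idx = [i for i, n in enumerate(perm_names) if n == name]
                if len(idx) < 2:
                    continue
                vals = [
                    np.mean([sim[i, j] for j in idx if j != i]) for i in idx
                ]
                scores.append(np.mean(vals))
                weights.append(len(idx))
            return np.average(scores, weights=weights)

        exact = np.mean([stat(p) for p in permutations(names)])
        null = cs.shuffled_name_null(df, reps=200, seed=1, profile_cols=PROFILE_COLS)
        mc_err = 3 * null.values.std(ddof=1) / np.sqrt(null.reps)
        assert abs(null.mean - exact) < max(mc_err, 1e-6)


class TestTopClusterShare:
    def test_three_of_four_in_cluster_one(self):
        df = product_table([[1, 0, 0]] * 4, ["a"] * 4, clusters=["I", "I", "I", "II"])
        res = cs.top_cluster_share(df, ["a"])
        assert res.loc[0, "top_cluster"] == "I"
        assert res.loc[0, "share_pct"] == pytest.approx(75.0)

    def test_all_one_cluster_gives_hundred(self):
        df = product_table([[1, 0, 0]] * 3, ["a"] * 3, clusters=["II"] * 3)
        res = cs.top_cluster_share(df, ["a"])
        assert res.loc[0, "share_pct"] == pytest.approx(100.0)

    def test_tie_reports_lowest_cluster(self):
        df = product_table([[1, 0, 0]] * 4, ["a"] * 4, clusters=["II", "I", "II", "I"])
        res = cs.top_cluster_share(df, ["a"])
        assert res.loc[0, "top_cluster"] == "I"
        assert res.loc[0, "share_pct"] == pytest.approx(50.0)


class TestShuffledClusterNull:
    def test_single_cluster_every_rep_hundred(self):
        df = product_table([[1, 0, 0]] * 6, ["a"] * 3 + ["b"] * 3, clusters=["I"] * 6)
        null = cs.shuffled_cluster_null(df, ["a", "b"], reps=10, seed=0)
        np.testing.assert_allclose(null.values, 100.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        df = product_table(
            rng.exponential(size=(12, 3)), ["a", "b", "c"] * 4,
            clusters=list(rng.choice(["I", "II", "III"], 12)),
        )
        n1 = cs.shuffled_cluster_null(df, ["a", "b", "c"], reps=12, seed=3)
        n2 = cs.shuffled_cluster_null(df, ["a", "b", "c"], reps=12, seed=3)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_uniform_clusters_match_monte_carlo_oracle(self):
        """Strains of size 4 over 2 equal clusters: null mean matches a
        direct Monte-Carlo estimate of the expected modal share."""
        rng = np.random.default_rng(7)
        n_strains, size, k = 6, 4, 2
        clusters = list(rng.choice(["I", "II"], n_strains * size))
        names = [f"s{i}" for i in range(n_strains) for _ in range(size)]
        df = product_table(
            rng.exponential(size=(n_strains * size, 3)), names, clusters=clusters
        )
        null = cs.shuffled_cluster_null(
            df, sorted(set(names)), reps=400, seed=0
        )
        # oracle: resample assignments without replacement directly
        arr = np.array(clusters)
        oracle = []
        for _ in range(4000):
            perm = rng.permutation(arr)
            shares = [
                100.0 * np.max(np.unique(perm[i * size:(i + 1) * size],
                                         return_counts=True)[1]) / size
                for i in range(n_strains)
            ]
            oracle.append(np.mean(shares))
        se = 3 * (np.std(oracle) / np.sqrt(len(oracle)) +
                  null.values.std(ddof=1) / np.sqrt(null.reps))
        assert abs(null.mean - np.mean(oracle)) < se


class TestEnrichment:
    def test_matching_proportions_give_zero_statistic(self):
        labels = ["Indica", "Hybrid", "Sativa"] * 8
        df = product_table(
            [[1, 0, 0]] * 24, [f"s{i}" for i in range(24)],
            clusters=["I", "II"] * 12, labels=labels,
        )
        res = cs.category_cluster_enrichment(df)
        np.testing.assert_allclose(res["x2"], 0.0, atol=1e-12)

    def test_unknown_labels_excluded(self):
        labels = ["Indica"] * 6 + ["Unknown"] * 6
        df = product_table(
            [[1, 0, 0]] * 12, [f"s{i}" for i in range(12)],
            clusters=["I"] * 12, labels=labels,
        )
        res = cs.category_cluster_enrichment(df)
        assert res.loc[0, "n"] == 6

    def test_enriched_cluster_detected(self):
        # cluster III is Sativa-heavy; I and II mirror the overall mix
        rows = (
            [("I", "Indica")] * 30 + [("I", "Hybrid")] * 30 + [("I", "Sativa")] * 30
            + [("II", "Indica")] * 30 + [("II", "Hybrid")] * 30 + [("II", "Sativa")] * 30
            + [("III", "Sativa")] * 55 + [("III", "Indica")] * 3 + [("III", "Hybrid")] * 2
        )
        df = product_table(
            [[1, 0, 0]] * len(rows), [f"s{i}" for i in range(len(rows))],
            clusters=[r[0] for r in rows], labels=[r[1] for r in rows],
        )
        res = cs.category_cluster_enrichment(df).set_index("cluster")
        assert res.loc["III", "significant"]
        assert not res.loc["I", "significant"]
        assert not res.loc["II", "significant"]
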