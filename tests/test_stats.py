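"""Level summaries, Bray-Curtis, group contrasts and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mireomics.stats import (
    between_treatment_distances,
    bray_curtis,
    dunn_posthoc,
    kruskal_dunn_bh,
    level_summaries,
    permanova,
)


class TestLevelSummaries:
    def test_mag_sum_and_conservation(self, tiny_counts):
        counts, catalog = tiny_counts
        expr = counts.astype(float)
        gene, mag, annotation, coverage = level_summaries(expr, catalog)
        assert mag.at["A", "s1"] == 14.0  # 10 + 0 + 4
        np.testing.assert_allclose(gene.sum(axis=0).to_numpy(), mag.sum(axis=0).to_numpy())

    def test_annotation_level_and_coverage(self, tiny_counts):
        counts, catalog = tiny_counts
        _, _, annotation, coverage = level_summaries(counts.astype(float), catalog)
        # K00001 carried by g0 (A) and g3 (B); GH13 by g1
        assert annotation.at["K00001", "s1"] == 60.0
        assert annotation.at["GH13", "s2"] == 5.0
        unannotated = coverage.loc[~coverage["annotated"], "gene_id"]
        assert list(unannotated) == ["g2", "g4"]

    def test_sums_match_groupby_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(rng.uniform(size=(30, 3)),
                            index=pd.Index(genes, name="gene_id"),
                            columns=["a", "b", "c"])
        catalog = pd.DataFrame({"gene_id": genes,
                                "mag_id": rng.choice(["M1", "M2", "M3"], 30),
                                "length_bp": 1000})
        _, mag, _, _ = level_summaries(expr, catalog)
        for m in ("M1", "M2", "M3"):
            sel = catalog.loc[catalog["mag_id"] == m, "gene_id"]
            np.testing.assert_allclose(mag.loc[m].to_numpy(),
                                       expr.loc[sel].sum(axis=0).to_numpy())


class TestBrayCurtis:
    def test_hand_example(self):
        d = bray_curtis(pd.DataFrame({"x": [2, 0, 1], "y": [1, 1, 0]}))
        assert d.at["x", "y"] == pytest.approx(0.6)

    def test_metric_properties(self):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(rng.uniform(size=(15, 5)), columns=list("abcde"))
        d = bray_curtis(ab)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
        assert ((arr >= 0) & (arr <= 1)).all()

    def test_identical_and_disjoint_columns(self):
        d = bray_curtis(pd.DataFrame({"a": [1, 2, 0], "b": [1, 2, 0], "c": [0, 0, 5]}))
        assert d.at["a", "b"] == 0.0
        assert d.at["a", "c"] == 1.0

    def test_all_zero_pair_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 2]}))


class TestBetweenTreatmentDistances:
    @staticmethod
    def _samples(n_un, n_cat, day=7):
        rows = [{"sample_id": f"u{i}", "treatment": "unamended", "day": day,
                 "replicate": i} for i in range(n_un)]
        rows += [{"sample_id": f"c{i}", "treatment": "catechin", "day": day,
                  "replicate": i} for i in range(n_cat)]
        return pd.DataFrame(rows)

    def test_pair_counts(self):
        rng = np.random.default_rng(1)
        for n_un, n_cat in [(2, 2), (1, 1), (3, 2)]:
            samples = self._samples(n_un, n_cat)
            ab = pd.DataFrame(rng.uniform(size=(10, n_un + n_cat)),
                              columns=samples["sample_id"])
            d = bray_curtis(ab)
            got = between_treatment_distances(d, samples, 7)
            assert len(got) == n_un * n_cat
            # enumeration oracle
            expected = sorted(
                d.at[f"c{i}", f"u{j}"] for i in range(n_cat) for j in range(n_un)
            )
            assert sorted(got) == pytest.approx(expected)

    def test_missing_treatment_raises(self):
        samples = self._samples(2, 0)
        ab = pd.DataFrame(np.ones((4, 2)), columns=samples["sample_id"])
        d = pd.DataFrame(0.0, index=samples["sample_id"], columns=samples["sample_id"])
        with pytest.raises(ValueError, match="both treatments"):
            between_treatment_distances(d, samples, 7)


class TestKruskalDunnBH:
    def test_identical_groups_p_one(self):
        out = kruskal_dunn_bh({"a": np.array([2.0, 2.0]), "b": np.array([2.0, 2.0])})
        assert out["kw_p"] == 1.0
        assert (out["pairwise"]["p_adjusted"] == 1.0).all()

    def test_separated_groups_exact_h(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([101.0, 102, 103]),
                  "c": np.array([201.0, 202, 203])}
        out = kruskal_dunn_bh(groups)
        # ranks are 1..9 by construction: H = 12/(N(N+1)) * sum n (Rbar - (N+1)/2)^2
        assert out["kw_h"] == pytest.approx(12.0 / 90.0 * 3 * (9 + 0 + 9))
        assert out["kw_p"] < 0.05
        assert (out["pairwise"].loc[lambda t: (t.group_a == "a") & (t.group_b == "c"),
                                    "z"] < 0).all()

    def test_dunn_matches_rank_formula_oracle(self):
        groups = {"a": np.array([1.0, 5.0, 3.0]), "b": np.array([2.0, 2.0, 8.0]),
                  "c": np.array([9.0, 7.0, 4.0])}
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        n = 9
        tie = sum(t**3 - t for t in np.unique(pooled, return_counts=True)[1]) / (12 * (n - 1))
        rbar = {"a": ranks[:3].mean(), "b": ranks[3:6].mean(), "c": ranks[6:].mean()}
        table = dunn_posthoc(groups).set_index(["group_a", "group_b"])
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            se = np.sqrt((n * (n + 1) / 12 - tie) * (2 / 3))
            z = (rbar[a] - rbar[b]) / se
            assert table.at[(a, b), "z"] == pytest.approx(z, abs=1e-12)
            assert table.at[(a, b), "p_value"] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            kruskal_dunn_bh({"a": np.array([1.0]), "b": np.array([])})


class TestPermanova:
    @staticmethod
    def _design(n_per=3, days=(0, 7)):
        rows = []
        for day in days:
            for trt in ("unamended", "catechin"):
                for i in range(n_per):
                    rows.append({"sample_id": f"{trt[:2]}{day}_{i}", "treatment": trt,
                                 "day": day, "replicate": i})
        return pd.DataFrame(rows)

    def test_pseudo_f_matches_independent_implementation(self):
        """Cross-check the one-factor pseudo-F against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        samples = self._design(n_per=4, days=(0,))
        ab = pd.DataFrame(rng.lognormal(0, 1, size=(25, len(samples))),
                          columns=samples["sample_id"])
        d = bray_curtis(ab)
        mine = permanova(d, samples, ["treatment"], n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = skbio_stats.permanova(dm, samples.set_index("sample_id"),
                                       column="treatment", permutations=99)
        assert mine.loc["treatment", "pseudo_f"] == pytest.approx(
            theirs["test statistic"], rel=1e-10
        )

    def test_planted_separation_hits_permutation_floor(self):
        rng = np.random.default_rng(3)
        samples = self._design(n_per=4, days=(0,))
        base = rng.uniform(1, 2, size=(30, 1))
        shift = np.where(samples["treatment"] == "catechin", 10.0, 1.0)
        ab = pd.DataFrame(base * shift[None, :] * rng.uniform(0.9, 1.1, (30, 8)),
                          columns=samples["sample_id"])
        res = permanova(bray_curtis(ab), samples, ["treatment"], n_perm=199, seed=1)
        # only permutations reproducing the planted grouping (prob ~2.9% each)
        # can tie the observed F, so p sits at the permutation floor
        floor = 1 / 200
        assert floor <= res.loc["treatment", "p_value"] <= 5 * floor

    def test_consistent_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        samples = self._design()
        ab = pd.DataFrame(rng.lognormal(0, 1, size=(20, len(samples))),
                          columns=samples["sample_id"])
        d = bray_curtis(ab)
        res1 = permanova(d, samples, ["treatment", "day"], n_perm=49, seed=7)
        order = rng.permutation(len(samples))
        d2 = d.iloc[order, order]
        res2 = permanova(d2, samples, ["treatment", "day"], n_perm=49, seed=7)
        np.testing.assert_allclose(res1["pseudo_f"].iloc[:2].to_numpy(),
                                   res2["pseudo_f"].iloc[:2].to_numpy())

    def test_single_level_factor_rejected(self):
        samples = self._design(days=(0,))
        samples["day"] = 0
        d = pd.DataFrame(np.zeros((len(samples),) * 2),
                         index=samples["sample_id"], columns=samples["sample_id"])
        with pytest.raises(ValueError, match="single level"):
            permanova(d, samples, ["day"], n_perm=1)

    def test_n_perm_one_with_identical_samples(self):
        samples = self._design(n_per=2, days=(0,))
        n = len(samples)
        d = pd.DataFrame(1 - np.eye(n), index=samples["sample_id"],
                         columns=samples["sample_id"])
        res = permanova(d, samples, ["treatment"], n_perm=1, seed=0)
        assert res.loc["treatment", "p_value"] == 1.0
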