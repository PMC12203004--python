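"""Count filtering, RPK, TMM factors and the MAG activity filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mireomics.normalize import (
    NormConfig,
    filter_low_counts,
    getmm,
    mag_on_filter,
    rpk,
    tmm_factors,
)


def brute_force_tmm(x: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Independent TMM oracle: materialize M/A, rank, trim, weighted mean."""
    lib = x.sum(axis=0)
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(x.shape[0]):
            o, r = x[g, j], x[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * np.log2(po * pr))
            w_vals.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        m_vals, a_vals, w_vals = map(np.asarray, (m_vals, a_vals, w_vals))
        if np.max(np.abs(m_vals)) < 1e-6:
            continue
        n = len(m_vals)
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        keep = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        num = sum(m / w for m, w, k in zip(m_vals, w_vals, keep) if k)
        den = sum(1 / w for w, k in zip(w_vals, keep) if k)
        logf[j] = num / den
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


class TestFilterLowCounts:
    @pytest.mark.parametrize("value,expected", [(4, 0), (5, 5), (0, 0), (100, 100)])
    def test_threshold_boundary(self, value, expected):
        m = pd.DataFrame({"s": [value]}, index=["g"])
        assert filter_low_counts(m, 5).iloc[0, 0] == expected

    def test_zero_threshold_is_identity_and_idempotent(self, tiny_counts):
        counts, _ = tiny_counts
        assert filter_low_counts(counts, 0).equals(counts)
        once = filter_low_counts(counts, 5)
        assert filter_low_counts(once, 5).equals(once)


class TestRpk:
    def test_values(self, tiny_counts):
        counts, catalog = tiny_counts
        r = rpk(counts, catalog)
        assert r.at["g0", "s1"] == 10.0        # 10 reads / 1 kb
        assert r.at["g1", "s2"] == 10.0        # 5 reads / 0.5 kb
        assert r.at["g1", "s1"] == 0.0

    def test_missing_length_named(self, tiny_counts):
        counts, catalog = tiny_counts
        with pytest.raises(KeyError, match="g4"):
            rpk(counts, catalog[catalog["gene_id"] != "g4"])


class TestTmmFactors:
    def test_identical_columns_unit_factors(self):
        col = np.array([5.0, 10.0, 3.0, 40.0])
        m = pd.DataFrame({"a": col, "b": col})
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self):
        col = np.array([5.0, 10.0, 3.0, 40.0, 17.0])
        m = pd.DataFrame({"a": col, "b": 2 * col})
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), [1.0, 1.0])

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.lognormal(2, 1, size=(60, 5)))
        f = tmm_factors(m)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.negative_binomial(2, 0.02, size=(50, 4)).astype(float)
        x[x < 1] = 0
        m = pd.DataFrame(x, columns=list("abcd"))
        np.testing.assert_allclose(
            tmm_factors(m).to_numpy(), brute_force_tmm(x), atol=1e-9
        )

    def test_no_coexpressed_genes_fails_with_pair(self):
        m = pd.DataFrame({"a": [1.0, 0.0, 5.0], "b": [0.0, 0.0, 3.0], "c": [0.0, 4.0, 0.0]})
        with pytest.raises(ValueError, match="reference"):
            tmm_factors(m, reference="c")


class TestGetmm:
    def test_single_sample_is_rpk_per_million(self, tiny_counts):
        counts, catalog = tiny_counts
        single = counts[["s1"]]
        g = getmm(single, catalog)
        r = rpk(filter_low_counts(single, 5), catalog)
        np.testing.assert_allclose(g.to_numpy(), (r / r.sum() * 1e6).to_numpy())

    def test_duplicate_samples_identical_columns(self, tiny_counts):
        counts, catalog = tiny_counts
        dup = pd.concat([counts, counts.add_suffix("_dup", axis=1)], axis=1)
        g = getmm(dup, catalog)
        np.testing.assert_allclose(g["s1"].to_numpy(), g["s1_dup"].to_numpy())

    def test_depth_scaling_invariance(self):
        # counts at or above the low-count threshold, so tripling one sample
        # changes only its depth, not its zero pattern
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            filter_low_counts(
                pd.DataFrame(rng.negative_binomial(3, 0.05, size=(80, 4))), 5
            ).to_numpy(),
            index=pd.Index([f"g{i}" for i in range(80)], name="gene_id"),
            columns=list("abcd"),
        )
        catalog = pd.DataFrame(
            {"gene_id": counts.index, "mag_id": "M", "length_bp": rng.integers(300, 3000, 80)}
        )
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        # unweighted trimmed mean: exactly depth-invariant (M, A and the trim
        # set depend only on relative expression)
        f_plain = tmm_factors(rpk(counts, catalog), weighted=False)
        f_scaled = tmm_factors(rpk(scaled, catalog), weighted=False)
        np.testing.assert_allclose(f_plain.to_numpy(), f_scaled.to_numpy(), rtol=1e-12)
        # precision weights carry a weak absolute-depth dependence; geTMM
        # stays within 2% under a 3x depth change
        np.testing.assert_allclose(
            getmm(counts, catalog).to_numpy(), getmm(scaled, catalog).to_numpy(), rtol=0.02
        )

    def test_zero_count_gives_zero_getmm(self, tiny_counts):
        counts, catalog = tiny_counts
        g = getmm(counts, catalog)
        assert (g.to_numpy()[counts.to_numpy() == 0] == 0).all()

    def test_empty_after_filter_raises(self, tiny_counts):
        _, catalog = tiny_counts
        low = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]},
                           index=pd.Index(["g0", "g1"], name="gene_id"))
        with pytest.raises(ValueError, match="empty"):
            getmm(low, catalog)


class TestMagOnFilter:
    @staticmethod
    def _expr(n_on_a: int):
        genes = [f"a{i}" for i in range(25)] + [f"b{i}" for i in range(25)]
        catalog = pd.DataFrame(
            {"gene_id": genes, "mag_id": ["A"] * 25 + ["B"] * 25, "length_bp": 1000}
        )
        expr = pd.DataFrame(
            {"s": [1.0] * n_on_a + [0.0] * (25 - n_on_a) + [1.0] * 25},
            index=pd.Index(genes, name="gene_id"),
        )
        return expr, catalog

    def test_below_threshold_zeroed(self):
        expr, catalog = self._expr(21)
        out, activity = mag_on_filter(expr, catalog, 22)
        assert (out.loc[[f"a{i}" for i in range(25)], "s"] == 0).all()
        assert not activity.set_index("mag_id").at["A", "passed"]

    def test_at_threshold_retained(self):
        expr, catalog = self._expr(22)
        out, _ = mag_on_filter(expr, catalog, 22)
        assert out.loc["a0", "s"] == 1.0

    def test_threshold_one_is_noop(self):
        expr, catalog = self._expr(10)
        out, _ = mag_on_filter(expr, catalog, 1)
        pd.testing.assert_frame_equal(out, expr)

    def test_idempotent(self):
        expr, catalog = self._expr(21)
        once, _ = mag_on_filter(expr, catalog, 22)
        twice, _ = mag_on_filter(once, catalog, 22)
        pd.testing.assert_frame_equal(once, twice)

    def test_auto_threshold_is_median_of_active_pairs(self):
        expr, catalog = self._expr(21)  # active counts: A=21, B=25 -> median 23
        _, activity = mag_on_filter(expr, catalog, "auto")
        assert activity["threshold"].iloc[0] == 23

    def test_nonpositive_threshold_rejected(self):
        expr, catalog = self._expr(10)
        with pytest.raises(ValueError):
            mag_on_filter(expr, catalog, 0)


def test_norm_config_rejects_bad_trims():
    with pytest.raises(ValueError):
        NormConfig(tmm_trim_m=0.6)
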