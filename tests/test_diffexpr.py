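"""Median-of-ratios closed forms and substitute-test behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from reciprotrace import diffexpr as dx
from reciprotrace.errors import NormalizationError, SchemaError


def _counts(rows, cols=None):
    arr = np.asarray(rows, dtype=float)
    cols = cols or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols, index=[f"g{i}" for i in range(arr.shape[0])])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        sf = dx.size_factors(_counts([[10, 10], [7, 7], [100, 100]]))
        assert np.allclose(sf, 1.0)

    def test_scaled_column_closed_form(self):
        # each gene's column-2/column-1 ratio is exactly 2 -> factors (c, 2c)
        sf = dx.size_factors(_counts([[10, 20], [100, 200]]))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_single_gene_single_sample(self):
        sf = dx.size_factors(_counts([[5]]))
        assert sf.iloc[0] == pytest.approx(1.0)

    def test_genes_with_zeros_excluded_from_median(self):
        with_zero = _counts([[10, 20], [0, 50], [100, 200]])
        without = _counts([[10, 20], [100, 200]])
        pd.testing.assert_series_equal(
            dx.size_factors(with_zero), dx.size_factors(without), check_names=False
        )

    def test_no_all_positive_gene_errors_with_fallback_hint(self):
        c = _counts([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError, match="pseudo_reference"):
            dx.size_factors(c)
        sf = dx.size_factors(c, allow_pseudo_reference=True)
        assert (sf > 0).all()

    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           col=st.integers(min_value=0, max_value=2))
    @settings(max_examples=25, deadline=None)
    def test_scaling_property(self, scale, col):
        # scaling one sample's column by c multiplies its factor by c relative
        # to the others (the geometric-mean reference moves by a common
        # c**(1/m), so factors and normalized counts are defined up to one
        # common positive scale)
        base = _counts([[10, 40, 20], [55, 30, 90], [7, 12, 21], [500, 300, 100]])
        scaled = base.copy()
        scaled.iloc[:, col] *= scale
        sf0 = dx.size_factors(base)
        sf1 = dx.size_factors(scaled)
        expect = sf0.copy()
        expect.iloc[col] *= scale
        common = (sf1 / expect).iloc[0]
        assert np.allclose(sf1, expect * common)
        n0 = dx.normalize(base).normalized_counts.to_numpy()
        n1 = dx.normalize(scaled).normalized_counts.to_numpy()
        assert np.allclose(n1 * (n0[0, 0] / n1[0, 0]), n0)


class TestDifferential:
    def _groups(self, cols):
        return {c: ("mock" if c.startswith("m") else "condition") for c in cols}

    def test_identical_groups_null(self):
        nc = _counts([[10, 12, 10, 12], [5, 5, 5, 5]], ["m1", "m2", "c1", "c2"])
        res = dx.differential(nc, self._groups(nc.columns))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p_value"] >= 0.5).all()

    def test_infinity_sentinels(self):
        nc = _counts([[0, 0, 8, 8], [9, 9, 0, 0], [0, 0, 0, 0]], ["m1", "m2", "c1", "c2"])
        res = dx.differential(nc, self._groups(nc.columns))
        assert res.loc[0, "log2fc"] == np.inf
        assert res.loc[1, "log2fc"] == -np.inf
        assert np.isnan(res.loc[2, "log2fc"])

    def test_single_replicate_gives_missing_p(self):
        nc = _counts([[10, 80]], ["m1", "c1"])
        res = dx.differential(nc, self._groups(nc.columns))
        assert np.isnan(res.loc[0, "p_value"])
        assert res.loc[0, "log2fc"] == pytest.approx(3.0)

    def test_bad_group_labels_are_schema_error(self):
        nc = _counts([[1, 2]], ["a", "b"])
        with pytest.raises(SchemaError):
            dx.differential(nc, {"a": "mock", "b": "treated"})

    @pytest.mark.parametrize("reps,per_gene_tol", [(100, 0.3), (3, None)])
    def test_planted_effect_recovered(self, reps, per_gene_tol):
        # 2^4 effect at low dispersion: per-gene log2fc within +-0.3 at large
        # replicate count; at n=3 the estimator is centred on 4
        rng = np.random.default_rng(42)
        n = 500
        r = 1 / 0.05
        mu_mock = np.full(n, 300.0)
        mu_cond = mu_mock * 16.0
        mock = rng.negative_binomial(r, r / (r + mu_mock[:, None]), (n, reps))
        cond = rng.negative_binomial(r, r / (r + mu_cond[:, None]), (n, reps))
        cols = [f"m{i}" for i in range(reps)] + [f"c{i}" for i in range(reps)]
        nc = pd.DataFrame(np.hstack([mock, cond]), columns=cols,
                          index=[f"g{i}" for i in range(n)])
        res = dx.differential(nc, self._groups(nc.columns))
        if per_gene_tol is not None:
            assert np.abs(res["log2fc"] - 4.0).max() < per_gene_tol
        assert res["log2fc"].mean() == pytest.approx(4.0, abs=0.1)

    def test_null_p_uniform(self):
        # KS distance to uniform < 0.05 under the null at 10,000 genes
        rng = np.random.default_rng(7)
        n = 10000
        mu = np.exp(rng.uniform(np.log(50), np.log(1000), n))
        r = 1 / 0.05
        draw = lambda: rng.negative_binomial(r, r / (r + mu[:, None]), (n, 3))
        nc = pd.DataFrame(
            np.hstack([draw(), draw()]),
            columns=["m1", "m2", "m3", "c1", "c2", "c3"],
            index=[f"g{i}" for i in range(n)],
        )
        res = dx.differential(nc, self._groups(nc.columns))
        ks = stats.kstest(res["p_value"].dropna(), "uniform").statistic
        assert ks < 0.05
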