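"""Chromosome-usage fingerprint arithmetic and invariants."""

import numpy as np
import pandas as pd
import pytest

from reciprotrace import gudc
from reciprotrace.errors import ComputationError
from reciprotrace.signatures import filter_signature


def _universe(chrom_counts):
    rows = []
    i = 0
    for chrom, n in chrom_counts.items():
        for _ in range(n):
            rows.append((f"g{i}", chrom))
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chromosome"])


class TestFingerprint:
    def test_saturated_signature(self):
        uni = _universe({"1": 10, "2": 5, "X": 3})
        fp = gudc.fingerprint(set(uni["gene_id"]), uni)
        present = fp.table.loc[fp.table["universe_genes"] > 0]
        assert np.allclose(present["usage_pct"], 100.0)
        assert np.allclose(present["deviation_pct"], 0.0)
        assert fp.mean_usage_pct == pytest.approx(100.0)

    def test_proportional_allocation_zero_deviation(self):
        uni = _universe({"1": 10, "2": 10, "3": 20})
        sig = {"g0", "g10", "g20", "g21"}  # 1, 1, 2 genes -> 10% everywhere
        fp = gudc.fingerprint(sig, uni)
        present = fp.table.loc[fp.table["universe_genes"] > 0]
        assert np.allclose(present["deviation_pct"], 0.0)
        assert fp.mean_usage_pct == pytest.approx(10.0)

    def test_mean_usage_matches_small_fraction(self):
        # 50 genes out of 45,455 -> mean usage 0.11%
        uni = _universe({"1": 45455})
        sig = set(uni["gene_id"].iloc[:50])
        fp = gudc.fingerprint(sig, uni)
        assert fp.mean_usage_pct == pytest.approx(0.11, abs=0.0001)

    def test_weighted_deviations_cancel(self, small_dataset):
        _, tables, _, _, _ = small_dataset
        for tp, df in tables.items():
            sig = filter_signature(df, direction="up", timepoint=tp)
            fp = gudc.fingerprint(sig, df)
            weighted = (fp.table["universe_genes"] * fp.table["deviation_pct"]).sum()
            assert abs(weighted) < 1e-9 * max(1, fp.n_universe)

    def test_y_and_other_dropped_and_counted(self):
        uni = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "chromosome": ["1", "Y", "other", "1"]}
        )
        fp = gudc.fingerprint({"a"}, uni)
        assert fp.dropped == {"Y": 1, "other": 1}
        assert fp.n_universe == 2

    def test_permutation_invariance(self):
        uni = _universe({"1": 30, "2": 20, "MT": 5})
        sig = {"g1", "g35", "g50"}
        fp1 = gudc.fingerprint(sig, uni)
        fp2 = gudc.fingerprint(sig, uni.sample(frac=1.0, random_state=4))
        pd.testing.assert_frame_equal(fp1.table, fp2.table)

    def test_uniform_signature_relative_deviations_shrink_with_size(self):
        # genes drawn uniformly from the universe: deviations are pure
        # sampling noise, so deviation relative to the mean usage shrinks as
        # the signature grows (and vanishes at saturation)
        rng = np.random.default_rng(12)
        counts = {str(c): int(n) for c, n in zip(range(1, 23), rng.integers(1000, 3000, 22))}
        uni = _universe(counts)
        rel = {}
        for size in (500, 5000):
            sig = set(rng.choice(uni["gene_id"], size=size, replace=False).tolist())
            fp = gudc.fingerprint(sig, uni)
            rel[size] = float(np.nanmax(np.abs(fp.table["deviation_pct"]))) / fp.mean_usage_pct
        assert rel[5000] < rel[500]
        assert rel[5000] < 0.25  # a few sampling-noise standard deviations

    def test_exclude_mt_flag(self):
        uni = _universe({"1": 10, "MT": 10})
        fp = gudc.fingerprint({"g0"}, uni, include_mt=False)
        assert "MT" not in set(fp.table["chromosome"])
        assert fp.n_universe == 10

    def test_empty_universe_is_error(self):
        with pytest.raises(ComputationError):
            gudc.fingerprint(set(), pd.DataFrame(columns=["gene_id", "chromosome"]))

    def test_signature_outside_universe_is_error(self):
        uni = _universe({"1": 3})
        with pytest.raises(ComputationError):
            gudc.fingerprint({"missing"}, uni)

    def test_ranked_orders_by_deviation(self):
        uni = _universe({"1": 10, "2": 10})
        fp = gudc.fingerprint({"g0", "g1", "g2"}, uni)  # all on chromosome 1
        ranked = fp.ranked()
        assert ranked.iloc[0]["chromosome"] == "1"


class TestUsageFoldChange:
    def test_printed_percentages_give_18_fold(self):
        # 0.11% -> 1.96% is a ~17.8-fold increase
        uni_a = _universe({"1": 45455})
        uni_b = _universe({"1": 32347})
        fp_a = gudc.fingerprint(set(uni_a["gene_id"].iloc[:50]), uni_a)
        fp_b = gudc.fingerprint(set(uni_b["gene_id"].iloc[:634]), uni_b)
        fold = gudc.usage_fold_change(fp_a, fp_b)
        assert fold == pytest.approx(17.8, abs=0.1)

    def test_identical_signatures_unit_ratio(self):
        uni = _universe({"1": 100})
        fp = gudc.fingerprint({"g0", "g1"}, uni)
        assert gudc.usage_fold_change(fp, fp) == pytest.approx(1.0)

    def test_empty_first_signature_gives_infinity(self):
        uni = _universe({"1": 100})
        fp0 = gudc.fingerprint(set(), uni)
        fp1 = gudc.fingerprint({"g0"}, uni)
        assert gudc.usage_fold_change(fp0, fp1) == np.inf
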