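"""Filter predicates against a brute-force oracle; Venn region arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from reciprotrace.errors import ValidationError
from reciprotrace.signatures import (
    FilterParams,
    basis_reads,
    filter_signature,
    overlap,
    overlap_sizes,
)


def brute_force_members(records, params, direction):
    """Independent re-application of the three predicates, row by row."""
    out = set()
    for row in records.itertuples(index=False):
        reads = {
            "higher_group_mean": max(row.mock_reads, row.cond_reads),
            "mock": row.mock_reads,
            "condition": row.cond_reads,
            "mean_of_means": (row.mock_reads + row.cond_reads) / 2,
        }[params.reads_basis]
        p = row.p_value
        if p is None or (isinstance(p, float) and math.isnan(p)):
            continue
        if params.strict:
            ok = reads > params.min_reads and p < params.max_p
            if direction == "up":
                ok = ok and row.log2fc > params.min_abs_log2fc
            else:
                ok = ok and row.log2fc < -params.min_abs_log2fc
        else:
            ok = reads >= params.min_reads and p <= params.max_p
            if direction == "up":
                ok = ok and row.log2fc >= params.min_abs_log2fc
            else:
                ok = ok and row.log2fc <= -params.min_abs_log2fc
        if ok:
            out.add(row.gene_id)
    return out


def random_table(rng, n_rows):
    l2fc = rng.normal(0, 2.5, n_rows)
    l2fc[rng.random(n_rows) < 0.1] = np.inf
    l2fc[rng.random(n_rows) < 0.1] = -np.inf
    p = rng.random(n_rows)
    p[rng.random(n_rows) < 0.1] = np.nan
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_rows)],
            "mock_reads": np.round(rng.uniform(0, 40, n_rows), 2),
            "cond_reads": np.round(rng.uniform(0, 40, n_rows), 2),
            "log2fc": l2fc,
            "p_value": p,
        }
    )


class TestFilterOracle:
    def test_brute_force_equivalence_1000_trials(self):
        rng = np.random.default_rng(2024)
        bases = ("higher_group_mean", "mock", "condition", "mean_of_means")
        for trial in range(1000):
            df = random_table(rng, int(rng.integers(0, 51)))
            params = FilterParams(
                min_reads=float(rng.uniform(0, 30)),
                max_p=float(rng.uniform(0.01, 1.0)),
                min_abs_log2fc=float(rng.uniform(0, 4)),
                reads_basis=bases[trial % 4],
                strict=bool(trial % 2),
            )
            direction = "up" if trial % 3 else "down"
            sig = filter_signature(df, params, direction)
            assert sig.gene_ids == brute_force_members(df, params, direction), (
                f"trial {trial}"
            )

    def test_eight_row_fixture_two_pass(self, tiny_table):
        sig = filter_signature(tiny_table, direction="up")
        assert sig.gene_ids == {"g1", "g3"}
        down = filter_signature(tiny_table, direction="down")
        assert down.gene_ids == {"g6"}

    def test_empty_table(self):
        df = random_table(np.random.default_rng(0), 0)
        sig = filter_signature(df, direction="up")
        assert len(sig) == 0 and sig.total_reads == 0.0

    def test_infinite_log2fc_passes_magnitude(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "mock_reads": [0.0, 50.0], "cond_reads": [50.0, 0.0],
             "log2fc": [np.inf, -np.inf], "p_value": [0.01, 0.01]}
        )
        assert filter_signature(df, direction="up").gene_ids == {"a"}
        assert filter_signature(df, direction="down").gene_ids == {"b"}

    def test_missing_p_excluded(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "mock_reads": [5.0], "cond_reads": [500.0],
             "log2fc": [6.6], "p_value": [np.nan]}
        )
        assert len(filter_signature(df, direction="up")) == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        df = random_table(rng, 200)
        base = FilterParams()
        n0 = len(filter_signature(df, base, "up"))
        for tighter in (
            FilterParams(min_reads=20),
            FilterParams(max_p=0.01),
            FilterParams(min_abs_log2fc=3),
        ):
            assert len(filter_signature(df, tighter, "up")) <= n0

    def test_up_down_disjoint(self):
        df = random_table(np.random.default_rng(9), 300)
        up = filter_signature(df, direction="up").gene_ids
        down = filter_signature(df, direction="down").gene_ids
        assert not (up & down)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            FilterParams(max_p=0.0)
        with pytest.raises(ValidationError):
            FilterParams(min_reads=-1)
        with pytest.raises(ValidationError):
            FilterParams(reads_basis="median")

    def test_total_reads_uses_direction_relevant_basis(self, tiny_table):
        # members g1 (higher group 90) and g3 (higher group 40)
        sig = filter_signature(tiny_table, direction="up")
        assert sig.total_reads == pytest.approx(130.0)
        assert list(basis_reads(sig.records, "higher_group_mean")) == list(sig.records["reads"])


class TestOverlap:
    def test_disjoint_sets(self):
        sizes = overlap_sizes({"A": {"x"}, "B": {"y"}})
        assert sizes[("A", "B")] == 0
        assert sizes[("A",)] == 1 and sizes[("B",)] == 1

    def test_three_set_enumeration(self):
        regions = overlap_sizes({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4"}, "C": {"g3"}})
        assert regions == {
            ("A",): 1, ("B",): 1, ("C",): 0,
            ("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0,
            ("A", "B", "C"): 1,
        }

    def test_regions_partition_union(self):
        rng = np.random.default_rng(3)
        sets = {k: set(rng.choice(50, size=rng.integers(5, 30), replace=False).tolist())
                for k in "ABCD"}
        regions = overlap(sets)
        union = set().union(*sets.values())
        seen = []
        for members in regions.values():
            seen.extend(members)
        assert len(seen) == len(set(seen))  # mutually exclusive
        assert set(seen) == union           # exhaustive

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            overlap({"A": {"x"}})
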