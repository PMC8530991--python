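"""Shared fixtures: scaled-down and study-scale synthetic datasets."""

import pandas as pd
import pytest

from reciprotrace import synthetic as syn
from reciprotrace.io_ingest import ensure_annotated


@pytest.fixture(scope="session")
def small_cfg():
    return syn.small_config(seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(annotation, expression tables, atac tables, maintenance pairs, truth)."""
    ann = syn.generate_annotation(small_cfg)
    tables, atac, maint, truth = syn.generate_diff_tables(small_cfg, ann)
    return ann, tables, atac, maint, truth


@pytest.fixture(scope="session")
def study_dataset():
    """The study-condition (default-parameter) synthetic dataset."""
    cfg = syn.SyntheticConfig(seed=101)
    ann = syn.generate_annotation(cfg)
    tables, atac, maint, truth = syn.generate_diff_tables(cfg, ann)
    return cfg, ann, tables, atac, maint, truth


@pytest.fixture()
def tiny_table():
    """An 8-row annotated differential table with two genes passing the up filter."""
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 9)],
            "mock_reads": [5.0, 100.0, 3.0, 50.0, 0.0, 40.0, 12.0, 9.0],
            "cond_reads": [90.0, 900.0, 40.0, 55.0, 30.0, 2.0, 11.0, 200.0],
            "log2fc": [4.17, 3.17, 3.74, 0.14, float("inf"), -4.32, -0.13, 4.47],
            "p_value": [0.001, 0.2, 0.01, 0.01, 0.3, 0.002, 0.9, None],
            "gene_type": ["protein_coding"] * 4 + ["pseudogene"] * 4,
            "chromosome": ["1", "2", "3", "4", "5", "6", "7", "8"],
            "symbol": [f"S{i}" for i in range(1, 9)],
        }
    )
    return ensure_annotated(df)
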