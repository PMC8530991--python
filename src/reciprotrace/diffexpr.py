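"""Median-of-ratios normalization and a simple two-group substitute test.

This stage makes synthetic runs end-to-end: raw counts are normalized by the
geometric-mean (median-of-ratios) method, group means and log2 fold changes
are computed, and a Welch t-test on log2(x+1)-transformed replicates supplies
a p-value.  The substitute test is deliberately simple — reproduction of
published analyses ingests the study's own DESeq2 statistics instead, and the
downstream modules only consume (reads, log2FC, p).

Zero handling: no pseudocounts enter the fold change; a zero group mean yields
a signed infinity sentinel (both groups zero gives NaN), which the de-novo /
shut-down detector consumes as a first-class value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, SchemaError


@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample size factors and the column-wise normalized count matrix."""

    size_factors: pd.Series
    normalized_counts: pd.DataFrame


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, factor_j is the median over reference genes of
    ``count_ij / geometric_mean_i``.  Reference genes are those with strictly
    positive counts in every sample; with ``allow_pseudo_reference=True`` the
    geometric mean is instead taken over each gene's nonzero entries and all
    genes with at least one positive count serve as reference.

    Because the per-gene reference is the geometric mean across the samples
    themselves, rescaling one column by c moves every factor by a common
    c**(-1/m) in addition to scaling that column's factor by c: factor
    *ratios* are the meaningful quantity, and normalized counts are defined
    up to one common positive scale.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0:
        raise NormalizationError("empty count matrix")
    if (mat < 0).any():
        raise NormalizationError("negative counts")
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        if not allow_pseudo_reference:
            raise NormalizationError(
                "no gene has all-positive counts; re-run with allow_pseudo_reference=True "
                "to use a nonzero-entry pseudo-reference"
            )
        any_positive = (mat > 0).any(axis=1)
        ref = mat[any_positive]
        logs = np.where(ref > 0, np.log(np.where(ref > 0, ref, 1.0)), np.nan)
        log_gm = np.nanmean(logs, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ref > 0, ref / np.exp(log_gm)[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        ref = mat[all_positive]
        log_gm = np.log(ref).mean(axis=1)
        ratios = ref / np.exp(log_gm)[:, None]
        factors = np.median(ratios, axis=0)
    if not np.all(factors > 0) or not np.all(np.isfinite(factors)):
        raise NormalizationError(f"non-positive size factor(s): {factors}")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> NormalizationResult:
    sf = size_factors(counts, allow_pseudo_reference=allow_pseudo_reference)
    return NormalizationResult(size_factors=sf, normalized_counts=counts / sf)


def log2_ratio(mock_mean: np.ndarray, cond_mean: np.ndarray) -> np.ndarray:
    """log2(cond/mock) with signed-infinity sentinels and NaN when both are 0."""
    mock_mean = np.asarray(mock_mean, dtype=float)
    cond_mean = np.asarray(cond_mean, dtype=float)
    out = np.full(mock_mean.shape, np.nan)
    both = (mock_mean > 0) & (cond_mean > 0)
    out[both] = np.log2(cond_mean[both] / mock_mean[both])
    out[(mock_mean == 0) & (cond_mean > 0)] = np.inf
    out[(cond_mean == 0) & (mock_mean > 0)] = -np.inf
    return out


def differential(
    norm_counts: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-gene group means, log2 fold change and Welch-t p-value.

    ``groups`` labels every column of ``norm_counts`` as ``"mock"`` or
    ``"condition"``.  The p-value is a Welch t-test on log2(x+1)-transformed
    replicate values when both groups have at least two replicates, otherwise
    missing.  Exactly equal replicate vectors yield p = 1.
    """
    if not isinstance(groups, Mapping):
        groups = dict(zip(norm_counts.columns, groups))
    labels = {c: groups.get(c) for c in norm_counts.columns}
    if any(v not in {"mock", "condition"} for v in labels.values()):
        raise SchemaError(f"group labels must cover all columns with 'mock'/'condition': {labels}")
    mock_cols = [c for c, v in labels.items() if v == "mock"]
    cond_cols = [c for c, v in labels.items() if v == "condition"]
    if not mock_cols or not cond_cols:
        raise SchemaError("both groups need at least one replicate")

    mock = norm_counts[mock_cols].to_numpy(dtype=float)
    cond = norm_counts[cond_cols].to_numpy(dtype=float)
    mock_mean = mock.mean(axis=1)
    cond_mean = cond.mean(axis=1)
    l2fc = log2_ratio(mock_mean, cond_mean)

    if len(mock_cols) >= 2 and len(cond_cols) >= 2:
        a = np.log2(mock + 1.0)
        b = np.log2(cond + 1.0)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance replicate vectors trip a scipy precision warning;
            # those rows are resolved explicitly below
            warnings.filterwarnings("ignore", message="Precision loss occurred")
            p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
        # zero variance in both groups: p is NaN; decide by mean equality
        both_flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        p = np.where(both_flat & np.isnan(p), np.where(a.mean(axis=1) == b.mean(axis=1), 1.0, 0.0), p)
    else:
        p = np.full(len(norm_counts), np.nan)

    out = pd.DataFrame(
        {
            "gene_id": norm_counts.index.astype(str),
            "mock_reads": mock_mean,
            "cond_reads": cond_mean,
            "log2fc": l2fc,
            "p_value": p,
        }
    )
    if timepoint is not None:
        out["timepoint"] = timepoint
    return out.reset_index(drop=True)
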