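"""Stringent signature filtering and Venn overlap structure.

A *signature* is the set of genes in one comparison passing three predicates
simultaneously: minimum reads (>10 by default), raw p-value (<0.05) and
absolute log2 fold change (>2 for expression, >1 for accessibility).  The
inequalities are strict by default, matching the published thresholds as
printed; a flag relaxes them to >=/<= since supplementary tables may have been
produced either way.  An infinite log2 fold change passes the magnitude test.

The reads predicate is evaluated on a configurable basis; the default is the
mean normalized reads of whichever group is higher, so that genes silent in
mock (de novo) can still pass.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

READS_BASES = ("higher_group_mean", "mock", "condition", "mean_of_means")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the stringent signature filter.

    min_reads / max_p / min_abs_log2fc are the three predicates; ``strict``
    selects strict (printed) vs non-strict inequalities; ``adjust_p`` switches
    the p predicate to Benjamini-Hochberg adjusted values (off by default —
    the published filter uses raw p).
    """

    min_reads: float = 10.0
    max_p: float = 0.05
    min_abs_log2fc: float = 2.0
    reads_basis: str = "higher_group_mean"
    strict: bool = True
    adjust_p: bool = False

    def __post_init__(self):
        if self.min_reads < 0:
            raise ValidationError("min_reads must be >= 0")
        if not (0 < self.max_p <= 1):
            raise ValidationError("max_p must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if self.reads_basis not in READS_BASES:
            raise ValidationError(f"reads_basis must be one of {READS_BASES}")


#: Published accessibility-table variant of the filter (>2 reads, log2 > +-1).
ATAC_FILTER = FilterParams(min_reads=2.0, min_abs_log2fc=1.0)


def basis_reads(records: pd.DataFrame, basis: str = "higher_group_mean") -> pd.Series:
    """The per-gene reads value the min_reads predicate is applied to."""
    mock = records["mock_reads"].astype(float)
    cond = records["cond_reads"].astype(float)
    if basis == "higher_group_mean":
        return np.maximum(mock, cond)
    if basis == "mock":
        return mock
    if basis == "condition":
        return cond
    if basis == "mean_of_means":
        return (mock + cond) / 2.0
    raise ValidationError(f"unknown reads basis {basis!r}")


@dataclass
class Signature:
    """A filtered up- or down-regulated gene set with its filter parameters."""

    timepoint: str
    direction: str
    records: pd.DataFrame  # carries a "reads" column with the basis values
    params: FilterParams = field(default_factory=FilterParams)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.records["gene_id"])

    @property
    def total_reads(self) -> float:
        """Sum of direction-relevant (basis) reads over members."""
        return float(self.records["reads"].sum())

    def to_tsv(self, path) -> None:
        cols = [c for c in ("gene_id", "symbol", "gene_type", "chromosome",
                            "reads", "log2fc", "p_value") if c in self.records.columns]
        out = self.records[cols].copy()
        out["direction"] = self.direction
        out["timepoint"] = self.timepoint
        out.to_csv(path, sep="\t", index=False)


def filter_signature(
    records: pd.DataFrame,
    params: FilterParams | None = None,
    direction: str = "up",
    timepoint: str | None = None,
) -> Signature:
    """Apply the three-predicate stringent filter to one comparison table.

    Membership requires reads above min_reads AND p below max_p AND log2fc
    beyond +-min_abs_log2fc in the requested direction.  Genes with missing
    p-values are excluded (and counted in the log).
    """
    if direction not in {"up", "down"}:
        raise ValidationError("direction must be 'up' or 'down'")
    params = params or FilterParams()
    df = records.copy()
    reads = basis_reads(df, params.reads_basis)
    p = df["p_value"].astype(float)
    n_missing_p = int(p.isna().sum())
    if n_missing_p:
        logger.info("filter_signature: %d gene(s) without p-value excluded", n_missing_p)
    if params.adjust_p:
        adj = np.full(len(df), np.nan)
        mask = p.notna().to_numpy()
        if mask.any():
            adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
        p = pd.Series(adj, index=df.index)

    l2fc = df["log2fc"].astype(float)
    if params.strict:
        pass_reads = reads > params.min_reads
        pass_p = p < params.max_p
        pass_fc = l2fc > params.min_abs_log2fc if direction == "up" else l2fc < -params.min_abs_log2fc
    else:
        pass_reads = reads >= params.min_reads
        pass_p = p <= params.max_p
        pass_fc = l2fc >= params.min_abs_log2fc if direction == "up" else l2fc <= -params.min_abs_log2fc
    member = pass_reads & pass_p.fillna(False) & pass_fc.fillna(False)

    out = df.loc[member].copy()
    out["reads"] = reads.loc[member]
    out = out.sort_values("gene_id").reset_index(drop=True)
    tp = timepoint or (str(df["timepoint"].iloc[0]) if "timepoint" in df.columns and len(df) else "")
    return Signature(timepoint=tp, direction=direction, records=out, params=params)


def overlap(sets: Mapping[str, Iterable[str]] | Iterable[Signature]) -> dict[tuple[str, ...], set[str]]:
    """Exact Venn decomposition of two or more gene sets.

    Accepts a mapping name -> gene ids or an iterable of Signatures (keyed by
    timepoint).  Returns every non-trivial region: the key is the tuple of set
    names whose intersection the region belongs to exclusively; region sets
    partition the union.
    """
    if not isinstance(sets, Mapping):
        sigs = list(sets)
        sets = {s.timepoint or f"set{i}": s.gene_ids for i, s in enumerate(sigs)}
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("overlap needs at least two sets")
    as_sets = {n: set(sets[n]) for n in names}
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(as_sets[n] for n in combo))
            outside = set.union(set(), *(as_sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    return regions


def overlap_sizes(sets) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in overlap(sets).items()}


def venn_to_json_dict(regions: Mapping[tuple[str, ...], set[str]]) -> dict[str, list[str]]:
    """Serialize Venn regions with '&'-joined keys and sorted members."""
    return {"&".join(k): sorted(v) for k, v in regions.items()}


def tighten(params: FilterParams, **kwargs) -> FilterParams:
    """Convenience: a copy of params with some thresholds replaced."""
    return replace(params, **kwargs)
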