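"""De novo / shut-down detection (DAGE) and signature tracing (ST).

The discriminator is log2_var = ln(fold change)/ln 2 evaluated with signed
infinity sentinels: a gene with exactly zero mock reads and positive condition
reads is *de novo transcribed* (+inf), the mirror image is *shut down* (-inf),
and a gene silent in both groups is undefined and belongs to neither set.
"Zero" means all-replicate raw zero when count matrices are available, or a
normalized group mean of exactly 0 when only result tables are — averaging
cannot create spurious zeros.

Tracing follows each flagged set across ordered timepoints, labels every gene
with its first appearance, and reports per-origin persistence fractions.  The
counting identity |flagged at t| = sum over origins o<=t of
|first at o| * persistence(o->t) holds exactly and is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .io_ingest import TIMEPOINTS


def log2_var(mock_reads, cond_reads):
    """ln(cond/mock)/ln2 with sentinels: +inf (de novo), -inf (shut down), NaN (both zero).

    Accepts scalars or arrays; negative inputs raise a validation error.
    """
    mock = np.asarray(mock_reads, dtype=float)
    cond = np.asarray(cond_reads, dtype=float)
    if (mock < 0).any() or (cond < 0).any():
        raise ValidationError("reads must be non-negative")
    out = np.full(np.broadcast(mock, cond).shape, np.nan)
    mock, cond = np.broadcast_arrays(mock, cond)
    both = (mock > 0) & (cond > 0)
    with np.errstate(divide="ignore"):
        out[both] = np.log(cond[both] / mock[both]) / np.log(2.0)
    out[(mock == 0) & (cond > 0)] = np.inf
    out[(cond == 0) & (mock > 0)] = -np.inf
    if out.ndim == 0:
        return float(out)
    return out


def detect_de_novo(records: pd.DataFrame, min_reads: float = 0.0) -> set[str]:
    """Genes with mock reads exactly 0 and condition reads positive (>= min_reads)."""
    lv = log2_var(records["mock_reads"], records["cond_reads"])
    member = np.isposinf(lv) & (records["cond_reads"].to_numpy(dtype=float) >= min_reads)
    return set(records.loc[member, "gene_id"])


def detect_shutdown(records: pd.DataFrame, min_reads: float = 0.0) -> set[str]:
    """Mirror image: condition reads exactly 0, mock reads positive (>= min_reads)."""
    lv = log2_var(records["mock_reads"], records["cond_reads"])
    member = np.isneginf(lv) & (records["mock_reads"].to_numpy(dtype=float) >= min_reads)
    return set(records.loc[member, "gene_id"])


@dataclass
class TraceTable:
    """Membership of flagged genes across timepoints with first-appearance labels."""

    membership: pd.DataFrame  # bool, genes x timepoints
    first_appearance: pd.Series  # gene -> timepoint label
    persistence: pd.DataFrame  # origin x timepoint, NaN before the origin
    new_counts: dict[str, int]  # timepoint -> newly appearing genes

    @property
    def timepoints(self) -> list[str]:
        return list(self.membership.columns)

    def flagged_at(self, timepoint: str) -> set[str]:
        return set(self.membership.index[self.membership[timepoint]])

    def to_tsv(self, path) -> None:
        out = self.membership.astype(int).copy()
        out["first_appearance"] = self.first_appearance
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def summary(self) -> dict:
        return {
            "timepoints": self.timepoints,
            "n_genes": int(len(self.membership)),
            "new_counts": self.new_counts,
            "flagged_counts": {t: int(self.membership[t].sum()) for t in self.timepoints},
            "persistence": {
                o: {t: (None if pd.isna(v) else float(v)) for t, v in row.items()}
                for o, row in self.persistence.iterrows()
            },
        }


def trace(sets: Mapping[str, Iterable[str]], order: Sequence[str] = TIMEPOINTS) -> TraceTable:
    """Trace flagged gene sets over ordered timepoints.

    Deterministic, invariant to gene order, idempotent.  ``order`` fixes both
    the column order and the meaning of "first appearance"; unknown timepoint
    labels in ``sets`` are a schema error.
    """
    unknown = set(sets) - set(order)
    if unknown:
        raise SchemaError(f"unknown timepoint label(s): {sorted(unknown)}")
    if len(sets) < 2:
        raise SchemaError("trace needs at least two timepoints")
    tps = [t for t in order if t in sets]
    as_sets = {t: set(map(str, sets[t])) for t in tps}
    genes = sorted(set().union(*as_sets.values()))
    membership = pd.DataFrame(
        {t: [g in as_sets[t] for g in genes] for t in tps}, index=pd.Index(genes, name="gene_id")
    )
    first = membership.idxmax(axis=1) if genes else pd.Series(dtype=object)
    # idxmax finds the first True column because columns follow `order`
    persistence = pd.DataFrame(np.nan, index=tps, columns=tps)
    new_counts = {}
    for i, o in enumerate(tps):
        cohort = membership.index[first == o] if genes else []
        new_counts[o] = int(len(cohort))
        for t in tps[i:]:
            if len(cohort):
                persistence.loc[o, t] = membership.loc[cohort, t].mean()
            else:
                persistence.loc[o, t] = np.nan

    # counting identity: flagged(t) == sum_o new(o) * persistence(o, t)
    for t in tps:
        total = sum(
            new_counts[o] * (persistence.loc[o, t] if not pd.isna(persistence.loc[o, t]) else 0.0)
            for o in tps[: tps.index(t) + 1]
        )
        assert round(total) == int(membership[t].sum()), "trace counting identity violated"

    return TraceTable(
        membership=membership,
        first_appearance=first,
        persistence=persistence,
        new_counts=new_counts,
    )


def maintained_fraction(set_early: Iterable[str], set_late: Iterable[str]) -> float:
    """Percent of the early set still present in the late set; NaN if early is empty."""
    early = set(set_early)
    if not early:
        return float("nan")
    late = set(set_late)
    return 100.0 * len(early & late) / len(early)
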