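"""Differential analysis by gene type (DAGT).

Decomposes a signature into the eight gene-type classes with member counts and
summed direction-relevant reads.  Classes are mutually exclusive and
exhaustive (mitochondrial takes precedence via the upstream MT policy), so the
breakdown is a partition of the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_ingest import GENE_TYPES
from .signatures import Signature


@dataclass
class GeneTypeBreakdown:
    """Per-class gene counts and read sums for one signature."""

    table: pd.DataFrame  # gene_type, n_genes, total_reads (one row per class)
    n_total: int
    reads_total: float
    timepoint: str = ""
    direction: str = ""
    annotation_source: str = ""

    def n(self, gene_type: str) -> int:
        return int(self.table.set_index("gene_type").loc[gene_type, "n_genes"])

    def reads(self, gene_type: str) -> float:
        return float(self.table.set_index("gene_type").loc[gene_type, "total_reads"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["timepoint"] = self.timepoint
        out["direction"] = self.direction
        out.to_csv(path, sep="\t", index=False)


def breakdown(signature: Signature, annotation_source: str = "") -> GeneTypeBreakdown:
    """Subclassify signature members by gene type.

    Reads are summed on the same basis used for filtering (the signature's
    ``reads`` column).  Class membership depends on the supplied annotation
    build, which is recorded in the output metadata.
    """
    df = signature.records
    grouped = df.groupby("gene_type", observed=True).agg(
        n_genes=("gene_id", "size"), total_reads=("reads", "sum")
    )
    grouped = grouped.reindex(GENE_TYPES, fill_value=0)
    grouped["total_reads"] = grouped["total_reads"].astype(float).fillna(0.0)
    table = grouped.reset_index(names="gene_type")
    return GeneTypeBreakdown(
        table=table,
        n_total=int(table["n_genes"].sum()),
        reads_total=float(table["total_reads"].sum()),
        timepoint=signature.timepoint,
        direction=signature.direction,
        annotation_source=annotation_source,
    )


@dataclass
class MitoProfile:
    """Reads of named mitochondrial genes across timepoints."""

    table: pd.DataFrame  # symbol x timepoint (values: condition reads; optional mock column)
    warnings: list[str] = field(default_factory=list)


def mito_profile(
    tables: Mapping[str, pd.DataFrame],
    symbols: Iterable[str],
    include_mock: bool = True,
) -> MitoProfile:
    """Per-timepoint reads for named (mitochondrial) genes.

    ``tables`` maps timepoint labels to annotated comparison tables.  Symbols
    that resolve nowhere are reported in the warnings field and their row is
    omitted.  The mock column, when requested, is taken from the first table
    that carries the gene.
    """
    symbols = list(symbols)
    timepoints = list(tables)
    rows = []
    warnings: list[str] = []
    for sym in symbols:
        values: dict[str, float] = {}
        mock_val = None
        for tp in timepoints:
            df = tables[tp]
            hit = df.loc[df.get("symbol", pd.Series(dtype=str)) == sym]
            if len(hit):
                values[tp] = float(hit["cond_reads"].iloc[0])
                if mock_val is None:
                    mock_val = float(hit["mock_reads"].iloc[0])
        if not values:
            warnings.append(f"symbol {sym!r} not found in any table")
            continue
        row = {"symbol": sym}
        if include_mock:
            row["mock"] = mock_val
        row.update({tp: values.get(tp) for tp in timepoints})
        rows.append(row)
    cols = ["symbol"] + (["mock"] if include_mock else []) + timepoints
    table = pd.DataFrame(rows, columns=cols)
    return MitoProfile(table=table, warnings=warnings)
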