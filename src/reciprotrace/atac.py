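"""MACE <-> ATAC integration: chromatin concordance and attribution.

Each transcriptional target (a gene in a MACE signature) is matched by gene id
against the gene-keyed ATAC accessibility table and attributed to accessible
(ATAC log2FC > 0) or less accessible (log2FC < 0) chromatin; genes with an
ATAC change of exactly 0 form a separate, reported bucket so the attribution
is total.  Concordance is the fraction of MACE targets found in the ATAC data
at all.  Matched genes are additionally split into pseudogene/non-annotated
(PG/NA) versus protein-coding (PCG) classes.

Duplicate ATAC entries for one gene are resolved by keeping the entry with the
largest absolute log2 fold change (logged).  Peak-to-gene mapping is upstream
and out of scope: ATAC input is already gene-keyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dage_st import maintained_fraction
from .io_ingest import CHROMOSOMES
from .signatures import ATAC_FILTER, FilterParams, Signature, filter_signature

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """MACE targets of one (timepoint, direction) partitioned by ATAC accessibility."""

    timepoint: str
    direction: str
    n_mace_targets: int
    n_matched: int
    n_from_accessible: int
    n_from_less_accessible: int
    n_atac_zero: int
    concordance_pct: float
    class_split: dict[str, int]  # matched genes: pg_na / pcg / other_types

    def as_dict(self) -> dict:
        return {
            "timepoint": self.timepoint,
            "direction": self.direction,
            "n_mace_targets": self.n_mace_targets,
            "n_matched": self.n_matched,
            "n_from_accessible": self.n_from_accessible,
            "n_from_less_accessible": self.n_from_less_accessible,
            "n_atac_zero": self.n_atac_zero,
            "concordance_pct": self.concordance_pct,
            "class_split": dict(self.class_split),
        }


def _dedupe_atac(atac_records: pd.DataFrame) -> pd.DataFrame:
    df = atac_records.copy()
    if df["gene_id"].duplicated().any():
        n = int(df["gene_id"].duplicated().sum())
        logger.info("ATAC table: resolving %d duplicate gene entr%s by largest |log2fc|",
                    n, "y" if n == 1 else "ies")
        df["_abs"] = df["log2fc"].abs()
        df = (
            df.sort_values(["gene_id", "_abs"], ascending=[True, False])
            .drop_duplicates("gene_id", keep="first")
            .drop(columns="_abs")
        )
    return df


def match_and_attribute(
    mace_signature: Signature,
    atac_records: pd.DataFrame,
    atac_params: FilterParams | None = ATAC_FILTER,
) -> ConcordanceResult:
    """Match a MACE signature against ATAC records and attribute by accessibility sign.

    ``atac_params`` optionally pre-filters the ATAC table with the published
    accessibility thresholds (>2 reads, p < 0.05, log2 beyond +-1 by default);
    pass None to match against the unfiltered table.
    """
    atac = _dedupe_atac(atac_records)
    if atac_params is not None and len(atac):
        keep = pd.concat(
            [
                filter_signature(atac, atac_params, "up").records,
                filter_signature(atac, atac_params, "down").records,
            ]
        )
        atac = atac.loc[atac["gene_id"].isin(set(keep["gene_id"]))]

    targets = mace_signature.gene_ids
    atac_fc = atac.set_index("gene_id")["log2fc"] if len(atac) else pd.Series(dtype=float)
    matched = sorted(targets & set(atac_fc.index))
    fc = atac_fc.loc[matched].astype(float)
    n_acc = int((fc > 0).sum())
    n_less = int((fc < 0).sum())
    n_zero = int((fc == 0).sum())

    types = (
        mace_signature.records.set_index("gene_id")["gene_type"]
        if "gene_type" in mace_signature.records.columns
        else pd.Series(dtype=object)
    )
    mtypes = types.reindex(matched)
    split = {
        "pg_na": int(mtypes.isin(["pseudogene", "non_annotated"]).sum()),
        "pcg": int((mtypes == "protein_coding").sum()),
    }
    split["other_types"] = len(matched) - split["pg_na"] - split["pcg"]

    n_targets = len(targets)
    return ConcordanceResult(
        timepoint=mace_signature.timepoint,
        direction=mace_signature.direction,
        n_mace_targets=n_targets,
        n_matched=len(matched),
        n_from_accessible=n_acc,
        n_from_less_accessible=n_less,
        n_atac_zero=n_zero,
        concordance_pct=(100.0 * len(matched) / n_targets) if n_targets else 0.0,
        class_split=split,
    )


def chromatin_maintenance(atac_early_sig: Signature | Iterable[str],
                          atac_late_sig: Signature | Iterable[str]) -> float:
    """Percent of the early accessibility signature still present at the late timepoint."""
    early = atac_early_sig.gene_ids if isinstance(atac_early_sig, Signature) else atac_early_sig
    late = atac_late_sig.gene_ids if isinstance(atac_late_sig, Signature) else atac_late_sig
    return maintained_fraction(early, late)


def export_circos(annotated: pd.DataFrame, out_dir: str | Path, value_col: str = "log2fc",
                  prefix: str = "circos") -> dict[str, Path]:
    """Write Circos-compatible plain-text data files.

    The pipeline is gene-keyed with no genomic intervals, so positions are the
    per-chromosome gene ordinal (synthetic coordinates): the karyotype spans
    chromosomes 1-22, X and MT with length = gene count, and the value file
    places each gene at its ordinal index.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = annotated.loc[annotated["chromosome"].isin(CHROMOSOMES)].copy()
    df = df.sort_values(["chromosome", "gene_id"])
    counts = df["chromosome"].value_counts()

    karyotype = out_dir / f"{prefix}.karyotype.txt"
    with open(karyotype, "w", encoding="utf-8") as fh:
        for chrom in CHROMOSOMES:
            n = int(counts.get(chrom, 0))
            if n:
                fh.write(f"chr - hs{chrom} {chrom} 0 {n} grey\n")

    values = out_dir / f"{prefix}.values.txt"
    with open(values, "w", encoding="utf-8") as fh:
        for chrom in CHROMOSOMES:
            sub = df.loc[df["chromosome"] == chrom]
            for i, (_, row) in enumerate(sub.iterrows()):
                v = row[value_col]
                if np.isfinite(v):
                    fh.write(f"hs{chrom} {i} {i + 1} {v:.4f}\n")
    return {"karyotype": karyotype, "values": values}
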