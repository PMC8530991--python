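"""Gene usage on different chromosomes (GUDC) — the chromosome fingerprint.

For a signature S drawn from a universe U (all annotated genes of that
comparison table), each chromosome c gets a usage ``100 * |S_c| / |U_c|``
percent; the mean usage is ``100 * |S| / |U|``, and the fingerprint is the
per-chromosome deviation from that mean.  Chromosome Y and unplaced ("other")
genes are dropped from both sets, with the dropped counts recorded.
Deviations weighted by universe gene counts cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError
from .io_ingest import CHROMOSOMES
from .signatures import Signature

_EXCLUDED = ("Y", "other")


@dataclass
class ChromosomeFingerprint:
    """Per-chromosome usage of a signature relative to its universe."""

    table: pd.DataFrame  # chromosome, universe_genes, signature_genes, usage_pct, deviation_pct
    mean_usage_pct: float
    n_universe: int
    n_signature: int
    dropped: dict[str, int]

    def ranked(self) -> pd.DataFrame:
        """Chromosomes ordered by deviation, most over-used first."""
        return self.table.sort_values("deviation_pct", ascending=False).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fingerprint(
    signature: Signature | set[str] | frozenset[str],
    universe: pd.DataFrame,
    include_mt: bool = True,
) -> ChromosomeFingerprint:
    """Compute the chromosome fingerprint of a signature.

    ``universe`` is the annotated comparison table the signature was filtered
    from (columns gene_id and chromosome); the signature must be a subset of
    it.  ``include_mt=False`` additionally drops chromosome MT (the published
    signatures are mitochondria-heavy; the default keeps MT).
    """
    if len(universe) == 0:
        raise ComputationError("empty universe")
    ids = signature.gene_ids if isinstance(signature, Signature) else frozenset(signature)
    uni = universe[["gene_id", "chromosome"]].copy()
    missing = ids - set(uni["gene_id"])
    if missing:
        raise ComputationError(f"signature genes absent from universe: {sorted(missing)[:10]}")

    excluded = _EXCLUDED if include_mt else _EXCLUDED + ("MT",)
    drop_mask = uni["chromosome"].isin(excluded)
    dropped = {
        lbl: int((uni.loc[drop_mask, "chromosome"] == lbl).sum()) for lbl in excluded
    }
    kept = uni.loc[~drop_mask]
    if len(kept) == 0:
        raise ComputationError("universe empty after dropping Y/other chromosomes")

    chroms = [c for c in CHROMOSOMES if include_mt or c != "MT"]
    uni_counts = kept["chromosome"].value_counts().reindex(chroms, fill_value=0)
    sig_kept = kept.loc[kept["gene_id"].isin(ids)]
    sig_counts = sig_kept["chromosome"].value_counts().reindex(chroms, fill_value=0)

    n_universe = int(uni_counts.sum())
    n_signature = int(sig_counts.sum())
    mean_usage = 100.0 * n_signature / n_universe
    with np.errstate(divide="ignore", invalid="ignore"):
        usage = np.where(uni_counts > 0, 100.0 * sig_counts / uni_counts, np.nan)
    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "universe_genes": uni_counts.to_numpy(),
            "signature_genes": sig_counts.to_numpy(),
            "usage_pct": usage,
            "deviation_pct": usage - mean_usage,
        }
    )
    return ChromosomeFingerprint(
        table=table,
        mean_usage_pct=mean_usage,
        n_universe=n_universe,
        n_signature=n_signature,
        dropped=dropped,
    )


def usage_fold_change(fp_a: ChromosomeFingerprint, fp_b: ChromosomeFingerprint) -> float:
    """Ratio of mean usages b/a; infinity sentinel when a's mean usage is 0."""
    if fp_a.mean_usage_pct == 0:
        return np.inf
    return fp_b.mean_usage_pct / fp_a.mean_usage_pct
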