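"""Pipeline orchestration: run every stage over configured timepoints and
emit signature tables, Venn regions, fingerprints, gene-type breakdowns,
trace tables, concordance results, heatmap/volcano export matrices, Circos
data files and a single JSON run summary with content hashes.

Outputs are byte-deterministic for identical inputs and configuration: no
timestamps enter any file, orderings are fixed (gene id, then the configured
timepoint order), and every threshold is echoed into the summary for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import atac as atac_mod
from . import dage_st, dagt, gudc
from .errors import ConfigurationError, PipelineError
from .io_ingest import TIMEPOINTS, ensure_annotated, read_annotation, read_diff_table
from .signatures import ATAC_FILTER, FilterParams, Signature, filter_signature, overlap, venn_to_json_dict

logger = logging.getLogger(__name__)

#: Mitochondrial genes the study highlights; default mito-profile panel.
MITO_PANEL = ("MT-ATP6", "MT-CO1", "MT-CO2", "MT-CO3", "MT-CYB", "MT-ND4",
              "MT-RNR1", "MT-RNR2")


@dataclass
class RunConfig:
    """Inputs, thresholds and flags of one pipeline run."""

    mace_paths: dict[str, str]                      # timepoint -> path
    out_dir: str
    atac_paths: dict[str, str] = field(default_factory=dict)
    counts_paths: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None
    timepoints: tuple[str, ...] = TIMEPOINTS
    expression_filter: FilterParams = field(default_factory=FilterParams)
    atac_filter: FilterParams = field(default_factory=lambda: ATAC_FILTER)
    include_mt_in_gudc: bool = True
    mito_panel: tuple[str, ...] = MITO_PANEL
    volcano_p_cap: float = 310.0
    de_novo_min_reads: float = 0.0
    column_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        tps = [t for t in self.timepoints if t in self.mace_paths]
        if len(tps) != len(set(tps)):
            raise ConfigurationError("timepoints must be unique")
        if not tps:
            raise ConfigurationError("no MACE input tables configured")
        for p in list(self.mace_paths.values()) + list(self.atac_paths.values()):
            if not Path(p).exists():
                raise ConfigurationError(f"input does not exist: {p}")
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise ConfigurationError(f"annotation does not exist: {self.annotation_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("expression_filter", "atac_filter"):
            if key in d and isinstance(d[key], dict):
                d[key] = FilterParams(**d[key])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if "mito_panel" in d:
            d["mito_panel"] = tuple(d["mito_panel"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_heatmap_matrix(
    tables: Mapping[str, pd.DataFrame],
    signatures: Mapping[tuple[str, str], Signature],
    timepoints: tuple[str, ...] = TIMEPOINTS,
    gene_type: str | None = "protein_coding",
) -> pd.DataFrame:
    """log2FC matrix over the union of signature genes across timepoints.

    Rows are the union of (by default protein-coding) signature members, one
    column per timepoint; a gene absent from a timepoint's table gets an
    explicit missing value, never 0.  Row order is gene id, column order the
    configured timepoint order.
    """
    union: set[str] = set()
    for (tp, _d), sig in signatures.items():
        recs = sig.records
        if gene_type is not None and "gene_type" in recs.columns:
            recs = recs.loc[recs["gene_type"] == gene_type]
        union |= set(recs["gene_id"])
    genes = sorted(union)
    cols = {}
    for tp in timepoints:
        if tp not in tables:
            continue
        fc = tables[tp].set_index("gene_id")["log2fc"]
        cols[tp] = fc.reindex(genes)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def export_volcano_table(table: pd.DataFrame, p_cap: float = 310.0) -> pd.DataFrame:
    """(symbol, log2fc, -log10 p) rows for external volcano rendering.

    p = 0 maps to the configurable cap (and is logged); rows without a p-value
    are dropped.
    """
    df = table.loc[table["p_value"].notna(),
                   [c for c in ("gene_id", "symbol", "log2fc", "p_value") if c in table.columns]].copy()
    zero = df["p_value"] == 0
    if zero.any():
        logger.warning("volcano export: %d p-value(s) of 0 capped at %g", int(zero.sum()), p_cap)
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = np.where(zero, p_cap, -np.log10(df["p_value"]))
    return df.drop(columns="p_value").reset_index(drop=True)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {
            "timepoints": list(config.timepoints),
            "expression_filter": vars(config.expression_filter).copy(),
            "atac_filter": vars(config.atac_filter).copy(),
            "include_mt_in_gudc": config.include_mt_in_gudc,
            "de_novo_min_reads": config.de_novo_min_reads,
            "seed": config.seed,
        },
        "outputs": {},
    }
    written: dict[str, Path] = {}

    def _stage(name: str, detail: str = ""):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    msg = f"{detail}: {exc}" if detail else str(exc)
                    raise PipelineError(name, msg) from exc
                return False
        return _Ctx()

    annotation = None
    if config.annotation_path:
        with _stage("annotation", config.annotation_path):
            annotation = read_annotation(config.annotation_path)

    tps = [t for t in config.timepoints if t in config.mace_paths]
    tables: dict[str, pd.DataFrame] = {}
    for tp in tps:
        with _stage("read_mace", config.mace_paths[tp]):
            df = read_diff_table(config.mace_paths[tp], column_map=config.column_map or None,
                                 timepoint=tp)
            tables[tp] = ensure_annotated(df, annotation)

    signatures: dict[tuple[str, str], Signature] = {}
    summary["signatures"] = {}
    for tp in tps:
        for direction in ("up", "down"):
            with _stage("filter_signature", f"{tp} {direction}"):
                sig = filter_signature(tables[tp], config.expression_filter, direction, timepoint=tp)
            signatures[(tp, direction)] = sig
            p = out_dir / f"signature_{tp}_{direction}.tsv"
            sig.to_tsv(p)
            written[f"signature_{tp}_{direction}"] = p
            summary["signatures"][f"{tp}:{direction}"] = {
                "n": len(sig), "total_reads": sig.total_reads}

    summary["venn"] = {}
    for direction in ("up", "down"):
        sets = {tp: signatures[(tp, direction)].gene_ids for tp in tps}
        if len(sets) >= 2:
            with _stage("overlap", direction):
                regions = overlap(sets)
            p = out_dir / f"venn_{direction}.json"
            p.write_text(json.dumps(venn_to_json_dict(regions), sort_keys=True, indent=1),
                         encoding="utf-8")
            written[f"venn_{direction}"] = p
            summary["venn"][direction] = {"&".join(k): len(v) for k, v in regions.items()}

    summary["gudc"] = {}
    for tp in tps:
        for direction in ("up", "down"):
            with _stage("gudc", f"{tp} {direction}"):
                fp = gudc.fingerprint(signatures[(tp, direction)], tables[tp],
                                      include_mt=config.include_mt_in_gudc)
            p = out_dir / f"gudc_{tp}_{direction}.tsv"
            fp.to_tsv(p)
            written[f"gudc_{tp}_{direction}"] = p
            summary["gudc"][f"{tp}:{direction}"] = {
                "mean_usage_pct": fp.mean_usage_pct,
                "n_universe": fp.n_universe,
                "n_signature": fp.n_signature,
            }

    summary["dagt"] = {}
    for tp in tps:
        for direction in ("up", "down"):
            with _stage("dagt", f"{tp} {direction}"):
                bd = dagt.breakdown(signatures[(tp, direction)],
                                    annotation_source=config.annotation_path or "in-table")
            p = out_dir / f"dagt_{tp}_{direction}.tsv"
            bd.to_tsv(p)
            written[f"dagt_{tp}_{direction}"] = p
            summary["dagt"][f"{tp}:{direction}"] = {
                row.gene_type: {"n": int(row.n_genes), "reads": float(row.total_reads)}
                for row in bd.table.itertuples()
            }

    with _stage("mito_profile"):
        profile = dagt.mito_profile(tables, config.mito_panel)
    p = out_dir / "mito_profile.tsv"
    profile.table.to_csv(p, sep="\t", index=False)
    written["mito_profile"] = p
    summary["mito_profile_warnings"] = profile.warnings

    summary["trace"] = {}
    if len(tps) >= 2:
        with _stage("trace"):
            dn_sets = {tp: dage_st.detect_de_novo(tables[tp], config.de_novo_min_reads)
                       for tp in tps}
            sd_sets = {tp: dage_st.detect_shutdown(tables[tp], config.de_novo_min_reads)
                       for tp in tps}
            dn_trace = dage_st.trace(dn_sets, order=config.timepoints)
            sd_trace = dage_st.trace(sd_sets, order=config.timepoints)
        for label, tr in (("de_novo", dn_trace), ("shutdown", sd_trace)):
            p = out_dir / f"trace_{label}.tsv"
            tr.to_tsv(p)
            written[f"trace_{label}"] = p
            p = out_dir / f"trace_{label}.json"
            p.write_text(json.dumps(tr.summary(), sort_keys=True, indent=1), encoding="utf-8")
            written[f"trace_{label}_summary"] = p
            summary["trace"][label] = tr.summary()

    summary["atac"] = {}
    atac_tps = [t for t in config.timepoints if t in config.atac_paths]
    for tp in atac_tps:
        with _stage("read_atac", config.atac_paths[tp]):
            adf = read_diff_table(config.atac_paths[tp], column_map=config.column_map or None,
                                  timepoint=tp)
            adf = ensure_annotated(adf, annotation)
        for direction in ("up", "down"):
            if (tp, direction) not in signatures:
                continue
            with _stage("match_and_attribute", f"{tp} {direction}"):
                conc = atac_mod.match_and_attribute(
                    signatures[(tp, direction)], adf, config.atac_filter)
            summary["atac"][f"{tp}:{direction}"] = conc.as_dict()
        with _stage("circos", tp):
            files = atac_mod.export_circos(tables[tp], out_dir, prefix=f"circos_mace_{tp}")
            written.update({f"circos_mace_{tp}_{k}": v for k, v in files.items()})
            files = atac_mod.export_circos(adf, out_dir, prefix=f"circos_atac_{tp}")
            written.update({f"circos_atac_{tp}_{k}": v for k, v in files.items()})

    with _stage("heatmap_export"):
        hm = export_heatmap_matrix(tables, signatures, config.timepoints)
    p = out_dir / "heatmap_matrix.tsv"
    hm.to_csv(p, sep="\t", na_rep="NA")
    written["heatmap_matrix"] = p
    summary["heatmap_genes"] = int(len(hm))

    for tp in tps:
        with _stage("volcano_export", tp):
            pcg = tables[tp]
            if "gene_type" in pcg.columns:
                pcg = pcg.loc[pcg["gene_type"] == "protein_coding"]
            vt = export_volcano_table(pcg, p_cap=config.volcano_p_cap)
        p = out_dir / f"volcano_{tp}.tsv"
        vt.to_csv(p, sep="\t", index=False)
        written[f"volcano_{tp}"] = p

    summary["outputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                          for k, v in sorted(written.items())}
    p = out_dir / "run_summary.json"
    p.write_text(json.dumps(summary, sort_keys=True, indent=1, default=_json_default),
                 encoding="utf-8")
    return summary


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
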