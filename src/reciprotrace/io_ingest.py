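"""Reading, validation and annotation of differential-result tables.

The pipeline is gene-keyed throughout.  A differential table holds one row per
gene for one timepoint-vs-mock comparison with DESeq2-style columns: mean
normalized reads per group, log2 fold change and a raw p-value.  Supplementary
tables in the wild mix numeric dialects — ``33,058`` and ``33.058`` both appear
as thousands-separated integers, and decimal commas occur — so numeric parsing
is deliberately tolerant for columns declared integer-like.

Annotation maps a gene id to ``(gene_type, chromosome, symbol)``.  The gene-type
taxonomy is fixed to eight classes: pseudogene, non_annotated, lincRNA, miRNA,
snoRNA, mitochondrial, protein_coding and other.  Ensembl/GENCODE biotypes are
folded onto these classes; genes without annotation become non_annotated, and
anything on chromosome MT is forced to mitochondrial.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

GENE_TYPES = (
    "pseudogene",
    "non_annotated",
    "lincRNA",
    "miRNA",
    "snoRNA",
    "mitochondrial",
    "protein_coding",
    "other",
)

#: Autosomes 1-22, X and MT.  Y is parsed and kept but excluded from GUDC.
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "MT")

TIMEPOINTS = ("d0", "d3", "d12", "d28")

#: Canonical column names of a differential table.
DIFF_COLUMNS = ("gene_id", "mock_reads", "cond_reads", "log2fc", "p_value")
OPTIONAL_COLUMNS = ("symbol", "gene_type", "chromosome", "timepoint")

_THOUSANDS_RE = re.compile(r"^[+-]?\d{1,3}(?:[.,]\d{3})+$")
_MISSING = {"", "na", "nan", "none", "null", "-"}


def parse_number(text: str, integer_like: bool = False) -> float:
    """Parse one numeric cell tolerantly.

    ``integer_like=True`` declares the column to hold (possibly large) counts,
    so both ``33,058`` and ``33.058`` are read as the thousands-separated
    integer 33058.  A single decimal comma with no dot present is accepted as
    a decimal separator when unambiguous.  Raises ``ValueError`` on anything
    else unparseable.
    """
    s = str(text).strip()
    if s.lower() in _MISSING:
        return math.nan
    low = s.lower()
    if low in {"inf", "+inf", "infinity", "+infinity"}:
        return math.inf
    if low in {"-inf", "-infinity"}:
        return -math.inf
    if integer_like and _THOUSANDS_RE.match(s):
        return float(int(re.sub(r"[.,]", "", s)))
    if "," in s and "." not in s:
        if _THOUSANDS_RE.match(s):
            return float(int(s.replace(",", "")))
        if s.count(",") == 1:
            return float(s.replace(",", "."))
        raise ValueError(f"ambiguous numeric cell {s!r}")
    return float(s)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_diff_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    timepoint: str | None = None,
    integer_like: Sequence[str] = ("mock_reads", "cond_reads"),
) -> pd.DataFrame:
    """Read one differential-result table into the canonical schema.

    Parameters
    ----------
    column_map
        Maps canonical names (``gene_id``, ``mock_reads``, ``cond_reads``,
        ``log2fc``, ``p_value``, optionally ``symbol``/``gene_type``/
        ``chromosome``) to the source file's column names.  Defaults to the
        identity mapping.
    integer_like
        Canonical columns whose cells are thousands-separated integers in
        either dot or comma dialect.

    Rows with unparseable required numeric fields are dropped; their 1-based
    data row numbers are logged and recorded in ``df.attrs["rejected_rows"]``.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in DIFF_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in DIFF_COLUMNS:
            raise SchemaError(
                f"{path.name}: required column {canonical!r} (mapped to {src!r}) not found; "
                f"available: {list(raw.columns)}"
            )
    df = raw.rename(columns=rename)[list(rename.values())].copy()

    rejected: list[tuple[int, str]] = []
    numeric = [c for c in ("mock_reads", "cond_reads", "log2fc", "p_value") if c in df.columns]
    parsed = {c: np.full(len(df), np.nan) for c in numeric}
    ok = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        for c in numeric:
            try:
                parsed[c][i] = parse_number(getattr(row, c), integer_like=c in integer_like)
            except ValueError as exc:
                rejected.append((i + 1, f"{c}: {exc}"))
                ok[i] = False
                break
    for c in numeric:
        df[c] = parsed[c]
    if rejected:
        logger.warning(
            "%s: rejected %d row(s) with unparseable fields: %s",
            path.name, len(rejected), rejected[:10],
        )
    df = df.loc[ok].reset_index(drop=True)

    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    if (df["gene_id"] == "").any():
        raise ValidationError(f"{path.name}: empty gene_id value(s)")
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
    if len(dupes):
        raise ValidationError(f"{path.name}: duplicate gene_id(s): {sorted(dupes)[:20]}")

    bad_p = df["p_value"].notna() & ((df["p_value"] < 0) | (df["p_value"] > 1))
    if bad_p.any():
        raise ValidationError(f"{path.name}: p_value outside [0,1] for {df.loc[bad_p, 'gene_id'].tolist()[:20]}")
    for col in ("mock_reads", "cond_reads"):
        if (df[col].fillna(0) < 0).any():
            raise ValidationError(f"{path.name}: negative {col}")

    if timepoint is not None:
        df["timepoint"] = timepoint
    if "chromosome" in df.columns:
        df["chromosome"] = normalize_chromosome(df["chromosome"])
    df.attrs["rejected_rows"] = rejected
    df.attrs["source"] = str(path)
    return df


def write_diff_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a differential table as TSV (field-level round-trip safe)."""
    df.to_csv(path, sep="\t", index=False)


def normalize_chromosome(values: pd.Series | Sequence[str]) -> pd.Series:
    """Strip a leading ``chr``, map M→MT, and fold unknown labels to ``other``."""
    s = pd.Series(values, dtype=str).str.strip().str.replace(r"^chr", "", regex=True)
    s = s.str.upper().replace({"M": "MT"})
    # numeric autosomes keep their plain label
    known = set(CHROMOSOMES) | {"Y"}
    return s.where(s.isin(known), "other")


def map_biotype(biotype: str | None) -> str:
    """Fold an Ensembl/GENCODE biotype onto the eight-class taxonomy."""
    if biotype is None or str(biotype).strip() == "" or str(biotype).lower() == "nan":
        return "non_annotated"
    b = str(biotype).strip()
    if b in GENE_TYPES:
        return b
    if b.endswith("pseudogene"):
        return "pseudogene"
    if b in {"lincRNA", "lncRNA"}:
        return "lincRNA"
    if b == "miRNA":
        return "miRNA"
    if b == "snoRNA":
        return "snoRNA"
    if b == "protein_coding":
        return "protein_coding"
    if b in {"Mt_rRNA", "Mt_tRNA"}:
        return "mitochondrial"
    return "other"


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf_annotation(path: Path) -> pd.DataFrame:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs:
                continue
            rows.append(
                {
                    "gene_id": attrs["gene_id"],
                    "symbol": attrs.get("gene_name", ""),
                    "gene_type": map_biotype(attrs.get("gene_biotype") or attrs.get("gene_type")),
                    "chromosome": fields[0],
                }
            )
    df = pd.DataFrame(rows, columns=["gene_id", "symbol", "gene_type", "chromosome"])
    df["chromosome"] = normalize_chromosome(df["chromosome"])
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotation from a 4-column TSV or a GTF (gene lines only).

    Returns a frame with columns gene_id, symbol, gene_type, chromosome; one
    row per gene_id.  Gene types are folded onto the eight-class taxonomy and
    chromosome labels normalized.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        df = _read_gtf_annotation(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        if first.count("\t") >= 8 and ("gene_id \"" in first or first.startswith("#")):
            df = _read_gtf_annotation(path)
        else:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            missing = {"gene_id", "gene_type", "chromosome"} - set(df.columns)
            if missing:
                raise SchemaError(f"{path.name}: annotation missing columns {sorted(missing)}")
            if "symbol" not in df.columns:
                df["symbol"] = ""
            df = df[["gene_id", "symbol", "gene_type", "chromosome"]].copy()
            df["gene_type"] = df["gene_type"].map(map_biotype)
            df["chromosome"] = normalize_chromosome(df["chromosome"])
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
    if len(dupes):
        raise ValidationError(f"{path.name}: duplicate annotation entries: {sorted(dupes)[:20]}")
    return _apply_mt_policy(df)


def _apply_mt_policy(df: pd.DataFrame) -> pd.DataFrame:
    """Make gene_type mitochondrial and chromosome MT mutually consistent."""
    df = df.copy()
    on_mt = df["chromosome"] == "MT"
    df.loc[on_mt, "gene_type"] = "mitochondrial"
    df.loc[df["gene_type"] == "mitochondrial", "chromosome"] = "MT"
    return df


def annotate(records: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.DataFrame:
    """Join annotation onto differential records; the policy is total.

    Genes absent from the annotation become gene_type ``non_annotated`` on
    chromosome ``other``; genes on chromosome MT are forced to gene_type
    ``mitochondrial`` regardless of biotype.  Deterministic and independent of
    record order.
    """
    df = records.drop(columns=[c for c in ("symbol", "gene_type", "chromosome") if c in records.columns])
    if annotation is None or len(annotation) == 0:
        ann = pd.DataFrame(columns=["gene_id", "symbol", "gene_type", "chromosome"])
    else:
        ann = annotation[["gene_id", "symbol", "gene_type", "chromosome"]]
    out = df.merge(ann, on="gene_id", how="left")
    out["symbol"] = out["symbol"].fillna("")
    out["gene_type"] = out["gene_type"].fillna("non_annotated")
    out["chromosome"] = out["chromosome"].fillna("other")
    out["gene_type"] = out["gene_type"].map(map_biotype)
    return _apply_mt_policy(out)


def ensure_annotated(records: pd.DataFrame, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Return records with gene_type/chromosome/symbol present.

    With an annotation frame, joins it (overriding in-table columns).  Without
    one, a table that already carries its own gene_type and chromosome columns
    is kept, normalized and passed through the MT policy; otherwise the total
    fallback policy applies (everything non_annotated/other).
    """
    if annotation is not None:
        return annotate(records, annotation)
    if {"gene_type", "chromosome"}.issubset(records.columns):
        df = records.copy()
        if "symbol" not in df.columns:
            df["symbol"] = ""
        df["gene_type"] = df["gene_type"].map(map_biotype)
        df["chromosome"] = normalize_chromosome(df["chromosome"])
        return _apply_mt_policy(df)
    return annotate(records, None)
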