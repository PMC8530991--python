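"""Seeded synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: a four-point
time course (d0, d3, d12, d28) of condition-vs-mock comparisons with three
biological replicates, a 30k-45k gene universe carrying biotype and chromosome
labels, negative-binomial counts, planted up/down signatures per timepoint
with a large d3/d28 overlap, planted de novo (zero-in-mock) and shut-down
(zero-in-condition) cohorts traced with a per-step retention fraction, and
paired gene-keyed accessibility tables whose change sign mirrors the planted
expression direction with a configurable coupling.

Two output paths share one planting plan and one ground truth:

* :func:`generate_counts` draws raw NB count matrices (the stochastic path,
  exercised by the normalization / substitute-test / recovery properties);
* :func:`generate_diff_tables` emits DESeq2-style result tables directly,
  with planted mean-read fields set to their planted expectations, so the
  deterministic downstream arithmetic (filter sizes, class tallies, usage
  percentages, trace counts) reproduces the planted values exactly.

Default parameter values are the study conditions; they are set once here and
are not tuned elsewhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io_ingest import GENE_TYPES, TIMEPOINTS

# ---------------------------------------------------------------------------
# configuration

#: Human mitochondrial gene symbols (chromosome MT); the generator's MT pool.
MT_SYMBOLS = (
    "MT-TF MT-RNR1 MT-TV MT-RNR2 MT-TL1 MT-ND1 MT-TI MT-TQ MT-TM MT-ND2 "
    "MT-TW MT-TA MT-TN MT-TC MT-TY MT-CO1 MT-TS1 MT-TD MT-CO2 MT-TK MT-ATP8 "
    "MT-ATP6 MT-CO3 MT-TG MT-ND3 MT-TR MT-ND4L MT-ND4 MT-TH MT-TS2 MT-TL2 "
    "MT-ND5 MT-ND6 MT-TE MT-CYB MT-TT MT-TP"
).split()

#: Relative chromosome gene-count weights (rough human annotation densities).
DEFAULT_CHROMOSOME_WEIGHTS: dict[str, float] = {
    "1": 2000, "2": 1300, "3": 1100, "4": 800, "5": 900, "6": 1000,
    "7": 950, "8": 700, "9": 800, "10": 750, "11": 1300, "12": 1050,
    "13": 350, "14": 650, "15": 650, "16": 900, "17": 1200, "18": 300,
    "19": 1450, "20": 550, "21": 250, "22": 500, "X": 850,
}


def _default_type_proportions() -> dict[str, float]:
    return {
        "protein_coding": 0.40,
        "pseudogene": 0.28,
        "lincRNA": 0.09,
        "miRNA": 0.03,
        "snoRNA": 0.015,
        "non_annotated": 0.14,
        "mitochondrial": 0.000814,
        "other": 0.044186,
    }


@dataclass(frozen=True)
class ClassAllocation:
    """One gene-type block of a planted signature: n genes summing to total_reads."""

    gene_type: str
    n: int
    total_reads: float

    @property
    def reads_per_gene(self) -> float:
        return self.total_reads / self.n


@dataclass(frozen=True)
class SignaturePlan:
    """Planted composition of one (timepoint, direction) signature."""

    classes: tuple[ClassAllocation, ...]
    log2_effect: float = 4.0

    @property
    def n(self) -> int:
        return sum(c.n for c in self.classes)


def _plan(classes: Sequence[tuple[str, int, float]], effect: float = 4.0) -> SignaturePlan:
    return SignaturePlan(tuple(ClassAllocation(*c) for c in classes), log2_effect=effect)


def _pad(listed: list[tuple[str, int, float]], printed_total: int,
         pad_reads: float = 12.0) -> list[tuple[str, int, float]]:
    """Top up class tallies to the printed signature size with non_annotated filler.

    Merges into an existing non_annotated entry so each gene type appears once.
    """
    gap = printed_total - sum(n for _, n, _ in listed)
    if gap < 0:
        raise ConfigurationError("class tallies exceed printed signature size")
    if not gap:
        return listed
    out = list(listed)
    for idx, (t, n, r) in enumerate(out):
        if t == "non_annotated":
            out[idx] = (t, n + gap, r + pad_reads * gap)
            break
    else:
        out.append(("non_annotated", gap, pad_reads * gap))
    return out


def _down(classes: list[tuple[str, int]], reads_total: float,
          printed_total: int) -> list[tuple[str, int, float]]:
    """Down-signature tallies: per-class reads shared proportionally to gene counts."""
    listed_n = sum(n for _, n in classes)
    per_gene = reads_total / listed_n
    rows = [(t, n, per_gene * n) for t, n in classes]
    return _pad(rows, printed_total)


def default_signature_plans() -> dict[tuple[str, str], SignaturePlan]:
    """Per-timepoint planted signature compositions (study-scale defaults)."""
    return {
        ("d0", "up"): _plan(_pad([
            ("pseudogene", 15, 33058.0), ("non_annotated", 4, 54.0),
            ("lincRNA", 1, 16.0), ("protein_coding", 13, 3083.0),
            ("mitochondrial", 17, 305728.0)], 50)),
        ("d0", "down"): _plan(_down(
            [("pseudogene", 2), ("non_annotated", 1), ("protein_coding", 38)], 2769.0, 42)),
        ("d3", "up"): _plan(_pad([
            ("pseudogene", 255, 110862.0), ("non_annotated", 235, 45116.0),
            ("lincRNA", 13, 328.0), ("miRNA", 5, 1831.0), ("snoRNA", 2, 23.0),
            ("protein_coding", 107, 22656.0), ("mitochondrial", 11, 83435.0)], 634)),
        ("d3", "down"): _plan(_down(
            [("pseudogene", 16), ("non_annotated", 13), ("miRNA", 1),
             ("snoRNA", 2), ("protein_coding", 24)], 1616.0, 58)),
        ("d12", "up"): _plan(_pad([
            ("pseudogene", 14, 43329.0), ("non_annotated", 4, 53.0),
            ("protein_coding", 11, 9328.0), ("mitochondrial", 19, 323283.0)], 48)),
        ("d12", "down"): _plan(_down(
            [("pseudogene", 4), ("non_annotated", 6), ("lincRNA", 1),
             ("miRNA", 2), ("protein_coding", 36)], 674.0, 50)),
        ("d28", "up"): _plan(_pad([
            ("pseudogene", 288, 93989.0), ("non_annotated", 186, 31028.0),
            ("lincRNA", 4, 80.0), ("miRNA", 4, 1497.0), ("snoRNA", 3, 51.0),
            ("protein_coding", 51, 14799.0), ("mitochondrial", 17, 72853.0)], 555)),
        ("d28", "down"): _plan(_down(
            [("pseudogene", 6), ("non_annotated", 7), ("miRNA", 1),
             ("protein_coding", 37)], 1186.0, 53)),
    }


@dataclass(frozen=True)
class TracedSetPlan:
    """Planted de-novo or shut-down structure.

    ``totals`` gives the flagged-set size at each timepoint; first-appearance
    cohorts are derived from them with a per-step retention fraction
    (``persistence``) using nested prefixes, so a dropped gene stays dropped.
    ``pcg_core`` plants that many protein-coding genes inside the day-0 cohort
    core that survives to the last timepoint.
    """

    totals: dict[str, int]
    persistence: float = 0.5
    pcg_core: int | None = None
    type_cycle: tuple[str, ...] = ("pseudogene", "protein_coding", "non_annotated")


def default_de_novo_plan() -> TracedSetPlan:
    return TracedSetPlan(
        totals={"d0": 2221, "d3": 3803, "d12": 2119, "d28": 3672},
        persistence=0.5, pcg_core=95)


def default_shutdown_plan() -> TracedSetPlan:
    return TracedSetPlan(
        totals={"d0": 3957, "d3": 3171, "d12": 3964, "d28": 2973},
        persistence=0.5)


@dataclass(frozen=True)
class MaintenancePlan:
    """One construct of the follow-up accessibility experiment: an early
    signature of n_early genes of which n_overlap recur in the late signature."""

    label: str
    n_early: int = 500
    n_overlap: int = 101
    n_late_new: int = 300


def default_maintenance_plans() -> tuple[MaintenancePlan, ...]:
    return (
        MaintenancePlan("dual", 500, 101),
        MaintenancePlan("mll_af4", 500, 31),
        MaintenancePlan("af4_mll", 500, 23),
    )


def _default_universe_sizes() -> dict[str, int]:
    # d0/d3 derived from the printed mean gene usages (50/0.0011, 634/0.0196)
    return {"d0": 45455, "d3": 32347, "d12": 43636, "d28": 31000}


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the synthetic time-course generator."""

    n_genes: int = 45455
    type_proportions: dict[str, float] = field(default_factory=_default_type_proportions)
    chromosomes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHROMOSOME_WEIGHTS))
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    baseline_mean_log_range: tuple[float, float] = (20.0, 2000.0)
    planted_signatures: dict[tuple[str, str], SignaturePlan] = field(
        default_factory=default_signature_plans)
    up_overlap_d3_d28: int = 418
    planted_de_novo: TracedSetPlan = field(default_factory=default_de_novo_plan)
    planted_shutdown: TracedSetPlan = field(default_factory=default_shutdown_plan)
    universe_sizes: dict[str, int] = field(default_factory=_default_universe_sizes)
    timepoints: tuple[str, ...] = TIMEPOINTS
    atac_timepoints: tuple[str, ...] = ("d0", "d3", "d28")
    atac_coupling: float = 0.9
    atac_coverage: float = 0.93
    atac_background: int = 800
    atac_null_rows: int = 10000
    atac_maintenance: tuple[MaintenancePlan, ...] = field(default_factory=default_maintenance_plans)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    low_expression_mean: float = 4.0
    null_log2fc_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"type_proportions must sum to 1 (got {total})")
        if any(v < 0 for v in self.type_proportions.values()):
            raise ConfigurationError("type_proportions must be non-negative")
        unknown = set(self.type_proportions) - set(GENE_TYPES)
        if unknown:
            raise ConfigurationError(f"unknown gene types: {sorted(unknown)}")
        for plan in (self.planted_de_novo, self.planted_shutdown):
            if not (0.0 <= plan.persistence <= 1.0):
                raise ConfigurationError("persistence fraction must be in [0, 1]")
        for (tp, d), plan in self.planted_signatures.items():
            if tp not in self.timepoints or d not in ("up", "down"):
                raise ConfigurationError(f"bad planted signature key {(tp, d)}")
            if plan.n > self.n_genes:
                raise ConfigurationError("planted set larger than gene universe")
            for c in plan.classes:
                if c.n > 0 and c.reads_per_gene * 2 ** abs(plan.log2_effect) > 2 ** 62:
                    raise ConfigurationError("planted effect overflows the count range")
        for tp, size in self.universe_sizes.items():
            if size > self.n_genes:
                raise ConfigurationError(f"universe size for {tp} exceeds n_genes")
        if not (0.0 <= self.atac_coupling <= 1.0 and 0.0 <= self.atac_coverage <= 1.0):
            raise ConfigurationError("atac_coupling/atac_coverage must be in [0, 1]")


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down configuration for fast tests: same structure, tiny sizes."""
    plans = {
        ("d0", "up"): _plan([("protein_coding", 20, 20 * 400.0), ("pseudogene", 5, 5 * 300.0)]),
        ("d0", "down"): _plan([("protein_coding", 15, 15 * 350.0)]),
        ("d3", "up"): _plan([("protein_coding", 30, 30 * 400.0), ("mitochondrial", 2, 2 * 5000.0)]),
        ("d3", "down"): _plan([("protein_coding", 10, 10 * 350.0)]),
        ("d12", "up"): _plan([("protein_coding", 8, 8 * 400.0)]),
        ("d12", "down"): _plan([("protein_coding", 6, 6 * 350.0)]),
        ("d28", "up"): _plan([("protein_coding", 25, 25 * 400.0), ("pseudogene", 5, 5 * 300.0)]),
        ("d28", "down"): _plan([("protein_coding", 7, 7 * 350.0)]),
    }
    cfg = SyntheticConfig(
        n_genes=3000,
        planted_signatures=plans,
        up_overlap_d3_d28=12,
        planted_de_novo=TracedSetPlan(
            totals={"d0": 60, "d3": 80, "d12": 40, "d28": 70}, persistence=0.5, pcg_core=4),
        planted_shutdown=TracedSetPlan(
            totals={"d0": 50, "d3": 40, "d12": 45, "d28": 30}, persistence=0.5),
        universe_sizes={"d0": 3000, "d3": 2500, "d12": 2800, "d28": 2400},
        atac_background=100,
        atac_null_rows=500,
        atac_maintenance=(MaintenancePlan("dual", 50, 11, 30),),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# ground truth and planting plan

@dataclass
class GroundTruth:
    """Planted structure the downstream stages must recover."""

    signatures: dict[tuple[str, str], set[str]]          # (tp, dir) -> gene ids
    de_novo_flagged: dict[str, set[str]]                 # tp -> flagged ids
    de_novo_first: dict[str, str]                        # gene -> origin tp
    shutdown_flagged: dict[str, set[str]]
    shutdown_first: dict[str, str]
    accessibility_direction: dict[str, int]              # gene -> +1 / -1
    maintenance_sets: dict[str, tuple[set[str], set[str]]]  # label -> (early, late)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signatures": {f"{tp}:{d}": sorted(v) for (tp, d), v in self.signatures.items()},
            "de_novo_flagged": {tp: sorted(v) for tp, v in self.de_novo_flagged.items()},
            "de_novo_first": self.de_novo_first,
            "shutdown_flagged": {tp: sorted(v) for tp, v in self.shutdown_flagged.items()},
            "shutdown_first": self.shutdown_first,
            "accessibility_direction": self.accessibility_direction,
            "maintenance_sets": {
                k: {"early": sorted(a), "late": sorted(b)}
                for k, (a, b) in self.maintenance_sets.items()
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8")


def largest_remainder(total: int, weights: Sequence[float],
                      names: Sequence[str] | None = None) -> list[int]:
    """Apportion ``total`` items by ``weights`` with the largest-remainder method.

    Ties in the fractional remainders are broken by name order (or by input
    order when names are not given).
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("weights must have a positive sum")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    rema = exact - base
    keys = names if names is not None else [str(i).zfill(6) for i in range(len(w))]
    order = sorted(range(len(w)), key=lambda i: (-rema[i], keys[i]))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


class _Pools:
    """Deterministic per-type gene-id pools with a draw pointer."""

    def __init__(self, annotation: pd.DataFrame, rng: np.random.Generator):
        self.by_type: dict[str, list[str]] = {}
        self.ptr: dict[str, int] = {}
        for t in GENE_TYPES:
            ids = annotation.loc[annotation["gene_type"] == t, "gene_id"].to_numpy()
            ids = ids[rng.permutation(len(ids))]
            self.by_type[t] = list(ids)
            self.ptr[t] = 0

    def take(self, gene_type: str, k: int) -> list[str]:
        p = self.ptr[gene_type]
        pool = self.by_type[gene_type]
        if p + k > len(pool):
            raise ConfigurationError(
                f"gene-type pool '{gene_type}' exhausted (need {k}, have {len(pool) - p}); "
                "increase n_genes or the type proportion"
            )
        self.ptr[gene_type] = p + k
        return pool[p:p + k]

    def peek_all(self, gene_type: str) -> list[str]:
        return self.by_type[gene_type]


@dataclass
class _PlantingPlan:
    annotation: pd.DataFrame
    sig_members: dict[tuple[str, str], pd.DataFrame]   # gene_id, gene_type, reads, effect
    de_novo: dict[str, set[str]]
    de_novo_first: dict[str, str]
    de_novo_dropped: dict[str, set[str]]               # tp -> cohort genes not flagged at tp
    shutdown: dict[str, set[str]]
    shutdown_first: dict[str, str]
    shutdown_dropped: dict[str, set[str]]
    universes: dict[str, list[str]]
    truth: GroundTruth


def _build_traced_cohorts(plan: TracedSetPlan, pools: _Pools, order: Sequence[str],
                          ) -> tuple[dict[str, set[str]], dict[str, str], dict[str, set[str]]]:
    """Derive first-appearance cohorts from per-timepoint totals and retention."""
    tps = [t for t in order if t in plan.totals]
    if not tps:
        return {}, {}, {}
    rho = plan.persistence
    cohorts: dict[str, list[str]] = {}
    sizes: dict[str, int] = {}
    for i, t in enumerate(tps):
        retained = sum(
            int(sizes[o] * rho ** (i - j) + 0.5) for j, o in enumerate(tps[:i])
        )
        n_new = plan.totals[t] - retained
        if n_new < 0:
            raise ConfigurationError(
                f"traced totals incompatible with persistence {rho}: "
                f"{t} needs {n_new} new genes"
            )
        sizes[t] = n_new
        cohorts[t] = []

    # assign gene types; the day-0 core surviving to the end carries pcg_core PCGs
    first_tp = tps[0]
    last_idx = len(tps) - 1
    core_len = int(sizes[first_tp] * rho ** last_idx + 0.5) if sizes[first_tp] else 0
    if plan.pcg_core is not None and plan.pcg_core > core_len:
        raise ConfigurationError(
            f"pcg_core {plan.pcg_core} exceeds the surviving day-0 core ({core_len})")
    for i, t in enumerate(tps):
        n_new = sizes[t]
        types: list[str] = []
        if t == first_tp and plan.pcg_core is not None:
            types += ["protein_coding"] * plan.pcg_core
            # the rest of the surviving core must stay non-PCG so the planted
            # all-timepoint PCG overlap is exactly pcg_core
            guard = ("pseudogene", "non_annotated")
            types += [guard[k % 2] for k in range(core_len - plan.pcg_core)]
        cycle = plan.type_cycle
        types += [cycle[k % len(cycle)] for k in range(n_new - len(types))]
        genes: list[str] = []
        for gt in types:
            genes.extend(pools.take(gt, 1))
        cohorts[t] = genes

    flagged: dict[str, set[str]] = {}
    dropped: dict[str, set[str]] = {}
    first: dict[str, str] = {}
    for i, t in enumerate(tps):
        fl: set[str] = set()
        dr: set[str] = set()
        for j, o in enumerate(tps[: i + 1]):
            keep = int(sizes[o] * rho ** (i - j) + 0.5) if i > j else sizes[o]
            fl.update(cohorts[o][:keep])
            dr.update(cohorts[o][keep:])
        flagged[t] = fl
        dropped[t] = dr
        for g in cohorts[t]:
            first[g] = t
    return flagged, first, dropped


# ---------------------------------------------------------------------------
# generation

def generate_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the gene annotation table (gene_id, symbol, gene_type, chromosome).

    Type counts follow the configured proportions by deterministic
    largest-remainder rounding (ties broken by type-name order); mitochondrial
    genes live on chromosome MT exclusively and carry real MT gene symbols;
    chromosome Y is absent.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    names = sorted(config.type_proportions)
    counts = largest_remainder(
        config.n_genes, [config.type_proportions[n] for n in names], names)
    type_arr = np.repeat(names, counts)
    type_arr = type_arr[rng.permutation(config.n_genes)]

    chrom_labels = [c for c in config.chromosomes if c != "MT"]
    weights = np.array([config.chromosomes[c] for c in chrom_labels], dtype=float)
    weights /= weights.sum()
    chroms = rng.choice(chrom_labels, size=config.n_genes, p=weights)
    chroms = np.where(type_arr == "mitochondrial", "MT", chroms)

    width = max(6, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]
    per_type_counter: dict[str, int] = {}
    symbols = []
    prefixes = {
        "protein_coding": "PCG", "pseudogene": "PSG", "lincRNA": "LINC",
        "miRNA": "MIR", "snoRNA": "SNORD", "non_annotated": "NA",
        "other": "OTH", "mitochondrial": "MT",
    }
    for t in type_arr:
        k = per_type_counter.get(t, 0)
        per_type_counter[t] = k + 1
        if t == "mitochondrial":
            symbols.append(MT_SYMBOLS[k % len(MT_SYMBOLS)] if k < len(MT_SYMBOLS)
                           else f"MT-SYN{k}")
        else:
            symbols.append(f"{prefixes[t]}{k + 1}")
    return pd.DataFrame(
        {"gene_id": gene_ids, "symbol": symbols, "gene_type": type_arr,
         "chromosome": chroms}
    )


def build_plan(config: SyntheticConfig,
               annotation: pd.DataFrame | None = None) -> _PlantingPlan:
    """Assign every planted role to concrete gene ids (deterministic given seed)."""
    config.validate()
    if annotation is None:
        annotation = generate_annotation(config)
    rng = np.random.default_rng([config.seed, 2])
    pools = _Pools(annotation, rng)

    de_novo, dn_first, dn_dropped = _build_traced_cohorts(
        config.planted_de_novo, pools, config.timepoints)
    shutdown, sd_first, sd_dropped = _build_traced_cohorts(
        config.planted_shutdown, pools, config.timepoints)

    # planted signatures: build d3 up first, derive the d28 up overlap from it,
    # then everything else from fresh pool genes (mitochondrial genes are drawn
    # from a prefix of the small MT pool and recur across timepoints).
    sig_ids: dict[tuple[str, str], dict[str, list[str]]] = {}
    mt_pool = pools.peek_all("mitochondrial")

    def fresh(gene_type: str, k: int) -> list[str]:
        if gene_type == "mitochondrial":
            raise ConfigurationError("mitochondrial signature genes use the shared MT prefix")
        return pools.take(gene_type, k)

    plans = config.planted_signatures
    keys = sorted(plans, key=lambda k: (config.timepoints.index(k[0]), k[1]))
    for key in keys:
        tp, direction = key
        alloc: dict[str, list[str]] = {}
        for c in plans[key].classes:
            if c.n == 0:
                continue
            if c.gene_type == "mitochondrial":
                if c.n > len(mt_pool):
                    raise ConfigurationError("mitochondrial pool too small for planted signature")
                alloc[c.gene_type] = mt_pool[: c.n]
            else:
                alloc[c.gene_type] = []  # filled below (overlap-aware)
        sig_ids[key] = alloc

    d3_key, d28_key = ("d3", "up"), ("d28", "up")
    overlap_left = 0
    if d3_key in plans and d28_key in plans and config.up_overlap_d3_d28:
        d3_classes = {c.gene_type: c.n for c in plans[d3_key].classes}
        d28_classes = {c.gene_type: c.n for c in plans[d28_key].classes}
        shared_types = [t for t in sorted(set(d3_classes) & set(d28_classes))
                        if t != "mitochondrial"]
        mt_shared = min(d3_classes.get("mitochondrial", 0), d28_classes.get("mitochondrial", 0))
        overlap_left = config.up_overlap_d3_d28 - mt_shared
        if overlap_left < 0:
            raise ConfigurationError("up_overlap_d3_d28 smaller than the shared MT prefix")
        mins = [min(d3_classes[t], d28_classes[t]) for t in shared_types]
        if overlap_left > sum(mins):
            raise ConfigurationError("up_overlap_d3_d28 exceeds shared class capacity")
        shares = largest_remainder(overlap_left, mins, shared_types) if shared_types else []
        overlap_share = dict(zip(shared_types, shares))
    else:
        overlap_share = {}

    # fill non-MT classes: d3 first, then d28 reusing the planned overlap, then the rest
    for key in keys:
        tp, direction = key
        for c in plans[key].classes:
            if c.gene_type == "mitochondrial" or c.n == 0:
                continue
            if key == d28_key and c.gene_type in overlap_share:
                k_shared = overlap_share[c.gene_type]
                shared = sig_ids[d3_key][c.gene_type][:k_shared]
                sig_ids[key][c.gene_type] = shared + fresh(c.gene_type, c.n - k_shared)
            else:
                sig_ids[key][c.gene_type] = fresh(c.gene_type, c.n)

    sig_members: dict[tuple[str, str], pd.DataFrame] = {}
    truth_sigs: dict[tuple[str, str], set[str]] = {}
    for key in keys:
        rows = []
        for c in plans[key].classes:
            if c.n == 0:
                continue
            for g in sig_ids[key][c.gene_type]:
                rows.append((g, c.gene_type, c.reads_per_gene, plans[key].log2_effect))
        df = pd.DataFrame(rows, columns=["gene_id", "gene_type", "reads", "effect"])
        if df["gene_id"].duplicated().any():
            raise ConfigurationError(f"planted sets within {key} are not disjoint")
        sig_members[key] = df
        truth_sigs[key] = set(df["gene_id"])

    # universes: planted genes for the timepoint plus a seeded fill
    universes: dict[str, list[str]] = {}
    all_ids = annotation["gene_id"].to_numpy()
    for tp in config.timepoints:
        planted = set()
        for d in ("up", "down"):
            planted |= truth_sigs.get((tp, d), set())
        planted |= de_novo.get(tp, set()) | shutdown.get(tp, set())
        planted |= dn_dropped.get(tp, set()) | sd_dropped.get(tp, set())
        size = config.universe_sizes.get(tp, config.n_genes)
        if size < len(planted):
            raise ConfigurationError(f"universe for {tp} smaller than its planted genes")
        others = np.array(sorted(set(all_ids) - planted))
        fill = others[rng.permutation(len(others))[: size - len(planted)]]
        universes[tp] = sorted(set(planted) | set(fill))

    truth = GroundTruth(
        signatures=truth_sigs,
        de_novo_flagged={t: set(v) for t, v in de_novo.items()},
        de_novo_first=dict(dn_first),
        shutdown_flagged={t: set(v) for t, v in shutdown.items()},
        shutdown_first=dict(sd_first),
        accessibility_direction={},
        maintenance_sets={},
    )
    return _PlantingPlan(
        annotation=annotation, sig_members=sig_members,
        de_novo=de_novo, de_novo_first=dn_first, de_novo_dropped=dn_dropped,
        shutdown=shutdown, shutdown_first=sd_first, shutdown_dropped=sd_dropped,
        universes=universes, truth=truth,
    )


def _gene_states(plan: _PlantingPlan, tp: str) -> pd.DataFrame:
    """Per-universe-gene state and planted means for one timepoint."""
    ann = plan.annotation.set_index("gene_id")
    ids = plan.universes[tp]
    state = pd.Series("null", index=pd.Index(ids, name="gene_id"))
    mean_mock = pd.Series(np.nan, index=state.index)
    mean_cond = pd.Series(np.nan, index=state.index)
    effect = pd.Series(np.nan, index=state.index)
    for d in ("up", "down"):
        df = plan.sig_members.get((tp, d))
        if df is None:
            continue
        idx = df.set_index("gene_id")
        state.loc[idx.index] = d
        if d == "up":
            mean_cond.loc[idx.index] = idx["reads"]
            mean_mock.loc[idx.index] = idx["reads"] / 2.0 ** idx["effect"]
        else:
            mean_mock.loc[idx.index] = idx["reads"]
            mean_cond.loc[idx.index] = idx["reads"] / 2.0 ** idx["effect"]
        effect.loc[idx.index] = idx["effect"] * (1 if d == "up" else -1)
    for name, flagged in (("de_novo", plan.de_novo), ("shutdown", plan.shutdown)):
        fl = flagged.get(tp, set())
        state.loc[state.index.isin(fl)] = name
    dropped = plan.de_novo_dropped.get(tp, set()) | plan.shutdown_dropped.get(tp, set())
    state.loc[state.index.isin(dropped) & (state == "null")] = "dropped_trace"
    out = pd.DataFrame({
        "state": state, "mean_mock": mean_mock, "mean_cond": mean_cond, "effect": effect,
    })
    out["gene_type"] = ann.loc[out.index, "gene_type"]
    out["chromosome"] = ann.loc[out.index, "chromosome"]
    out["symbol"] = ann.loc[out.index, "symbol"]
    return out


def generate_diff_tables(
    config: SyntheticConfig,
    annotation: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame],
           dict[str, tuple[pd.DataFrame, pd.DataFrame]], GroundTruth]:
    """Emit DESeq2-style result tables per timepoint plus paired ATAC tables.

    Planted genes carry their planted expectations in the mean-read fields
    (signature members their class means, de novo genes an exact mock zero);
    unplanted genes get log-uniform baselines with a small random log2 shift
    and uniform p-values.  Returns (expression tables, accessibility tables,
    maintenance table pairs, ground truth).
    """
    config.validate()
    plan = build_plan(config, annotation)
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.baseline_mean_log_range
    tables: dict[str, pd.DataFrame] = {}
    for tp in config.timepoints:
        st = _gene_states(plan, tp)
        n = len(st)
        base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        delta = rng.normal(0.0, config.null_log2fc_sd, size=n)
        p_null = rng.uniform(0.0, 1.0, size=n)
        p_hit = rng.uniform(1e-8, 0.01, size=n)
        low = rng.uniform(0.5, 2.0 * config.low_expression_mean, size=n)
        low2 = rng.uniform(0.5, 2.0 * config.low_expression_mean, size=n)

        mock = base.copy()
        cond = base * 2.0 ** delta
        l2fc = delta.copy()
        p = p_null.copy()
        s = st["state"].to_numpy()

        is_sig = (s == "up") | (s == "down")
        mock[is_sig] = st["mean_mock"].to_numpy()[is_sig]
        cond[is_sig] = st["mean_cond"].to_numpy()[is_sig]
        l2fc[is_sig] = st["effect"].to_numpy()[is_sig]
        p[is_sig] = p_hit[is_sig]

        dn = s == "de_novo"
        mock[dn] = 0.0
        cond[dn] = low[dn]
        l2fc[dn] = np.inf
        sd = s == "shutdown"
        cond[sd] = 0.0
        mock[sd] = low[sd]
        l2fc[sd] = -np.inf
        dr = s == "dropped_trace"
        mock[dr] = low[dr]
        cond[dr] = low2[dr]
        l2fc[dr] = np.log2(cond[dr] / mock[dr])

        tables[tp] = pd.DataFrame({
            "gene_id": st.index,
            "symbol": st["symbol"].to_numpy(),
            "gene_type": st["gene_type"].to_numpy(),
            "chromosome": st["chromosome"].to_numpy(),
            "mock_reads": mock,
            "cond_reads": cond,
            "log2fc": l2fc,
            "p_value": p,
            "timepoint": tp,
        }).reset_index(drop=True)

    atac = _generate_atac(config, plan, rng)
    maintenance = _generate_maintenance(config, plan, rng)
    return tables, atac, maintenance, plan.truth


def _atac_row_block(ids, ann, rng, tp, signs=None, deregulated=True,
                    null_sd=0.15):
    n = len(ids)
    mock = rng.uniform(5.0, 50.0, size=n)
    if deregulated:
        mag = rng.uniform(1.2, 3.0, size=n)
        fc = mag * (signs if signs is not None else rng.choice([-1.0, 1.0], size=n))
        p = rng.uniform(1e-8, 0.04, size=n)
    else:
        fc = rng.normal(0.0, null_sd, size=n)
        p = rng.uniform(0.0, 1.0, size=n)
    sub = ann.loc[ids]
    return pd.DataFrame({
        "gene_id": ids,
        "symbol": sub["symbol"].to_numpy(),
        "gene_type": sub["gene_type"].to_numpy(),
        "chromosome": sub["chromosome"].to_numpy(),
        "mock_reads": mock,
        "cond_reads": mock * 2.0 ** fc,
        "log2fc": fc,
        "p_value": p,
        "timepoint": tp,
    })


def _generate_atac(config: SyntheticConfig, plan: _PlantingPlan,
                   rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    ann = plan.annotation.set_index("gene_id")
    out: dict[str, pd.DataFrame] = {}
    for tp in config.atac_timepoints:
        blocks = []
        covered_sig: set[str] = set()
        for d in ("up", "down"):
            members = plan.sig_members.get((tp, d))
            if members is None or not len(members):
                continue
            ids = members["gene_id"].to_numpy()
            n_cov = int(round(config.atac_coverage * len(ids)))
            cov = ids[rng.permutation(len(ids))[:n_cov]]
            covered_sig |= set(cov)
            n_agree = int(round(config.atac_coupling * len(cov)))
            direction = 1.0 if d == "up" else -1.0
            signs = np.full(len(cov), -direction)
            agree_idx = rng.permutation(len(cov))[:n_agree]
            signs[agree_idx] = direction
            for g, sgn in zip(cov, signs):
                plan.truth.accessibility_direction[g] = int(sgn)
            blocks.append(_atac_row_block(list(cov), ann, rng, tp, signs=signs))
        # accessibility-only deregulated background
        uni = [g for g in plan.universes[tp] if g not in covered_sig]
        uni = np.array(uni)
        bg = uni[rng.permutation(len(uni))[: config.atac_background]]
        blocks.append(_atac_row_block(list(bg), ann, rng, tp, deregulated=True,
                                      signs=rng.choice([-1.0, 1.0], size=len(bg))))
        rest = np.array([g for g in uni if g not in set(bg)])
        null_ids = rest[rng.permutation(len(rest))[: config.atac_null_rows]]
        blocks.append(_atac_row_block(list(null_ids), ann, rng, tp, deregulated=False,
                                      null_sd=config.null_log2fc_sd))
        df = pd.concat(blocks, ignore_index=True)
        out[tp] = df.sort_values("gene_id").reset_index(drop=True)
    return out


def _generate_maintenance(config: SyntheticConfig, plan: _PlantingPlan,
                          rng: np.random.Generator
                          ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    ann = plan.annotation.set_index("gene_id")
    all_ids = plan.annotation["gene_id"].to_numpy()
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for mp in config.atac_maintenance:
        if mp.n_overlap > mp.n_early:
            raise ConfigurationError("maintenance overlap exceeds early set size")
        need = mp.n_early + mp.n_late_new
        pick = all_ids[rng.permutation(len(all_ids))[:need]]
        early = pick[: mp.n_early]
        late = np.concatenate([early[: mp.n_overlap], pick[mp.n_early:]])
        null_ids = all_ids[rng.permutation(len(all_ids))[:200]]
        early_df = pd.concat([
            _atac_row_block(list(early), ann, rng, "d3",
                            signs=rng.choice([-1.0, 1.0], size=len(early))),
            _atac_row_block(list(null_ids), ann, rng, "d3", deregulated=False),
        ], ignore_index=True)
        late_df = pd.concat([
            _atac_row_block(list(late), ann, rng, "d28",
                            signs=rng.choice([-1.0, 1.0], size=len(late))),
            _atac_row_block(list(null_ids), ann, rng, "d28", deregulated=False),
        ], ignore_index=True)
        early_df = early_df.drop_duplicates("gene_id").reset_index(drop=True)
        late_df = late_df.drop_duplicates("gene_id").reset_index(drop=True)
        out[mp.label] = (early_df, late_df)
        plan.truth.maintenance_sets[mp.label] = (set(early), set(late))
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             size: tuple[int, int]) -> np.ndarray:
    """NB(mean, dispersion) counts; Poisson limit for tiny dispersion."""
    mu = np.broadcast_to(np.asarray(mean, dtype=float)[:, None], size)
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    out = np.zeros(size, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def generate_counts(
    config: SyntheticConfig,
    annotation: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Draw per-timepoint raw NB count matrices (mock and condition replicates).

    Column names are ``mock_1..n`` and ``cond_1..n``; per-sample library-size
    factors are drawn from ``size_factor_range`` and multiply all means, so
    median-of-ratios normalization has something to undo.  The planted zero
    patterns are exact: groups of genes not planted as de novo / shut down are
    never left all-zero (one replicate is bumped to 1 if sampling produced an
    all-zero group), and the expressed group of a planted de novo / shut-down
    gene always has at least one nonzero replicate.
    """
    config.validate()
    plan = build_plan(config, annotation)
    rng = np.random.default_rng([config.seed, 4])
    lo, hi = config.baseline_mean_log_range
    nrep = config.n_replicates
    out: dict[str, pd.DataFrame] = {}
    for tp in config.timepoints:
        st = _gene_states(plan, tp)
        n = len(st)
        base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        low = rng.uniform(0.5, 2.0 * config.low_expression_mean, size=n)
        low2 = rng.uniform(0.5, 2.0 * config.low_expression_mean, size=n)
        s = st["state"].to_numpy()
        mock_mean = base.copy()
        cond_mean = base.copy()
        is_sig = (s == "up") | (s == "down")
        mock_mean[is_sig] = st["mean_mock"].to_numpy()[is_sig]
        cond_mean[is_sig] = st["mean_cond"].to_numpy()[is_sig]
        dn = s == "de_novo"
        mock_mean[dn], cond_mean[dn] = 0.0, low[dn]
        sd = s == "shutdown"
        mock_mean[sd], cond_mean[sd] = low[sd], 0.0
        dr = s == "dropped_trace"
        mock_mean[dr], cond_mean[dr] = low[dr], low2[dr]

        sf = rng.uniform(*config.size_factor_range, size=2 * nrep)
        mock_counts = np.column_stack([
            _nb_draw(rng, mock_mean * sf[j], config.nb_dispersion, (n, 1))[:, 0]
            for j in range(nrep)
        ])
        cond_counts = np.column_stack([
            _nb_draw(rng, cond_mean * sf[nrep + j], config.nb_dispersion, (n, 1))[:, 0]
            for j in range(nrep)
        ])
        # exact zero-pattern guarantee
        fix_mock = (mock_counts.sum(axis=1) == 0) & ~dn
        mock_counts[fix_mock, 0] = 1
        fix_cond = (cond_counts.sum(axis=1) == 0) & ~sd
        cond_counts[fix_cond, 0] = 1

        cols = {f"mock_{j + 1}": mock_counts[:, j] for j in range(nrep)}
        cols.update({f"cond_{j + 1}": cond_counts[:, j] for j in range(nrep)})
        out[tp] = pd.DataFrame(cols, index=pd.Index(st.index, name="gene_id"))
    return out, plan.truth


# ---------------------------------------------------------------------------
# serialization

def write_dataset(out_dir: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Generate and write the full synthetic dataset (tables, annotation, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    tables, atac, maintenance, truth = generate_diff_tables(config, annotation)
    paths: dict[str, Path] = {}
    p = out_dir / "annotation.tsv"
    annotation.to_csv(p, sep="\t", index=False)
    paths["annotation"] = p
    for tp, df in tables.items():
        p = out_dir / f"mace_{tp}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"mace_{tp}"] = p
    for tp, df in atac.items():
        p = out_dir / f"atac_{tp}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"atac_{tp}"] = p
    for label, (early, late) in maintenance.items():
        for tag, df in (("early", early), ("late", late)):
            p = out_dir / f"atac2_{label}_{tag}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"atac2_{label}_{tag}"] = p
    p = out_dir / "ground_truth.json"
    truth.to_json(p)
    paths["ground_truth"] = p
    p = out_dir / "config.yaml"
    save_config(config, p)
    paths["config"] = p
    return paths


def _to_plain(obj):
    """Recursively convert tuples to lists for YAML emission."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    d = asdict(config)
    d["planted_signatures"] = {
        f"{tp}:{dr}": {"log2_effect": plan["log2_effect"],
                       "classes": [list(c.values()) for c in plan["classes"]]}
        for (tp, dr), plan in d["planted_signatures"].items()
    }
    Path(path).write_text(yaml.safe_dump(_to_plain(d), sort_keys=True), encoding="utf-8")


def load_config(path: str | Path) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    sigs = {}
    for key, plan in d.pop("planted_signatures", {}).items():
        tp, dr = key.split(":")
        sigs[(tp, dr)] = SignaturePlan(
            tuple(ClassAllocation(*c) for c in plan["classes"]),
            log2_effect=plan["log2_effect"])
    d["planted_signatures"] = sigs
    d["planted_de_novo"] = TracedSetPlan(**{
        **d["planted_de_novo"],
        "type_cycle": tuple(d["planted_de_novo"]["type_cycle"])})
    d["planted_shutdown"] = TracedSetPlan(**{
        **d["planted_shutdown"],
        "type_cycle": tuple(d["planted_shutdown"]["type_cycle"])})
    d["atac_maintenance"] = tuple(MaintenancePlan(**m) for m in d["atac_maintenance"])
    d["baseline_mean_log_range"] = tuple(d["baseline_mean_log_range"])
    d["size_factor_range"] = tuple(d["size_factor_range"])
    d["timepoints"] = tuple(d["timepoints"])
    d["atac_timepoints"] = tuple(d["atac_timepoints"])
    return SyntheticConfig(**d)
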