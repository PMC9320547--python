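"""Extracellular-flux stress-test metrics.

Turns injection-scheduled ECAR/OCR traces from a Seahorse-style plate into
the standard bioenergetic quantities:

* glycolysis stress test (ECAR, mpH/min; injections glucose -> oligomycin
  -> 2-deoxyglucose): non-glycolytic acidification, basal glycolysis,
  glycolytic capacity, glycolytic reserve, capacity-utilization fraction;
* mitochondrial stress test (OCR, pmol O2/min; injections oligomycin ->
  FCCP -> rotenone/antimycin A): non-mitochondrial respiration, basal
  respiration, ATP-linked respiration, proton leak, maximal respiration,
  spare respiratory capacity, capacity-utilization fraction.

Rates may be normalized per fixed cell number (post-run counts), and
condition-level summaries compare adherent vs suspended wells with Welch's
two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

GLYCOLYSIS_STRESS = "glycolysis_stress"
MITO_STRESS = "mito_stress"

#: canonical injection order per assay kind; segment 0 precedes the first
#: injection (glucose-free baseline for ECAR, basal respiration for OCR)
CANONICAL_COMPOUNDS = {
    GLYCOLYSIS_STRESS: ("glucose", "oligomycin", "2DG"),
    MITO_STRESS: ("oligomycin", "FCCP", "rotenone/antimycin A"),
}

#: segment labels = baseline then one per injected compound
SEGMENT_LABELS = {
    GLYCOLYSIS_STRESS: ("baseline", "glucose", "oligomycin", "2DG"),
    MITO_STRESS: ("baseline", "oligomycin", "FCCP", "rotenone/antimycin A"),
}


class FluxValidationError(ValueError):
    """Raised when a trace, schedule or metric input violates its contract."""


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered compound injections with the measurement cycle they follow.

    ``injections`` is a list of ``(compound, after_cycle)`` pairs; the cycle
    index of an injection belongs to the preceding segment (segments are
    half-open on the right).
    """

    assay_kind: str
    injections: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.assay_kind not in CANONICAL_COMPOUNDS:
            raise FluxValidationError(f"unknown assay kind: {self.assay_kind!r}")
        expected = CANONICAL_COMPOUNDS[self.assay_kind]
        compounds = tuple(c for c, _ in self.injections)
        if compounds != expected:
            raise FluxValidationError(
                f"{self.assay_kind} expects injections {expected}, got {compounds}"
            )
        cycles = [i for _, i in self.injections]
        if any(b <= a for a, b in zip(cycles, cycles[1:])) or any(c < 1 for c in cycles):
            raise FluxValidationError("injection cycle indices must be strictly increasing and >= 1")

    @property
    def segment_labels(self) -> tuple[str, ...]:
        return SEGMENT_LABELS[self.assay_kind]

    def segment_slices(self, n_cycles: int) -> list[slice]:
        """Half-open cycle ranges per segment over a trace of n_cycles."""
        bounds = [0] + [c for _, c in self.injections] + [n_cycles]
        if bounds[-2] > n_cycles:
            raise FluxValidationError("injection cycle index beyond trace length")
        return [slice(a, b) for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class FluxTrace:
    """One well's timed rate measurements plus its injection schedule."""

    well: str
    kind: str  # "ECAR" (mpH/min) or "OCR" (pmol O2/min)
    time_min: np.ndarray
    rates: np.ndarray
    schedule: InjectionSchedule
    cell_count: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "rates", r)
        if self.kind not in ("ECAR", "OCR"):
            raise FluxValidationError(f"measurement kind must be ECAR or OCR, got {self.kind!r}")
        if t.shape != r.shape or t.ndim != 1:
            raise FluxValidationError("time and rate vectors must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise FluxValidationError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise FluxValidationError("rates must be finite")
        if self.cell_count <= 0:
            raise FluxValidationError("cell_count must be positive")

    @property
    def n_cycles(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class SegmentLevels:
    """Estimated plateau rate per schedule segment."""

    assay_kind: str
    levels: dict[str, float]
    n_points: dict[str, int]
    sd: dict[str, float]

    def __getitem__(self, label: str) -> float:
        return self.levels[label]


@dataclass
class GlycolysisMetrics:
    non_glycolytic_acidification: float
    basal_glycolysis: float
    glycolytic_capacity: float
    glycolytic_reserve: float
    utilization_fraction: float
    warnings: list[str] = field(default_factory=list)

    RATE_FIELDS = (
        "non_glycolytic_acidification",
        "basal_glycolysis",
        "glycolytic_capacity",
        "glycolytic_reserve",
    )


@dataclass
class MitoMetrics:
    non_mitochondrial_ocr: float
    basal_respiration: float
    atp_linked_respiration: float
    proton_leak: float
    maximal_respiration: float
    spare_capacity: float
    utilization_fraction: float
    warnings: list[str] = field(default_factory=list)

    RATE_FIELDS = (
        "non_mitochondrial_ocr",
        "basal_respiration",
        "atp_linked_respiration",
        "proton_leak",
        "maximal_respiration",
        "spare_capacity",
    )


def segment_trace(trace: FluxTrace, k: int = 3, drop_first_post_injection: bool = True) -> SegmentLevels:
    """Estimate per-segment plateau levels.

    Each level is the mean of the last ``min(k, n_segment)`` cycles of its
    segment. For non-first segments with more than ``k`` cycles the first
    post-injection cycle is excluded before taking the last ``k``, to skip
    the mixing/equilibration transient.
    """
    slices = trace.schedule.segment_slices(trace.n_cycles)
    labels = trace.schedule.segment_labels
    levels: dict[str, float] = {}
    n_points: dict[str, int] = {}
    sds: dict[str, float] = {}
    for i, (label, sl) in enumerate(zip(labels, slices)):
        seg = trace.rates[sl]
        if len(seg) == 0:
            raise FluxValidationError(f"segment {label!r} has no measurement cycles")
        if i > 0 and drop_first_post_injection and len(seg) > k:
            seg = seg[1:]
        used = seg[-k:] if len(seg) > k else seg
        levels[label] = float(np.mean(used))
        n_points[label] = len(used)
        sds[label] = float(np.std(used, ddof=1)) if len(used) > 1 else 0.0
    return SegmentLevels(trace.schedule.assay_kind, levels, n_points, sds)


def glycolysis_stress_metrics(levels: SegmentLevels) -> GlycolysisMetrics:
    """Derive glycolysis stress-test metrics from segment plateaus.

    Basal glycolysis is the glucose response above the glucose-free
    baseline; glycolytic capacity is the oligomycin (ATP-synthase blocked)
    response above the same baseline; reserve = capacity - basal.
    Negative derived values are reported as computed with a warning flag.
    """
    if levels.assay_kind != GLYCOLYSIS_STRESS:
        raise FluxValidationError(f"expected {GLYCOLYSIS_STRESS} levels, got {levels.assay_kind}")
    non_glyc = levels["baseline"]
    basal = levels["glucose"] - non_glyc
    capacity = levels["oligomycin"] - non_glyc
    reserve = capacity - basal
    warns: list[str] = []
    if capacity > 0:
        utilization = basal / capacity
    else:
        utilization = math.nan
        warns.append("utilization undefined: glycolytic capacity <= 0")
    for name, val in (("basal_glycolysis", basal), ("glycolytic_capacity", capacity),
                      ("glycolytic_reserve", reserve)):
        if val < 0:
            warns.append(f"negative {name}: {val:.4g}")
    return GlycolysisMetrics(non_glyc, basal, capacity, reserve, utilization, warns)


def mito_stress_metrics(levels: SegmentLevels) -> MitoMetrics:
    """Derive mitochondrial stress-test metrics from segment plateaus.

    Rotenone/antimycin A block the electron transport chain, so that
    segment's level is non-mitochondrial OCR and every respiration quantity
    is measured above it. Oligomycin blocks ATP synthase (its drop from
    baseline is ATP-linked respiration; its excess over non-mitochondrial
    OCR is proton leak) and FCCP uncouples to reveal maximal respiration.
    """
    if levels.assay_kind != MITO_STRESS:
        raise FluxValidationError(f"expected {MITO_STRESS} levels, got {levels.assay_kind}")
    non_mito = levels["rotenone/antimycin A"]
    basal = levels["baseline"] - non_mito
    atp_linked = levels["baseline"] - levels["oligomycin"]
    proton_leak = levels["oligomycin"] - non_mito
    maximal = levels["FCCP"] - non_mito
    spare = maximal - basal
    warns: list[str] = []
    if maximal != 0:
        utilization = basal / maximal
    else:
        utilization = math.nan
        warns.append("utilization undefined: maximal respiration = 0")
    for name, val in (("basal_respiration", basal), ("atp_linked_respiration", atp_linked),
                      ("proton_leak", proton_leak), ("maximal_respiration", maximal),
                      ("spare_capacity", spare)):
        if val < 0:
            warns.append(f"negative {name}: {val:.4g}")
    return MitoMetrics(non_mito, basal, atp_linked, proton_leak, maximal, spare,
                       utilization, warns)


def normalize_per_cells(metrics, cell_count: int, unit_cells: int = 10_000):
    """Rescale every rate field to a fixed cell number (default per 10^4 cells).

    Utilization fractions are ratios of rates and are left untouched.
    """
    if cell_count <= 0:
        raise FluxValidationError("cell_count must be positive")
    factor = unit_cells / cell_count
    updates = {f: getattr(metrics, f) * factor for f in metrics.RATE_FIELDS}
    return replace(metrics, **updates)


def ocr_ecar_ratio(mito: MitoMetrics, glyco: GlycolysisMetrics) -> float:
    """Basal respiration over basal glycolysis: the oxidative-vs-glycolytic
    preference index. NaN (flagged) when basal glycolysis is non-positive."""
    if glyco.basal_glycolysis <= 0:
        warnings.warn("OCR/ECAR ratio undefined: basal glycolysis <= 0", stacklevel=2)
        return math.nan
    return mito.basal_respiration / glyco.basal_glycolysis


def metrics_to_row(metrics) -> dict[str, float]:
    """Flatten a metrics object to a {metric_name: value} mapping."""
    row = {f: getattr(metrics, f) for f in metrics.RATE_FIELDS}
    row["utilization_fraction"] = metrics.utilization_fraction
    return row


def trace_metrics(trace: FluxTrace, k: int = 3, unit_cells: int | None = 10_000):
    """segment_trace -> stress-test metrics (-> per-cell normalization)."""
    levels = segment_trace(trace, k=k)
    if levels.assay_kind == GLYCOLYSIS_STRESS:
        m = glycolysis_stress_metrics(levels)
    else:
        m = mito_stress_metrics(levels)
    if unit_cells is not None:
        m = normalize_per_cells(m, trace.cell_count, unit_cells)
    return m


def compare_conditions(
    well_metrics: pd.DataFrame,
    reference: str,
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Condition-level summary and Welch comparison per metric.

    ``well_metrics`` is tidy: one row per well with a condition column and
    one numeric column per metric. Returns one row per (condition, metric)
    with mean, sample SD, fold over the reference condition's mean, and a
    two-sided Welch t-test p-value against the reference (NaN with a warning
    when either group has fewer than two wells).
    """
    metric_cols = [c for c in well_metrics.columns if c != condition_col]
    conditions = list(dict.fromkeys(well_metrics[condition_col]))
    if reference not in conditions:
        raise FluxValidationError(f"reference condition {reference!r} not present")
    rows = []
    ref_df = well_metrics[well_metrics[condition_col] == reference]
    for cond in conditions:
        sub = well_metrics[well_metrics[condition_col] == cond]
        for m in metric_cols:
            x = sub[m].to_numpy(dtype=float)
            ref = ref_df[m].to_numpy(dtype=float)
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else math.nan
            ref_mean = float(np.mean(ref))
            fold = mean / ref_mean if ref_mean != 0 else math.nan
            if cond == reference:
                p = math.nan
            elif len(x) >= 2 and len(ref) >= 2:
                p = float(stats.ttest_ind(x, ref, equal_var=False).pvalue)
            else:
                warnings.warn(
                    f"Welch test skipped for {m} ({cond} vs {reference}): <2 wells",
                    stacklevel=2,
                )
                p = math.nan
            rows.append({
                "condition": cond, "metric": m, "mean": mean, "sd": sd,
                "n_wells": len(x), "fold_vs_reference": fold, "p_value": p,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate TSV I/O: one row per (well, cycle) plus sidecar schedule/cell tables
# ---------------------------------------------------------------------------

def write_plate_tsv(traces: list[FluxTrace], plate_path, schedule_path, cells_path) -> None:
    rows = []
    for tr in traces:
        for cyc, (t, r) in enumerate(zip(tr.time_min, tr.rates)):
            rows.append({"well": tr.well, "kind": tr.kind, "cycle": cyc,
                         "time_min": t, "rate": r})
    pd.DataFrame(rows).to_csv(plate_path, sep="\t", index=False)
    sched = traces[0].schedule
    pd.DataFrame(
        [{"assay_kind": sched.assay_kind, "compound": c, "after_cycle": i}
         for c, i in sched.injections]
    ).to_csv(schedule_path, sep="\t", index=False)
    pd.DataFrame(
        [{"well": tr.well, "cells": tr.cell_count} for tr in traces]
    ).to_csv(cells_path, sep="\t", index=False)


def read_plate_tsv(plate_path, schedule_path, cells_path) -> list[FluxTrace]:
    plate = pd.read_csv(plate_path, sep="\t")
    sched_df = pd.read_csv(schedule_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t").set_index("well")["cells"]
    schedule = InjectionSchedule(
        assay_kind=str(sched_df["assay_kind"].iloc[0]),
        injections=tuple((str(c), int(i)) for c, i in
                         zip(sched_df["compound"], sched_df["after_cycle"])),
    )
    traces = []
    for well, grp in plate.groupby("well", sort=False):
        grp = grp.sort_values("cycle")
        traces.append(FluxTrace(
            well=str(well),
            kind=str(grp["kind"].iloc[0]),
            time_min=grp["time_min"].to_numpy(dtype=float),
            rates=grp["rate"].to_numpy(dtype=float),
            schedule=schedule,
            cell_count=int(cells.loc[str(well)]),
        ))
    return traces
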