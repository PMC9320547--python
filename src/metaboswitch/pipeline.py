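"""End-to-end pipeline: simulate -> analyze -> report.

Stages are plain functions over the library so the numbered analysis
drivers, the CLI and the tests all share one code path. ``run_pipeline``
wires them together over the mirror dataset (or user-supplied tables),
writes tidy TSVs, a human-readable report and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import (
    ddct_fold,
    proliferation_ratio,
    relative_lactate,
    ros_relative,
    sensitivity_contrast,
)
from .flux import (
    GLYCOLYSIS_STRESS,
    compare_conditions,
    metrics_to_row,
    trace_metrics,
)
from .screen import (
    consistent_direction_screen,
    relative_expression_table,
    select_gene_sets,
    transporter_panel,
    union_genes,
    write_gmt,
    write_study_tsv,
)
from .synthetic import (
    ADHESION,
    SUSPENSION,
    MIRROR_GLUCOSE_NORMAL,
    MIRROR_QPCR_FOLDS,
    MirrorDataset,
    generate_mirror_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis parameters and output location for one pipeline run."""

    out_dir: str
    seed: int = 0
    k_cycles: int = 3            # plateau estimator window
    tau: float = 0.10            # consistent-direction threshold (fraction)
    bold_threshold: float = 0.35  # panel |r| marking threshold
    unit_cells: int = 10_000     # rate normalization denominator
    keyword: str = "glucose"

    def validate(self) -> None:
        if self.k_cycles < 1:
            raise ValueError("k_cycles must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.unit_cells <= 0:
            raise ValueError("unit_cells must be positive")
        if not self.keyword:
            raise ValueError("keyword must be non-empty")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load from a declarative YAML file; keyword overrides win."""
        import yaml

        with open(path) as fh:
            params = yaml.safe_load(fh) or {}
        unknown = set(params) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**params)

    def digest(self) -> str:
        params = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def flux_stage(dataset: MirrorDataset, k_cycles: int = 3, unit_cells: int = 10_000):
    """Per-well metrics, condition summaries and the OCR/ECAR ratio fold."""
    well_rows = []
    basal = {("ECAR", ADHESION): [], ("ECAR", SUSPENSION): [],
             ("OCR", ADHESION): [], ("OCR", SUSPENSION): []}
    warnings_log: list[str] = []
    for plate, kind in ((dataset.ecar_plate, "ECAR"), (dataset.ocr_plate, "OCR")):
        for tr in plate.traces:
            cond = plate.condition_of[tr.well]
            m = trace_metrics(tr, k=k_cycles, unit_cells=unit_cells)
            warnings_log.extend(f"{tr.well}: {w}" for w in m.warnings)
            row = {"well": tr.well, "kind": kind, "condition": cond}
            row.update(metrics_to_row(m))
            well_rows.append(row)
            key = "basal_glycolysis" if kind == "ECAR" else "basal_respiration"
            basal[(kind, cond)].append(row[key])
    well_df = pd.DataFrame(well_rows)

    summaries = {}
    for kind in ("ECAR", "OCR"):
        sub = well_df[well_df["kind"] == kind].drop(columns=["well", "kind"])
        sub = sub.dropna(axis=1, how="all")  # the other assay family's metrics
        summaries[kind] = compare_conditions(sub, reference=ADHESION)

    ratio = {c: float(np.mean(basal[("OCR", c)])) / float(np.mean(basal[("ECAR", c)]))
             for c in (ADHESION, SUSPENSION)}
    ratio_fold = ratio[SUSPENSION] / ratio[ADHESION]
    return well_df, summaries, {"ratio": ratio, "fold": ratio_fold,
                                "warnings": warnings_log}


def screen_stage(dataset: MirrorDataset, keyword: str = "glucose",
                 tau: float = 0.10, bold_threshold: float = 0.35):
    """Keyword gene-set mining, relative expression, screen and panel."""
    selected = select_gene_sets(dataset.gene_sets, keyword)
    universe = union_genes(selected)
    r_table = relative_expression_table(dataset.study)
    result = consistent_direction_screen(r_table, universe, tau=tau)
    panel = transporter_panel(r_table, bold_threshold=bold_threshold)
    return selected, universe, r_table, result, panel


def assays_stage(dataset: MirrorDataset) -> pd.DataFrame:
    """All supporting-assay estimates as one tidy table."""
    rows = []
    for gene in MIRROR_QPCR_FOLDS:
        est = ddct_fold(dataset.qpcr, gene, SUSPENSION, ADHESION)
        rows.append({"assay": "qpcr", "condition": SUSPENSION, "quantity": f"fold_{gene}",
                     "estimate": est.fold, "sd": est.sd, "p_value": np.nan})

    prolif = proliferation_ratio(dataset.counts, MIRROR_GLUCOSE_NORMAL)
    for _, r in prolif.iterrows():
        rows.append({"assay": "proliferation", "condition": r["condition"],
                     "quantity": f"ratio_at_{r['glucose']:g}gL",
                     "estimate": r["ratio"], "sd": np.nan, "p_value": np.nan})

    fluor = dataset.ros.groupby("sample")["fluorescence"].mean()
    percents = {s: ros_relative(fluor, s) for s in fluor.index
                if s not in ("antimycin A", "N-acetylcysteine")}
    for s, pct in percents.items():
        rows.append({"assay": "ros", "condition": s.rsplit("_", 1)[-1],
                     "quantity": f"percent_{s}", "estimate": pct,
                     "sd": np.nan, "p_value": np.nan})
    for species in ("superoxide", "ros"):
        adh = percents[f"{species}_{ADHESION}"]
        susp = percents[f"{species}_{SUSPENSION}"]
        rows.append({"assay": "ros", "condition": SUSPENSION,
                     "quantity": f"fold_{species}", "estimate": susp / adh,
                     "sd": np.nan, "p_value": np.nan})

    lact = relative_lactate(dataset.lactate)
    for _, r in lact.iterrows():
        rows.append({"assay": "lactate", "condition": r["condition"],
                     "quantity": f"mean_at_pH{r['ph']:g}", "estimate": r["mean"],
                     "sd": r["sd"], "p_value": r["p_value"]})

    for compound in dataset.viability["compound"].unique():
        c = sensitivity_contrast(dataset.viability, ADHESION, SUSPENSION, compound)
        rows.append({"assay": "sensitivity", "condition": ADHESION,
                     "quantity": f"score_{compound}", "estimate": c["score_a"],
                     "sd": np.nan, "p_value": np.nan})
        rows.append({"assay": "sensitivity", "condition": SUSPENSION,
                     "quantity": f"score_{compound}", "estimate": c["score_b"],
                     "sd": np.nan, "p_value": np.nan})
        rows.append({"assay": "sensitivity", "condition": "delta",
                     "quantity": f"delta_score_{compound}", "estimate": c["delta"],
                     "sd": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report + manifest
# ---------------------------------------------------------------------------

def _fmt_pct(r: float) -> str:
    return f"{100 * r:+.1f}%"


def render_report(summaries, ratio_info, result, panel, assays: pd.DataFrame) -> str:
    lines = ["# Detachment-stress bioenergetic switch: run report", ""]
    lines.append("## Stress-test metrics (condition means, per 10^4 cells)")
    for kind, summ in summaries.items():
        lines.append(f"### {kind}")
        for _, r in summ.iterrows():
            p = "" if np.isnan(r["p_value"]) else f", p={r['p_value']:.3g}"
            lines.append(f"- {r['condition']} {r['metric']}: {r['mean']:.3g} "
                         f"± {r['sd']:.2g} (fold {r['fold_vs_reference']:.3g}{p})")
    lines.append("")
    lines.append(f"OCR/ECAR ratio: adhesion {ratio_info['ratio'][ADHESION]:.3g}, "
                 f"suspension {ratio_info['ratio'][SUSPENSION]:.3g} "
                 f"(suspension/adhesion fold {ratio_info['fold']:.2f})")
    lines.append("")
    lines.append("## Consistent-direction screen")
    lines.append(f"- universe: {len(result.universe)} genes; tau = {result.tau}")
    lines.append(f"- down in all lines ({len(result.down)}): {', '.join(result.down)}")
    lines.append(f"- up in all lines ({len(result.up)}): {', '.join(result.up)}")
    lines.append("")
    lines.append("## Transporter panel (relative expression, suspension vs adhesion)")
    for name, grp in panel.groupby("name", sort=False):
        cells = [f"{r['line']} {r['relative_expression']}"
                 + ("*" if r["marked"] else "") for _, r in grp.iterrows()]
        lines.append(f"- {name} ({grp['gene'].iloc[0]}): " + "; ".join(cells))
    lines.append("")
    lines.append("## Supporting assays")
    for _, r in assays.iterrows():
        p = "" if np.isnan(r["p_value"]) else f" (p={r['p_value']:.3g})"
        lines.append(f"- {r['assay']}/{r['condition']} {r['quantity']}: "
                     f"{r['estimate']:.3g}{p}")
    return "\n".join(lines) + "\n"


@dataclass
class RunManifest:
    version: str
    config_digest: str
    seed: int
    row_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timestamp: str = ""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig, dataset: MirrorDataset | None = None) -> Path:
    """simulate -> flux -> screen -> assays -> report; returns the output dir.

    Deterministic given the config (seed included): rerunning yields
    byte-identical TSVs. Partial outputs are removed on failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    try:
        if dataset is None:
            dataset = generate_mirror_dataset(config.seed)

        well_df, summaries, ratio_info = flux_stage(dataset, config.k_cycles,
                                                    config.unit_cells)
        emit(well_df, "flux_well_metrics.tsv")
        emit(pd.concat([s.assign(kind=k) for k, s in summaries.items()],
                       ignore_index=True), "flux_condition_summary.tsv")

        selected, universe, r_table, result, panel = screen_stage(
            dataset, config.keyword, config.tau, config.bold_threshold)
        emit(result.to_frame().reset_index(), "screen_calls.tsv")
        emit(panel, "transporter_panel.tsv")
        write_gmt(selected, out / "selected_gene_sets.gmt")
        written.append(out / "selected_gene_sets.gmt")

        assays = assays_stage(dataset)
        emit(assays, "assay_estimates.tsv")

        write_study_tsv(dataset.study, out / "expression_study.tsv")
        dataset.truth.save(out / "ground_truth.json")

        report = render_report(summaries, ratio_info, result, panel, assays)
        (out / "report.md").write_text(report)

        manifest = RunManifest(
            version=__version__,
            config_digest=config.digest(),
            seed=config.seed,
            row_counts={p.name: sum(1 for _ in open(p)) - 1 for p in written},
            warnings=list(ratio_info["warnings"])
            + ([f"excluded {len(result.excluded)} universe genes"]
               if result.excluded else []),
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        manifest.save(out / "manifest.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return out
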