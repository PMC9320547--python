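"""Seeded recovery experiments over the mirror fixture.

Each function re-runs a slice of the pipeline on freshly generated synthetic
data many times and returns the recovered estimates, so that planted study
quantities (capacity-utilization fractions, the OCR/ECAR ratio fold, the
maximal-respiration fold, the 10/7 consistent-direction gene lists, the
transporter-panel percentages, assay folds) can be compared with their
ground truth. Estimator noise shrinks with the number of replicate
simulations, so multi-seed means/medians are the stable summaries.
"""

from __future__ import annotations

import numpy as np

from .assays import ddct_fold, ros_relative
from .flux import (
    glycolysis_stress_metrics,
    mito_stress_metrics,
    segment_trace,
    trace_metrics,
)
from .screen import (
    consistent_direction_screen,
    relative_expression_table,
    select_gene_sets,
    union_genes,
)
from .synthetic import (
    ADHESION,
    SUSPENSION,
    MIRROR_QPCR_FOLDS,
    MIRROR_ROS_PERCENTS,
    MIRROR_WELLS_PER_CONDITION,
    N_DECOY_SETS,
    N_GENE_SETS,
    PLANTED_DOWN,
    PLANTED_UP,
    covering_gene_sets,
    generate_expression_study,
    generate_flux_experiment,
    generate_flux_trace,
    generate_qpcr_table,
    generate_ros_table,
    mirror_expression_spec,
    mirror_flux_spec,
    mirror_universe,
)


def mito_utilization_estimates(n_sims: int, seed: int,
                               condition: str = SUSPENSION) -> np.ndarray:
    """Recovered basal/maximal respiration fractions over seeded traces."""
    out = np.empty(n_sims)
    for i in range(n_sims):
        spec = mirror_flux_spec("OCR", condition, seed + i)
        levels = segment_trace(generate_flux_trace(spec))
        out[i] = mito_stress_metrics(levels).utilization_fraction
    return out


def glyco_utilization_estimates(n_sims: int, seed: int,
                                condition: str = ADHESION) -> np.ndarray:
    """Recovered basal/capacity glycolysis fractions over seeded traces."""
    out = np.empty(n_sims)
    for i in range(n_sims):
        spec = mirror_flux_spec("ECAR", condition, seed + i)
        levels = segment_trace(generate_flux_trace(spec))
        out[i] = glycolysis_stress_metrics(levels).utilization_fraction
    return out


def _plate_pair(seed: int):
    ecar = generate_flux_experiment(
        {c: mirror_flux_spec("ECAR", c, seed) for c in (ADHESION, SUSPENSION)},
        MIRROR_WELLS_PER_CONDITION)
    ocr = generate_flux_experiment(
        {c: mirror_flux_spec("OCR", c, seed + 1) for c in (ADHESION, SUSPENSION)},
        MIRROR_WELLS_PER_CONDITION)
    return ecar, ocr


def flux_fold_estimates(n_pairs: int, seed: int) -> dict[str, np.ndarray]:
    """Suspension/adhesion folds recovered from paired ECAR+OCR plates.

    Returns per-pair estimates of the OCR/ECAR ratio fold, the
    maximal-respiration fold, and the adherent spare capacity (per 10^4
    cells).
    """
    ratio_fold = np.empty(n_pairs)
    maximal_fold = np.empty(n_pairs)
    adherent_spare = np.empty(n_pairs)
    for i in range(n_pairs):
        ecar, ocr = _plate_pair(seed + 2 * i)
        basal_glyc, basal_resp, maximal, spare = {}, {}, {}, {}
        for cond in (ADHESION, SUSPENSION):
            g = [trace_metrics(t) for t in ecar.wells(cond)]
            m = [trace_metrics(t) for t in ocr.wells(cond)]
            basal_glyc[cond] = np.mean([x.basal_glycolysis for x in g])
            basal_resp[cond] = np.mean([x.basal_respiration for x in m])
            maximal[cond] = np.mean([x.maximal_respiration for x in m])
            spare[cond] = np.mean([x.spare_capacity for x in m])
        ratio = {c: basal_resp[c] / basal_glyc[c] for c in basal_glyc}
        ratio_fold[i] = ratio[SUSPENSION] / ratio[ADHESION]
        maximal_fold[i] = maximal[SUSPENSION] / maximal[ADHESION]
        adherent_spare[i] = spare[ADHESION]
    return {"ocr_ecar_ratio_fold": ratio_fold,
            "maximal_respiration_fold": maximal_fold,
            "adherent_spare_capacity": adherent_spare}


def screen_recovery(n_seeds: int, seed: int, tau: float = 0.10) -> dict:
    """Exact-recovery rate of the planted 10-down/7-up lists over seeds.

    Each seed regenerates the full mirror expression study and gene-set
    collection, reruns keyword selection, the relative-expression table and
    the consistent-direction screen, and checks both recovered lists against
    the planted ones.
    """
    universe_ref = sorted(mirror_universe())
    exact = np.zeros(n_seeds, dtype=bool)
    n_down = np.zeros(n_seeds, dtype=int)
    n_up = np.zeros(n_seeds, dtype=int)
    for i in range(n_seeds):
        s = seed + i
        study, _ = generate_expression_study(mirror_expression_spec(s))
        sets = covering_gene_sets(list(mirror_universe()), N_GENE_SETS,
                                  "glucose", s, n_decoys=N_DECOY_SETS)
        selected = select_gene_sets(sets, "glucose")
        universe = union_genes(selected)
        assert sorted(universe) == universe_ref
        r = relative_expression_table(study)
        res = consistent_direction_screen(r, universe, tau=tau)
        exact[i] = (res.down == sorted(PLANTED_DOWN)) and (res.up == sorted(PLANTED_UP))
        n_down[i], n_up[i] = len(res.down), len(res.up)
    return {"exact": exact, "n_down": n_down, "n_up": n_up,
            "n_selected_sets": len(selected), "n_universe": len(universe)}


def panel_percent_estimates(n_seeds: int, seed: int,
                            genes=("SLC16A3", "SLC2A1"),
                            line: str = "A375") -> dict[str, np.ndarray]:
    """Recovered relative-expression percentages for panel genes (one line),
    plus the NOX4 fold (mean over lines), across regenerated studies."""
    out = {g: np.empty(n_seeds) for g in genes}
    nox4 = np.empty(n_seeds)
    for i in range(n_seeds):
        study, _ = generate_expression_study(mirror_expression_spec(seed + i))
        r = relative_expression_table(study)
        for g in genes:
            out[g][i] = 100.0 * r.at[g, line]
        nox4[i] = 1.0 + r.loc["NOX4"].mean()
    out["NOX4_fold"] = nox4
    return out


def assay_fold_estimates(n_seeds: int, seed: int) -> dict[str, np.ndarray]:
    """Recovered qPCR folds and ROS folds across regenerated assay tables."""
    qpcr_folds = {g: np.empty(n_seeds) for g in MIRROR_QPCR_FOLDS}
    superoxide = np.empty(n_seeds)
    total_ros = np.empty(n_seeds)
    for i in range(n_seeds):
        s = seed + i
        q = generate_qpcr_table(list(MIRROR_QPCR_FOLDS), MIRROR_QPCR_FOLDS, seed=s)
        for g in MIRROR_QPCR_FOLDS:
            qpcr_folds[g][i] = ddct_fold(q, g, SUSPENSION, ADHESION).fold
        ros = generate_ros_table(MIRROR_ROS_PERCENTS, noise_sd=10.0, seed=s)
        fluor = ros.groupby("sample")["fluorescence"].mean()
        pct = {k: ros_relative(fluor, k) for k in MIRROR_ROS_PERCENTS}
        superoxide[i] = pct["superoxide_suspension"] / pct["superoxide_adhesion"]
        total_ros[i] = pct["ros_suspension"] / pct["ros_adhesion"]
    return {"qpcr": qpcr_folds, "superoxide_fold": superoxide,
            "ros_fold": total_ros}
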