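"""Supporting assay quantifications.

Covers the wet-lab readouts around the flux and array analyses: relative
qPCR quantification by the 2^-ddCt method against a reference gene (GAPDH
by default), glucose-titration proliferation ratios, relative ROS percent
against the assay's positive (antimycin A) and negative (N-acetylcysteine)
controls, conditioned-medium lactate comparisons, and a normalized-AUC
drug-sensitivity score over log-dose viability curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FoldEstimate:
    fold: float
    sd: float  # SD propagated on the ddCt (log2) scale, expressed as fold SD
    ddct: float


def ddct_fold(
    qpcr: pd.DataFrame,
    target: str,
    test_group: str,
    control_group: str,
    reference_gene: str = "GAPDH",
) -> FoldEstimate:
    """Relative expression of ``target`` in test vs control group, 2^-ddCt.

    ``qpcr`` is tidy with columns group, gene, replicate, ct. Per group,
    dCt = mean Ct(target) - mean Ct(reference); ddCt = dCt(test) -
    dCt(control); fold = 2^-ddCt. Replicate SD is propagated on the ddCt
    scale (root sum of the four per-gene-per-group SEM-free SDs) and
    reported as a multiplicative fold SD via 2^sd(ddCt) - 1 scaling of the
    point estimate.
    """
    def group_ct(group: str, gene: str) -> np.ndarray:
        sel = qpcr[(qpcr["group"] == group) & (qpcr["gene"] == gene)]["ct"]
        if sel.empty:
            raise ValueError(f"no Ct values for gene {gene!r} in group {group!r}")
        return sel.to_numpy(dtype=float)

    cts = {(g, gene): group_ct(g, gene)
           for g in (test_group, control_group)
           for gene in (target, reference_gene)}
    dct_test = cts[(test_group, target)].mean() - cts[(test_group, reference_gene)].mean()
    dct_ctrl = cts[(control_group, target)].mean() - cts[(control_group, reference_gene)].mean()
    ddct = dct_test - dct_ctrl
    fold = 2.0 ** (-ddct)
    var = sum(np.var(v, ddof=1) if len(v) > 1 else 0.0 for v in cts.values())
    sd_ddct = math.sqrt(var)
    fold_sd = fold * (2.0 ** sd_ddct - 1.0)
    return FoldEstimate(fold, fold_sd, ddct)


def proliferation_ratio(
    counts: pd.DataFrame,
    reference_concentration: float,
) -> pd.DataFrame:
    """Relative proliferation per (condition, glucose concentration).

    ratio = mean cell count at the concentration / mean cell count at the
    normal-culture reference concentration, within each condition.
    ``counts`` is tidy: condition, glucose, replicate, count.
    """
    rows = []
    for cond, grp in counts.groupby("condition", sort=False):
        ref = grp[grp["glucose"] == reference_concentration]["count"]
        if ref.empty:
            raise ValueError(f"condition {cond!r} has no reference-concentration counts")
        ref_mean = float(ref.mean())
        if ref_mean <= 0:
            raise ValueError(f"condition {cond!r}: reference mean count is {ref_mean}")
        for conc, sub in grp.groupby("glucose", sort=True):
            rows.append({"condition": cond, "glucose": conc,
                         "ratio": float(sub["count"].mean()) / ref_mean})
    return pd.DataFrame(rows)


def ros_relative(
    fluorescence: pd.Series,
    sample: str,
    positive_control: str = "antimycin A",
    negative_control: str = "N-acetylcysteine",
) -> float:
    """Relative ROS percent of the positive/negative control span.

    percent = 100 * (F_sample - F_neg) / (F_pos - F_neg). Invariant under
    affine transforms of the fluorescence channel (gain and offset cancel).
    """
    f_pos = float(fluorescence[positive_control])
    f_neg = float(fluorescence[negative_control])
    if f_pos == f_neg:
        raise ValueError("positive and negative control fluorescence are equal")
    return 100.0 * (float(fluorescence[sample]) - f_neg) / (f_pos - f_neg)


def relative_lactate(measurements: pd.DataFrame) -> pd.DataFrame:
    """Condition means +/- SD of lactate with a Welch comparison per pH.

    ``measurements`` is tidy: condition, ph, replicate, lactate. Per
    (condition, pH): mean and sample SD. Per pH, the two conditions are
    compared with a two-sided Welch t-test; with fewer than two replicates
    on either side the test is skipped with a warning. The fold column is
    the condition mean over the other condition's mean at the same pH.
    """
    rows = []
    for ph, at_ph in measurements.groupby("ph", sort=True):
        conds = list(dict.fromkeys(at_ph["condition"]))
        groups = {c: at_ph[at_ph["condition"] == c]["lactate"].to_numpy(dtype=float)
                  for c in conds}
        for c in conds:
            x = groups[c]
            others = [groups[o] for o in conds if o != c]
            other = others[0] if others else np.array([])
            if len(x) >= 2 and len(other) >= 2:
                p = float(stats.ttest_ind(x, other, equal_var=False).pvalue)
            else:
                if len(other):
                    warnings.warn(f"Welch test skipped at pH {ph}: <2 replicates", stacklevel=2)
                p = math.nan
            fold = float(np.mean(x)) / float(np.mean(other)) if len(other) else math.nan
            rows.append({"condition": c, "ph": ph,
                         "mean": float(np.mean(x)),
                         "sd": float(np.std(x, ddof=1)) if len(x) > 1 else math.nan,
                         "fold_vs_other": fold, "p_value": p})
    return pd.DataFrame(rows)


def sensitivity_score(
    viability: pd.DataFrame,
    condition: str,
    compound: str,
) -> float:
    """Normalized-AUC sensitivity in [0, 1]; higher = more drug-sensitive.

    Viability signals are normalized to the vehicle (dose 0) mean for the
    same (condition, compound); the score is 1 minus the trapezoidal mean of
    normalized viability over the log10-dose grid of the non-vehicle doses.
    Ordinal by design: it ranks sensitivities without fitting an IC50, so it
    stays defined for curves that never cross 50% viability. Invariant under
    rescaling the raw signal; normalized viability is clipped to [0, 1].
    """
    sub = viability[(viability["condition"] == condition)
                    & (viability["compound"] == compound)]
    if sub.empty:
        raise ValueError(f"no viability rows for ({condition!r}, {compound!r})")
    vehicle = sub[sub["dose"] == 0]["signal"]
    if vehicle.empty:
        raise ValueError("vehicle (dose 0) wells are required")
    v0 = float(vehicle.mean())
    dosed = sub[sub["dose"] > 0]
    mean_by_dose = dosed.groupby("dose")["signal"].mean().sort_index()
    if len(mean_by_dose) < 2:
        raise ValueError("need at least 2 non-vehicle doses")
    norm = np.clip(mean_by_dose.to_numpy() / v0, 0.0, 1.0)
    logd = np.log10(mean_by_dose.index.to_numpy(dtype=float))
    auc = np.trapezoid(norm, logd) / (logd[-1] - logd[0])
    return float(1.0 - auc)


def sensitivity_contrast(
    viability: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    compound: str,
) -> dict[str, float]:
    """Delta sensitivity score (b - a) for one compound; positive means
    condition b is the more sensitive one."""
    sa = sensitivity_score(viability, condition_a, compound)
    sb = sensitivity_score(viability, condition_b, compound)
    return {"score_a": sa, "score_b": sb, "delta": sb - sa}
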