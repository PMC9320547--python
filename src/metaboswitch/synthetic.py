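"""Seeded synthetic-data generators.

Every generator is a pure function of its spec (seed included): rerunning
with the same spec reproduces the output bit-identically. Each generated
table draws from its own named pseudo-random stream derived from the spec
seed, so adding one generator never perturbs another's output.

The module also ships the *mirror fixture*: a complete synthetic study with
the same design as the melanoma detachment-stress experiments it emulates —
4 cell lines (A375, A2058, RPMI7951, Hs695t) x {adhesion, suspension},
3 replicates, a 1,005-gene glucose-metabolism universe covered by 29
keyword-matching gene-sets, 10 planted consistently-down and 7 planted
consistently-up genes, flux plateaus planted so the suspended cells run at
46.7% of maximal respiration while adherent cells have no spare capacity,
both conditions use 80% of glycolytic capacity, the suspended/adherent
OCR/ECAR ratio fold is 3.3 and the maximal-respiration fold is 4.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .flux import (
    FluxTrace,
    FluxValidationError,
    InjectionSchedule,
    SEGMENT_LABELS,
)
from .screen import ExpressionStudy, GeneSet, GeneSetCollection

LINES = ("A375", "A2058", "RPMI7951", "Hs695t")
ADHESION = "adhesion"
SUSPENSION = "suspension"


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: independent stream per generated table."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted generative parameters, serializable alongside the dataset."""

    spec: dict = field(default_factory=dict)
    flux_plateaus: dict = field(default_factory=dict)   # condition -> {segment: level}
    expression_effects: dict = field(default_factory=dict)  # gene -> {line: r}
    qpcr_folds: dict = field(default_factory=dict)
    ros_percents: dict = field(default_factory=dict)
    dose_response: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# flux traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxSimSpec:
    """Segment-plateau model of one well's stress-test trace.

    ``segment_plateaus`` is an ordered list of (segment label, mean rate):
    the labels must be exactly the canonical segments of one assay kind
    (baseline + one per injection). Measurement i in segment s is
    plateau_s + drift_per_cycle * global_cycle + N(0, noise_sd).
    """

    segment_plateaus: tuple[tuple[str, float], ...]
    kind: str = "OCR"  # ECAR (mpH/min) or OCR (pmol O2/min)
    cycles_per_segment: int = 3
    cycle_interval_min: float = 6.0
    noise_sd: float = 0.0
    drift_per_cycle: float = 0.0
    cell_count: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        labels = tuple(lbl for lbl, _ in self.segment_plateaus)
        kinds = [k for k, segs in SEGMENT_LABELS.items() if segs == labels]
        if not kinds:
            raise FluxValidationError(
                f"segment labels {labels} do not match any assay kind; "
                f"expected one of {list(SEGMENT_LABELS.values())}"
            )
        if self.cycles_per_segment < 1:
            raise FluxValidationError("cycles_per_segment must be >= 1")
        if self.cycle_interval_min <= 0:
            raise FluxValidationError("cycle_interval_min must be positive")
        if self.noise_sd < 0:
            raise FluxValidationError("noise_sd must be >= 0")
        if self.cell_count <= 0:
            raise FluxValidationError("cell_count must be positive")
        if any(mean < 0 for _, mean in self.segment_plateaus):
            raise FluxValidationError("plateau means must be >= 0")

    @property
    def assay_kind(self) -> str:
        labels = tuple(lbl for lbl, _ in self.segment_plateaus)
        return next(k for k, segs in SEGMENT_LABELS.items() if segs == labels)

    def schedule(self) -> InjectionSchedule:
        from .flux import CANONICAL_COMPOUNDS

        compounds = CANONICAL_COMPOUNDS[self.assay_kind]
        return InjectionSchedule(
            self.assay_kind,
            tuple((c, self.cycles_per_segment * (i + 1)) for i, c in enumerate(compounds)),
        )


def generate_flux_trace(spec: FluxSimSpec, well: str = "W1") -> FluxTrace:
    rng = stream(spec.seed, f"flux/{well}")
    n_seg = len(spec.segment_plateaus)
    n = n_seg * spec.cycles_per_segment
    plateaus = np.repeat([m for _, m in spec.segment_plateaus], spec.cycles_per_segment)
    cycles = np.arange(n)
    rates = plateaus + spec.drift_per_cycle * cycles
    if spec.noise_sd > 0:
        rates = rates + rng.normal(0.0, spec.noise_sd, size=n)
    time = spec.cycle_interval_min * (cycles + 1.0)
    return FluxTrace(well, spec.kind, time, rates, spec.schedule(), spec.cell_count)


@dataclass
class FluxPlate:
    """Labeled traces for one assay run plus attached ground truth."""

    traces: list[FluxTrace]
    condition_of: dict[str, str]
    truth: GroundTruth

    def wells(self, condition: str) -> list[FluxTrace]:
        return [t for t in self.traces if self.condition_of[t.well] == condition]


def generate_flux_experiment(
    condition_specs: dict[str, FluxSimSpec],
    wells_per_condition: int,
) -> FluxPlate:
    """One plate: ``wells_per_condition`` wells per condition, unique labels."""
    if not condition_specs:
        raise ValueError("need at least one condition")
    if wells_per_condition < 1:
        raise ValueError("wells_per_condition must be >= 1")
    traces: list[FluxTrace] = []
    condition_of: dict[str, str] = {}
    truth = GroundTruth()
    for cond, spec in condition_specs.items():
        truth.flux_plateaus[cond] = dict(spec.segment_plateaus)
        truth.spec.setdefault("flux", {})[cond] = {
            "kind": spec.kind, "noise_sd": spec.noise_sd, "seed": spec.seed,
            "cycles_per_segment": spec.cycles_per_segment,
        }
        for w in range(wells_per_condition):
            well = f"{cond}_w{w + 1}"
            if well in condition_of:
                raise ValueError(f"duplicate well label {well}")
            traces.append(generate_flux_trace(spec, well=well))
            condition_of[well] = cond
    return FluxPlate(traces, condition_of, truth)


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Planted-effect model of a multi-line adhesion/suspension array study.

    Per (gene, line) the baseline intensity is log-normal; suspension
    samples are scaled by (1 + r) where r is the planted relative effect:
    drawn uniformly (with the planted sign) from ``effect_range`` for
    ``planted_down``/``planted_up`` genes, taken from ``planted_effects``
    where given, 0 otherwise. Replicate noise is multiplicative Gaussian
    with fractional SD ``background_noise_sd``.
    """

    n_genes: int
    lines: tuple[str, ...] = LINES
    replicates_per_condition: int = 3
    baseline_log_mean: float = 6.9  # ~1000 on the intensity scale
    baseline_log_sd: float = 0.8
    planted_down: tuple[str, ...] = ()
    planted_up: tuple[str, ...] = ()
    effect_range: tuple[float, float] = (0.25, 0.65)
    background_noise_sd: float = 0.05
    seed: int = 0
    genes: tuple[str, ...] | None = None
    planted_effects: dict | None = None  # gene -> {line: signed r}

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        lo, hi = self.effect_range
        if not (0 < lo <= hi < 1):
            raise ValueError("effect_range must satisfy 0 < min <= max < 1")
        if set(self.planted_down) & set(self.planted_up):
            raise ValueError("planted_down and planted_up overlap")
        universe = set(self.gene_universe())
        planted = set(self.planted_down) | set(self.planted_up) | set(self.planted_effects or {})
        missing = planted - universe
        if missing:
            raise ValueError(f"planted genes not in universe: {sorted(missing)}")

    def gene_universe(self) -> tuple[str, ...]:
        if self.genes is not None:
            if len(self.genes) != self.n_genes:
                raise ValueError("len(genes) != n_genes")
            return self.genes
        named = list(self.planted_down) + list(self.planted_up)
        fillers = [f"G{i:04d}" for i in range(self.n_genes - len(named))]
        return tuple(named + fillers)


def generate_expression_study(spec: ExpressionSimSpec) -> tuple[ExpressionStudy, GroundTruth]:
    rng = stream(spec.seed, "expression")
    genes = list(spec.gene_universe())
    lines = list(spec.lines)
    n_g, n_l, n_r = len(genes), len(lines), spec.replicates_per_condition

    # planted relative effects r(gene, line)
    effects = np.zeros((n_g, n_l))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in spec.planted_down:
        effects[gene_idx[g]] = -rng.uniform(*spec.effect_range, size=n_l)
    for g in spec.planted_up:
        effects[gene_idx[g]] = rng.uniform(*spec.effect_range, size=n_l)
    for g, per_line in (spec.planted_effects or {}).items():
        for line, r in per_line.items():
            effects[gene_idx[g], lines.index(line)] = r

    baselines = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, size=(n_g, n_l))

    columns, blocks = [], []
    for li, line in enumerate(lines):
        for cond, factor in ((ADHESION, 1.0), (SUSPENSION, 1.0 + effects[:, li])):
            mean = baselines[:, li] * factor
            for rep in range(1, n_r + 1):
                noise = rng.normal(0.0, spec.background_noise_sd, size=n_g) \
                    if spec.background_noise_sd > 0 else 0.0
                blocks.append(mean * (1.0 + noise))
                columns.append(f"{line}_{cond}_{rep}")
    matrix = pd.DataFrame(np.column_stack(blocks), index=pd.Index(genes, name="gene"),
                          columns=columns)
    samples = pd.DataFrame(
        {"line": [c.rsplit("_", 2)[0] for c in columns],
         "condition": [c.rsplit("_", 2)[1] for c in columns]},
        index=pd.Index(columns, name="sample"),
    )
    truth = GroundTruth(
        spec={"expression": {"n_genes": n_g, "lines": lines, "replicates": n_r,
                             "noise_sd": spec.background_noise_sd, "seed": spec.seed}},
        expression_effects={
            g: {line: float(effects[gene_idx[g], li]) for li, line in enumerate(lines)}
            for g in genes if np.any(effects[gene_idx[g]] != 0)
        },
    )
    return ExpressionStudy(matrix, samples), truth


# ---------------------------------------------------------------------------
# gene-set collections
# ---------------------------------------------------------------------------

def generate_gene_sets(
    universe: list[str],
    n_sets: int,
    keyword: str,
    fraction_keyword_sets: float,
    membership_range: tuple[int, int],
    seed: int,
) -> GeneSetCollection:
    """Random collection with a planted fraction of keyword-matching names.

    Exactly round(n_sets * fraction) set names contain the keyword
    (uppercased, GO-style); member counts are uniform in membership_range,
    drawn from the universe without replacement per set.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not 0 <= fraction_keyword_sets <= 1:
        raise ValueError("fraction must be in [0, 1]")
    lo, hi = membership_range
    if hi > len(universe):
        raise ValueError("membership max exceeds universe size")
    if lo < 1 or lo > hi:
        raise ValueError("bad membership_range")
    rng = stream(seed, "gene_sets")
    n_match = round(n_sets * fraction_keyword_sets)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(rng.choice(universe, size=size, replace=False))
        if i < n_match:
            name = f"GOBP_{keyword.upper()}_PROCESS_{i + 1}"
            desc = f"simulated pathway {i + 1} related to {keyword} metabolism"
        else:
            name = f"GOBP_DECOY_PROCESS_{i + 1}"
            desc = f"simulated decoy pathway {i + 1}"
        sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(tuple(sets))


def covering_gene_sets(
    universe: list[str],
    n_sets: int,
    keyword: str,
    seed: int,
    n_decoys: int = 0,
    name_only_fraction_without_keyword: float = 0.1,
    extra_overlap: int = 25,
) -> GeneSetCollection:
    """Keyword collection whose matching sets jointly cover the universe.

    Every universe gene belongs to at least one keyword set, so the union of
    the selected sets is exactly the universe (the property the mirror
    fixture needs). A small fraction of matching sets carry the keyword only
    in their description, exercising description-field search; decoy sets
    match in neither field.
    """
    rng = stream(seed, "gene_sets_cover")
    order = list(np.array(universe)[rng.permutation(len(universe))])
    cuts = sorted(rng.choice(np.arange(1, len(order)), size=n_sets - 1, replace=False))
    chunks = np.split(np.array(order), cuts)
    n_nameless = max(1, round(n_sets * name_only_fraction_without_keyword))
    sets = []
    for i, chunk in enumerate(chunks):
        members = list(chunk)
        n_extra = int(rng.integers(0, extra_overlap + 1))
        if n_extra:
            members += list(rng.choice(universe, size=n_extra, replace=False))
        members = list(dict.fromkeys(members))
        if i < n_sets - n_nameless:
            name = f"GOBP_{keyword.upper()}_RELATED_PROCESS_{i + 1}"
            desc = f"simulated process {i + 1} involving {keyword} handling"
        else:
            name = f"GOBP_ORGAN_DEVELOPMENT_{i + 1}"
            desc = f"simulated developmental process {i + 1} with {keyword} signaling genes"
        sets.append(GeneSet(name, desc, tuple(members)))
    for j in range(n_decoys):
        size = int(rng.integers(10, 51))
        members = tuple(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"GOBP_DECOY_PROCESS_{j + 1}",
                            f"simulated decoy pathway {j + 1}", members))
    return GeneSetCollection(tuple(sets))


# ---------------------------------------------------------------------------
# qPCR, ROS, lactate, proliferation, dose-response tables
# ---------------------------------------------------------------------------

def generate_qpcr_table(
    genes: list[str],
    planted_folds: dict[str, float],
    ct_ref_mean: float = 18.0,
    noise_sd_ct: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    test_group: str = SUSPENSION,
    control_group: str = ADHESION,
    reference_gene: str = "GAPDH",
    target_dct: float = 5.0,
) -> pd.DataFrame:
    """Tidy Ct table (group, gene, replicate, ct) with planted fold changes.

    Noise-free, the 2^-ddCt estimate of each gene equals its planted fold:
    the test group's target Ct is shifted by -log2(fold) relative to the
    control group, with both groups sharing the reference-gene level.
    """
    for g, f in planted_folds.items():
        if f <= 0:
            raise ValueError(f"planted fold for {g} must be positive")
    rng = stream(seed, "qpcr")
    rows = []
    for group in (control_group, test_group):
        for gene in [reference_gene] + list(genes):
            if gene == reference_gene:
                mean_ct = ct_ref_mean
            else:
                mean_ct = ct_ref_mean + target_dct
                if group == test_group:
                    mean_ct -= np.log2(planted_folds.get(gene, 1.0))
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                rows.append({"group": group, "gene": gene, "replicate": rep,
                             "ct": mean_ct + noise})
    return pd.DataFrame(rows)


def generate_ros_table(
    planted_percents: dict[str, float],
    negative_fluorescence: float = 100.0,
    positive_fluorescence: float = 1100.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy fluorescence table (sample, replicate, fluorescence).

    Samples sit at their planted percent of the positive/negative control
    span; the controls themselves are included as samples.
    """
    rng = stream(seed, "ros")
    span = positive_fluorescence - negative_fluorescence
    if span == 0:
        raise ValueError("control fluorescences must differ")
    levels = {"N-acetylcysteine": negative_fluorescence,
              "antimycin A": positive_fluorescence}
    levels.update({s: negative_fluorescence + span * p / 100.0
                   for s, p in planted_percents.items()})
    rows = []
    for sample, mean in levels.items():
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"sample": sample, "replicate": rep, "fluorescence": mean + noise})
    return pd.DataFrame(rows)


def generate_lactate_table(
    condition_means: dict[tuple[str, float], float],
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy lactate table (condition, ph, replicate, lactate)."""
    rng = stream(seed, "lactate")
    rows = []
    for (cond, ph), mean in condition_means.items():
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"condition": cond, "ph": ph, "replicate": rep,
                         "lactate": mean + noise})
    return pd.DataFrame(rows)


def generate_count_table(
    planted_ratios: dict[tuple[str, float], float],
    reference_concentration: float,
    base_count: float = 4e5,
    noise_sd_fraction: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy proliferation counts (condition, glucose, replicate, count).

    The reference concentration is planted at ratio 1 per condition.
    """
    rng = stream(seed, "counts")
    ratios = dict(planted_ratios)
    for cond in {c for c, _ in planted_ratios}:
        ratios.setdefault((cond, reference_concentration), 1.0)
    rows = []
    for (cond, conc), ratio in sorted(ratios.items()):
        mean = base_count * ratio
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd_fraction) if noise_sd_fraction > 0 else 0.0
            rows.append({"condition": cond, "glucose": conc, "replicate": rep,
                         "count": max(mean * (1.0 + noise), 0.0)})
    return pd.DataFrame(rows)


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """4-parameter logistic in dose; dose 0 maps to top (vehicle)."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(top))
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (dose[pos] / ic50) ** hill)
    return out


def generate_dose_response(
    doses: list[float],
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy viability table (dose, replicate, signal) along a 4PL curve."""
    if not doses:
        raise ValueError("dose list is empty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    rng = stream(seed, "dose_response")
    means = four_pl(np.array(doses, dtype=float), top, bottom, ic50, hill)
    rows = []
    for dose, mean in zip(doses, means):
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"dose": dose, "replicate": rep, "signal": mean + noise})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the mirror fixture: study-design defaults in one place
# ---------------------------------------------------------------------------

PLANTED_DOWN = ("CAV1", "IRS1", "LMNA", "LMNB2", "PEA15", "POLD1",
                "PRKAG2", "RNASEH2A", "SLC29A1", "SLC2A1")
PLANTED_UP = ("AMACR", "ARNT2", "BBS2", "FOS", "FOXO1", "PCSK1", "PLAG1")

#: transporter-panel relative expressions per line (fractions); these are
#: the planted per-line condition effects for the panel genes.
PANEL_EFFECTS = {
    "SLC16A1": {"A375": -0.076, "A2058": +0.006, "RPMI7951": -0.067, "Hs695t": +0.147},
    "SLC16A7": {"A375": -0.115, "A2058": -0.064, "RPMI7951": +0.154, "Hs695t": -0.065},
    "SLC16A3": {"A375": -0.627, "A2058": -0.286, "RPMI7951": -0.025, "Hs695t": -0.517},
    "SLC2A1": {"A375": -0.660, "A2058": -0.407, "RPMI7951": -0.384, "Hs695t": -0.600},
}
NOX4_EFFECT = 0.74  # +74% on detachment; NOX4 sits outside the glucose universe

UNIVERSE_SIZE = 1005
N_GENE_SETS = 29
N_DECOY_SETS = 11

# planted mito-stress plateaus (pmol O2/min): suspended basal/maximal =
# 28/60 = 0.467, adherent basal = maximal (no spare capacity), maximal fold
# 60/15 = 4.0
MIRROR_OCR_PLATEAUS = {
    ADHESION: (("baseline", 17.0), ("oligomycin", 10.0), ("FCCP", 17.0),
               ("rotenone/antimycin A", 2.0)),
    SUSPENSION: (("baseline", 30.0), ("oligomycin", 10.0), ("FCCP", 62.0),
                 ("rotenone/antimycin A", 2.0)),
}
# planted glycolysis-stress plateaus (mpH/min): both conditions use 80% of
# glycolytic capacity; basal glycolysis 28.2857 (adh) vs 16 (susp) makes the
# suspended/adherent OCR/ECAR ratio fold (28/16)/(15/28.2857) = 3.3
MIRROR_ECAR_PLATEAUS = {
    ADHESION: (("baseline", 10.0), ("glucose", 38.285714285714285),
               ("oligomycin", 45.357142857142854), ("2DG", 11.0)),
    SUSPENSION: (("baseline", 8.0), ("glucose", 24.0), ("oligomycin", 28.0),
                 ("2DG", 9.0)),
}

#: measurement noise as a fraction of each trace's plateau dynamic range
MIRROR_FLUX_NOISE_FRACTION = 0.05
MIRROR_WELLS_PER_CONDITION = 3
MIRROR_CELLS_PER_WELL = 50_000

# qPCR planted folds (suspension vs adhesion, A375): consistent with the
# transporter panel's A375 column (fold = 1 + r)
MIRROR_QPCR_FOLDS = {"SLC16A1": 0.924, "SLC16A7": 0.885,
                     "SLC16A3": 0.373, "SLC2A1": 0.340}

# ROS percents of the control span: superoxide fold 47/10 = 4.7, total ROS
# fold 30/20 = 1.5 (suspension vs adhesion)
MIRROR_ROS_PERCENTS = {
    "superoxide_adhesion": 10.0, "superoxide_suspension": 47.0,
    "ros_adhesion": 20.0, "ros_suspension": 30.0,
}

# lactate (relative concentration units): lower secretion from suspended
# cells at pH 7.0, saturated and equal at pH 8.5
MIRROR_LACTATE_MEANS = {
    (ADHESION, 7.0): 12.0, (SUSPENSION, 7.0): 7.0,
    (ADHESION, 8.5): 15.0, (SUSPENSION, 8.5): 15.0,
}
MIRROR_LACTATE_NOISE = 0.6

# glucose-titration proliferation ratios (normal culture = 4.5 g/L)
MIRROR_GLUCOSE_NORMAL = 4.5
MIRROR_PROLIF_RATIOS = {
    (ADHESION, 0.45): 0.10, (ADHESION, 2.25): 0.55,
    (SUSPENSION, 0.45): 0.60, (SUSPENSION, 2.25): 0.85,
}

# dose-response: adherent cells sensitive to glycolysis blockade (2DG),
# suspended cells sensitive to complex-I blockade (rotenone)
MIRROR_DOSE_RESPONSE = {
    ("2DG", ADHESION): dict(doses=[0, 1, 2, 5, 10, 20, 50], top=1.0,
                            bottom=0.2, ic50=5.0, hill=1.2),
    ("2DG", SUSPENSION): dict(doses=[0, 1, 2, 5, 10, 20, 50], top=1.0,
                              bottom=0.85, ic50=20.0, hill=1.0),
    ("rotenone", ADHESION): dict(doses=[0, 0.01, 0.03, 0.1, 0.3, 1, 3, 10],
                                 top=1.0, bottom=0.7, ic50=1.0, hill=1.0),
    ("rotenone", SUSPENSION): dict(doses=[0, 0.01, 0.03, 0.1, 0.3, 1, 3, 10],
                                   top=1.0, bottom=0.25, ic50=0.1, hill=1.0),
}
MIRROR_VIABILITY_NOISE = 0.03
MIRROR_VIABILITY_REPLICATES = 6


def _plateau_range(plateaus) -> float:
    vals = [m for _, m in plateaus]
    return max(vals) - min(vals)


def mirror_flux_spec(kind: str, condition: str, seed: int,
                     noise_fraction: float = MIRROR_FLUX_NOISE_FRACTION) -> FluxSimSpec:
    plateaus = (MIRROR_OCR_PLATEAUS if kind == "OCR" else MIRROR_ECAR_PLATEAUS)[condition]
    return FluxSimSpec(
        segment_plateaus=plateaus, kind=kind,
        noise_sd=noise_fraction * _plateau_range(plateaus),
        cell_count=MIRROR_CELLS_PER_WELL,
        seed=seed,
    )


def mirror_universe() -> tuple[str, ...]:
    named = list(PLANTED_DOWN) + list(PLANTED_UP)
    fillers = [f"G{i:04d}" for i in range(UNIVERSE_SIZE - len(named))]
    return tuple(named + fillers)


def mirror_expression_spec(seed: int, noise_sd: float = 0.05) -> ExpressionSimSpec:
    universe = mirror_universe()
    extras = ("SLC16A1", "SLC16A7", "SLC16A3", "NOX4")
    genes = universe + extras
    planted_effects = {g: dict(v) for g, v in PANEL_EFFECTS.items()}
    planted_effects["NOX4"] = {line: NOX4_EFFECT for line in LINES}
    return ExpressionSimSpec(
        n_genes=len(genes), genes=genes,
        planted_down=PLANTED_DOWN, planted_up=PLANTED_UP,
        planted_effects=planted_effects,
        background_noise_sd=noise_sd, seed=seed,
    )


@dataclass
class MirrorDataset:
    """Everything the downstream pipeline consumes, plus ground truth."""

    ecar_plate: FluxPlate
    ocr_plate: FluxPlate
    study: ExpressionStudy
    gene_sets: GeneSetCollection
    qpcr: pd.DataFrame
    ros: pd.DataFrame
    lactate: pd.DataFrame
    counts: pd.DataFrame
    viability: pd.DataFrame
    truth: GroundTruth


def generate_mirror_dataset(seed: int) -> MirrorDataset:
    """The full mirror-of-study synthetic dataset under one master seed."""
    ecar_plate = generate_flux_experiment(
        {c: mirror_flux_spec("ECAR", c, seed) for c in (ADHESION, SUSPENSION)},
        MIRROR_WELLS_PER_CONDITION,
    )
    ocr_plate = generate_flux_experiment(
        {c: mirror_flux_spec("OCR", c, seed + 1) for c in (ADHESION, SUSPENSION)},
        MIRROR_WELLS_PER_CONDITION,
    )
    study, expr_truth = generate_expression_study(mirror_expression_spec(seed))
    gene_sets = covering_gene_sets(list(mirror_universe()), N_GENE_SETS,
                                   "glucose", seed, n_decoys=N_DECOY_SETS)
    qpcr = generate_qpcr_table(list(MIRROR_QPCR_FOLDS), MIRROR_QPCR_FOLDS, seed=seed)
    ros = generate_ros_table(MIRROR_ROS_PERCENTS, noise_sd=10.0, seed=seed)
    lactate = generate_lactate_table(MIRROR_LACTATE_MEANS,
                                     noise_sd=MIRROR_LACTATE_NOISE, seed=seed)
    counts = generate_count_table(MIRROR_PROLIF_RATIOS, MIRROR_GLUCOSE_NORMAL,
                                  noise_sd_fraction=0.05, seed=seed)
    frames = []
    for (compound, cond), params in MIRROR_DOSE_RESPONSE.items():
        df = generate_dose_response(
            **params, noise_sd=MIRROR_VIABILITY_NOISE,
            replicates=MIRROR_VIABILITY_REPLICATES,
            seed=seed + zlib.crc32(f"{compound}/{cond}".encode()) % 10_000,
        )
        df.insert(0, "condition", cond)
        df.insert(0, "compound", compound)
        frames.append(df)
    viability = pd.concat(frames, ignore_index=True)

    truth = GroundTruth(
        spec={"seed": seed},
        flux_plateaus={"ECAR": {c: dict(p) for c, p in MIRROR_ECAR_PLATEAUS.items()},
                       "OCR": {c: dict(p) for c, p in MIRROR_OCR_PLATEAUS.items()}},
        expression_effects=expr_truth.expression_effects,
        qpcr_folds=dict(MIRROR_QPCR_FOLDS),
        ros_percents=dict(MIRROR_ROS_PERCENTS),
        dose_response={f"{k[0]}/{k[1]}": v for k, v in MIRROR_DOSE_RESPONSE.items()},
        extras={"proliferation_ratios": {f"{c}@{g}": r for (c, g), r
                                         in MIRROR_PROLIF_RATIOS.items()},
                "lactate_means": {f"{c}@{p}": m for (c, p), m
                                  in MIRROR_LACTATE_MEANS.items()}},
    )
    return MirrorDataset(ecar_plate, ocr_plate, study, gene_sets, qpcr, ros,
                         lactate, counts, viability, truth)
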