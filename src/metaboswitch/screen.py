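"""Glucose gene-set mining and consistent-direction expression screen.

The screen takes normalized microarray intensities for melanoma cell lines
profiled under adhesion and suspension, restricts attention to the union of
keyword-selected gene-sets (GMT/MSigDB-style collections), computes the
relative expression r = (mean suspension intensity - mean adhesion
intensity) / (mean adhesion intensity) per gene per line, and calls a gene
down (up) only when r is below -tau (above +tau) in EVERY line. No
significance testing is performed: the screen is direction-consistency only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADHESION = "adhesion"
SUSPENSION = "suspension"

#: monocarboxylate/glucose transporter panel: display name -> gene symbol
TRANSPORTER_PANEL = {
    "MCT1": "SLC16A1",
    "MCT2": "SLC16A7",
    "MCT4": "SLC16A3",
    "GLUT1": "SLC2A1",
}


class GmtFormatError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene-set names must be unique")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file: name, description, member symbols.

    Duplicate member symbols within a set are deduplicated (first occurrence
    kept) with a logged count; a line with fewer than 3 fields is an error.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning("%s:%d: set %s had %d duplicate member symbols",
                               path, lineno, name, len(members) - len(deduped))
            sets.append(GeneSet(name, desc, tuple(deduped)))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def select_gene_sets(
    collection: GeneSetCollection,
    keyword: str,
    fields: frozenset[str] | set[str] = frozenset({"name", "description"}),
) -> GeneSetCollection:
    """Case-insensitive substring keyword match over the chosen fields.

    Searching name+description (the default) mirrors database keyword
    queries that match annotation text, not just the set name; pass
    ``fields={"name"}`` for name-only matching. Original order is kept.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    kw = keyword.lower()
    selected = []
    for s in collection:
        haystacks = []
        if "name" in fields:
            haystacks.append(s.name.lower())
        if "description" in fields:
            haystacks.append(s.description.lower())
        if any(kw in h for h in haystacks):
            selected.append(s)
    return GeneSetCollection(tuple(selected))


def union_genes(collection: GeneSetCollection) -> list[str]:
    """Set union of all member genes, ordered by first appearance."""
    if len(collection) == 0:
        raise ValueError("collection is empty")
    seen: dict[str, None] = {}
    for s in collection:
        for g in s.members:
            seen.setdefault(g, None)
    return list(seen)


@dataclass
class ExpressionStudy:
    """Probe- or gene-level intensity matrix with sample annotations.

    ``matrix``: rows = probes or genes, columns = sample ids, positive
    normalized intensities. ``samples``: indexed by sample id with 'line'
    and 'condition' columns. ``probe_gene``: optional probe -> gene-symbol
    map (required for :func:`aggregate_probes`).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    probe_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing annotations: {sorted(missing)}")
        for col in ("line", "condition"):
            if col not in self.samples.columns:
                raise ValueError(f"sample annotation column {col!r} missing")

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))


def aggregate_probes(study: ExpressionStudy, method: str = "mean") -> ExpressionStudy:
    """Collapse probe-level rows to gene level (arithmetic mean by default).

    Probes without a gene mapping are dropped; the count is logged.
    """
    if study.probe_gene is None or len(study.probe_gene) == 0:
        raise ValueError("probe -> gene map is required for aggregation")
    if method != "mean":
        raise ValueError(f"unsupported aggregation method {method!r}")
    mapped = study.matrix.index.intersection(study.probe_gene.index)
    n_dropped = len(study.matrix) - len(mapped)
    if n_dropped:
        logger.warning("dropping %d unmapped probes", n_dropped)
    sub = study.matrix.loc[mapped]
    genes = study.probe_gene.loc[mapped]
    gene_matrix = sub.groupby(genes.to_numpy()).mean()
    gene_matrix.index.name = "gene"
    return ExpressionStudy(gene_matrix, study.samples.copy(), None)


def relative_expression_table(study: ExpressionStudy) -> pd.DataFrame:
    """Per (gene, line) relative expression of suspension vs adhesion.

    r = (mean suspension intensity - mean adhesion intensity) /
    (mean adhesion intensity); replicates are averaged per (line, condition)
    before the ratio. Returns a gene x line DataFrame of r (fraction, not
    percent). An adhesion mean of 0 yields NaN for that cell.
    """
    ann = study.samples
    out = {}
    for line in study.lines:
        adh = ann[(ann["line"] == line) & (ann["condition"] == ADHESION)].index
        susp = ann[(ann["line"] == line) & (ann["condition"] == SUSPENSION)].index
        if len(adh) == 0 or len(susp) == 0:
            raise ValueError(f"line {line!r} lacks one of the two conditions")
        mean_a = study.matrix[list(adh)].mean(axis=1)
        mean_s = study.matrix[list(susp)].mean(axis=1)
        r = (mean_s - mean_a) / mean_a.where(mean_a != 0, np.nan)
        out[line] = r
    table = pd.DataFrame(out)
    table.index.name = "gene"
    return table


@dataclass
class ScreenResult:
    universe: list[str]
    down: list[str]
    up: list[str]
    r_table: pd.DataFrame
    tau: float
    excluded: list[str] = field(default_factory=list)

    def call(self, gene: str) -> str:
        if gene in self.down:
            return "down"
        if gene in self.up:
            return "up"
        return "none"

    def to_frame(self) -> pd.DataFrame:
        """Tidy output: gene, per-line r as signed %, and the call."""
        df = (100 * self.r_table.loc[self.r_table.index.intersection(self.universe)]).round(1)
        df = df.rename(columns=lambda c: f"r_{c}_pct")
        df["call"] = [self.call(g) for g in df.index]
        return df.sort_index()


def consistent_direction_screen(
    r_table: pd.DataFrame,
    universe: list[str],
    tau: float = 0.0,
) -> ScreenResult:
    """Call genes whose relative expression has a consistent sign in all lines.

    down = {g : r(g, line) < -tau for every line}; up = {g : r(g, line) >
    +tau for every line}. Strict inequalities, so tau = 0 demands strict
    sign agreement. Universe genes missing from the table (or with NaN in
    any line) are excluded and logged. Output lists are alphabetical.
    """
    if not universe:
        raise ValueError("gene universe is empty")
    present = [g for g in universe if g in r_table.index]
    sub = r_table.loc[present]
    complete = sub.dropna().index
    excluded = sorted(set(universe) - set(complete))
    if excluded:
        logger.warning("excluding %d universe genes missing measurements", len(excluded))
    sub = sub.loc[complete]
    down = sorted(sub.index[(sub < -tau).all(axis=1)])
    up = sorted(sub.index[(sub > tau).all(axis=1)])
    return ScreenResult(list(universe), down, up, r_table, tau, excluded)


def format_percent(r: float) -> str:
    """Signed percent with one decimal, e.g. -0.627 -> '-62.7%'."""
    if math.isnan(r):
        return ""
    return f"{100 * r:+.1f}%".replace("+", "+")


def transporter_panel(
    r_table: pd.DataFrame,
    panel: dict[str, str] | None = None,
    bold_threshold: float = 0.35,
) -> pd.DataFrame:
    """Relative-expression panel for the lactate/glucose transporters.

    Returns one row per (panel gene, line) with the signed percent string
    and a ``marked`` flag when |r| >= bold_threshold. Panel genes absent
    from the table get blank cells and a logged warning.
    """
    if panel is None:
        panel = TRANSPORTER_PANEL
    rows = []
    for display, symbol in panel.items():
        for line in r_table.columns:
            if symbol in r_table.index:
                r = float(r_table.at[symbol, line])
                rows.append({"name": display, "gene": symbol, "line": line,
                             "relative_expression": format_percent(r),
                             "marked": (not math.isnan(r)) and abs(r) >= bold_threshold})
            else:
                logger.warning("panel gene %s (%s) missing from table", display, symbol)
                rows.append({"name": display, "gene": symbol, "line": line,
                             "relative_expression": "", "marked": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# series-matrix-like TSV I/O for expression studies
# ---------------------------------------------------------------------------

def write_study_tsv(study: ExpressionStudy, path) -> None:
    """Write matrix + annotations as a series-matrix-like TSV.

    Three header rows (#sample, #line, #condition) then one row per
    probe/gene. An optional fourth header is not used; probe->gene maps are
    written alongside as ``<path>.genes.tsv`` when present.
    """
    with open(path, "w") as fh:
        cols = list(study.matrix.columns)
        fh.write("#sample\t" + "\t".join(cols) + "\n")
        fh.write("#line\t" + "\t".join(str(study.samples.at[c, "line"]) for c in cols) + "\n")
        fh.write("#condition\t" + "\t".join(str(study.samples.at[c, "condition"]) for c in cols) + "\n")
        study.matrix.to_csv(fh, sep="\t", header=False)
    if study.probe_gene is not None:
        study.probe_gene.rename("gene").rename_axis("probe").to_csv(
            str(path) + ".genes.tsv", sep="\t")


def read_study_tsv(path) -> ExpressionStudy:
    import os

    with open(path) as fh:
        header = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, *values = line.rstrip("\n").split("\t")
            header[key.lstrip("#")] = values
            pos = fh.tell()
        matrix = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    matrix.columns = header["sample"]
    matrix.index.name = "gene"
    samples = pd.DataFrame(
        {"line": header["line"], "condition": header["condition"]},
        index=pd.Index(header["sample"], name="sample"),
    )
    probe_gene = None
    genes_path = str(path) + ".genes.tsv"
    if os.path.exists(genes_path):
        probe_gene = pd.read_csv(genes_path, sep="\t", index_col=0)["gene"]
    return ExpressionStudy(matrix, samples, probe_gene)
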