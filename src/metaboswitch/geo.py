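"""GEO series-matrix import for expression studies.

A series-matrix file is a block of ``!key<TAB>value...`` header lines
followed by a tab-separated intensity table delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``. Cell line and
culture condition are not structured fields, so the caller supplies a
mapping from sample title to (line, condition); unmapped samples are dropped
with a warning.
"""

from __future__ import annotations

import logging
from io import StringIO

import pandas as pd

from .screen import ExpressionStudy

logger = logging.getLogger(__name__)

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"


class SeriesMatrixError(ValueError):
    pass


def _strip_quotes(s: str) -> str:
    return s[1:-1] if len(s) >= 2 and s[0] == '"' and s[-1] == '"' else s


def read_series_matrix(path) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Parse header key-values and the intensity matrix."""
    header: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == TABLE_BEGIN:
                in_table, saw_begin = True, True
                continue
            if line == TABLE_END:
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, *values = line.split("\t")
                header.setdefault(key.lstrip("!"), []).extend(_strip_quotes(v) for v in values)
    if not (saw_begin and saw_end):
        raise SeriesMatrixError(f"{path}: missing {TABLE_BEGIN}/{TABLE_END} delimiters")
    matrix = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [_strip_quotes(str(c)) for c in matrix.columns]
    matrix.index = [_strip_quotes(str(i)) for i in matrix.index]
    matrix.index.name = "probe"
    return header, matrix


def geo_import(path, title_map: dict[str, tuple[str, str]]) -> ExpressionStudy:
    """Series-matrix file -> :class:`ExpressionStudy`.

    ``title_map`` maps sample titles to (cell line, condition). Samples with
    titles missing from the map are excluded and logged.
    """
    header, matrix = read_series_matrix(path)
    titles = header.get("Sample_title")
    accessions = header.get("Sample_geo_accession", titles)
    if titles is None:
        raise SeriesMatrixError(f"{path}: no !Sample_title header")
    title_of = dict(zip(accessions, titles))
    keep, lines, conds = [], [], []
    for col in matrix.columns:
        title = title_of.get(col, col)
        if title in title_map:
            line, cond = title_map[title]
            keep.append(col)
            lines.append(line)
            conds.append(cond)
        else:
            logger.warning("dropping unmapped sample %s (title %r)", col, title)
    samples = pd.DataFrame({"line": lines, "condition": conds},
                           index=pd.Index(keep, name="sample"))
    return ExpressionStudy(matrix[keep], samples)


def write_series_matrix(study: ExpressionStudy, path, series_id: str = "GSE000000") -> None:
    """Export a study in series-matrix form (round-trips with geo_import)."""
    cols = list(study.matrix.columns)
    with open(path, "w") as fh:
        fh.write(f"!Series_geo_accession\t\"{series_id}\"\n")
        fh.write("!Sample_title\t" + "\t".join(f'"{c}"' for c in cols) + "\n")
        fh.write("!Sample_geo_accession\t" + "\t".join(f'"{c}"' for c in cols) + "\n")
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\"ID_REF\"\t" + "\t".join(f'"{c}"' for c in cols) + "\n")
        study.matrix.to_csv(fh, sep="\t", header=False)
        fh.write(TABLE_END + "\n")
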