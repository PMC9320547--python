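"""Gene-set mining and the cross-line consistent-direction screen: GMT
round-trips, keyword selection, relative-expression arithmetic, brute-force
oracle equivalence, tau-monotonicity and per-line scale invariance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboswitch.screen import (
    ExpressionStudy,
    GeneSet,
    GeneSetCollection,
    GmtFormatError,
    aggregate_probes,
    consistent_direction_screen,
    format_percent,
    read_gmt,
    read_study_tsv,
    relative_expression_table,
    select_gene_sets,
    transporter_panel,
    union_genes,
    write_gmt,
    write_study_tsv,
)
from metaboswitch.synthetic import (
    ExpressionSimSpec,
    generate_expression_study,
)


def tiny_study(values_by_line, replicates=1):
    """Build a study from {line: {gene: (adh_mean, susp_mean)}}."""
    cols, data, lines, conds = [], {}, [], []
    genes = list(next(iter(values_by_line.values())))
    for line, per_gene in values_by_line.items():
        for cond_i, cond in enumerate(("adhesion", "suspension")):
            for rep in range(replicates):
                col = f"{line}_{cond}_{rep}"
                cols.append(col)
                lines.append(line)
                conds.append(cond)
                data[col] = [per_gene[g][cond_i] for g in genes]
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame({"line": lines, "condition": conds},
                           index=pd.Index(cols, name="sample"))
    return ExpressionStudy(matrix, samples)


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection((
            GeneSet("SET_A", "first", ("G1", "G2", "G3")),
            GeneSet("SET_B", "second", ("G2", "G4")),
        ))
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        assert read_gmt(path) == coll

    def test_duplicate_members_deduplicated(self, tmp_path, caplog):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tdesc\tG1\tG2\tG1\n")
        with caplog.at_level("WARNING"):
            coll = read_gmt(path)
        assert coll.sets[0].members == ("G1", "G2")
        assert "duplicate" in caplog.text

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tG1\nS2\tonly-two-fields\n")
        with pytest.raises(GmtFormatError, match=":2:"):
            read_gmt(path)


class TestSelectAndUnion:
    @pytest.fixture()
    def collection(self):
        return GeneSetCollection((
            GeneSet("GOBP_GLUCOSE_IMPORT", "glucose uptake", ("A", "B")),
            GeneSet("GOBP_PANCREAS_DEVELOPMENT", "organ with glucose sensing", ("B", "C")),
            GeneSet("GOBP_LIPID_STORAGE", "fat", ("C", "D")),
        ))

    def test_keyword_is_case_insensitive(self, collection):
        upper = select_gene_sets(collection, "GLUCOSE")
        lower = select_gene_sets(collection, "glucose")
        assert upper == lower
        assert len(lower) == 2

    def test_name_only_field_restriction(self, collection):
        assert select_gene_sets(collection, "glucose", fields={"name"}).names() == \
            ["GOBP_GLUCOSE_IMPORT"]

    def test_absent_keyword_gives_empty_collection(self, collection):
        assert len(select_gene_sets(collection, "zzz")) == 0

    def test_union_order_and_brute_force_size(self):
        rng = np.random.default_rng(5)
        universe = [f"G{i}" for i in range(60)]
        sets = tuple(
            GeneSet(f"S{i}", "", tuple(rng.choice(universe, size=rng.integers(3, 20),
                                                  replace=False)))
            for i in range(12))
        coll = GeneSetCollection(sets)
        got = union_genes(coll)
        brute = set()
        for s in sets:
            brute |= set(s.members)
        assert set(got) == brute
        assert len(got) == len(brute)
        # first-appearance order
        assert got[:len(sets[0].members)] == list(sets[0].members)

    def test_simple_overlap(self):
        coll = GeneSetCollection((GeneSet("x", "", ("A", "B", "C")),
                                  GeneSet("y", "", ("B", "C", "D"))))
        assert union_genes(coll) == ["A", "B", "C", "D"]


class TestAggregateProbes:
    def test_mean_collapse_and_order_invariance(self):
        matrix = pd.DataFrame({"s1": [10.0, 30.0, 7.0]},
                              index=pd.Index(["p1", "p2", "p3"], name="probe"))
        samples = pd.DataFrame({"line": ["A375"], "condition": ["adhesion"]},
                               index=pd.Index(["s1"], name="sample"))
        pg = pd.Series({"p1": "G1", "p2": "G1", "p3": "G2"})
        study = ExpressionStudy(matrix, samples, pg)
        out = aggregate_probes(study)
        assert out.matrix.at["G1", "s1"] == 20.0
        assert out.matrix.at["G2", "s1"] == 7.0
        shuffled = ExpressionStudy(matrix.iloc[::-1], samples, pg)
        pd.testing.assert_frame_equal(aggregate_probes(shuffled).matrix, out.matrix)

    def test_unmapped_probes_dropped_with_log(self, caplog):
        matrix = pd.DataFrame({"s1": [1.0, 2.0]},
                              index=pd.Index(["p1", "p2"], name="probe"))
        samples = pd.DataFrame({"line": ["A375"], "condition": ["adhesion"]},
                               index=pd.Index(["s1"], name="sample"))
        study = ExpressionStudy(matrix, samples, pd.Series({"p1": "G1"}))
        with caplog.at_level("WARNING"):
            out = aggregate_probes(study)
        assert list(out.matrix.index) == ["G1"]
        assert "1 unmapped" in caplog.text

    def test_missing_map_rejected(self):
        matrix = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        samples = pd.DataFrame({"line": ["A375"], "condition": ["adhesion"]},
                               index=pd.Index(["s1"], name="sample"))
        with pytest.raises(ValueError, match="map"):
            aggregate_probes(ExpressionStudy(matrix, samples, None))


class TestRelativeExpression:
    def test_worked_arithmetic(self):
        study = tiny_study({"A375": {"GLUT1": (1000.0, 340.0), "X": (50.0, 50.0)}})
        r = relative_expression_table(study)
        assert r.at["GLUT1", "A375"] == pytest.approx(-0.66)
        assert r.at["X", "A375"] == 0.0

    def test_noise_free_planted_effect_recovered_in_every_line(self):
        spec = ExpressionSimSpec(n_genes=4, genes=("G", "A", "B", "C"),
                                 planted_effects={"G": {line: -0.5 for line in
                                                        ("A375", "A2058",
                                                         "RPMI7951", "Hs695t")}},
                                 background_noise_sd=0.0, seed=1)
        study, _ = generate_expression_study(spec)
        r = relative_expression_table(study)
        assert np.allclose(r.loc["G"], -0.5)

    def test_zero_adhesion_mean_flagged_nan(self):
        study = tiny_study({"A375": {"G": (0.0, 10.0)}})
        r = relative_expression_table(study)
        assert np.isnan(r.at["G", "A375"])

    def test_per_line_scale_invariance(self, mirror):
        study = mirror.study
        r = relative_expression_table(study)
        scaled = study.matrix.copy()
        a375 = study.samples.index[study.samples["line"] == "A375"]
        scaled[list(a375)] *= 7.3
        r2 = relative_expression_table(ExpressionStudy(scaled, study.samples))
        pd.testing.assert_frame_equal(r, r2)


def brute_force_screen(r_table, universe, tau):
    down, up = [], []
    for g in universe:
        if g not in r_table.index or r_table.loc[g].isna().any():
            continue
        vals = r_table.loc[g]
        if all(v < -tau for v in vals):
            down.append(g)
        if all(v > tau for v in vals):
            up.append(g)
    return sorted(down), sorted(up)


class TestConsistentDirectionScreen:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            genes = [f"G{i}" for i in range(40)]
            r = pd.DataFrame(rng.normal(0, 0.3, size=(40, 4)), index=genes,
                             columns=["L1", "L2", "L3", "L4"])
            tau = float(rng.uniform(0, 0.3))
            res = consistent_direction_screen(r, genes, tau=tau)
            assert (res.down, res.up) == brute_force_screen(r, genes, tau)

    def test_sign_inconsistent_gene_called_neither(self):
        r = pd.DataFrame([[-0.05, -0.05, -0.05, 0.01]], index=["G"],
                         columns=list("abcd"))
        res = consistent_direction_screen(r, ["G"], tau=0.0)
        assert res.down == [] and res.up == []

    def test_strict_inequality_at_zero(self):
        r = pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["G"], columns=list("abcd"))
        res = consistent_direction_screen(r, ["G"], tau=0.0)
        assert res.down == [] and res.up == []

    @given(st.floats(0, 0.2), st.floats(0, 0.2))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_tau(self, t1, t2):
        t1, t2 = sorted((t1, t2))
        rng = np.random.default_rng(23)
        genes = [f"G{i}" for i in range(30)]
        r = pd.DataFrame(rng.normal(0, 0.2, size=(30, 4)), index=genes,
                         columns=list("abcd"))
        lo = consistent_direction_screen(r, genes, tau=t1)
        hi = consistent_direction_screen(r, genes, tau=t2)
        assert set(hi.down) <= set(lo.down)
        assert set(hi.up) <= set(lo.up)

    def test_gene_missing_a_line_is_excluded_and_logged(self, caplog):
        r = pd.DataFrame([[-0.5, -0.5, -0.5, np.nan]], index=["G"],
                         columns=list("abcd"))
        with caplog.at_level("WARNING"):
            res = consistent_direction_screen(r, ["G"], tau=0.0)
        assert res.excluded == ["G"]
        assert res.down == []

    def test_empty_universe_rejected(self):
        r = pd.DataFrame([[0.1]], index=["G"], columns=["a"])
        with pytest.raises(ValueError, match="empty"):
            consistent_direction_screen(r, [], tau=0.0)

    def test_output_is_alphabetical(self):
        r = pd.DataFrame([[-0.5] * 4, [-0.4] * 4], index=["ZZZ", "AAA"],
                         columns=list("abcd"))
        res = consistent_direction_screen(r, ["ZZZ", "AAA"], tau=0.0)
        assert res.down == ["AAA", "ZZZ"]


class TestTransporterPanel:
    def test_percent_formatting_and_marking(self):
        assert format_percent(-0.627) == "-62.7%"
        assert format_percent(0.006) == "+0.6%"
        r = pd.DataFrame(
            {"A375": [-0.627, -0.076], "A2058": [-0.286, 0.006]},
            index=["SLC16A3", "SLC16A1"])
        panel = transporter_panel(r, panel={"MCT4": "SLC16A3", "MCT1": "SLC16A1"})
        by = {(row["gene"], row["line"]): row for _, row in panel.iterrows()}
        assert by[("SLC16A3", "A375")]["relative_expression"] == "-62.7%"
        assert by[("SLC16A3", "A375")]["marked"]
        assert by[("SLC16A3", "A2058")]["relative_expression"] == "-28.6%"
        assert not by[("SLC16A3", "A2058")]["marked"]
        assert by[("SLC16A1", "A2058")]["relative_expression"] == "+0.6%"
        assert not by[("SLC16A1", "A2058")]["marked"]

    def test_missing_panel_gene_blank_with_warning(self, caplog):
        r = pd.DataFrame({"A375": [0.1]}, index=["OTHER"])
        with caplog.at_level("WARNING"):
            panel = transporter_panel(r, panel={"MCT4": "SLC16A3"})
        assert panel.iloc[0]["relative_expression"] == ""
        assert "missing" in caplog.text


class TestStudyIO:
    def test_round_trip(self, tmp_path, mirror):
        path = tmp_path / "study.tsv"
        write_study_tsv(mirror.study, path)
        back = read_study_tsv(path)
        pd.testing.assert_frame_equal(back.matrix, mirror.study.matrix,
                                      check_exact=False, rtol=1e-12)
        pd.testing.assert_frame_equal(back.samples, mirror.study.samples)
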