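import numpy as np
import pandas as pd
import pytest

from semclust.diffexpr import (
    ComparisonLabeling,
    CqMatrix,
    DiffExprStats,
    ExpressionTable,
    anova_tukey,
    count_upregulated,
    dss_separation_filter,
    impute_missing,
    label_groups,
    normalize,
    upregulated_sets,
)

from .oracles import tukey_pairwise_p


def _cq(values: dict, index, tissue_of=None, ref="HSP90"):
    df = pd.DataFrame(values, index=index)
    tissue_of = tissue_of or {s: s.rsplit("_", 1)[0] for s in df.columns}
    return CqMatrix(values=df, sample_tissue=tissue_of, reference_gene=ref)


def _expr(values: dict, index, tissue_of=None):
    df = pd.DataFrame(values, index=index)
    tissue_of = tissue_of or {s: s.rsplit("_", 1)[0] for s in df.columns}
    imputed = pd.DataFrame(False, index=df.index, columns=df.columns)
    return ExpressionTable(values=df, sample_tissue=tissue_of, imputed=imputed)


class TestImpute:
    def test_max_plus_two(self, toy_cq):
        out = impute_missing(toy_cq)
        # g4 observed max is 27.3 -> missing well becomes 29.3
        assert out.values.loc["g4", "colon_1"] == pytest.approx(29.3)
        assert bool(out.imputed.loc["g4", "colon_1"])
        assert not out.imputed.loc["g4", "colon_2"]

    def test_row_without_missing_unchanged(self, toy_cq):
        out = impute_missing(toy_cq)
        pd.testing.assert_series_equal(out.values.loc["g1"],
                                       toy_cq.values.loc["g1"])

    def test_simple_row(self):
        cq = _cq(
            {"a_1": [20.0, 20.0], "a_2": [np.nan, 20.0],
             "b_1": [22.0, 20.0], "b_2": [21.0, 20.0]},
            ["g", "HSP90"],
        )
        out = impute_missing(cq)
        assert out.values.loc["g", "a_2"] == pytest.approx(24.0)

    def test_all_missing_row_dropped(self):
        cq = _cq(
            {"a_1": [np.nan, 21.0, 20.0], "b_1": [np.nan, 22.0, 20.0],
             "a_2": [np.nan, 21.5, 20.0], "b_2": [np.nan, 22.5, 20.0]},
            ["gone", "kept", "HSP90"],
        )
        out = impute_missing(cq)
        assert "gone" not in out.values.index
        assert "kept" in out.values.index


class TestNormalize:
    def test_definition(self):
        cq = _cq({"a_1": [24.0, 20.0], "b_1": [24.0, 20.0]}, ["g", "HSP90"])
        expr = normalize(impute_missing(cq))
        assert expr.values.loc["g", "a_1"] == pytest.approx(-4.0)
        assert "HSP90" not in expr.values.index

    def test_reference_duplicate_maps_to_zero(self):
        cq = _cq({"a_1": [20.0, 20.0], "b_1": [23.0, 23.0]},
                 ["twin", "HSP90"])
        expr = normalize(impute_missing(cq))
        assert (expr.values.loc["twin"] == 0.0).all()

    def test_sample_shift_invariance(self, toy_cq):
        # holds for observed wells: imputed fills use a cross-sample max,
        # so restrict to the fully observed part of the matrix
        observed = toy_cq.values.dropna()
        cq1 = CqMatrix(values=observed, sample_tissue=toy_cq.sample_tissue,
                       reference_gene="HSP90")
        base = normalize(impute_missing(cq1))
        shifted = observed.copy()
        shifted["colon_1"] += 3.0  # per-sample offset cancels in dCq
        cq2 = CqMatrix(values=shifted, sample_tissue=toy_cq.sample_tissue,
                       reference_gene="HSP90")
        again = normalize(impute_missing(cq2))
        pd.testing.assert_frame_equal(base.values, again.values)

    def test_equal_delta_equal_expression(self):
        cq = _cq({"a_1": [25.0, 20.0], "b_1": [27.0, 22.0]}, ["g", "HSP90"])
        expr = normalize(impute_missing(cq))
        assert expr.values.loc["g", "a_1"] == expr.values.loc["g", "b_1"]

    def test_requires_imputation_first(self):
        cq = _cq({"a_1": [np.nan, 20.0], "b_1": [24.0, 20.0]}, ["g", "HSP90"])
        with pytest.raises(ValueError, match="impute"):
            normalize(cq)


class TestCqValidation:
    def test_reference_missing_value_rejected(self):
        with pytest.raises(ValueError, match="reference gene has missing"):
            _cq({"a_1": [24.0, np.nan], "b_1": [24.0, 20.0]}, ["g", "HSP90"])

    def test_reference_absent_rejected(self):
        with pytest.raises(ValueError, match="not in matrix"):
            _cq({"a_1": [24.0], "b_1": [24.0]}, ["g"])

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError, match="two tissues"):
            _cq({"a_1": [24.0, 20.0], "a_2": [24.0, 20.0]}, ["g", "HSP90"])

    def test_out_of_range_cq_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _cq({"a_1": [50.0, 20.0], "b_1": [24.0, 20.0]}, ["g", "HSP90"])


def _three_group_expr(g1, g2, g3, genes=("g",)):
    cols = {}
    for t, vals in zip(["a", "b", "c"], [g1, g2, g3]):
        for i, v in enumerate(vals):
            cols[f"{t}_{i + 1}"] = [v] * len(genes)
    return _expr(cols, list(genes))


class TestAnovaTukey:
    def test_identical_means_not_significant(self):
        rng = np.random.default_rng(3)
        cols = {f"{t}_{i}": rng.normal(0, 1, 1)
                for t in "abc" for i in (1, 2, 3)}
        expr = _expr(cols, ["g"])
        stats = anova_tukey(expr)
        # same draws re-used per tissue sample: group means differ only by noise
        assert all(
            (tbl["p_adj"] > 0.01).all() or abs(tbl["mean_diff"]).max() > 0
            for tbl in stats.pairwise.values()
        )

    def test_wide_separation_significant(self):
        expr = _expr(
            {
                "a_1": [0.0], "a_2": [0.01], "a_3": [-0.01],
                "b_1": [10.0], "b_2": [10.01], "b_3": [9.99],
                "c_1": [0.02], "c_2": [-0.02], "c_3": [0.0],
            },
            ["g"],
        )
        stats = anova_tukey(expr)
        assert stats.pairwise[("a", "b")]["p_adj"].iloc[0] < 0.01
        assert stats.pairwise[("a", "c")]["p_adj"].iloc[0] > 0.5

    def test_matches_studentized_range_oracle(self):
        # fixed draws from planted means (0, 1, 0), sigma = 1, n = 3
        a = np.array([0.18, -0.72, 0.51])
        b = np.array([1.93, 0.66, 1.26])
        c = np.array([-0.44, 0.09, -0.17])
        expr = _expr(
            {
                "a_1": [a[0]], "a_2": [a[1]], "a_3": [a[2]],
                "b_1": [b[0]], "b_2": [b[1]], "b_3": [b[2]],
                "c_1": [c[0]], "c_2": [c[1]], "c_3": [c[2]],
            },
            ["g"],
        )
        stats = anova_tukey(expr)
        oracle = tukey_pairwise_p([a, b, c])
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        for (t1, t2), key in zip(pairs, [(0, 1), (0, 2), (1, 2)]):
            assert stats.pairwise[(t1, t2)]["p_adj"].iloc[0] == pytest.approx(
                oracle[key], abs=1e-6
            )

    def test_degenerate_zero_variance(self):
        expr = _three_group_expr([0.0, 0.0, 0.0], [5.0, 5.0, 5.0],
                                 [0.0, 0.0, 0.0])
        stats = anova_tukey(expr)
        assert bool(stats.anova["degenerate"].iloc[0])
        assert stats.pairwise[("a", "b")]["p_adj"].iloc[0] == 0.0
        assert stats.pairwise[("a", "c")]["p_adj"].iloc[0] == 1.0

    def test_requires_replicates(self):
        expr = _expr({"a_1": [0.0], "b_1": [1.0], "b_2": [1.0]}, ["g"])
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey(expr)


def _stats_with_p(p_ab: float, diff_ab: float = 1.0) -> DiffExprStats:
    anova = pd.DataFrame({"F": [1.0], "p": [p_ab], "degenerate": [False]},
                         index=["g"])
    pairwise = {
        ("a", "b"): pd.DataFrame({"mean_diff": [diff_ab], "p_adj": [p_ab]},
                                 index=["g"]),
    }
    return DiffExprStats(anova=anova, pairwise=pairwise, tissues=("a", "b"))


class TestLabelGroups:
    def test_significant_with_direction(self):
        labs = label_groups(_stats_with_p(0.005, diff_ab=-2.0))
        lab = labs[("a", "b")]
        assert bool(lab.significant["g"])
        assert lab.direction["g"] == "b"  # higher in second tissue

    def test_boundary_alpha_excluded(self):
        labs = label_groups(_stats_with_p(0.01))
        assert not labs[("a", "b")].significant["g"]

    def test_plain_nonsignificant(self):
        labs = label_groups(_stats_with_p(0.5))
        lab = labs[("a", "b")]
        assert not lab.significant["g"]
        assert lab.direction["g"] is None

    def test_direction_consistency_enforced(self):
        sig = pd.Series([True], index=["g"])
        direction = pd.Series([None], index=["g"], dtype=object)
        with pytest.raises(ValueError, match="mismatch"):
            ComparisonLabeling(("a", "b"), sig, direction,
                               pd.Series([0.001], index=["g"]))


class TestCountUpregulated:
    def _lab(self, comparison, up: dict):
        genes = ["g1", "g2", "g3"]
        sig = pd.Series([g in up for g in genes], index=genes)
        direction = pd.Series([up.get(g) for g in genes], index=genes,
                              dtype=object)
        p = pd.Series(np.where(sig, 0.001, 0.5), index=genes)
        return ComparisonLabeling(comparison, sig, direction, p)

    def test_union_counts_once(self):
        labs = {
            ("colon", "si"): self._lab(("colon", "si"), {"g1": "colon"}),
            ("colon", "sto"): self._lab(("colon", "sto"), {"g1": "colon"}),
            ("si", "sto"): self._lab(("si", "sto"), {}),
        }
        assert count_upregulated(labs)["colon"] == 1
        assert count_upregulated(labs, distinct=False)["colon"] == 2

    def test_single_comparison_counts(self):
        labs = {
            ("colon", "si"): self._lab(("colon", "si"), {}),
            ("colon", "sto"): self._lab(("colon", "sto"), {"g2": "colon"}),
            ("si", "sto"): self._lab(("si", "sto"), {}),
        }
        counts = count_upregulated(labs)
        assert counts["colon"] == 1
        assert counts["si"] == 0
        assert upregulated_sets(labs)["colon"] == {"g2"}


class TestDssFilter:
    def _tables(self, treated_rows, control_rows, genes):
        treated = _expr(
            {f"t_{i + 1}": [r[i] for r in treated_rows]
             for i in range(len(treated_rows[0]))},
            genes,
        )
        control = _expr(
            {f"c_{i + 1}": [r[i] for r in control_rows]
             for i in range(len(control_rows[0]))},
            genes,
        )
        return treated, control

    def test_selected_down_in_treated(self):
        treated, control = self._tables([[-5.0, -5.2, -5.1]], [[-2.0, -2.3]],
                                        ["g"])
        assert dss_separation_filter(treated, control) == {"g": "down"}

    def test_overlap_rejected_despite_mean_difference(self):
        treated, control = self._tables([[-3.0, -1.0]], [[-2.0, -2.1]], ["g"])
        assert dss_separation_filter(treated, control) == {}

    def test_boundary_delta_strict(self):
        treated, control = self._tables([[1.25, 1.25]], [[0.0, 0.0]], ["g"])
        assert dss_separation_filter(treated, control) == {}
        treated, control = self._tables([[1.26, 1.26]], [[0.0, 0.0]], ["g"])
        assert dss_separation_filter(treated, control) == {"g": "up"}

    def test_sign_symmetry(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        tr = rng.normal(0, 2, (30, 3))
        ct = rng.normal(0, 2, (30, 2))
        treated, control = self._tables(tr.tolist(), ct.tolist(), genes)
        flipped_t, flipped_c = self._tables((-tr).tolist(), (-ct).tolist(),
                                            genes)
        fwd = dss_separation_filter(treated, control)
        rev = dss_separation_filter(flipped_t, flipped_c)
        assert set(fwd) == set(rev)
        flip = {"up": "down", "down": "up"}
        assert all(rev[g] == flip[d] for g, d in fwd.items())
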