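"""t-tests, fold-change conventions, BH FDR and time-course selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from colicord.diffexpr import (
    bh_fdr,
    differential_expression,
    fold_changes,
    log2fc_to_signed,
    signed_to_log2fc,
    student_t_test,
    timecourse_select,
)
from colicord.io_core import AnalysisConfig, ExpressionMatrix, SampleDesign, ValidationError


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        res = student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0 and res.p == 1

    def test_pooled_variance_hand_example(self):
        res = student_t_test([1, 2, 3], [3, 4, 5])
        assert res.t == pytest.approx(-2.449, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0705, abs=1e-3)

    def test_constant_nonzero_paired_difference_is_degenerate(self):
        res = student_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], paired=True)
        assert res.degenerate and res.p == 0

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            na, nb = rng.integers(2, 10, size=2)
            a, b = rng.normal(size=na), rng.normal(size=nb)
            mine = student_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)
            n = int(min(na, nb))
            mine_p = student_t_test(a[:n], b[:n], paired=True)
            ref_p = stats.ttest_rel(a[:n], b[:n])
            assert mine_p.t == pytest.approx(ref_p.statistic, abs=1e-10)
            assert mine_p.p == pytest.approx(ref_p.pvalue, abs=1e-10)


class TestFoldChangeConvention:
    @pytest.mark.parametrize(
        "log2fc,signed",
        [
            (0.0, 1.0),
            (3.109, 8.63),  # up-regulated interleukin-scale change
            (-2.211, -4.63),  # down-regulated nuclear-receptor-scale change
        ],
    )
    def test_signed_convention(self, log2fc, signed):
        assert log2fc_to_signed(log2fc) == pytest.approx(signed, abs=5e-3)

    def test_conversion_round_trips(self):
        rng = np.random.default_rng(2)
        lfc = rng.uniform(-6, 6, size=200)
        back = signed_to_log2fc(log2fc_to_signed(lfc))
        np.testing.assert_allclose(back, lfc, atol=1e-12)

    def test_signed_magnitude_at_least_one(self):
        lfc = np.linspace(-4, 4, 101)
        assert (np.abs(log2fc_to_signed(lfc)) >= 1).all()

    def test_signed_to_log2fc_rejects_sub_unit_values(self):
        with pytest.raises(ValidationError):
            signed_to_log2fc(0.5)

    def test_fold_changes_antisymmetric(self, small_log2_matrix, small_design):
        ab = fold_changes(small_log2_matrix, small_design, "T3", "T0")
        ba = fold_changes(small_log2_matrix, small_design, "T0", "T3")
        np.testing.assert_array_equal(
            ab["log2fc"].to_numpy(), -ba["log2fc"].to_numpy()
        )

    def test_missing_condition_rejected(self, small_log2_matrix, small_design):
        with pytest.raises(ValidationError):
            fold_changes(small_log2_matrix, small_design, "T7", "T0")


class TestBhFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.1, 0.2]), [0.015, 0.15, 0.2], atol=1e-12
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_and_empty(self):
        np.testing.assert_allclose(bh_fdr([1.0]), [1.0])
        assert bh_fdr([]).size == 0

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_permutation_invariant(self, ps, rnd):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = bh_fdr([ps[i] for i in perm])
        np.testing.assert_allclose([q_perm[perm.index(i)] for i in range(len(ps))], q)


def _paired_study(effects, noise_sd, n_subjects, seed, conditions=("T0", "T3", "T7", "T12")):
    """Matrix + design with per-gene planted log2 effects per condition."""
    rng = np.random.default_rng(seed)
    n_genes = effects.shape[0]
    rows, cols, data = [], [], []
    for s in range(n_subjects):
        for ci, cond in enumerate(conditions):
            sid = f"r{s}_{cond}"
            cols.append(sid)
            rows.append({"sample_id": sid, "subject_id": f"r{s}", "condition": cond, "species": "rat"})
            data.append(8 + effects[:, ci] + rng.normal(0, noise_sd, n_genes) if noise_sd else 8 + effects[:, ci])
    values = pd.DataFrame(
        np.column_stack(data), index=[f"g{i}" for i in range(n_genes)], columns=cols
    )
    return (
        ExpressionMatrix(values=values, scale="log2"),
        SampleDesign(table=pd.DataFrame(rows)),
    )


class TestTimecourseSelect:
    def test_constant_gene_never_selected(self):
        effects = np.zeros((5, 4))
        effects[0, 1:] = 2.0  # one regulated gene provides variance contrast
        m, design = _paired_study(effects, noise_sd=0.3, n_subjects=4, seed=1)
        sel = timecourse_select(m, design, AnalysisConfig(rng_seed=0))
        assert not sel.table.loc["g1":"g4", "selected"].any()

    def test_strong_sustained_effect_selected(self):
        # 20% of genes carry a sustained 2.0 log2 effect; at 5 subjects
        # and noise 0.5 the selection should recover the large majority
        effects = np.zeros((200, 4))
        effects[:40, 1:] = 2.0
        m, design = _paired_study(effects, noise_sd=0.5, n_subjects=5, seed=2)
        sel = timecourse_select(m, design, AnalysisConfig(rng_seed=3))
        regulated = [f"g{i}" for i in range(40)]
        assert sel.table.loc[regulated, "selected"].mean() >= 0.8
        assert not sel.table.drop(regulated)["selected"].any()

    def test_null_selection_rate_at_most_alpha(self):
        m, design = _paired_study(np.zeros((400, 4)), noise_sd=0.5, n_subjects=5, seed=4)
        sel = timecourse_select(m, design, AnalysisConfig(rng_seed=5))
        # under the complete null the q<=alpha fraction stays within
        # binomial noise of alpha
        assert sel.table["selected"].mean() <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 400)

    def test_permutation_method_calibrated_under_null(self):
        m, design = _paired_study(np.zeros((150, 4)), noise_sd=0.5, n_subjects=5, seed=6)
        cfg = AnalysisConfig(rng_seed=7, tc_permutations=200)
        sel = timecourse_select(m, design, cfg, method="permutation")
        assert (sel.table["p"] < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 150)

    def test_unpaired_design_rejected(self):
        effects = np.zeros((3, 4))
        m, design = _paired_study(effects, noise_sd=0.1, n_subjects=3, seed=8)
        broken = design.table.drop(0)  # subject r0 now lacks T0
        with pytest.raises(ValidationError):
            timecourse_select(
                ExpressionMatrix(values=m.values[broken["sample_id"]], scale="log2"),
                SampleDesign(table=broken),
                AnalysisConfig(),
            )


class TestDifferentialExpression:
    def test_table_has_full_contract_columns(self, small_log2_matrix, small_design):
        de = differential_expression(small_log2_matrix, small_design, "T3", "T0")
        assert list(de.columns) == ["mean_a", "mean_b", "log2fc", "signed_fc", "p", "q"]
        assert de.attrs["contrast"] == "T3_vs_T0"
        assert ((de["q"] >= de["p"] - 1e-12) & (de["q"] <= 1)).all()

    def test_paired_and_unpaired_agree_on_fold_change(self, small_log2_matrix, small_design):
        un = differential_expression(small_log2_matrix, small_design, "T3", "T0")
        pa = differential_expression(small_log2_matrix, small_design, "T3", "T0", paired=True)
        np.testing.assert_allclose(un["log2fc"], pa["log2fc"])
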