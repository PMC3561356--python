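"""Gene- and pathway-level cross-species concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from colicord.concordance import (
    classify_concordance,
    join_orthologs,
    pathway_concordance,
    pathway_fold_changes,
    spearman,
    translate_to_human,
)
from colicord.io_core import (
    AnalysisConfig,
    GeneSet,
    GeneSetCollection,
    OrthologMap,
    ValidationError,
)


def midrank_pearson(x, y):
    """Brute-force Spearman: Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).p == 0.0
        assert spearman([1, 2, 3, 4], [-1, -2, -3, -4]).rho == pytest.approx(-1.0)

    def test_tied_hand_example(self):
        res = spearman([1, 2, 2, 3], [1, 3, 2, 4])
        assert res.rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        assert spearman([1, 1, 1], [1, 2, 3]).undefined

    def test_short_input_flagged_undefined(self):
        assert spearman([1, 2], [2, 1]).undefined

    def test_matches_midrank_oracle_on_random_tied_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float) + 0.1 * rng.normal(size=n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y).rho == pytest.approx(midrank_pearson(x, y), abs=1e-12)


def _de_table(d):
    """dict gene -> (log2fc, p) to a contrast-table DataFrame."""
    df = pd.DataFrame(
        {"log2fc": {g: v[0] for g, v in d.items()}, "p": {g: v[1] for g, v in d.items()}}
    )
    df.index.name = "gene"
    return df


class TestJoinOrthologs:
    def test_empty_map_gives_empty_table(self):
        joined = join_orthologs(
            _de_table({"r1": (1, 0.1)}), _de_table({"h1": (1, 0.1)}), OrthologMap(pairs=())
        )
        assert joined.empty

    def test_pair_missing_from_one_side_dropped(self):
        omap = OrthologMap(pairs=(("r1", "h1"), ("r2", "h2")))
        joined = join_orthologs(
            _de_table({"r1": (1, 0.1), "r2": (2, 0.1)}),
            _de_table({"h1": (1, 0.1)}),
            omap,
        )
        assert list(joined["rat_gene"]) == ["r1"]
        assert joined.attrs["join_report"]["n_dropped"] == 1

    def test_full_join_aligns_columns(self):
        omap = OrthologMap(pairs=(("r1", "h1"), ("r2", "h2"), ("r3", "h3")))
        rat = _de_table({"r1": (1.0, 0.1), "r2": (2.0, 0.2), "r3": (3.0, 0.3)})
        human = _de_table({"h1": (-1.0, 0.4), "h2": (-2.0, 0.5), "h3": (-3.0, 0.6)})
        joined = join_orthologs(rat, human, omap)
        assert len(joined) == 3
        np.testing.assert_allclose(joined["rat_log2fc"], [1, 2, 3])
        np.testing.assert_allclose(joined["human_log2fc"], [-1, -2, -3])


class TestClassifyConcordance:
    CFG = AnalysisConfig()

    def _classify(self, rows):
        joined = pd.DataFrame(
            rows,
            columns=["rat_gene", "human_gene", "rat_log2fc", "rat_p", "human_log2fc", "human_p"],
        )
        return classify_concordance(joined, self.CFG)

    def test_rule_examples(self):
        table, _ = self._classify(
            [
                ("r1", "h1", 1.5, 0.01, 2.0, 0.02),  # both up, both significant
                ("r2", "h2", -2.21, 0.0005, -1.2, 0.01),  # both down
                ("r3", "h3", 1.5, 0.01, -1.5, 0.01),  # opposite signs
                ("r4", "h4", 1.5, 0.2, 2.0, 0.01),  # rat not significant
                ("r5", "h5", 0.9, 0.01, 2.0, 0.01),  # rat below fold threshold
            ]
        )
        assert list(table["status"]) == [
            "concordant_up",
            "concordant_down",
            "nonconcordant",
            "nonconcordant",
            "nonconcordant",
        ]

    def test_counts_partition_pairs(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"r{i}", f"h{i}", rng.normal(0, 2), rng.uniform(0, 0.2), rng.normal(0, 2), rng.uniform(0, 0.2))
            for i in range(200)
        ]
        _, summary = self._classify(rows)
        assert (
            summary.n_concordant_up + summary.n_concordant_down + summary.n_nonconcordant
            == summary.n_pairs
            == 200
        )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"r{i}", f"h{i}", rng.normal(0, 2), rng.uniform(0, 0.2), rng.normal(0, 2), rng.uniform(0, 0.2))
            for i in range(300)
        ]
        joined = pd.DataFrame(
            rows,
            columns=["rat_gene", "human_gene", "rat_log2fc", "rat_p", "human_log2fc", "human_p"],
        )
        base = classify_concordance(joined, AnalysisConfig())[1]
        stricter_fc = classify_concordance(joined, AnalysisConfig(lfc_threshold=2.0))[1]
        stricter_p = classify_concordance(joined, AnalysisConfig(p_threshold=0.01))[1]
        for strict in (stricter_fc, stricter_p):
            assert (
                strict.n_concordant_up + strict.n_concordant_down
                <= base.n_concordant_up + base.n_concordant_down
            )

    def test_symmetry_under_species_swap(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"r{i}", f"h{i}", rng.normal(0, 2), rng.uniform(0, 0.1), rng.normal(0, 2), rng.uniform(0, 0.1))
            for i in range(100)
        ]
        joined = pd.DataFrame(
            rows,
            columns=["rat_gene", "human_gene", "rat_log2fc", "rat_p", "human_log2fc", "human_p"],
        )
        swapped = joined.rename(
            columns={
                "rat_log2fc": "human_log2fc",
                "human_log2fc": "rat_log2fc",
                "rat_p": "human_p",
                "human_p": "rat_p",
            }
        )
        t1, s1 = classify_concordance(joined, self.CFG)
        t2, s2 = classify_concordance(swapped, self.CFG)
        assert s1.rho == pytest.approx(s2.rho, abs=1e-12)
        assert list(t1["status"]) == list(t2["status"])

    def test_too_few_pairs_rho_undefined_statuses_kept(self):
        table, summary = self._classify([("r1", "h1", 2.0, 0.01, 2.0, 0.01)])
        assert summary.rho_undefined
        assert list(table["status"]) == ["concordant_up"]


class TestPathwayLevel:
    CFG = AnalysisConfig()

    def test_uniform_members_give_that_fold_change(self):
        de = _de_table({f"g{i}": (0.7, 0.01) for i in range(5)})
        sets = GeneSetCollection(
            sets={"p": GeneSet("p", "", tuple(f"g{i}" for i in range(5)))}
        )
        pfc = pathway_fold_changes(de, sets, self.CFG)
        assert pfc.loc["p", "mean_log2fc"] == pytest.approx(0.7)

    def test_mean_is_arithmetic_on_log2_scale(self):
        vals = [1.0, -0.5, 0.5, 1.0, 0.0]
        de = _de_table({f"g{i}": (v, 0.01) for i, v in enumerate(vals)})
        sets = GeneSetCollection(
            sets={"p": GeneSet("p", "", tuple(f"g{i}" for i in range(5)))}
        )
        pfc = pathway_fold_changes(de, sets, self.CFG)
        assert pfc.loc["p", "mean_log2fc"] == pytest.approx(0.4)

    def test_small_pathway_excluded(self):
        de = _de_table({f"g{i}": (1.0, 0.01) for i in range(4)})
        sets = GeneSetCollection(
            sets={"p": GeneSet("p", "", ("g0", "g1", "g2", "g3", "absent"))}
        )
        pfc = pathway_fold_changes(de, sets, self.CFG)  # only 4 members present
        assert bool(pfc.loc["p", "excluded"])
        assert np.isnan(pfc.loc["p", "mean_log2fc"])

    def test_identical_tables_fully_concordant(self):
        de = _de_table({f"g{i}": (float(i - 10) / 3, 0.01) for i in range(30)})
        sets = GeneSetCollection(
            sets={
                f"p{j}": GeneSet(f"p{j}", "", tuple(f"g{i}" for i in range(j, j + 7)))
                for j in range(0, 21, 3)
            }
        )
        pfc = pathway_fold_changes(de, sets, self.CFG)
        pc = pathway_concordance(pfc, pfc)
        assert pc.rho.rho == pytest.approx(1.0)
        assert pc.n_nonconcordant == 0

    def test_opposite_sign_pathway_nonconcordant(self):
        rat = pd.DataFrame(
            {"n_mapped_genes": [6, 6, 6], "mean_log2fc": [0.4, 1.0, -1.0], "excluded": False},
            index=pd.Index(["a", "b", "c"], name="pathway"),
        )
        human = rat.copy()
        human["mean_log2fc"] = [-0.2, 0.8, -0.6]
        pc = pathway_concordance(rat, human)
        assert not pc.table.loc["a", "concordant"]
        assert pc.table.loc["b", "concordant"] and pc.table.loc["c", "concordant"]

    def test_empty_comparison_has_undefined_rho(self):
        empty = pd.DataFrame(columns=["n_mapped_genes", "mean_log2fc", "excluded"])
        pc = pathway_concordance(empty, empty)
        assert pc.rho.undefined and pc.table.empty

    def test_translate_to_human_reindexes(self):
        de = _de_table({"r1": (1.0, 0.1), "r2": (2.0, 0.2), "r9": (3.0, 0.3)})
        omap = OrthologMap(pairs=(("r1", "h1"), ("r2", "h2")))
        out = translate_to_human(de, omap)
        assert list(out.index) == ["h1", "h2"]
        np.testing.assert_allclose(out["log2fc"], [1.0, 2.0])


class TestSyntheticRecovery:
    def test_fully_concordant_study_recovers_high_rho(self):
        from colicord.diffexpr import differential_expression
        from colicord.preprocess import log2_transform, quantile_normalize
        from colicord.synthetic_data import SimConfig, simulate_experiment

        study = simulate_experiment(
            SimConfig(
                n_genes=500,
                fraction_concordant=1.0,
                fraction_regulated=0.3,
                effect_sd=0.0,
                rng_seed=21,
            )
        )
        rat = log2_transform(quantile_normalize(study.rat_expr))
        hum = log2_transform(quantile_normalize(study.human_expr))
        cfg = AnalysisConfig()
        statuses = {}
        for tc in ("T3", "T7", "T12"):
            de_r = differential_expression(rat, study.rat_design, tc, "T0")
            de_h = differential_expression(hum, study.human_design, "UC", "N")
            joined = join_orthologs(de_r, de_h, study.orthologs)
            table, summary = classify_concordance(joined, cfg)
            statuses[tc] = table.set_index("rat_gene")["status"]
        pairs = study.truth.pairs
        regulated = pairs[pairs["label"].str.startswith("concordant")]
        recovered = sum(
            statuses[row["designated_condition"]][row["rat_gene"]] == row["label"]
            for _, row in regulated.iterrows()
        )
        assert recovered / len(regulated) > 0.9
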