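"""ΔΔCt chain, fold-suppression ratios, and test selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reporterscreen import (
    CtSimConfig,
    InsufficientDataError,
    RelativeExpressionModel,
    aggregate_technical,
    delta_ct,
    fold_change,
    run_comparison,
    select_test,
    significance_stars,
    simulate_ct_experiment,
    suppression_ratio,
)


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["experiment_id", "condition", "gene", "ct"])


class TestAggregateTechnical:
    def test_mean_of_technical_replicates(self):
        df = ct_frame([("E1", "M0", "IL-6", 24.9), ("E1", "M0", "IL-6", 25.1)])
        out = aggregate_technical(df)
        assert out["ct_mean"].iloc[0] == pytest.approx(25.0)
        assert out["n_technical"].iloc[0] == 2

    def test_single_value_accepted_with_warning(self, caplog):
        out = aggregate_technical(ct_frame([("E1", "M0", "IL-6", 25.0)]))
        assert out["ct_mean"].iloc[0] == 25.0
        assert any("no technical replication" in r.message for r in caplog.records)

    def test_ct_out_of_plausible_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            aggregate_technical(ct_frame([("E1", "M0", "IL-6", 46.0)]))

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            aggregate_technical(ct_frame([]))


class TestDeltaCt:
    def _means(self):
        return aggregate_technical(
            ct_frame(
                [
                    ("E1", "M0", "IL-6", 25.0),
                    ("E1", "M0", "RPL37A", 20.0),
                ]
            )
        )

    def test_subtracts_reference_within_sample(self):
        out = delta_ct(self._means(), "RPL37A")
        il6 = out[out.gene == "IL-6"]["delta_ct"].iloc[0]
        assert il6 == pytest.approx(5.0)

    def test_reference_gene_delta_is_exactly_zero(self):
        out = delta_ct(self._means(), "RPL37A")
        assert (out[out.gene == "RPL37A"]["delta_ct"] == 0.0).all()

    def test_missing_reference_in_a_condition_fails(self):
        means = aggregate_technical(
            ct_frame([("E1", "M1_DMSO", "IL-6", 25.0), ("E1", "M0", "RPL37A", 20.0)])
        )
        with pytest.raises(InsufficientDataError, match="RPL37A"):
            delta_ct(means, "RPL37A")


class TestFoldChange:
    def test_worked_example(self):
        # test: Ct(gene)=25, Ct(ref)=20 -> dCt 5; M0: 28-20 -> 8; ddCt -3 -> fold 8
        fc = fold_change([5.0], [8.0], gene="IL-6", condition="M1")
        assert fc.folds[0] == pytest.approx(8.0)

    def test_identical_groups_center_on_one(self):
        fc = fold_change([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert fc.mean == pytest.approx(1.0) and fc.sd == 0.0

    def test_noiseless_planted_fold_recovered_exactly(self):
        cfg = CtSimConfig(
            genes=("IL-6",),
            conditions=("M0", "M1_DMSO"),
            true_folds={("IL-6", "M1_DMSO"): 4.0},
            sigma_technical=0.0,
        )
        table, _ = simulate_ct_experiment(cfg)
        res = RelativeExpressionModel(table).fit()
        assert res.fold("IL-6", "M1_DMSO").mean == pytest.approx(4.0, abs=1e-12)
        assert res.fold("IL-6", "M0").mean == pytest.approx(1.0, abs=1e-12)

    def test_reference_gene_shift_invariance(self):
        # adding a constant to every Ct of every gene leaves folds unchanged
        cfg = CtSimConfig(
            genes=("IL-6",),
            conditions=("M0", "M1_DMSO"),
            true_folds={("IL-6", "M1_DMSO"): 37.0},
            sigma_technical=0.2,
            seed=9,
        )
        table, _ = simulate_ct_experiment(cfg)
        base = RelativeExpressionModel(table).fit().fold("IL-6", "M1_DMSO").folds
        shifted = table.copy()
        shifted["ct"] += 2.5
        after = RelativeExpressionModel(shifted).fit().fold("IL-6", "M1_DMSO").folds
        np.testing.assert_allclose(after, base, rtol=1e-12)

    def test_gene_shift_doubles_every_fold(self):
        cfg = CtSimConfig(
            genes=("IL-6",),
            conditions=("M0", "M1_DMSO"),
            true_folds={("IL-6", "M1_DMSO"): 5.0},
            sigma_technical=0.2,
            seed=10,
        )
        table, _ = simulate_ct_experiment(cfg)
        base = RelativeExpressionModel(table).fit().fold("IL-6", "M1_DMSO").folds
        shifted = table.copy()
        mask = (shifted.gene == "IL-6") & (shifted.condition == "M1_DMSO")
        shifted.loc[mask, "ct"] -= 1.0
        after = RelativeExpressionModel(shifted).fit().fold("IL-6", "M1_DMSO").folds
        np.testing.assert_allclose(after, 2.0 * base, rtol=1e-12)

    def test_estimator_agrees_with_direct_simulation_oracle(self, rng):
        """Pipeline mean-fold estimates match an oracle that simulates the
        same generative model and estimator without the pipeline machinery."""
        F, sigma, n_bio, n_tech, n_rep = 8.0, 0.2, 3, 2, 200

        def oracle_once():
            dct = lambda: np.array(
                [
                    rng.normal(0, sigma, n_tech).mean() - rng.normal(0, sigma, n_tech).mean()
                    for _ in range(n_bio)
                ]
            )
            test = -np.log2(F) + dct()
            ctrl = dct()
            return float(np.mean(2.0 ** -(test - ctrl.mean())))

        oracle = np.array([oracle_once() for _ in range(n_rep)])
        pipeline = []
        cfg = CtSimConfig(
            genes=("G",),
            conditions=("M0", "T"),
            true_folds={("G", "T"): F},
            sigma_technical=sigma,
            n_technical=n_tech,
            n_biological=n_bio,
        )
        for i in range(n_rep):
            table, _ = simulate_ct_experiment(cfg, seed=50_000 + i)
            pipeline.append(RelativeExpressionModel(table).fit().fold("G", "T").mean)
        pipeline = np.array(pipeline)
        # same location and spread within Monte-Carlo error
        se = np.sqrt(oracle.var(ddof=1) / n_rep + pipeline.var(ddof=1) / n_rep)
        assert abs(oracle.mean() - pipeline.mean()) < 3 * se
        assert stats.ks_2samp(oracle, pipeline).pvalue > 0.01


class TestSuppressionRatio:
    @pytest.mark.parametrize(
        "vehicle,compound,expected",
        [
            (7617.0, 68.7, 110.87),   # strong suppression
            (7617.0, 58.1, 131.10),
            (114.9, 7.6, 15.12),
            (12432.0, 1364.0, 9.11),
            (237.2, 26.6, 8.92),
        ],
    )
    def test_table_worked_examples(self, vehicle, compound, expected):
        assert suppression_ratio(vehicle, compound) == pytest.approx(expected, abs=0.005)

    def test_equal_folds_give_unity(self):
        assert suppression_ratio(5.0, 5.0) == 1.0

    def test_inverted_ratio_reads_as_activation(self):
        # vehicle 396.0 vs compound 927.1: the compound more than doubled it
        assert suppression_ratio(927.1, 396.0) == pytest.approx(2.34, abs=0.005)

    def test_ratio_chain_consistency(self):
        a, b, c = 500.0, 50.0, 10.0
        assert suppression_ratio(a, b) * suppression_ratio(b, c) == pytest.approx(
            suppression_ratio(a, c)
        )

    def test_zero_compound_fold_rejected(self):
        with pytest.raises(ZeroDivisionError):
            suppression_ratio(10.0, 0.0)


class TestSelectTest:
    def _normal(self, rng, mu, sd, n=20):
        return rng.normal(mu, sd, n)

    def test_two_normal_equal_sd_groups_use_plain_t(self, rng):
        groups = {"a": self._normal(rng, 10, 1), "b": self._normal(rng, 12, 1)}
        spec = select_test(groups)
        assert spec.test == "t_test" and spec.correction == "none"

    def test_two_normal_unequal_sd_groups_use_welch(self, rng):
        groups = {"a": self._normal(rng, 10, 1, 30), "b": self._normal(rng, 12, 15, 30)}
        spec = select_test(groups)
        assert spec.test == "welch_t_test"

    def test_three_normal_unequal_sd_groups_use_welch_anova(self, rng):
        groups = {
            "a": self._normal(rng, 10, 1, 30),
            "b": self._normal(rng, 12, 14, 30),
            "c": self._normal(rng, 11, 1, 30),
        }
        spec = select_test(groups)
        assert spec.test == "welch_anova" and spec.correction == "dunnett_t3"

    def test_three_normal_equal_sd_groups_use_anova_dunnett(self, rng):
        groups = {g: self._normal(rng, mu, 1, 30) for g, mu in [("a", 10), ("b", 12), ("c", 11)]}
        spec = select_test(groups)
        assert spec.test == "anova" and spec.correction == "dunnett"

    def test_any_non_normal_group_routes_to_rank_tests(self, rng):
        heavy = np.concatenate([self._normal(rng, 10, 1, 25), [60.0, 80.0, 120.0]])
        groups = {"a": self._normal(rng, 10, 1, 28), "b": heavy, "c": self._normal(rng, 11, 1, 28)}
        spec = select_test(groups)
        assert spec.test == "kruskal_wallis" and spec.correction == "dunn_holm"
        two = select_test({"a": groups["a"], "b": heavy})
        assert two.test == "mann_whitney"

    def test_too_few_replicates_for_normality(self):
        with pytest.raises(InsufficientDataError, match="insufficient replicates"):
            select_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestRunComparison:
    def test_identical_groups_degenerate_p_one(self):
        groups = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}
        with pytest.warns(UserWarning, match="degenerate"):
            (res,) = run_comparison(groups)
        assert res.p_value == 1.0 and res.stars == ""

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, ""), (0.03, "*"), (0.004, "**"), (0.0005, "***"), (5e-5, "****")],
    )
    def test_star_banding(self, p, stars):
        assert significance_stars(p) == stars

    def test_plain_t_test_matches_scipy(self, rng):
        a, b = rng.normal(10, 1, 10), rng.normal(12, 1, 10)
        (res,) = run_comparison({"a": a, "b": b})
        expected = stats.ttest_ind(b, a, equal_var=res.test == "t_test").pvalue
        assert res.p_value == pytest.approx(float(expected))

    def test_dunnett_contrasts_against_control(self, rng):
        groups = {
            "ctrl": rng.normal(10, 1, 15),
            "g1": rng.normal(10.2, 1, 15),
            "g2": rng.normal(14, 1, 15),
        }
        spec = select_test(groups)
        results = run_comparison(groups, spec, control="ctrl")
        by_group = {r.groups[1]: r for r in results}
        assert set(by_group) == {"g1", "g2"}
        assert by_group["g2"].p_value < 0.001 < by_group["g1"].p_value

    def test_dunn_two_group_p_equals_kruskal_chi2(self, rng):
        """For two tie-free groups Dunn's z² equals the Kruskal–Wallis H, so
        the p-values must coincide (independent scipy cross-check)."""
        from reporterscreen.expression import _dunn_posthoc

        a = rng.normal(0, 1, 12)
        b = rng.normal(1.2, 1, 9)
        dunn = _dunn_posthoc({"ctrl": a, "b": b}, "ctrl")
        h = stats.kruskal(a, b).statistic
        assert dunn["b"] == pytest.approx(float(stats.chi2.sf(h, 1)), rel=1e-9)

    def test_kruskal_dunn_family_reports_omnibus(self, rng):
        heavy = np.concatenate([rng.normal(10, 1, 25), [60.0, 90.0, 150.0]])
        groups = {"ctrl": rng.normal(10, 1, 28), "b": heavy, "c": rng.normal(13, 1, 28)}
        spec = select_test(groups)
        results = run_comparison(groups, spec, control="ctrl")
        assert all(r.test == "kruskal_wallis" and r.omnibus_p is not None for r in results)
        assert all(0.0 <= r.p_value <= 1.0 for r in results)


def test_model_summary_prints_fold_table():
    cfg = CtSimConfig(
        genes=("IL-6", "CCL2"),
        conditions=("M0", "M1_DMSO"),
        true_folds={("IL-6", "M1_DMSO"): 6000.0, ("CCL2", "M1_DMSO"): 150.0},
        sigma_technical=0.0,
    )
    table, _ = simulate_ct_experiment(cfg)
    res = RelativeExpressionModel(table).fit()
    text = res.summary()
    assert "IL-6" in text and "6000.00" in text
    assert res.suppression("IL-6", "M1_DMSO", "M1_DMSO") == 1.0
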