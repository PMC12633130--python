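"""Predictor chain: stage structure, balanced weights, grid search,
rollouts, and baselines."""

import numpy as np
import pandas as pd
import pytest
from sklearn.utils.class_weight import compute_sample_weight

import hntwin as h
from hntwin import chain as cm
from hntwin.schema import Cohort


class TestChainStructure:
    def test_relapse_conditions_on_every_other_feature(self, schema,
                                                       chain_spec):
        parents = chain_spec.parents_of("relapse_yr3")
        everything_else = [n for n in schema.names if n != "relapse_yr3"]
        assert sorted(parents) == sorted(everything_else)

    def test_first_action_conditions_on_ptf_only(self, schema, chain_spec):
        assert chain_spec.parents_of("definitive") == \
            schema.group_names("PTF")

    def test_rt_dose_is_regression_node(self, fitted_chain):
        assert fitted_chain.nodes["rt_dose"].task == "regression"
        assert fitted_chain.nodes["radio/chemo"].task == "multiclass"
        assert fitted_chain.nodes["definitive"].task == "binary"

    def test_node_count_is_schema_minus_ptf(self, schema, fitted_chain):
        assert len(fitted_chain.nodes) == len(schema) - \
            len(schema.group("PTF"))

    def test_acyclic_parents_precede_targets(self, chain_spec):
        seen = set(chain_spec.stages[0])
        for stage in chain_spec.stages[1:]:
            for target in stage:
                assert set(chain_spec.parents_of(target)) <= seen
            seen |= set(stage)


class TestBalancedWeights:
    def test_ninety_ten_ratio_is_nine(self):
        y = np.array([0] * 90 + [1] * 10)
        w = compute_sample_weight("balanced", y)
        assert np.isclose(w[y == 1][0] / w[y == 0][0], 9.0)

    def test_weighted_class_totals_equal(self):
        rng = np.random.default_rng(0)
        y = rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1], size=500)
        w = compute_sample_weight("balanced", y)
        totals = [w[y == k].sum() for k in np.unique(y)]
        assert np.allclose(totals, totals[0], atol=1e-9)


class TestFitNode:
    def test_single_grid_point_equals_direct_fit(self, schema, chain_spec,
                                                 train_test, fitted_chain):
        train, test = train_test
        # refit one node with the same single-point grid: identical output
        encoder = fitted_chain.encoder
        node = cm.fit_node("definitive", chain_spec.parents_of("definitive"),
                           train, schema, encoder, cm.fast_grid(), seed=1)
        X = encoder.tree_matrix(test.values, node.parents)
        a = node.model.predict(X)
        b = fitted_chain.nodes["definitive"].model.predict(X)
        assert (a == b).all()

    def test_cv_selects_signal_over_noise(self, schema, chain_spec,
                                          train_test, baselines):
        """Cross-validated macro-F1 of the grid winner beats the random
        baseline on the planted relapse signal."""
        train, _ = train_test
        grid = cm.GridConfig(
            boosted={"learning_rate": [0.1], "max_depth": [4, 6],
                     "min_child_weight": [5], "n_estimators": [100],
                     "colsample_bytree": [0.5]},
            mlp=cm.fast_grid().mlp)
        encoder = cm.ChainEncoder(schema).fit(train)
        node = cm.fit_node("relapse_yr3",
                           chain_spec.parents_of("relapse_yr3"),
                           train, schema, encoder, grid, seed=1)
        # random-guess macro-F1 for an imbalanced binary target is ~0.5
        assert node.cv_score > 0.5

    def test_single_observed_class_gives_constant_predictor(self, schema,
                                                            chain_spec):
        df = pd.DataFrame({"age": np.linspace(50, 70, 30),
                           "definitive": ["no"] * 30})
        train = Cohort(df)
        encoder = cm.ChainEncoder(schema).fit(train)
        node = cm.fit_node("definitive", ["age"], train, schema, encoder,
                           cm.fast_grid(), seed=0)
        pred = node.model.predict(np.array([[55.0], [65.0]]))
        assert (np.asarray(pred) == 0).all()  # code of 'no'


class TestDeterminism:
    def test_refit_same_seed_identical_predictions(self, schema, chain_spec,
                                                   train_test, fitted_chain):
        train, test = train_test
        again = cm.fit_chain(train, chain_spec, schema, cm.fast_grid(),
                             seed=1)
        probe = Cohort(test.values.iloc[:25])
        for target in ("relapse_yr3", "rt_dose", "mdasi_endrt_drymouth"):
            a = fitted_chain.predict_feature(target, probe)
            b = again.predict_feature(target, probe)
            if fitted_chain.nodes[target].task == "regression":
                np.testing.assert_allclose(a.astype(float),
                                           b.astype(float))
            else:
                assert (a == b).all()


class TestRollout:
    @pytest.fixture
    def ptf_row(self, schema, train_test):
        train, _ = train_test
        return train.subset_columns(schema.group_names("PTF")).values.iloc[0]

    def test_no_treatment_leaves_rt_fields_missing(self, fitted_chain,
                                                   ptf_row):
        res = fitted_chain.rollout(
            ptf_row, {"definitive": "no", "induction": "no",
                      "radio_chemo": "no"})
        for col in ("rt_type", "rt_dose", "rt_fraction", "ENE", "Margin"):
            assert pd.isna(res.record[col])
        assert not pd.isna(res.record["mdasi_endrt_fatigue"])

    def test_expected_mode_deterministic(self, fitted_chain, ptf_row):
        plan = {"definitive": "yes", "induction": "no",
                "radio_chemo": "yes"}
        a = fitted_chain.rollout(ptf_row, plan, mode="expected")
        b = fitted_chain.rollout(ptf_row, plan, mode="expected")
        pd.testing.assert_series_equal(a.record, b.record)
        assert a.relapse_prob == b.relapse_prob

    def test_unknown_action_label_error(self, fitted_chain, ptf_row):
        with pytest.raises(ValueError, match="maybe"):
            fitted_chain.rollout(ptf_row, {"definitive": "maybe",
                                           "induction": "no",
                                           "radio_chemo": "no"})

    def test_sampled_burden_higher_under_aggressive_plan(self, fitted_chain,
                                                         ptf_row):
        aggressive = {"definitive": "yes", "induction": "yes",
                      "radio_chemo": "yes-with-concurrent-chemotherapy"}
        conservative = {"definitive": "no", "induction": "no",
                        "radio_chemo": "no"}
        cols = [f"mdasi_endrt_{s}" for s in
                ("fatigue", "drymouth", "swallow", "taste")]

        def mean_burden(plan):
            vals = []
            for i in range(60):
                rec = fitted_chain.rollout(ptf_row, plan, mode="sampled",
                                           seed=i).record
                vals.append(np.mean([float(rec[c]) for c in cols]))
            return float(np.mean(vals))

        assert mean_burden(aggressive) > mean_burden(conservative)

    def test_sampled_values_respect_bounds(self, schema, fitted_chain,
                                           ptf_row):
        for i in range(10):
            rec = fitted_chain.rollout(
                ptf_row, {"definitive": "no", "induction": "no",
                          "radio_chemo": "yes"}, mode="sampled",
                seed=100 + i).record
            for s in ("fatigue", "drymouth"):
                v = float(rec[f"mdasi_endrt_{s}"])
                assert 0.0 <= v <= 10.0


class TestBaselines:
    def test_median_mean_predictor_is_constant(self, schema, chain_spec,
                                               train_test, baselines):
        _, test = train_test
        preds = baselines["median_mean"].predict_feature("radio/chemo", test)
        assert len(set(preds)) == 1
        mean_pred = baselines["median_mean"].predict_feature("rt_dose", test)
        assert len(set(np.asarray(mean_pred, float))) == 1

    def test_random_baseline_balanced_binary_macro_f1_half(self):
        """Brute-force expectation: for a balanced binary target, random
        guessing proportional to training frequencies scores macro-F1 0.5."""
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(300):
            y = rng.choice(["a", "b"], size=200)
            pred = rng.choice(["a", "b"], size=200)
            scores.append(h.macro_f1(y, pred, ["a", "b"]))
        assert abs(np.mean(scores) - 0.5) < 0.01

    def test_random_baseline_reproducible_and_frequency_matched(
            self, schema, train_test, baselines, chain_spec):
        train, test = train_test
        a = baselines["random"].predict_feature("definitive", test)
        b = baselines["random"].predict_feature("definitive", test)
        assert (a == b).all()
        big = Cohort(pd.concat([test.values] * 40))
        draws = pd.Series(
            baselines["random"].predict_feature("definitive", big))
        train_freq = (train.observed("definitive") == "yes").mean()
        assert abs((draws == "yes").mean() - train_freq) < 0.02


class TestMlpBaseline:
    def test_mlp_fits_selected_nodes(self, schema, train_test):
        train, test = train_test
        spec = cm.ChainSpec([schema.group_names("PTF"), ["definitive"],
                             ["mdasi_endrt_fatigue"]])
        mlp = cm.baseline_mlp(train, spec, schema, cm.fast_grid(), seed=0)
        preds = mlp.predict_feature("definitive", test)
        assert set(preds) <= {"no", "yes"}
        reg = mlp.predict_feature("mdasi_endrt_fatigue", test)
        assert np.isfinite(reg.astype(float)).all()


def test_chain_checkpoint_round_trip(fitted_chain, train_test, tmp_path):
    _, test = train_test
    path = tmp_path / "chain.ckpt"
    fitted_chain.save(path)
    back = cm.TwinChain.load(path)
    probe = Cohort(test.values.iloc[:10])
    a = fitted_chain.predict_feature("relapse_yr3", probe)
    b = back.predict_feature("relapse_yr3", probe)
    assert (a == b).all()
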