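"""Synthetic-cohort generator: parameter defaults, marginal recovery,
structural missingness, determinism, and the planted signal."""

import numpy as np
import pandas as pd
import pytest

import hntwin as h
from hntwin.generator import (
    CC,
    SEQUENCE_COUNTS,
    SEQUENCE_PATTERNS,
    _sequence_stats,
    corrected_location,
)


def implied_action_marginals(params):
    """Action marginals implied by the sequence distribution (the sampling
    distribution for the three action variables)."""
    out = {}
    for i, name in enumerate(("definitive", "induction", "radio/chemo")):
        m: dict[str, float] = {}
        for pattern, p in params.sequence_probs.items():
            m[pattern[i]] = m.get(pattern[i], 0.0) + p
        out[name] = m
    return out


class TestDefaultParams:
    def test_age_marginal_is_printed_moments(self, params):
        m = params.marginals["age"]
        assert (m.mean, m.sd) == (60.49, 8.92)

    def test_sequence_probs_normalized_over_651(self, params):
        assert abs(sum(params.sequence_probs.values()) - 1.0) < 1e-12
        assert params.sequence_probs[("no", "no", CC)] == 398 / 651

    def test_category_probs_are_counts_over_total(self, params):
        probs = params.marginals["gender"].probs
        assert probs["Male"] == 616 / 676
        assert abs(sum(probs.values()) - 1.0) < 1e-12

    def test_relapse_labeling_matches_outcome_table(self, params):
        miss = params.missingness
        assert miss.relapse_labeled_fraction == 188 / 676
        assert miss.relapse_p_true_given_labeled == 35 / 188


class TestSampleTreatmentSequence:
    def test_pattern_decodes_to_action_labels(self, params):
        assert ("yes", "no", "yes") in params.sequence_probs  # DS -> n/a -> RT
        rng = np.random.default_rng(0)
        for _ in range(20):
            ds, ic, rc = h.sample_treatment_sequence(params, rng)
            assert ds in ("no", "yes") and ic in ("no", "yes")
            assert rc in ("no", "yes", CC)

    def test_empirical_frequencies_match_probs(self, params):
        rng = np.random.default_rng(11)
        n = 100_000
        counts: dict = {}
        for _ in range(n):
            pat = h.sample_treatment_sequence(params, rng)
            counts[pat] = counts.get(pat, 0) + 1
        for pattern, p in params.sequence_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(pattern, 0) / n - p) < 3 * se + 1e-9

    def test_one_hot_distribution_is_degenerate(self, params):
        from dataclasses import replace
        probs = {p: 0.0 for p in params.sequence_probs}
        probs[("yes", "no", "no")] = 1.0
        degenerate = replace(params, sequence_probs=probs)
        rng = np.random.default_rng(0)
        draws = {h.sample_treatment_sequence(degenerate, rng)
                 for _ in range(50)}
        assert draws == {("yes", "no", "no")}


class TestGenerateCohort:
    def test_empty_and_negative(self, schema, params):
        empty, truth = h.generate_cohort(params, 0, seed=0, schema=schema)
        assert len(empty) == 0 and len(truth) == 0
        assert empty.columns == schema.names
        with pytest.raises(ValueError):
            h.generate_cohort(params, -1, seed=0, schema=schema)

    def test_same_seed_bit_identical(self, schema, params):
        a, ta = h.generate_cohort(params, 250, seed=9, schema=schema)
        b, tb = h.generate_cohort(params, 250, seed=9, schema=schema)
        assert a.equals(b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_cohort_passes_validation(self, schema, cohort676):
        cohort, _ = cohort676
        assert h.validate(cohort, schema).ok

    def test_structural_missingness_exact(self, schema, params):
        cohort, _ = h.generate_cohort(params, 10_000, seed=42, schema=schema)
        surgical = cohort["definitive"] == "yes"
        assert (cohort["ENE"].notna() == surgical).all()
        assert (cohort["Margin"].notna() == surgical).all()
        rt = cohort["radio/chemo"] != "no"
        assert (cohort["rt_type"].notna() == rt).all()
        assert (cohort["rt_dose"].notna() == rt).all()

    def test_truth_records_pattern_and_probabilities(self, cohort676):
        cohort, truth = cohort676
        assert ((truth["relapse_prob"] >= 0) & (truth["relapse_prob"] <= 1)).all()
        # truth pattern string agrees with the action columns
        joined = (cohort["definitive"] + " / " + cohort["induction"]
                  + " / " + cohort["radio/chemo"])
        assert (joined == truth["pattern"]).all()


@pytest.fixture(scope="module")
def big(schema, params):
    cohort, _ = h.generate_cohort(params, 40_000, seed=42, schema=schema)
    return cohort


class TestMarginalRecovery:
    """Large-sample recovery of the printed marginals (n = 40,000)."""

    def test_numerical_means_within_four_se(self, schema, big):
        for spec in schema:
            if spec.is_categorical:
                continue
            obs = big.observed(spec.name).astype(float)
            tol = 4 * spec.sd / np.sqrt(len(obs))
            assert abs(obs.mean() - spec.mean) < tol, spec.name

    def test_categorical_probabilities_within_002(self, schema, params, big):
        implied = implied_action_marginals(params)
        for spec in schema:
            if not spec.is_categorical:
                continue
            obs = big.observed(spec.name)
            emp = obs.value_counts(normalize=True)
            probs = implied.get(spec.name, params.marginals[spec.name].probs)
            for cat, p in probs.items():
                assert abs(emp.get(cat, 0.0) - p) < 0.02, (spec.name, cat)

    def test_shuffling_patients_leaves_marginals_invariant(self, big):
        rng = np.random.default_rng(0)
        shuffled = big.values.sample(frac=1.0, random_state=1)
        assert np.isclose(shuffled["age"].mean(), big.values["age"].mean())
        assert (shuffled["definitive"].value_counts()
                == big.values["definitive"].value_counts()).all()


class TestPlantedSignal:
    def test_aggressive_stratum_has_higher_endrt_burden(self, schema, params):
        # only ~2% of patients skip radiotherapy, so resolve the contrast at
        # a sample size where that stratum is a few hundred patients
        cohort, _ = h.generate_cohort(params, 10_000, seed=42, schema=schema)
        df = cohort.values
        aggressive = df["radio/chemo"] == CC
        none = df["radio/chemo"] == "no"
        for s in ("fatigue", "drymouth"):
            col = f"mdasi_endrt_{s}"
            assert (df.loc[aggressive, col].mean()
                    > df.loc[none, col].mean())

    def test_intensity_lowers_true_relapse_probability(self, cohort676):
        _, truth = cohort676
        hi = truth[truth["intensity"] >= 2.0]["relapse_prob"].mean()
        lo = truth[truth["intensity"] <= 1.0]["relapse_prob"].mean()
        assert hi < lo

    def test_zeroed_effects_decouple_actions_from_stage(self, schema, params):
        cohort, _ = h.generate_cohort(params.without_effects(), 20_000,
                                      seed=5, schema=schema)
        df = cohort.values
        # without planted couplings, surgery rate is flat across T stage
        rates = df.groupby("t_nominal")["definitive"].apply(
            lambda s: (s == "yes").mean())
        assert rates.loc[["t1", "t2", "t3"]].max() - \
            rates.loc[["t1", "t2", "t3"]].min() < 0.03


class TestClipRoundCorrection:
    def test_corrected_location_restores_target_mean(self):
        # low-mean bounded score: raw clipping would inflate the mean by ~0.38
        mu = corrected_location(1.08, 2.02, 0.0, 10.0, True)
        assert mu < 1.08
        rng = np.random.default_rng(0)
        x = np.round(np.clip(rng.normal(mu, 2.02, 400_000), 0, 10))
        assert abs(x.mean() - 1.08) < 0.02

    def test_lower_bounded_smoking_covariate(self):
        mu = corrected_location(14.99, 22.78, 0.0, None, False)
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(mu, 22.78, 400_000), 0, np.inf)
        assert abs(x.mean() - 14.99) < 0.15

    def test_unbounded_feature_is_unchanged(self):
        assert corrected_location(60.49, 8.92, None, None, False) == 60.49


def test_sequence_stats_consistent_with_pattern_table(params):
    stats = _sequence_stats(params.sequence_probs)
    assert np.isclose(stats["p_ds"], 58 / 651)
    assert np.isclose(stats["p_ic_given_nods"], 75 / 593)
    assert np.isclose(stats["p_cc_given_rt"], 469 / 637)
    assert np.isclose(stats["mean_intensity"],
                      sum(c * (0.5 * (p[0] == "yes") + 0.7 * (p[1] == "yes")
                               + {"no": 0, "yes": 1.0, CC: 1.5}[p[2]])
                          for p, c in zip(SEQUENCE_PATTERNS, SEQUENCE_COUNTS))
                      / 651)
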