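"""Shared fixtures: schema, generated cohorts, and fitted models.

Model fits are session-scoped so the trained VAE and predictor chain are
reused across the unit, environment, and acceptance tests.
"""

import warnings

import pytest
from hypothesis import HealthCheck, settings

import hntwin as h
from hntwin import chain as chain_mod
from hntwin import preprocess
from hntwin.timeline import Event
from hntwin.vae import VaeConfig, VaeModel, train_vae

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings(
    "ignore", message=".*least populated class.*")
warnings.filterwarnings(
    "ignore", message=".*Maximum iterations.*")


@pytest.fixture(scope="session")
def schema():
    return h.default_schema()


@pytest.fixture(scope="session")
def params(schema):
    return h.default_params(schema)


@pytest.fixture(scope="session")
def cohort676(schema, params):
    cohort, truth = h.generate_cohort(params, 676, seed=1, schema=schema)
    return cohort, truth


@pytest.fixture(scope="session")
def train_test(cohort676):
    cohort, _ = cohort676
    return preprocess.split(cohort, preprocess.SplitSpec(539, 137, seed=1))


@pytest.fixture(scope="session")
def ptf_prepared(schema, train_test):
    """(raw PTF train cohort, imputed+normalized cohort, normalizer)."""
    train, _ = train_test
    ptf_cols = schema.group_names("PTF")
    ptf = train.subset_columns(ptf_cols)
    imputed = preprocess.impute(ptf, schema, "vae_mlp")
    norm = preprocess.fit_normalizer(imputed, schema)
    return ptf, norm.apply(imputed), norm


@pytest.fixture(scope="session")
def trained_vae(schema, ptf_prepared):
    _, normalized, norm = ptf_prepared
    cfg = VaeConfig(epochs=300, seed=0)
    model, history = train_vae(normalized, cfg,
                               schema.subset(normalized.columns),
                               normalizer=norm)
    return model, history


@pytest.fixture(scope="session")
def untrained_vae(schema, ptf_prepared):
    _, normalized, norm = ptf_prepared
    cfg = VaeConfig(epochs=300, seed=0)
    return VaeModel(schema.subset(normalized.columns), cfg, norm)


@pytest.fixture(scope="session")
def chain_spec(schema):
    return chain_mod.default_chain(schema)


@pytest.fixture(scope="session")
def fitted_chain(schema, chain_spec, train_test):
    train, _ = train_test
    return chain_mod.fit_chain(train, chain_spec, schema,
                               chain_mod.fast_grid(), seed=1)


@pytest.fixture(scope="session")
def baselines(schema, chain_spec, train_test):
    train, _ = train_test
    return {
        "median_mean": chain_mod.baseline_median_mean(
            train, schema, chain_spec.targets),
        "random": chain_mod.baseline_random(
            train, schema, chain_spec.targets, seed=1),
    }


# -- case-study event logs ---------------------------------------------------

@pytest.fixture
def patient1_events():
    """Short course: concurrent chemoradiation, relapse at day 517."""
    return [
        Event(0, "TreatmentStart", "Treatment Start"),
        Event(28, "Action", "Chemotherapy/Biotherapy/Investigational/SMI"),
        Event(33, "Action", "Radiation Therapy"),
        Event(517, "Status", "Relapse/Recurrence"),
    ]


@pytest.fixture
def patient2_events():
    """Prolonged multi-modal history with recurrent disease."""
    rows = [
        (0, "TreatmentStart", "Treatment Start"),
        (53, "Action", "Radiation Therapy"),
        (168, "Status", "No Evidence of Disease (NED)"),
        (830, "Status", "Relapse/Recurrence"),
        (845, "Action", "Surgery"),
        (869, "Status", "Progression"),
        (888, "Action", "Chemotherapy"),
        (930, "Status", "Stable Disease"),
        (960, "Action", "Surgery"),
        (1027, "Action", "Radiation Therapy"),
        (1113, "Status", "No Evidence of Disease (NED)"),
        (2300, "Status", "Progression"),
        (2339, "Action", "Surgery"),
        (2489, "Action", "Other Therapies"),
        (2540, "Status", "Partial Remission/Partial or Mixed Response"),
        (2582, "Action", "Other Therapies"),
        (2624, "Status", "Stable Disease"),
        (2637, "Action", "Surgery"),
        (2666, "Action", "Other Therapies"),
        (2708, "Status", "Stable Disease"),
    ]
    return [Event(*r) for r in rows]
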