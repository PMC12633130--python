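"""Synthetic cohort generator parameterized from the printed registry tables.

The private registry behind the twin cannot be shared, so this module
emulates it: every marginal (category counts, means/SDs) comes from the
published demographic tables, first-cycle treatment sequences follow the
published eight-pattern frequency table, post-surgical pathology is
structurally missing for non-surgical patients, and 0-10 symptom scores are
integer-valued and bounded.

Dependencies are *planted* so downstream predictors have learnable signal,
via Gaussian-copula couplings that preserve the printed marginals exactly:
each categorical draw thresholds a standard-normal latent, and correlation
enters by sharing latents (e.g. the surgery decision shares the latent that
generated T stage).  Treatment actions are sampled hierarchically — surgery,
then induction given no surgery, then the radiotherapy class given the cell —
with cell-conditional probabilities taken from the published joint table, so
the pattern distribution is reproduced exactly while each action remains
predictable from pre-treatment features.

Bounded scores are drawn as clip-and-round Gaussians whose pre-clip location
is root-solved so the post-clip mean equals the printed mean (a raw clip
would bias low-mean scores by up to ~0.4 points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.stats import norm

from .schema import (
    CATEGORICAL_COUNTS,
    Cohort,
    FeatureSchema,
    SYMPTOMS,
    TIMEPOINTS,
    default_schema,
)

# ---------------------------------------------------------------------------
# Treatment-sequence patterns: (definitive, induction, radio/chemo) with the
# published counts (total 651; the remaining patients did not fit a pattern).
# ---------------------------------------------------------------------------

CC = "yes-with-concurrent-chemotherapy"

SEQUENCE_PATTERNS: tuple[tuple[str, str, str], ...] = (
    ("no", "no", CC),       # chemoradiation only
    ("no", "no", "yes"),    # radiotherapy only
    ("no", "yes", CC),      # induction then chemoradiation
    ("yes", "no", "yes"),   # surgery then radiotherapy
    ("no", "yes", "yes"),   # induction then radiotherapy
    ("yes", "no", CC),      # surgery then chemoradiation
    ("yes", "no", "no"),    # surgery alone
    ("no", "yes", "no"),    # induction alone
)
SEQUENCE_COUNTS = (398, 120, 52, 29, 19, 19, 10, 4)

#: latent treatment-intensity contribution of each action
INTENSITY_WEIGHTS = {
    "definitive": 0.5,
    "induction": 0.7,
    "radio_chemo": {"no": 0.0, "yes": 1.0, CC: 1.5},
}

RC_ORDER = ("no", "yes", CC)  # threshold order: higher latent -> more chemo


def pattern_intensity(pattern: tuple[str, str, str]) -> float:
    ds, ic, rc = pattern
    return (INTENSITY_WEIGHTS["definitive"] * (ds == "yes")
            + INTENSITY_WEIGHTS["induction"] * (ic == "yes")
            + INTENSITY_WEIGHTS["radio_chemo"][rc])


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalMarginal:
    probs: dict[str, float]

    def __post_init__(self):
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class NumericalMarginal:
    mean: float
    sd: float
    bounds: tuple[float | None, float | None] | None = None
    integer: bool = False

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class EffectSizes:
    """Documented planted-dependency strengths (package constants, not
    registry estimates).  Copula correlations are dimensionless in [-1, 1];
    symptom coefficients are score points per unit treatment intensity;
    relapse coefficients are log-odds per standardized unit."""

    surgery_tstage_rho: float = 0.50      # smaller T -> more surgery
    induction_nstage_rho: float = 0.50    # higher N -> more induction
    chemo_age_rho: float = -0.45          # younger -> concurrent chemo
    ene_nstage_rho: float = 0.65          # higher N -> extranodal extension
    margin_nstage_rho: float = 0.60       # higher N -> positive margins
    rttype_age_rho: float = -0.60         # younger -> proton therapy
    rtdose_concurrent_shift: float = 120.0    # cGy above/below mean with chemo
    rtfraction_concurrent_shift: float = 0.5  # fractions
    symptom_intensity: dict[str, float] = field(
        default_factory=lambda: {"endrt": 1.5, "wk6": 1.1, "m3": 0.8, "m12": 0.5})
    symptom_propensity_rho: float = 0.60  # within-patient symptom correlation
    relapse_intensity: float = -1.2       # aggressive treatment lowers relapse
    relapse_age: float = 0.3
    relapse_propensity: float = 0.5

    def zeroed(self) -> "EffectSizes":
        """All treatment/covariate couplings off; marginals are untouched."""
        return EffectSizes(
            surgery_tstage_rho=0.0, induction_nstage_rho=0.0,
            chemo_age_rho=0.0, ene_nstage_rho=0.0, margin_nstage_rho=0.0,
            rttype_age_rho=0.0, rtdose_concurrent_shift=0.0,
            rtfraction_concurrent_shift=0.0,
            symptom_intensity={t: 0.0 for t in TIMEPOINTS},
            symptom_propensity_rho=0.0, relapse_intensity=0.0,
            relapse_age=0.0, relapse_propensity=0.0,
        )


@dataclass(frozen=True)
class MissingnessConfig:
    prs_random_rate: float = 0.05
    relapse_labeled_fraction: float = 188 / 676
    relapse_p_true_given_labeled: float = 35 / 188


@dataclass
class GeneratorParams:
    marginals: dict[str, CategoricalMarginal | NumericalMarginal]
    sequence_probs: dict[tuple[str, str, str], float]
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.sequence_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sequence probabilities sum to {total}, not 1")

    def without_effects(self) -> "GeneratorParams":
        return replace(self, effect_sizes=self.effect_sizes.zeroed())


def default_params(schema: FeatureSchema | None = None) -> GeneratorParams:
    """Generator parameters read off the printed registry tables."""
    schema = schema or default_schema()
    marginals: dict[str, CategoricalMarginal | NumericalMarginal] = {}
    for spec in schema:
        if spec.is_categorical:
            counts = CATEGORICAL_COUNTS[spec.name]
            total = sum(counts.values())
            marginals[spec.name] = CategoricalMarginal(
                {k: v / total for k, v in counts.items()})
        else:
            marginals[spec.name] = NumericalMarginal(
                spec.mean, spec.sd, spec.bounds, spec.integer)
    total = sum(SEQUENCE_COUNTS)
    seq = {p: c / total for p, c in zip(SEQUENCE_PATTERNS, SEQUENCE_COUNTS)}
    return GeneratorParams(marginals=marginals, sequence_probs=seq)


# ---------------------------------------------------------------------------
# Derived quantities of the sequence distribution
# ---------------------------------------------------------------------------

def _sequence_stats(seq: dict[tuple[str, str, str], float]) -> dict:
    p_ds = sum(p for (ds, _, _), p in seq.items() if ds == "yes")
    p_nods = 1.0 - p_ds
    p_ic_nods = sum(p for (ds, ic, _), p in seq.items()
                    if ds == "no" and ic == "yes")
    cells = {}
    for cell in (("no", "no"), ("no", "yes"), ("yes", "no")):
        mass = {rc: seq.get((cell[0], cell[1], rc), 0.0) for rc in RC_ORDER}
        total = sum(mass.values())
        if total > 0:
            cells[cell] = np.array([mass[rc] / total for rc in RC_ORDER])
        else:
            cells[cell] = np.array([1.0, 0.0, 0.0])  # unreachable cell
    mean_i = sum(p * pattern_intensity(k) for k, p in seq.items())
    var_i = sum(p * (pattern_intensity(k) - mean_i) ** 2 for k, p in seq.items())
    p_rt = sum(p for (_, _, rc), p in seq.items() if rc != "no")
    p_cc_rt = (sum(p for (_, _, rc), p in seq.items() if rc == CC) / p_rt
               if p_rt > 0 else 0.0)
    return {
        "p_ds": p_ds,
        "p_ic_given_nods": p_ic_nods / p_nods if p_nods > 0 else 0.0,
        "cells": cells,
        "mean_intensity": mean_i,
        "sd_intensity": math.sqrt(var_i),
        "p_cc_given_rt": p_cc_rt,
    }


# ---------------------------------------------------------------------------
# Clip-and-round location corrections
# ---------------------------------------------------------------------------

def _clipround_mean(mu: float, sd: float, lo: int, hi: int) -> float:
    """Mean of round(clip(Normal(mu, sd), lo, hi)) on the integer grid."""
    ks = np.arange(lo, hi + 1)
    p = norm.cdf((ks + 0.5 - mu) / sd) - norm.cdf((ks - 0.5 - mu) / sd)
    p[0] = norm.cdf((lo + 0.5 - mu) / sd)
    p[-1] = 1.0 - norm.cdf((hi - 0.5 - mu) / sd)
    return float((ks * p).sum())


def _lowerclip_mean(mu: float, sd: float) -> float:
    """Mean of max(Normal(mu, sd), 0)."""
    z = mu / sd
    return float(mu * norm.cdf(z) + sd * norm.pdf(z))


@lru_cache(maxsize=256)
def corrected_location(target_mean: float, sd: float,
                       lo: float | None, hi: float | None,
                       integer: bool) -> float:
    """Pre-clip Gaussian location whose clipped(-and-rounded) mean equals the
    target.  Identity when no bound is active."""
    if sd == 0 or (lo is None and hi is None):
        return target_mean
    if integer and lo is not None and hi is not None:
        f = lambda mu: _clipround_mean(mu, sd, int(lo), int(hi)) - target_mean
        return brentq(f, lo - 8 * sd, hi + 8 * sd, xtol=1e-10)
    if lo == 0.0 and hi is None:
        f = lambda mu: _lowerclip_mean(mu, sd) - target_mean
        return brentq(f, target_mean - 8 * sd, target_mean + 8 * sd, xtol=1e-10)
    return target_mean


def _sample_numeric(rng_values: np.ndarray, marg: NumericalMarginal) -> np.ndarray:
    """Map standard-normal draws to the marginal (with location correction)."""
    mu = corrected_location(marg.mean, marg.sd,
                            None if marg.bounds is None else marg.bounds[0],
                            None if marg.bounds is None else marg.bounds[1],
                            marg.integer)
    x = mu + marg.sd * rng_values
    if marg.bounds is not None:
        lo, hi = marg.bounds
        x = np.clip(x, lo if lo is not None else -np.inf,
                    hi if hi is not None else np.inf)
    if marg.integer:
        x = np.round(x)
    return x


def _threshold_categorical(latent: np.ndarray, categories: list[str],
                           probs: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw from `probs` using Phi(latent) as the uniform."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard fp drift
    idx = np.searchsorted(cum, norm.cdf(latent), side="right")
    idx = np.clip(idx, 0, len(categories) - 1)
    return np.asarray(categories, dtype=object)[idx]


def _mix(rho: float, shared: np.ndarray, noise: np.ndarray) -> np.ndarray:
    return rho * shared + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise


# ---------------------------------------------------------------------------
# Sampling operations
# ---------------------------------------------------------------------------

def sample_treatment_sequence(params: GeneratorParams,
                              rng: np.random.Generator) -> tuple[str, str, str]:
    """Draw one (definitive, induction, radio/chemo) triple from the pattern
    distribution."""
    patterns = list(params.sequence_probs)
    probs = np.array([params.sequence_probs[p] for p in patterns])
    idx = rng.choice(len(patterns), p=probs)
    return patterns[idx]


@lru_cache(maxsize=32)
def _calibrated_relapse_logit(p_true: float, c_int: float, c_gauss_sd: float,
                              seq_items: tuple) -> float:
    """Base log-odds such that the marginal P(relapse | labeled) equals
    ``p_true`` under the centered covariate distribution (intensity is exact
    over the discrete patterns; Gaussian terms by Gauss-Hermite)."""
    seq = dict(seq_items)
    stats = _sequence_stats(seq)
    sd_i = stats["sd_intensity"] or 1.0
    shifts = np.array([c_int * (pattern_intensity(k) - stats["mean_intensity"]) / sd_i
                       for k in seq])
    weights = np.array(list(seq.values()))
    nodes, gh_w = hermegauss(40)
    gh_w = gh_w / gh_w.sum()

    def marginal(b0: float) -> float:
        z = b0 + shifts[:, None] + c_gauss_sd * nodes[None, :]
        return float((weights[:, None] * gh_w[None, :] / (1 + np.exp(-z))).sum())

    if c_int == 0 and c_gauss_sd == 0:
        return math.log(p_true / (1 - p_true))
    return brentq(lambda b: marginal(b) - p_true, -10, 5, xtol=1e-10)


def generate_cohort(params: GeneratorParams, n: int,
                    seed: int | None = None,
                    schema: FeatureSchema | None = None,
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate a synthetic cohort and its planted ground truth.

    Returns ``(cohort, truth)`` where ``truth`` records, per patient, the
    assigned treatment pattern, the latent treatment-intensity score, the
    symptom-propensity latent, and the true relapse probability — enabling
    parameter-recovery tests downstream.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    schema = schema or default_schema()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    eff = params.effect_sizes
    stats = _sequence_stats(params.sequence_probs)
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    cols: dict[str, np.ndarray] = {}

    def cat_marg(name: str) -> tuple[list[str], np.ndarray]:
        m = params.marginals[name]
        cats = list(m.probs)
        return cats, np.array([m.probs[c] for c in cats])

    # --- pre-treatment features (mutually independent; latents retained) ---
    g: dict[str, np.ndarray] = {}
    g["age"] = rng.standard_normal(n)
    cols["age"] = _sample_numeric(g["age"], params.marginals["age"])
    for name in ("gender", "ethnicity", "race", "smoking_status"):
        cats, probs = cat_marg(name)
        cols[name] = _threshold_categorical(rng.standard_normal(n), cats, probs)
    for name in ("tobacco_packs_per_day", "tobacco_used_years", "pack_years"):
        cols[name] = _sample_numeric(rng.standard_normal(n),
                                     params.marginals[name])
    for name in ("site_of_tumor", "ajcc_version", "p16_hpv_postive",
                 "tumor_laterality", "t_nominal", "n_nominal", "m",
                 "status_at_enrollememt"):
        g[name] = rng.standard_normal(n)
        cats, probs = cat_marg(name)
        cols[name] = _threshold_categorical(g[name], cats, probs)
    g_t, g_n, g_age = g["t_nominal"], g["n_nominal"], g["age"]

    # per-patient symptom propensity (shared across timepoints)
    propensity = rng.standard_normal(n)
    rho_u = eff.symptom_propensity_rho
    for s in SYMPTOMS:
        name = f"mdasi_baseline_{s}"
        draw = _mix(rho_u, propensity, rng.standard_normal(n))
        cols[name] = _sample_numeric(draw, params.marginals[name])

    # --- first-cycle actions: hierarchical copula over the pattern table ---
    # surgery | T stage (exact Bernoulli marginal)
    s_ds = _mix(eff.surgery_tstage_rho, -g_t, rng.standard_normal(n))
    ds = np.where(norm.cdf(s_ds) > 1.0 - stats["p_ds"], "yes", "no")
    # induction | N stage, only without surgery (exact given the cell)
    s_ic = _mix(eff.induction_nstage_rho, g_n, rng.standard_normal(n))
    ic = np.where((ds == "no")
                  & (norm.cdf(s_ic) > 1.0 - stats["p_ic_given_nods"]),
                  "yes", "no")
    # radiotherapy class | age, cell-conditional probabilities
    s_rc = _mix(eff.chemo_age_rho, g_age, rng.standard_normal(n))
    rc = np.empty(n, dtype=object)
    for cell, probs in stats["cells"].items():
        mask = (ds == cell[0]) & (ic == cell[1])
        if mask.any():
            rc[mask] = _threshold_categorical(s_rc[mask], list(RC_ORDER), probs)
    cols["definitive"], cols["induction"], cols["radio/chemo"] = ds, ic, rc

    intensity = (INTENSITY_WEIGHTS["definitive"] * (ds == "yes")
                 + INTENSITY_WEIGHTS["induction"] * (ic == "yes")
                 + np.vectorize(INTENSITY_WEIGHTS["radio_chemo"].get)(rc)
                 if n else np.zeros(0))
    centered_i = intensity - stats["mean_intensity"]

    # --- post-intervention outcomes ---
    surgical = ds == "yes"
    rt_given = rc != "no"
    order = ["Negative", "Unknown", "Positive"]  # Positive at the high end
    ene = _threshold_categorical(
        _mix(eff.ene_nstage_rho, g_n, rng.standard_normal(n)),
        order, np.array([params.marginals["ENE"].probs[c] for c in order]))
    cols["ENE"] = np.where(surgical, ene, None)
    m_marg = params.marginals["Margin"]
    order = [c for c in m_marg.probs if c != "Positive"] + ["Positive"]
    margin = _threshold_categorical(
        _mix(eff.margin_nstage_rho, g_n, rng.standard_normal(n)),
        order, np.array([m_marg.probs[c] for c in order]))
    cols["Margin"] = np.where(surgical, margin, None)

    rt_marg = params.marginals["rt_type"]
    order = ["Other", "3d Conformal", "IMRT", "Vmat", "IMPT"]  # IMPT high end
    rt_type = _threshold_categorical(
        _mix(eff.rttype_age_rho, g_age, rng.standard_normal(n)),
        order, np.array([rt_marg.probs[c] for c in order]))
    cols["rt_type"] = np.where(rt_given, rt_type, None)

    concurrent_centered = (rc == CC).astype(float) - stats["p_cc_given_rt"]
    dose = _sample_numeric(rng.standard_normal(n), params.marginals["rt_dose"])
    dose = dose + eff.rtdose_concurrent_shift * concurrent_centered
    cols["rt_dose"] = np.where(rt_given, dose, np.nan)
    frac_marg = params.marginals["rt_fraction"]
    frac = (corrected_location(frac_marg.mean, frac_marg.sd, 0.0, None, False)
            + frac_marg.sd * rng.standard_normal(n)
            + eff.rtfraction_concurrent_shift * concurrent_centered)
    frac = np.round(np.clip(frac, 0.0, np.inf))
    cols["rt_fraction"] = np.where(rt_given, frac, np.nan)

    # --- patient-reported scores: printed-mean level + intensity effect +
    # shared propensity ---
    for t in TIMEPOINTS:
        beta = eff.symptom_intensity.get(t, 0.0)
        for s in SYMPTOMS:
            name = f"mdasi_{t}_{s}"
            marg: NumericalMarginal = params.marginals[name]
            mu = corrected_location(marg.mean, marg.sd, marg.bounds[0],
                                    marg.bounds[1], marg.integer)
            draw = _mix(rho_u, propensity, rng.standard_normal(n))
            x = mu + beta * centered_i + marg.sd * draw
            cols[name] = np.round(np.clip(x, 0.0, 10.0))

    # --- year-3 relapse: logistic in centered covariates, base log-odds
    # calibrated so the labeled marginal matches the printed rate ---
    miss = params.missingness
    c_gauss = math.hypot(eff.relapse_age, eff.relapse_propensity)
    b0 = _calibrated_relapse_logit(
        miss.relapse_p_true_given_labeled, eff.relapse_intensity, c_gauss,
        tuple(sorted(params.sequence_probs.items())))
    sd_i = stats["sd_intensity"] or 1.0
    logit = (b0 + eff.relapse_intensity * centered_i / sd_i
             + eff.relapse_age * g_age + eff.relapse_propensity * propensity)
    relapse_prob = 1.0 / (1.0 + np.exp(-logit))
    relapse = np.where(rng.random(n) < relapse_prob, "True", "False")
    labeled = rng.random(n) < miss.relapse_labeled_fraction
    cols["relapse_yr3"] = np.where(labeled, relapse, None)

    # --- random missingness on patient-reported scores ---
    if miss.prs_random_rate > 0:
        for t in TIMEPOINTS:
            for s in SYMPTOMS:
                name = f"mdasi_{t}_{s}"
                drop = rng.random(n) < miss.prs_random_rate
                vals = cols[name].astype(float)
                vals[drop] = np.nan
                cols[name] = vals

    frame = pd.DataFrame(index=ids)
    for spec in schema:
        vals = cols[spec.name]
        if spec.is_categorical:
            frame[spec.name] = pd.Series(vals, index=ids, dtype="object")
        else:
            frame[spec.name] = pd.Series(np.asarray(vals, dtype=float), index=ids)

    pattern_strings = [" / ".join(p) for p in zip(ds, ic, rc)] if n else []
    truth = pd.DataFrame(
        {
            "pattern": pd.Series(pattern_strings, index=ids, dtype="object"),
            "intensity": pd.Series(np.asarray(intensity, dtype=float), index=ids),
            "propensity": pd.Series(propensity, index=ids),
            "relapse_prob": pd.Series(relapse_prob, index=ids),
            "labeled": pd.Series(labeled, index=ids),
        }
    )
    return Cohort(frame), truth
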