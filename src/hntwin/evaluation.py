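"""Fidelity and predictive-performance metrics.

Generative fidelity is measured feature-by-feature: order-1 Wasserstein
distance for numerical features (on the raw, denormalized scale) and total
variation for categorical features (the Wasserstein distance under the 0/1
ground metric), averaged into a single scalar.  Predictive performance uses
macro-F1 over the schema-declared classes (so rare classes absent from a test
split still count, matching the heavily imbalanced outcome distributions) and
MSE on denormalized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.metrics import f1_score

from .schema import Cohort, FeatureSchema


def wasserstein_1d(sample_a, sample_b) -> float:
    """Order-1 Wasserstein distance between two empirical distributions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wasserstein_1d requires non-empty samples")
    return float(wasserstein_distance(a, b))


def categorical_distance(sample_a, sample_b, categories) -> float:
    """Total-variation distance between empirical category distributions."""
    a = pd.Series(list(sample_a)).value_counts(normalize=True)
    b = pd.Series(list(sample_b)).value_counts(normalize=True)
    return float(0.5 * sum(abs(a.get(c, 0.0) - b.get(c, 0.0))
                           for c in categories))


@dataclass
class FidelityReport:
    per_feature: dict[str, float]
    n_real: int
    n_synth: int

    @property
    def mean_distance(self) -> float:
        return float(np.mean(list(self.per_feature.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.per_feature),
             "distance": list(self.per_feature.values())})


def fidelity_report(real: Cohort, synth: Cohort,
                    schema: FeatureSchema) -> FidelityReport:
    """Per-feature distances between two cohorts over their shared columns,
    missing values excluded per feature."""
    shared = [c for c in real.columns if c in synth.columns]
    if not shared:
        raise ValueError("cohorts share no columns")
    per: dict[str, float] = {}
    for col in shared:
        a, b = real.observed(col), synth.observed(col)
        if len(a) == 0 or len(b) == 0:
            continue
        if schema[col].is_categorical:
            per[col] = categorical_distance(a, b, schema[col].categories)
        else:
            per[col] = wasserstein_1d(a.astype(float), b.astype(float))
    return FidelityReport(per, n_real=len(real), n_synth=len(synth))


def macro_f1(y_true, y_pred, classes) -> float:
    """Unweighted mean of per-class F1 over the declared classes (a class
    absent from both truth and prediction contributes 0)."""
    return float(f1_score(list(y_true), list(y_pred), labels=list(classes),
                          average="macro", zero_division=0))


def mse(y_true, y_pred) -> float:
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.mean((a - b) ** 2))


def benchmark(models: dict[str, object], test: Cohort,
              schema: FeatureSchema, targets: list[str]) -> pd.DataFrame:
    """Score every model on every chain target of the test cohort.

    Each model must expose ``predict_feature(target, cohort) -> array``.
    Rows with missing test labels are scored on the observed subset.  Returns
    a frame with columns feature, metric, and one column per model.
    """
    if len(test) == 0:
        raise ValueError("empty test cohort")
    rows = []
    for target in targets:
        spec = schema[target]
        y = test.values[target]
        observed = y.notna()
        if not observed.any():
            continue
        metric = "F1" if spec.is_categorical else "MSE"
        row: dict[str, object] = {"feature": target, "metric": metric}
        for name, model in models.items():
            pred = pd.Series(model.predict_feature(target, test),
                             index=test.patient_ids)[observed]
            if spec.is_categorical:
                row[name] = macro_f1(y[observed], pred, spec.categories)
            else:
                row[name] = mse(y[observed].astype(float), pred.astype(float))
        rows.append(row)
    return pd.DataFrame(rows)
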