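"""Normalization, imputation, and the train/test split.

All statistics are fitted on training data only; transforms are invertible so
model outputs can be mapped back to clinical units.  The two model families
treat missing values differently: the VAE/MLP family requires imputation
(train mean for numerical, most frequent training category for categorical),
while gradient-boosted trees consume missing values natively and receive the
cohort unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .schema import Cohort, FeatureSchema

log = logging.getLogger(__name__)


class Normalizer:
    """Per-feature z-scoring with the population (divide-by-n) SD convention.

    Constant columns are passed through unchanged (SD treated as 1) and
    flagged in :attr:`constant_features`.
    """

    def __init__(self):
        self.means: dict[str, float] = {}
        self.sds: dict[str, float] = {}
        self.constant_features: list[str] = []

    def fit(self, train: Cohort, schema: FeatureSchema) -> "Normalizer":
        for col in train.columns:
            if schema[col].is_categorical:
                continue
            obs = train.observed(col).astype(float)
            if len(obs) == 0:
                raise ValueError(f"cannot normalize all-missing column {col!r}")
            mean = float(obs.mean())
            sd = float(obs.std(ddof=0))
            if sd == 0.0:
                log.warning("constant column %r passed through unnormalized", col)
                self.constant_features.append(col)
                sd = 1.0
            self.means[col], self.sds[col] = mean, sd
        return self

    def apply(self, cohort: Cohort) -> Cohort:
        df = cohort.values.copy()
        for col, mean in self.means.items():
            if col in df.columns:
                df[col] = (df[col].astype(float) - mean) / self.sds[col]
        return Cohort(df)

    def invert(self, cohort: Cohort) -> Cohort:
        df = cohort.values.copy()
        for col, mean in self.means.items():
            if col in df.columns:
                df[col] = df[col].astype(float) * self.sds[col] + mean
        return Cohort(df)

    def apply_series(self, col: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means[col]) / self.sds[col]

    def invert_series(self, col: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sds[col] + self.means[col]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds,
                           "constant_features": self.constant_features})

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        d = json.loads(text)
        out = cls()
        out.means, out.sds = d["means"], d["sds"]
        out.constant_features = d["constant_features"]
        return out


def fit_normalizer(train: Cohort, schema: FeatureSchema) -> Normalizer:
    return Normalizer().fit(train, schema)


@dataclass
class ImputationValues:
    numerical: dict[str, float]
    categorical: dict[str, str]

    @classmethod
    def fit(cls, train: Cohort, schema: FeatureSchema) -> "ImputationValues":
        num, cat = {}, {}
        for col in train.columns:
            obs = train.observed(col)
            if len(obs) == 0:
                continue
            if schema[col].is_categorical:
                cat[col] = obs.mode().iloc[0]
            else:
                num[col] = float(obs.astype(float).mean())
        return cls(num, cat)


def impute(cohort: Cohort, schema: FeatureSchema, family: str,
           values: ImputationValues | None = None) -> Cohort:
    """Fill missing cells for the given model family.

    ``family='boosted'`` returns the cohort unchanged (trees handle missing
    values natively).  ``family='vae_mlp'`` fills numerical features with the
    training mean and categorical features with the most frequent training
    category; pass ``values`` fitted on the training split to avoid leakage
    (defaults to fitting on ``cohort`` itself).
    """
    if family == "boosted":
        return Cohort(cohort.values.copy())
    if family != "vae_mlp":
        raise ValueError(f"unknown imputation family {family!r}")
    values = values or ImputationValues.fit(cohort, schema)
    df = cohort.values.copy()
    for col in df.columns:
        fill = (values.categorical.get(col) if schema[col].is_categorical
                else values.numerical.get(col))
        if fill is not None:
            df[col] = df[col].fillna(fill)
    return Cohort(df)


@dataclass(frozen=True)
class SplitSpec:
    n_train: int = 539
    n_test: int = 137
    seed: int = 0


def split(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive, seed-reproducible random partition."""
    if spec.n_train + spec.n_test != len(cohort):
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_test} != cohort size "
            f"{len(cohort)}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(cohort))
    ids = cohort.patient_ids
    train_ids = ids[np.sort(perm[:spec.n_train])]
    test_ids = ids[np.sort(perm[spec.n_train:])]
    return cohort.subset_rows(train_ids), cohort.subset_rows(test_ids)
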