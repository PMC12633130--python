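"""Sequential development predictor: one gradient-boosted model per
downstream feature, conditioned on everything earlier in the treatment
process, plus the median/mean, random, and multilayer-perceptron baselines.

The chain orders features chronologically — pre-treatment profile, surgery,
surgical pathology, induction, radiotherapy class, radiotherapy parameters,
the four symptom panels (end of RT, week 6, month 3, month 12), and finally
year-3 relapse — and each node's parents are all features of earlier stages.
Classification nodes use balanced sample weights (weight proportional to
n / (k * class count)) and are scored by macro-F1 in a 3-fold stratified
cross-validated grid search; regression nodes are scored by negative MSE.
Boosted nodes consume missing parents natively; the MLP baseline trains on
imputed, one-hot-encoded, z-scored inputs.
"""

from __future__ import annotations

import itertools
import logging
import pickle
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier, XGBRegressor

from .evaluation import macro_f1
from .preprocess import ImputationValues, Normalizer
from .schema import Cohort, FeatureSchema, SYMPTOMS, TIMEPOINTS

log = logging.getLogger(__name__)

ACTION_FEATURES = ("definitive", "induction", "radio/chemo")
RC_LABELS = ("no", "yes", "yes-with-concurrent-chemotherapy")


# ---------------------------------------------------------------------------
# Chain specification
# ---------------------------------------------------------------------------

@dataclass
class ChainSpec:
    """Ordered stages; stage 0 is input-only (PTF), later stages are
    prediction targets."""

    stages: list[list[str]]

    @property
    def targets(self) -> list[str]:
        return [t for stage in self.stages[1:] for t in stage]

    def parents_of(self, target: str) -> list[str]:
        parents: list[str] = []
        for stage in self.stages:
            if target in stage:
                return parents
            parents.extend(stage)
        raise KeyError(f"{target!r} is not a chain target")

    def validate_acyclic(self) -> None:
        seen: set[str] = set()
        for stage in self.stages:
            for name in stage:
                if name in seen:
                    raise ValueError(f"feature {name!r} appears twice in chain")
                seen.add(name)


def default_chain(schema: FeatureSchema) -> ChainSpec:
    """Chronological stage order; year-3 relapse is the final target."""
    stages = [schema.group_names("PTF"), ["definitive"], ["ENE", "Margin"],
              ["induction"], ["radio/chemo"],
              ["rt_type", "rt_dose", "rt_fraction"]]
    for t in TIMEPOINTS:
        stages.append([f"mdasi_{t}_{s}" for s in SYMPTOMS])
    stages.append(["relapse_yr3"])
    spec = ChainSpec(stages)
    spec.validate_acyclic()
    return spec


# ---------------------------------------------------------------------------
# Grid configuration
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    boosted: dict[str, list]
    mlp: dict[str, list]
    folds: int = 3


def full_grid() -> GridConfig:
    """The published search ranges."""
    return GridConfig(
        boosted={
            "learning_rate": [0.01, 0.1, 0.3],
            "max_depth": [4, 6, 8],
            "min_child_weight": [1, 3, 5],
            "n_estimators": [100, 200, 300],
            "colsample_bytree": [0.3, 0.5],
        },
        mlp={
            "hidden_layer_sizes": [(50, 50), (100, 100), (100, 50)],
            "solver": ["adam", "sgd"],
            "learning_rate_init": [0.001, 0.01],
            "max_iter": [200, 400],
        },
    )


def fast_grid() -> GridConfig:
    """One value per hyperparameter (the most regularized corner of the full
    grid); the default for tests and quick runs."""
    return GridConfig(
        boosted={
            "learning_rate": [0.1],
            "max_depth": [4],
            "min_child_weight": [5],
            "n_estimators": [100],
            "colsample_bytree": [0.5],
        },
        mlp={
            "hidden_layer_sizes": [(50, 50)],
            "solver": ["adam"],
            "learning_rate_init": [0.001],
            "max_iter": [200],
        },
    )


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    points = [dict(zip(keys, combo))
              for combo in itertools.product(*(grid[k] for k in keys))]
    # deterministic preference order for tie-breaking: fewer trees, shallower
    points.sort(key=lambda p: (p.get("n_estimators", 0), p.get("max_depth", 0),
                               sorted(p.items()).__repr__()))
    return points


# ---------------------------------------------------------------------------
# Feature encoding shared by all model families
# ---------------------------------------------------------------------------

class ChainEncoder:
    """Maps cohorts to model matrices; all statistics come from training data.

    Trees see categorical codes (schema order) with NaN for missing and raw
    numerics.  MLPs see imputed inputs, one-hot categories, z-scored
    numerics (population-SD convention).
    """

    def __init__(self, schema: FeatureSchema):
        self.schema = schema
        self.levels = {f.name: list(f.categories)
                       for f in schema if f.is_categorical}
        self.normalizer: Normalizer | None = None
        self.imputation: ImputationValues | None = None

    def fit(self, train: Cohort) -> "ChainEncoder":
        self.normalizer = Normalizer().fit(train, self.schema)
        self.imputation = ImputationValues.fit(train, self.schema)
        return self

    def codes(self, series: pd.Series, col: str) -> np.ndarray:
        c = pd.Categorical(series, categories=self.levels[col]).codes
        return np.where(c < 0, np.nan, c).astype(float)

    def tree_matrix(self, df: pd.DataFrame, parents: list[str]) -> np.ndarray:
        cols = []
        for p in parents:
            if p in self.levels:
                cols.append(self.codes(df[p], p))
            else:
                cols.append(df[p].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.zeros((len(df), 0))

    def mlp_matrix(self, df: pd.DataFrame, parents: list[str]) -> np.ndarray:
        assert self.imputation is not None and self.normalizer is not None
        cols = []
        for p in parents:
            if p in self.levels:
                fill = self.imputation.categorical.get(p, self.levels[p][0])
                vals = df[p].fillna(fill)
                onehot = pd.get_dummies(
                    pd.Categorical(vals, categories=self.levels[p]))
                cols.append(onehot.to_numpy(dtype=float))
            else:
                fill = self.imputation.numerical.get(p, 0.0)
                vals = df[p].astype(float).fillna(fill).to_numpy()
                if p in self.normalizer.means:
                    vals = self.normalizer.apply_series(p, vals)
                cols.append(vals[:, None])
        return np.concatenate(cols, axis=1) if cols else np.zeros((len(df), 0))


# ---------------------------------------------------------------------------
# Node models
# ---------------------------------------------------------------------------

class _ConstantClassifier:
    def __init__(self, label_code: int, n_classes: int):
        self.code, self.n_classes = label_code, n_classes

    def predict(self, X):
        return np.full(len(X), self.code)

    def predict_proba(self, X):
        p = np.zeros((len(X), self.n_classes))
        p[:, self.code] = 1.0
        return p


class _EncodedClassifier:
    """Wraps a classifier so folds/fits missing some classes still emit
    predictions and probabilities over the full observed-class code space."""

    def __init__(self, base, n_classes: int):
        self.base, self.n_classes = base, n_classes
        self.le = LabelEncoder()

    def fit(self, X, y_codes, sample_weight=None):
        y_enc = self.le.fit_transform(y_codes)
        if len(self.le.classes_) == 1:
            self.base = _ConstantClassifier(int(self.le.classes_[0]),
                                            self.n_classes)
            return self
        self.base.fit(X, y_enc, sample_weight=sample_weight) \
            if sample_weight is not None else self.base.fit(X, y_enc)
        return self

    def predict(self, X):
        if isinstance(self.base, _ConstantClassifier):
            return self.base.predict(X)
        return self.le.inverse_transform(self.base.predict(X).astype(int))

    def predict_proba(self, X):
        out = np.zeros((len(X), self.n_classes))
        if isinstance(self.base, _ConstantClassifier):
            return self.base.predict_proba(X)
        probs = self.base.predict_proba(X)
        for j, cls in enumerate(self.le.classes_):
            out[:, int(cls)] = probs[:, j]
        return out


@dataclass
class PredictorNode:
    """One conditional predictor of the chain.

    The boosted objective is the usual regularized additive-tree loss
    (a per-example loss l(y_i, yhat_i) plus a complexity penalty Omega(f_k)
    per tree): 'binary:logistic' / 'multi:softmax' for classification,
    squared error for regression.
    """

    target: str
    parents: list[str]
    task: str                      # 'binary' | 'multiclass' | 'regression'
    model: object = None
    classes: list[str] = field(default_factory=list)
    best_params: dict = field(default_factory=dict)
    cv_score: float = float("nan")
    residual_sd: float = 0.0


def _make_booster(task: str, n_classes: int, params: dict, seed: int):
    common = dict(params, random_state=seed, n_jobs=1, tree_method="hist",
                  verbosity=0)
    if task == "regression":
        return XGBRegressor(objective="reg:squarederror", **common)
    objective = "multi:softmax" if n_classes > 2 else "binary:logistic"
    return _EncodedClassifier(
        XGBClassifier(objective=objective, eval_metric="mlogloss", **common),
        n_classes)


def _make_mlp(task: str, n_classes: int, params: dict, seed: int):
    common = dict(params, activation="relu", random_state=seed)
    if task == "regression":
        return MLPRegressor(**common)
    return _EncodedClassifier(MLPClassifier(**common), n_classes)


def fit_node(target: str, parents: list[str], train: Cohort,
             schema: FeatureSchema, encoder: ChainEncoder,
             grid: GridConfig, seed: int, family: str = "boosted"
             ) -> PredictorNode:
    """Grid-search and fit one conditional predictor.

    Rows with a missing target are dropped for this node only.  Boosted
    models receive balanced sample weights for classification, recomputed
    inside each training fold.
    """
    spec = schema[target]
    observed = train.values[target].notna()
    df = train.values[observed]
    task = ("regression" if not spec.is_categorical
            else "multiclass" if len(spec.categories) > 2 else "binary")
    node = PredictorNode(target, list(parents), task,
                         classes=list(spec.categories))

    if family == "boosted":
        X = encoder.tree_matrix(df, parents)
        make, grid_points = _make_booster, _grid_points(grid.boosted)
    elif family == "mlp":
        X = encoder.mlp_matrix(df, parents)
        make, grid_points = _make_mlp, _grid_points(grid.mlp)
    else:
        raise ValueError(f"unknown family {family!r}")

    if task == "regression":
        y = encoder.normalizer.apply_series(target, df[target].to_numpy(float))
        splitter = KFold(grid.folds, shuffle=True, random_state=seed)
        n_classes = 0
    else:
        y = encoder.codes(df[target], target).astype(int)
        splitter = StratifiedKFold(grid.folds, shuffle=True, random_state=seed)
        n_classes = len(spec.categories)
        if len(np.unique(y)) < 2:
            only = spec.categories[int(y[0])] if len(y) else spec.categories[0]
            log.warning("target %r has a single observed class (%r); "
                        "constant predictor", target, only)
            node.model = _ConstantClassifier(int(y[0]) if len(y) else 0,
                                             n_classes)
            return node

    def weights(y_part):
        if task == "regression" or family != "boosted":
            return None
        return compute_sample_weight("balanced", y_part)

    best = None
    for params in grid_points:
        if len(grid_points) == 1:
            score = 0.0  # nothing to compare; skip the CV pass
        else:
            scores = []
            for tr_idx, va_idx in splitter.split(X, y if task != "regression"
                                                 else np.zeros(len(y))):
                model = make(task, n_classes, params, seed)
                w = weights(y[tr_idx])
                if w is not None or isinstance(model, _EncodedClassifier):
                    model.fit(X[tr_idx], y[tr_idx], sample_weight=w)
                else:
                    model.fit(X[tr_idx], y[tr_idx])
                pred = model.predict(X[va_idx])
                if task == "regression":
                    scores.append(-float(np.mean((pred - y[va_idx]) ** 2)))
                else:
                    scores.append(macro_f1(y[va_idx], pred,
                                           np.unique(y)))
            score = float(np.mean(scores))
        if best is None or score > best[0] + 1e-12:
            best = (score, params)

    node.best_params, node.cv_score = dict(best[1]), best[0]
    model = make(task, n_classes, best[1], seed)
    w = weights(y)
    if w is not None or isinstance(model, _EncodedClassifier):
        model.fit(X, y, sample_weight=w)
    else:
        model.fit(X, y)
    node.model = model
    if task == "regression":
        resid = y - model.predict(X)
        node.residual_sd = float(np.std(resid) * encoder.normalizer.sds[target])
    return node


# ---------------------------------------------------------------------------
# The fitted chain
# ---------------------------------------------------------------------------

@dataclass
class RolloutResult:
    record: pd.Series
    relapse_prob: float


class TwinChain:
    """Fitted predictor chain; also serves as the `boosted`/`mlp` entry in
    benchmark tables via :meth:`predict_feature`."""

    def __init__(self, schema: FeatureSchema, spec: ChainSpec,
                 encoder: ChainEncoder, family: str):
        self.schema = schema
        self.spec = spec
        self.encoder = encoder
        self.family = family
        self.nodes: dict[str, PredictorNode] = {}

    @property
    def targets(self) -> list[str]:
        return self.spec.targets

    def _matrix(self, df: pd.DataFrame, parents: list[str]) -> np.ndarray:
        if self.family == "boosted":
            return self.encoder.tree_matrix(df, parents)
        return self.encoder.mlp_matrix(df, parents)

    def predict_feature(self, target: str, cohort: Cohort) -> np.ndarray:
        """Predict one target from the observed parent columns of a cohort
        (labels for classification, denormalized values for regression)."""
        node = self.nodes[target]
        X = self._matrix(cohort.values, node.parents)
        if node.task == "regression":
            pred = np.asarray(node.model.predict(X), dtype=float)
            return self.encoder.normalizer.invert_series(target, pred)
        codes = np.asarray(node.model.predict(X), dtype=int)
        return np.asarray(node.classes, dtype=object)[codes]

    def predict_proba_feature(self, target: str, cohort: Cohort) -> np.ndarray:
        node = self.nodes[target]
        X = self._matrix(cohort.values, node.parents)
        return node.model.predict_proba(X)

    # -- simulation --------------------------------------------------------
    def rollout(self, ptf_row: pd.Series, actions: dict[str, str],
                mode: str = "expected", seed: int = 0) -> RolloutResult:
        """Simulate one patient's trajectory under a fixed treatment plan.

        ``actions`` maps definitive / induction / radio_chemo to labels.
        Expected mode takes class argmax and regression means; sampled mode
        draws classes from predicted probabilities and regression values from
        Normal(prediction, training residual SD), clipped to schema bounds.
        Structural rules are respected: surgical pathology appears only after
        surgery, radiotherapy parameters only when radiotherapy is given.
        """
        plan = {"definitive": actions["definitive"],
                "induction": actions["induction"],
                "radio/chemo": actions.get("radio_chemo",
                                           actions.get("radio/chemo"))}
        for name, label in plan.items():
            if label not in self.schema[name].categories:
                raise ValueError(f"unknown action label {label!r} for {name!r}")
        if mode not in ("expected", "sampled"):
            raise ValueError(f"unknown rollout mode {mode!r}")
        rng = np.random.default_rng(seed)

        record = pd.Series(np.nan, index=self.schema.names, dtype=object)
        record[ptf_row.index] = ptf_row.values
        for name, label in plan.items():
            record[name] = label

        relapse_prob = float("nan")
        for target in self.targets:
            if target in plan:
                continue
            spec = self.schema[target]
            mp = spec.missing_policy
            if (mp.kind == "structural"
                    and record[mp.condition_feature] not in mp.condition_values):
                continue
            node = self.nodes[target]
            df = record.to_frame().T
            X = self._matrix(df, node.parents)
            if node.task == "regression":
                pred = float(self.encoder.normalizer.invert_series(
                    target, np.asarray(node.model.predict(X), float))[0])
                if mode == "sampled":
                    pred += float(rng.normal(0.0, node.residual_sd))
                if spec.bounds is not None:
                    lo, hi = spec.bounds
                    pred = float(np.clip(pred, lo if lo is not None else -np.inf,
                                         hi if hi is not None else np.inf))
                if spec.integer:
                    pred = float(np.round(pred))
                record[target] = pred
            else:
                probs = node.model.predict_proba(X)[0]
                if target == "relapse_yr3":
                    true_idx = node.classes.index("True")
                    relapse_prob = float(probs[true_idx])
                if mode == "expected":
                    idx = int(np.argmax(probs))
                else:
                    idx = int(rng.choice(len(probs), p=probs / probs.sum()))
                record[target] = node.classes[idx]
        return RolloutResult(record, relapse_prob)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TwinChain":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_chain(train: Cohort, spec: ChainSpec, schema: FeatureSchema,
              grid: GridConfig | None = None, seed: int = 0,
              family: str = "boosted",
              encoder: ChainEncoder | None = None) -> TwinChain:
    """Fit every chain node in order; deterministic given the seed."""
    grid = grid or fast_grid()
    if encoder is None:
        encoder = ChainEncoder(schema).fit(train)
    chain = TwinChain(schema, spec, encoder, family)
    for target in spec.targets:
        chain.nodes[target] = fit_node(
            target, spec.parents_of(target), train, schema, encoder, grid,
            seed, family)
    return chain


def baseline_mlp(train: Cohort, spec: ChainSpec, schema: FeatureSchema,
                 grid: GridConfig | None = None, seed: int = 0,
                 encoder: ChainEncoder | None = None) -> TwinChain:
    return fit_chain(train, spec, schema, grid, seed, family="mlp",
                     encoder=encoder)


# ---------------------------------------------------------------------------
# Rule-based baselines
# ---------------------------------------------------------------------------

class MedianMeanBaseline:
    """Constant predictor: lower median of integer-coded labels for
    categorical targets (codes in schema order), training mean for numerical
    targets."""

    def __init__(self, train: Cohort, schema: FeatureSchema,
                 targets: list[str]):
        self.constants: dict[str, object] = {}
        for target in targets:
            obs = train.observed(target)
            if len(obs) == 0:
                continue
            spec = schema[target]
            if spec.is_categorical:
                codes = np.sort(pd.Categorical(
                    obs, categories=spec.categories).codes)
                self.constants[target] = spec.categories[
                    int(codes[(len(codes) - 1) // 2])]
            else:
                self.constants[target] = float(obs.astype(float).mean())

    def predict_feature(self, target: str, cohort: Cohort) -> np.ndarray:
        return np.full(len(cohort), self.constants[target], dtype=object)


class RandomBaseline:
    """Draws categorical labels proportional to training frequencies and
    numerical values from the empirical training distribution."""

    def __init__(self, train: Cohort, schema: FeatureSchema,
                 targets: list[str], seed: int = 0):
        self.seed = seed
        self.schema = schema
        self.pools: dict[str, np.ndarray] = {}
        for target in targets:
            self.pools[target] = train.observed(target).to_numpy()

    def predict_feature(self, target: str, cohort: Cohort) -> np.ndarray:
        rng = np.random.default_rng(
            [self.seed, zlib.crc32(target.encode()) & 0x7FFFFFFF])
        return rng.choice(self.pools[target], size=len(cohort), replace=True)


def baseline_median_mean(train: Cohort, schema: FeatureSchema,
                         targets: list[str]) -> MedianMeanBaseline:
    return MedianMeanBaseline(train, schema, targets)


def baseline_random(train: Cohort, schema: FeatureSchema,
                    targets: list[str], seed: int = 0) -> RandomBaseline:
    return RandomBaseline(train, schema, targets, seed)
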