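"""Heterogeneous-tabular variational autoencoder for pre-treatment profiles.

The generator learns the joint distribution of the pre-treatment feature
group (mixed categorical / numerical) and samples new synthetic patients.
Architecture: two fully connected ReLU layers of 64 units in the encoder,
two heads for the latent mean and log-variance (16 dimensions), and a decoder
mirroring the encoder with a linear head per numerical block and a softmax
head per categorical feature.  The latent is drawn with the
reparameterization trick, z = mu + exp(logvar/2) * eps.

Training maximizes the evidence lower bound: mean-squared-error
reconstruction for numerical features, cross-entropy for categorical
features, and the closed-form KL divergence to a standard-normal prior,
kl = 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2).  Losses are averaged over
the batch and summed over features (this convention interacts with
``kl_weight``).  The whole model is plain NumPy with a hand-written backward
pass and Adam, which is ample at tabular scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Normalizer
from .schema import Cohort, FeatureSchema


@dataclass(frozen=True)
class VaeConfig:
    hidden_layers: tuple[int, int] = (64, 64)
    latent_dim: int = 16
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 300          # desk-scale default; configurable upward
    kl_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ElboComponents:
    recon_numerical: float
    recon_categorical: float
    kl: float
    kl_weight: float = 1.0

    @property
    def total(self) -> float:
        return self.recon_numerical + self.recon_categorical + self.kl_weight * self.kl


@dataclass
class EncoderOutput:
    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray


def kl_standard_normal(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL(N(mu, sigma^2) || N(0, 1)), summed over dimensions and
    averaged over the batch."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per = 0.5 * (mu ** 2 + np.exp(logvar) - 1.0 - logvar)
    return float(per.sum(axis=1).mean())


def elbo_loss(batch: dict, reconstruction: dict, mu: np.ndarray,
              logvar: np.ndarray, config: VaeConfig) -> ElboComponents:
    """ELBO components for one batch.

    ``batch``: {'numerical': (B, p) array, 'categorical': list of (B,) int
    label arrays}; ``reconstruction``: {'numerical': (B, p) array,
    'categorical': list of (B, K_k) probability arrays}.
    """
    xn = np.atleast_2d(np.asarray(batch["numerical"], dtype=float))
    rn_hat = np.atleast_2d(np.asarray(reconstruction["numerical"], dtype=float))
    recon_num = float(((rn_hat - xn) ** 2).sum(axis=1).mean()) if xn.size else 0.0
    recon_cat = 0.0
    for k, labels in enumerate(batch["categorical"]):
        probs = np.atleast_2d(reconstruction["categorical"][k])
        picked = probs[np.arange(len(labels)), np.asarray(labels, dtype=int)]
        recon_cat += float(-np.log(np.clip(picked, 1e-12, None)).mean())
    kl = kl_standard_normal(mu, logvar)
    comp = ElboComponents(recon_num, recon_cat, kl, config.kl_weight)
    if not np.isfinite(comp.total):
        bad = ("numerical" if not np.isfinite(recon_num)
               else "categorical" if not np.isfinite(recon_cat) else "kl")
        raise FloatingPointError(f"non-finite ELBO ({bad} term)")
    return comp


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class VaeModel:
    """Trained (or freshly initialized) VAE over a feature subset.

    Holds the weights, the encoding layout (numerical column order and
    per-categorical category lists), the training history, and optionally the
    :class:`~hntwin.preprocess.Normalizer` used so samples can be returned in
    clinical units.
    """

    def __init__(self, schema: FeatureSchema, config: VaeConfig,
                 normalizer: Normalizer | None = None):
        self.schema = schema
        self.config = config
        self.normalizer = normalizer
        self.num_cols = [f.name for f in schema if not f.is_categorical]
        self.cat_cols = [f.name for f in schema if f.is_categorical]
        self.cat_levels = {c: list(schema[c].categories) for c in self.cat_cols}
        self.input_dim = len(self.num_cols) + sum(
            len(v) for v in self.cat_levels.values())
        self.history: list[ElboComponents] = []
        self.params: dict[str, np.ndarray] = {}
        self._init_weights(np.random.default_rng(config.seed))

    # -- layout ------------------------------------------------------------
    def encode_frame(self, cohort: Cohort) -> tuple[np.ndarray, list[np.ndarray]]:
        """Cohort (imputed, normalized) -> (numeric matrix, label arrays)."""
        df = cohort.values
        xn = df[self.num_cols].to_numpy(dtype=float) if self.num_cols else \
            np.zeros((len(df), 0))
        labels = []
        for c in self.cat_cols:
            levels = self.cat_levels[c]
            idx = pd.Categorical(df[c], categories=levels).codes
            if (idx < 0).any():
                raise ValueError(f"undeclared category in column {c!r}")
            labels.append(idx.astype(int))
        return xn, labels

    def _stack_input(self, xn: np.ndarray, labels: list[np.ndarray]) -> np.ndarray:
        parts = [xn]
        for c, idx in zip(self.cat_cols, labels):
            onehot = np.eye(len(self.cat_levels[c]))[idx]
            parts.append(onehot)
        return np.concatenate(parts, axis=1)

    # -- weights -----------------------------------------------------------
    def _init_weights(self, rng: np.random.Generator) -> None:
        h1, h2 = self.config.hidden_layers
        L = self.config.latent_dim
        p = len(self.num_cols)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        P = self.params
        P["enc_W1"], P["enc_b1"] = glorot(self.input_dim, h1), np.zeros(h1)
        P["enc_W2"], P["enc_b2"] = glorot(h1, h2), np.zeros(h2)
        P["enc_Wmu"], P["enc_bmu"] = glorot(h2, L), np.zeros(L)
        P["enc_Wlv"], P["enc_blv"] = glorot(h2, L), np.zeros(L)
        P["dec_W1"], P["dec_b1"] = glorot(L, h2), np.zeros(h2)
        P["dec_W2"], P["dec_b2"] = glorot(h2, h1), np.zeros(h1)
        P["dec_Wnum"], P["dec_bnum"] = glorot(h1, p), np.zeros(p)
        for k, c in enumerate(self.cat_cols):
            K = len(self.cat_levels[c])
            P[f"dec_Wcat{k}"], P[f"dec_bcat{k}"] = glorot(h1, K), np.zeros(K)

    # -- forward -----------------------------------------------------------
    def encode(self, x: np.ndarray, rng: np.random.Generator,
               sample: bool = True) -> tuple[EncoderOutput, dict]:
        P = self.params
        a1 = x @ P["enc_W1"] + P["enc_b1"]
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ P["enc_W2"] + P["enc_b2"]
        h2 = np.maximum(a2, 0.0)
        mu = h2 @ P["enc_Wmu"] + P["enc_bmu"]
        logvar = h2 @ P["enc_Wlv"] + P["enc_blv"]
        eps = rng.standard_normal(mu.shape) if sample else np.zeros_like(mu)
        z = mu + np.exp(0.5 * logvar) * eps
        cache = {"x": x, "a1": a1, "h1": h1, "a2": a2, "h2": h2, "eps": eps,
                 "logvar": logvar, "mu": mu}
        return EncoderOutput(mu, logvar, z), cache

    def decode(self, z: np.ndarray) -> tuple[dict, dict]:
        P = self.params
        a1 = z @ P["dec_W1"] + P["dec_b1"]
        d1 = np.maximum(a1, 0.0)
        a2 = d1 @ P["dec_W2"] + P["dec_b2"]
        d2 = np.maximum(a2, 0.0)
        xn_hat = d2 @ P["dec_Wnum"] + P["dec_bnum"]
        probs = []
        for k in range(len(self.cat_cols)):
            logits = d2 @ P[f"dec_Wcat{k}"] + P[f"dec_bcat{k}"]
            probs.append(_softmax(logits))
        recon = {"numerical": xn_hat, "categorical": probs}
        cache = {"z": z, "a1": a1, "d1": d1, "a2": a2, "d2": d2}
        return recon, cache

    # -- backward ----------------------------------------------------------
    def _backward(self, batch: dict, recon: dict, enc_cache: dict,
                  dec_cache: dict) -> dict[str, np.ndarray]:
        P = self.params
        B = max(1, len(dec_cache["z"]))
        kw = self.config.kl_weight
        grads: dict[str, np.ndarray] = {}

        # decoder output heads
        xn = batch["numerical"]
        g_xn = 2.0 * (recon["numerical"] - xn) / B
        d2 = dec_cache["d2"]
        g_d2 = g_xn @ P["dec_Wnum"].T
        grads["dec_Wnum"] = d2.T @ g_xn
        grads["dec_bnum"] = g_xn.sum(axis=0)
        for k in range(len(self.cat_cols)):
            probs = recon["categorical"][k]
            onehot = np.eye(probs.shape[1])[batch["categorical"][k]]
            g_logits = (probs - onehot) / B
            g_d2 += g_logits @ P[f"dec_Wcat{k}"].T
            grads[f"dec_Wcat{k}"] = d2.T @ g_logits
            grads[f"dec_bcat{k}"] = g_logits.sum(axis=0)

        # decoder trunk
        g_a2 = g_d2 * (dec_cache["a2"] > 0)
        grads["dec_W2"] = dec_cache["d1"].T @ g_a2
        grads["dec_b2"] = g_a2.sum(axis=0)
        g_d1 = g_a2 @ P["dec_W2"].T
        g_a1 = g_d1 * (dec_cache["a1"] > 0)
        grads["dec_W1"] = dec_cache["z"].T @ g_a1
        grads["dec_b1"] = g_a1.sum(axis=0)
        g_z = g_a1 @ P["dec_W1"].T

        # reparameterization + KL
        mu, logvar, eps = enc_cache["mu"], enc_cache["logvar"], enc_cache["eps"]
        g_mu = g_z + kw * mu / B
        g_lv = (g_z * eps * 0.5 * np.exp(0.5 * logvar)
                + kw * 0.5 * (np.exp(logvar) - 1.0) / B)

        # encoder
        h2 = enc_cache["h2"]
        grads["enc_Wmu"] = h2.T @ g_mu
        grads["enc_bmu"] = g_mu.sum(axis=0)
        grads["enc_Wlv"] = h2.T @ g_lv
        grads["enc_blv"] = g_lv.sum(axis=0)
        g_h2 = g_mu @ P["enc_Wmu"].T + g_lv @ P["enc_Wlv"].T
        g_a2e = g_h2 * (enc_cache["a2"] > 0)
        grads["enc_W2"] = enc_cache["h1"].T @ g_a2e
        grads["enc_b2"] = g_a2e.sum(axis=0)
        g_h1 = g_a2e @ P["enc_W2"].T
        g_a1e = g_h1 * (enc_cache["a1"] > 0)
        grads["enc_W1"] = enc_cache["x"].T @ g_a1e
        grads["enc_b1"] = g_a1e.sum(axis=0)
        return grads

    def loss_and_grads(self, batch: dict, rng: np.random.Generator
                       ) -> tuple[ElboComponents, dict[str, np.ndarray]]:
        x = self._stack_input(batch["numerical"], batch["categorical"])
        enc, enc_cache = self.encode(x, rng)
        recon, dec_cache = self.decode(enc.z)
        comp = elbo_loss(batch, recon, enc.mu, enc.logvar, self.config)
        grads = self._backward(batch, recon, enc_cache, dec_cache)
        return comp, grads

    # -- persistence -------------------------------------------------------
    @staticmethod
    def _sidecars(path) -> tuple[Path, Path]:
        base = Path(path)
        return (base.parent / (base.name + ".npz"),
                base.parent / (base.name + ".json"))

    def save(self, path) -> None:
        npz_path, json_path = self._sidecars(path)
        np.savez(npz_path, **self.params)
        meta = {
            "config": asdict(self.config),
            "schema": json.loads(self.schema.to_json()),
            "normalizer": (json.loads(self.normalizer.to_json())
                           if self.normalizer else None),
        }
        json_path.write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "VaeModel":
        npz_path, json_path = cls._sidecars(path)
        meta = json.loads(json_path.read_text())
        cfg = meta["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        config = VaeConfig(**cfg)
        schema = FeatureSchema.from_json(json.dumps(meta["schema"]))
        norm = (Normalizer.from_json(json.dumps(meta["normalizer"]))
                if meta["normalizer"] else None)
        model = cls(schema, config, norm)
        with np.load(npz_path) as data:
            model.params = {k: data[k] for k in data.files}
        return model


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray],
             b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_vae(train: Cohort, config: VaeConfig, schema: FeatureSchema,
              normalizer: Normalizer | None = None
              ) -> tuple[VaeModel, list[ElboComponents]]:
    """Fit the VAE on an imputed, normalized training cohort.

    Seed-reproducible; the returned history holds per-epoch mean loss
    components.  Aborts on divergence with the offending epoch index.
    """
    sub = schema.subset([c for c in train.columns])
    model = VaeModel(sub, config, normalizer)
    xn, labels = model.encode_frame(train)
    n = len(train.values)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = {"numerical": xn[idx],
                     "categorical": [lab[idx] for lab in labels]}
            try:
                comp, grads = model.loss_and_grads(batch, rng)
            except FloatingPointError as exc:
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: {exc}") from exc
            opt.step(model.params, grads)
            sums += (comp.recon_numerical, comp.recon_categorical, comp.kl)
            batches += 1
        model.history.append(
            ElboComponents(*(sums / max(1, batches)), config.kl_weight))
    return model, model.history


def sample_patients(model: VaeModel, n: int, seed: int = 0,
                    argmax_categories: bool = False) -> Cohort:
    """Draw ``n`` synthetic patients from the prior and decode them.

    Numeric outputs are denormalized (when the model holds a normalizer) and
    clipped to schema bounds; categorical outputs are sampled from the
    decoder probabilities (or taken as the argmax).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.latent_dim))
    recon, _ = model.decode(z)
    data: dict[str, np.ndarray] = {}
    xn = recon["numerical"]
    for j, col in enumerate(model.num_cols):
        vals = xn[:, j]
        if model.normalizer is not None and col in model.normalizer.means:
            vals = model.normalizer.invert_series(col, vals)
        spec = model.schema[col]
        if spec.bounds is not None:
            lo, hi = spec.bounds
            vals = np.clip(vals, lo if lo is not None else -np.inf,
                           hi if hi is not None else np.inf)
        if spec.integer:
            vals = np.round(vals)
        data[col] = vals
    for k, col in enumerate(model.cat_cols):
        probs = recon["categorical"][k]
        levels = np.asarray(model.cat_levels[col], dtype=object)
        if argmax_categories:
            idx = probs.argmax(axis=1)
        else:
            u = rng.random((n, 1))
            idx = (probs.cumsum(axis=1) < u).sum(axis=1)
            idx = np.clip(idx, 0, len(levels) - 1)
        data[col] = levels[idx]
    ids = pd.Index([f"V{i:05d}" for i in range(n)], name="patient_id")
    df = pd.DataFrame(index=ids)
    for col in model.schema.names:
        df[col] = data[col]
    return Cohort(df)
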