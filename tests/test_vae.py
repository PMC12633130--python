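"""VAE: ELBO closed forms against oracles, backprop correctness, training
progress, determinism, and sampling legality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import norm as normal

import hntwin as h
from hntwin import evaluation
from hntwin.vae import (
    VaeConfig,
    VaeModel,
    elbo_loss,
    kl_standard_normal,
    sample_patients,
    train_vae,
)


def kl_numeric_oracle(mu: float, sigma: float) -> float:
    """KL(N(mu, sigma^2) || N(0,1)) by numerical integration."""
    p = lambda x: normal.pdf(x, mu, sigma)
    integrand = lambda x: p(x) * (normal.logpdf(x, mu, sigma)
                                  - normal.logpdf(x, 0, 1))
    lo, hi = mu - 12 * sigma, mu + 12 * sigma
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


class TestElbo:
    def test_kl_closed_form_matches_integration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mu = float(rng.uniform(-3, 3))
            logvar = float(rng.uniform(-2, 2))
            closed = kl_standard_normal(np.array([[mu]]),
                                        np.array([[logvar]]))
            oracle = kl_numeric_oracle(mu, np.exp(logvar / 2))
            assert abs(closed - oracle) < 1e-6

    def test_perfect_reconstruction_standard_latent_is_zero(self):
        cfg = VaeConfig()
        batch = {"numerical": np.array([[1.0, 2.0]]), "categorical": []}
        recon = {"numerical": np.array([[1.0, 2.0]]), "categorical": []}
        comp = elbo_loss(batch, recon, np.zeros((1, 2)), np.zeros((1, 2)), cfg)
        assert comp.recon_numerical == 0.0 and comp.kl == 0.0

    def test_unit_mean_scalar_latent_kl_is_half(self):
        kl = kl_standard_normal(np.array([[1.0]]), np.array([[0.0]]))
        assert abs(kl - 0.5) < 1e-12

    def test_categorical_cross_entropy_by_hand(self):
        cfg = VaeConfig()
        batch = {"numerical": np.zeros((1, 0)),
                 "categorical": [np.array([2])]}
        recon = {"numerical": np.zeros((1, 0)),
                 "categorical": [np.array([[0.5, 0.25, 0.25]])]}
        comp = elbo_loss(batch, recon, np.zeros((1, 1)), np.zeros((1, 1)), cfg)
        assert abs(comp.recon_categorical - (-np.log(0.25))) < 1e-12

    def test_non_finite_loss_raises(self):
        cfg = VaeConfig()
        batch = {"numerical": np.array([[0.0]]), "categorical": []}
        recon = {"numerical": np.array([[np.inf]]), "categorical": []}
        with pytest.raises(FloatingPointError):
            elbo_loss(batch, recon, np.zeros((1, 1)), np.zeros((1, 1)), cfg)

    @given(st.floats(-3, 3), st.floats(-2, 2))
    def test_kl_nonnegative(self, mu, logvar):
        assert kl_standard_normal(np.array([[mu]]),
                                  np.array([[logvar]])) >= -1e-12


class _FixedEps:
    """Deterministic stand-in for the reparameterization noise source."""

    def __init__(self, eps):
        self.eps = eps

    def standard_normal(self, shape):
        return self.eps


class TestBackprop:
    def test_gradients_match_finite_differences(self, schema, ptf_prepared):
        _, normalized, norm = ptf_prepared
        cfg = VaeConfig(hidden_layers=(8, 8), latent_dim=3, seed=0)
        model = VaeModel(schema.subset(normalized.columns), cfg, norm)
        xn, labels = model.encode_frame(normalized)
        batch = {"numerical": xn[:16],
                 "categorical": [lab[:16] for lab in labels]}
        eps = np.random.default_rng(5).standard_normal((16, cfg.latent_dim))
        _, grads = model.loss_and_grads(batch, _FixedEps(eps))
        step = 1e-6
        for key in ("enc_W1", "enc_Wmu", "enc_Wlv", "dec_W1", "dec_Wnum",
                    "dec_Wcat0", "enc_b2", "dec_b2"):
            W = model.params[key]
            idx = (0, 0) if W.ndim == 2 else (0,)
            W[idx] += step
            up, _ = model.loss_and_grads(batch, _FixedEps(eps))
            W[idx] -= 2 * step
            down, _ = model.loss_and_grads(batch, _FixedEps(eps))
            W[idx] += step
            numeric = (up.total - down.total) / (2 * step)
            assert abs(numeric - grads[key][idx]) < 1e-5, key


class TestTraining:
    def test_loss_decreases_over_training(self, trained_vae):
        _, history = trained_vae
        assert history[-1].total < history[0].total

    def test_same_seed_identical_final_loss(self, schema, ptf_prepared):
        _, normalized, norm = ptf_prepared
        sub = schema.subset(normalized.columns)
        cfg = VaeConfig(epochs=30, seed=7)
        _, h1 = train_vae(normalized, cfg, sub, normalizer=norm)
        _, h2 = train_vae(normalized, cfg, sub, normalizer=norm)
        assert h1[-1].total == h2[-1].total

    def test_zero_kl_weight_still_reduces_reconstruction(self, schema,
                                                         ptf_prepared):
        _, normalized, norm = ptf_prepared
        sub = schema.subset(normalized.columns)
        cfg = VaeConfig(epochs=60, seed=7, kl_weight=0.0)
        _, hist = train_vae(normalized, cfg, sub, normalizer=norm)
        recon0 = hist[0].recon_numerical + hist[0].recon_categorical
        recon1 = hist[-1].recon_numerical + hist[-1].recon_categorical
        assert recon1 < recon0
        assert hist[-1].total == pytest.approx(recon1)  # KL excluded


class TestSampling:
    def test_sample_count_and_ptf_columns_only(self, schema, trained_vae):
        model, _ = trained_vae
        synth = sample_patients(model, 500, seed=1)
        assert len(synth) == 500
        assert synth.columns == schema.group_names("PTF")

    def test_empty_sample(self, trained_vae):
        model, _ = trained_vae
        assert len(sample_patients(model, 0, seed=1)) == 0

    def test_samples_legal_under_schema(self, schema, trained_vae):
        model, _ = trained_vae
        synth = sample_patients(model, 300, seed=2)
        assert h.validate(synth, schema).ok

    def test_fidelity_improves_with_training(self, schema, ptf_prepared,
                                             trained_vae, untrained_vae):
        ptf_raw, _, _ = ptf_prepared
        model, _ = trained_vae
        synth_t = sample_patients(model, 1000, seed=9)
        synth_u = sample_patients(untrained_vae, 1000, seed=9)
        rep_t = evaluation.fidelity_report(ptf_raw, synth_t, schema)
        rep_u = evaluation.fidelity_report(ptf_raw, synth_u, schema)
        assert rep_t.mean_distance < rep_u.mean_distance
        better = sum(rep_t.per_feature[k] < rep_u.per_feature[k]
                     for k in rep_t.per_feature)
        assert better >= 0.9 * len(rep_t.per_feature)

    def test_checkpoint_round_trip(self, trained_vae, tmp_path):
        model, _ = trained_vae
        model.save(tmp_path / "vae.ckpt")
        back = VaeModel.load(tmp_path / "vae.ckpt")
        a = sample_patients(model, 50, seed=3)
        b = sample_patients(back, 50, seed=3)
        assert a.equals(b)
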