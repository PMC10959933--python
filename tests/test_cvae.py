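"""Conditional VAE: architecture audit, sampler, losses, schedule, training."""

import numpy as np
import pytest

from fovecast import cvae
from fovecast.cvae import (
    CVAE,
    PerceptualLoss,
    VAEConfig,
    VAEState,
    bce_loss,
    beta_schedule,
    kld,
    ms_ssim,
    sample,
    vae_loss,
)
from fovecast.nn import Tensor


@pytest.fixture(scope="module")
def tiny_cfg():
    return VAEConfig(
        image_size=32, base_channels=4, latent_dim=8, batch_size=4,
        max_epochs=4, recon_switch_epoch=4, kld_warmup_epochs=2, patience=6, seed=0,
    )


@pytest.fixture(scope="module")
def tiny_model(tiny_cfg):
    return CVAE(tiny_cfg)


class TestArchitecture:
    def test_encoder_spatial_reduction(self):
        """Four 2x pooling stages take 224 to 14 pixels."""
        cfg = VAEConfig()
        assert cfg.reduced_size == 14
        assert 224 // 2**4 == 14

    def test_channel_doubling_and_kernel_geometry(self, tiny_model, tiny_cfg):
        c = tiny_cfg.base_channels
        chans = [conv.weight.data.shape[0] for conv in tiny_model.enc_convs]
        assert chans == [c, 2 * c, 4 * c, 8 * c]
        for conv in tiny_model.enc_convs + tiny_model.dec_convs:
            assert conv.weight.data.shape[-2:] == (3, 3)
            assert conv.pad == 1

    def test_five_fc_layers_each_side(self, tiny_model):
        # encoder: three shared layers + parallel mu/logvar heads = depth 5
        assert len(tiny_model.enc_fcs) == 3
        assert tiny_model.fc_mu.weight.data.shape == tiny_model.fc_logvar.weight.data.shape
        assert len(tiny_model.dec_fcs) == 5

    def test_condition_enters_first_fc(self, tiny_model, tiny_cfg):
        flat = tiny_cfg.flat_dim
        assert tiny_model.enc_fcs[0].weight.data.shape[0] == flat + 4
        assert tiny_model.dec_fcs[0].weight.data.shape[0] == tiny_cfg.latent_dim + 4

    def test_encode_output_shapes_and_condition_sensitivity(self, tiny_model, rng):
        tiny_model.eval()
        x = Tensor(rng.uniform(0, 1, (2, 1, 32, 32)))
        c0 = Tensor(np.tile([1.0, 0, 0, 0], (2, 1)))
        c3 = Tensor(np.tile([0, 0, 0, 1.0], (2, 1)))
        mu0, lv0 = tiny_model.encode(x, c0)
        mu3, _ = tiny_model.encode(x, c3)
        assert mu0.shape == (2, 8) and lv0.shape == (2, 8)
        assert not np.allclose(mu0.data, mu3.data)  # condition reaches the code

    def test_decode_range_and_shape(self, tiny_model, rng):
        tiny_model.eval()
        z = Tensor(rng.normal(size=(2, 8)))
        c = Tensor(np.tile([1.0, 0, 0, 0], (2, 1)))
        out = tiny_model.decode(z, c)
        assert out.shape == (2, 1, 32, 32)
        assert 0 < out.data.min() and out.data.max() < 1

    def test_wrong_input_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode(Tensor(np.zeros((1, 1, 16, 16))), Tensor(np.zeros((1, 4))))


class TestSampler:
    def test_degenerate_variance_returns_mean(self):
        mu = np.array([1.0, -2.0])
        z = sample(mu, np.full(2, -745.0), seed=0)  # exp underflows to 0
        assert np.allclose(z, mu)

    def test_seeded_reproducibility(self):
        mu, lv = np.zeros(4), np.zeros(4)
        assert np.array_equal(sample(mu, lv, seed=5), sample(mu, lv, seed=5))

    def test_moments_match_parameters(self):
        mu = np.array([0.5])
        logvar = np.array([np.log(4.0)])
        draws = np.array([sample(mu, logvar, seed=s)[0] for s in range(10_000)])
        se_mean = 2.0 / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se_mean
        assert abs(draws.var() - 4.0) < 4.0 * 3 * np.sqrt(2 / len(draws))


class TestKLD:
    def test_prior_match_is_zero(self):
        assert kld(np.zeros(4), np.zeros(4)).item() == pytest.approx(0.0)

    def test_unit_mean_scalar_case(self):
        assert kld(np.array([1.0]), np.array([0.0])).item() == pytest.approx(0.5)

    def test_nonnegative_over_random_probes(self, rng):
        for _ in range(100):
            mu = rng.normal(size=6)
            lv = rng.normal(size=6)
            assert kld(mu, lv).item() >= -1e-12


class TestLosses:
    def test_perfect_reconstruction_floors(self, rng):
        x = np.clip(rng.uniform(0.05, 0.95, (1, 1, 32, 32)), 0, 1)
        t = Tensor(x)
        assert ms_ssim(t, Tensor(x.copy())).item() == pytest.approx(1.0, abs=1e-9)
        assert PerceptualLoss(seed=1)(t, Tensor(x.copy())).item() == pytest.approx(0.0)
        entropy = -(x * np.log(x + 1e-7) + (1 - x) * np.log(1 - x + 1e-7)).mean()
        assert bce_loss(t, Tensor(x.copy())).item() == pytest.approx(entropy, rel=1e-9)

    def test_bce_domain_enforced(self):
        with pytest.raises(ValueError):
            bce_loss(Tensor(np.array([[1.5]])), Tensor(np.array([[0.5]])))

    def test_beta_schedule_ramp(self):
        assert beta_schedule(0, 50) == 0.0
        assert beta_schedule(50, 50) == 1.0
        assert beta_schedule(120, 50) == 1.0
        betas = [beta_schedule(e, 50) for e in range(120)]
        assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))

    def test_recon_family_switches_at_configured_epoch(self, rng):
        cfg = VAEConfig(
            image_size=32, base_channels=4, latent_dim=8,
            max_epochs=10, recon_switch_epoch=5, kld_warmup_epochs=2,
        )
        x = Tensor(np.clip(rng.uniform(0.1, 0.9, (1, 1, 32, 32)), 0, 1))
        y = Tensor(np.clip(rng.uniform(0.1, 0.9, (1, 1, 32, 32)), 0, 1))
        mu, lv = Tensor(rng.normal(size=(1, 8))), Tensor(rng.normal(size=(1, 8)))
        perc = PerceptualLoss(seed=2)
        _, at_switch = vae_loss(x, y, mu, lv, 5, cfg, perc)
        _, after = vae_loss(x, y, mu, lv, 6, cfg, perc)
        assert at_switch["family"] == "bce+msssim"
        assert after["family"] == "perceptual"
        assert at_switch["kld"] == pytest.approx(after["kld"])  # only recon changes

    def test_ms_ssim_penalises_mismatch(self, rng):
        x = np.clip(rng.uniform(0.2, 0.8, (1, 1, 64, 64)), 0, 1)
        y = np.roll(x, 8, axis=-1)
        assert ms_ssim(Tensor(x), Tensor(y)).item() < 0.99


@pytest.fixture(scope="module")
def trained():
    """A short run on a toy band-translation task."""
    n = 24
    pre = np.zeros((n, 32, 32))
    post = np.zeros((n, 32, 32))
    for i in range(n):
        row = 8 + (i % 4)
        pre[i, row : row + 8] = 0.8
        post[i, row + 2 : row + 10] = 0.8
    cond = (np.arange(n) % 4).astype(int)
    cfg = VAEConfig(
        image_size=32, base_channels=4, latent_dim=8, batch_size=8,
        max_epochs=6, recon_switch_epoch=6, kld_warmup_epochs=3,
        learning_rate=1e-3, patience=10, seed=0,
    )
    state = cvae.train((pre, post, cond, None), (pre[:8], post[:8], cond[:8]), cfg)
    return state, (pre, post, cond)


class TestTraining:
    def test_history_recorded_per_epoch(self, trained):
        state, _ = trained
        assert len(state.history) == 6
        assert {"epoch", "train_loss", "val_loss", "beta"} <= set(state.history[0])

    def test_best_epoch_is_argmin_of_validation_loss(self, trained):
        state, _ = trained
        losses = [h["val_loss"] for h in state.history]
        assert state.best_epoch == int(np.argmin(losses))

    def test_training_determinism(self, trained):
        state, (pre, post, cond) = trained
        cfg = state.config
        again = cvae.train((pre, post, cond, None), (pre[:8], post[:8], cond[:8]), cfg)
        assert [h["val_loss"] for h in again.history] == [
            h["val_loss"] for h in state.history
        ]

    def test_predict_deterministic_and_valid(self, trained):
        state, (pre, _, cond) = trained
        a = cvae.predict(pre[0], int(cond[0]), state)
        b = cvae.predict(pre[0], int(cond[0]), state)
        assert np.array_equal(a, b)
        assert a.shape == (32, 32)
        assert 0 <= a.min() and a.max() <= 1

    def test_untrained_state_refuses_prediction(self, tiny_cfg):
        model_state = cvae.untrained_state(tiny_cfg)
        model_state.trained = False
        with pytest.raises(ValueError):
            cvae.predict(np.zeros((32, 32)), 0, model_state)

    def test_empty_dataset_rejected(self, tiny_cfg):
        empty = (np.zeros((0, 32, 32)),) * 2 + (np.zeros(0, dtype=int), None)
        with pytest.raises(ValueError):
            cvae.train(empty, empty[:3], tiny_cfg)

    def test_state_save_load_round_trip(self, trained, tmp_path):
        state, (pre, _, cond) = trained
        state.save(tmp_path / "model")
        back = VAEState.load(tmp_path / "model")
        assert back.best_epoch == state.best_epoch
        assert np.array_equal(
            cvae.predict(pre[0], int(cond[0]), back),
            cvae.predict(pre[0], int(cond[0]), state),
        )
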