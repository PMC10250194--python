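"""Frequency marching, band-limiting, auto-decoder inference, training loop."""

import numpy as np
import pytest

import flexrec as fr
from flexrec.flow_model import FlowGenerator
from flexrec.forward_model import ctf_multiplier, CTFParams
from flexrec.model import default_mesh, FlexModel
from flexrec.training import (
    bandlimit_volume,
    frequency_march,
    infer_latents,
    train,
    TrainConfig,
)


def quiet_config(**kw):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TrainConfig(**kw)


class TestFrequencyMarch:
    def test_epoch_zero_is_start_shell(self):
        assert frequency_march(0, (4, 16, 10)) == 4

    def test_after_ramp_is_end_shell(self):
        assert frequency_march(10, (4, 16, 10)) == 16
        assert frequency_march(50, (4, 16, 10)) == 16

    def test_monotone_nondecreasing(self):
        shells = [frequency_march(e, (4, 16, 10)) for e in range(40)]
        assert all(b >= a for a, b in zip(shells, shells[1:]))


class TestBandlimit:
    def test_nyquist_shell_is_identity(self, rng):
        vol = fr.CanonicalVolume(rng.standard_normal((16, 16, 16)), 1.0)
        out = bandlimit_volume(vol, 8)
        assert np.allclose(out.data, vol.data, atol=1e-12)

    def test_idempotent_at_same_shell(self, rng):
        vol = fr.CanonicalVolume(rng.standard_normal((16, 16, 16)), 1.0)
        once = bandlimit_volume(vol, 5)
        twice = bandlimit_volume(once, 5)
        assert np.max(np.abs(twice.data - once.data)) < 1e-12

    def test_power_beyond_rolloff_is_zero(self, rng):
        vol = fr.CanonicalVolume(rng.standard_normal((32, 32, 32)), 1.0)
        out = bandlimit_volume(vol, 8)
        spec = np.abs(np.fft.fftn(out.data)) ** 2
        f = np.fft.fftfreq(32) * 32
        r = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2)
        assert spec[r > 10 + 1e-9].max() < 1e-20 * spec.max()

    def test_invalid_shell_rejected(self, rng):
        vol = fr.CanonicalVolume(rng.standard_normal((16, 16, 16)), 1.0)
        with pytest.raises(ValueError):
            bandlimit_volume(vol, 0)
        with pytest.raises(ValueError):
            bandlimit_volume(vol, 9)


class TestInferLatents:
    def _problem(self, rng, sigma=0.0):
        """Images generated at known z* from a generator with real flows."""
        from tests.conftest import gaussian_volume
        from flexrec.forward_model import predict_image

        vol = gaussian_volume(16, [((8, 8, 8), 2.0, 1.0), ((11, 6, 9), 1.5, 0.6)])
        mask = fr.make_soft_mask(vol, 0.05, dilation_vox=2)
        mesh = fr.generate_regular_mesh(mask, 5.0, 1.0)
        gen = FlowGenerator(k=1, n_v=mesh.n_vertices, n_layers=2, hidden=16,
                            init_scale=0.3, seed=11)
        z_star = np.array([1.2, -0.7, 0.3])
        imgs = []
        from scipy.spatial.transform import Rotation

        rots = np.stack(
            [Rotation.random(random_state=np.random.RandomState(i)).as_matrix() for i in range(3)]
        )
        for i, zs in enumerate(z_star):
            img = predict_image(vol, gen, mesh, np.array([zs]), rots[i], (0, 0), None)
            imgs.append(img + sigma * rng.standard_normal(img.shape))
        return vol, mesh, gen, np.array(imgs), rots, z_star

    def test_noiseless_recovery_matches_grid_oracle(self, rng):
        vol, mesh, gen, imgs, rots, z_star = self._problem(rng)
        shifts = np.zeros((3, 2))
        z = infer_latents(imgs, vol, gen, mesh, np.zeros((3, 1)), rots, shifts, None,
                          cycles=3, steps=12)
        # oracle: dense 1-D grid over the search interval
        from flexrec.forward_model import predict_image

        for i in range(3):
            grid = np.linspace(-4, 4, 401)
            vals = [
                0.5 * np.sum((imgs[i] - predict_image(vol, gen, mesh, np.array([t]),
                                                      rots[i], (0, 0), None)) ** 2)
                + 0.5 * t * t
                for t in grid
            ]
            z_oracle = grid[int(np.argmin(vals))]
            assert abs(z[i, 0] - z_oracle) < 0.05

    def test_objective_never_increases(self, rng):
        vol, mesh, gen, imgs, rots, z_star = self._problem(rng, sigma=0.5)
        shifts = np.zeros((3, 2))

        def obj(zb):
            from flexrec.forward_model import predict_image

            return sum(
                0.5 * np.sum((imgs[i] - predict_image(vol, gen, mesh, zb[i], rots[i],
                                                      (0, 0), None)) ** 2)
                + 0.5 * np.sum(zb[i] ** 2)
                for i in range(3)
            )

        z0 = rng.uniform(-2, 2, (3, 1))
        for method in ("coordinate_descent", "gradient"):
            z1 = infer_latents(imgs, vol, gen, mesh, z0.copy(), rots, shifts, None,
                               method=method, cycles=1, steps=6)
            assert obj(z1) <= obj(z0) + 1e-9

    def test_prior_pulls_to_zero_when_data_is_flat(self, rng):
        # V = 0: the data term is independent of z, so the prior wins
        vol = fr.CanonicalVolume(np.zeros((16, 16, 16)), 1.0)
        mask_data = np.zeros((16, 16, 16))
        mask_data[4:12, 4:12, 4:12] = 1
        mesh = fr.generate_regular_mesh(fr.MaskVolume(mask_data), 7.0, 1.0)
        gen = FlowGenerator(k=1, n_v=mesh.n_vertices, init_scale=0.5, seed=0)
        imgs = np.zeros((2, 16, 16))
        rots = np.stack([np.eye(3)] * 2)
        z = infer_latents(imgs, vol, gen, mesh, np.array([[2.0], [-3.0]]), rots,
                          np.zeros((2, 2)), None, cycles=2, steps=10)
        assert np.max(np.abs(z)) < 0.05


@pytest.fixture(scope="module")
def tiny_run(toy_spec):
    ds = fr.generate_dataset(toy_spec, m=24, snr=0.5, seed=9)
    mesh = default_mesh(ds.volume, element_size_A=24.0)
    cfg = quiet_config(k_latent=1, batch_size=24, n_epochs=6, warmup_epochs=2,
                       latent_cycles=1, latent_steps=4, seed=5, lr_theta=1e-3,
                       freq_start_shell=4, freq_end_shell=8, freq_ramp_epochs=3,
                       early_stop_patience=100)
    state = train(ds.particles, ds.volume, mesh, cfg)
    return ds, mesh, cfg, state


class TestTrainLoop:

    def test_trace_structure(self, tiny_run):
        _, _, cfg, state = tiny_run
        assert len(state.trace) == cfg.n_epochs
        assert list(state.trace.phase[:2]) == ["warmup", "warmup"]
        assert set(state.trace.phase[2:]) == {"volume", "flow"}
        assert state.trace.bandlimit.is_monotonic_increasing

    def test_identical_seeds_identical_traces(self, toy_spec):
        ds = fr.generate_dataset(toy_spec, m=16, snr=0.5, seed=9)
        mesh = default_mesh(ds.volume, element_size_A=24.0)
        cfg = quiet_config(k_latent=1, batch_size=16, n_epochs=4, warmup_epochs=2,
                           latent_cycles=1, latent_steps=4, seed=5,
                           freq_start_shell=4, freq_end_shell=8, freq_ramp_epochs=2)
        a = train(ds.particles, ds.volume, mesh, cfg)
        b = train(ds.particles, ds.volume, mesh, cfg)
        assert np.array_equal(a.trace.total.to_numpy(), b.trace.total.to_numpy())
        assert np.array_equal(a.latents, b.latents)
        for wa, wb in zip(a.generator.weights, b.generator.weights):
            assert np.array_equal(wa, wb)

    def test_zero_deformation_mask_exactly_honored(self, toy_spec):
        ds = fr.generate_dataset(toy_spec, m=12, snr=0.5, seed=4)
        mesh = default_mesh(ds.volume, element_size_A=24.0)
        # freeze the static-domain half of the box
        zmask = np.zeros((32, 32, 32))
        zmask[:, :, :16] = 1.0
        cfg = quiet_config(k_latent=1, batch_size=12, n_epochs=4, warmup_epochs=2,
                           latent_cycles=1, latent_steps=4, seed=1,
                           freq_start_shell=4, freq_end_shell=8, freq_ramp_epochs=2)
        model = FlexModel(ds.particles, ds.volume, mesh=mesh, config=cfg,
                          zero_deformation_mask=fr.MaskVolume(zmask, role="zero_deformation"))
        res = model.fit()
        frozen = model.mesh.frozen_vertices
        assert frozen.any()
        flows = res.generator.forward(np.array([[2.0], [-1.0], [0.3]]))
        assert np.all(flows[:, frozen, :] == 0.0)

    def test_external_latents_fixed_during_warmup(self, toy_spec):
        ds = fr.generate_dataset(toy_spec, m=12, snr=0.5, seed=4)
        mesh = default_mesh(ds.volume, element_size_A=24.0)
        ds.particles.latents = ds.latents_true.copy()
        cfg = quiet_config(k_latent=1, batch_size=12, n_epochs=2, warmup_epochs=2,
                           latent_cycles=1, latent_steps=4, seed=1,
                           freq_start_shell=4, freq_end_shell=8, freq_ramp_epochs=2)
        state = train(ds.particles, ds.volume, mesh, cfg)
        assert np.array_equal(state.latents, ds.latents_true)

    def test_warmup_loss_nonincreasing_within_tolerance(self, tiny_run):
        _, _, _, state = tiny_run
        tr = state.trace
        warm = tr[tr.phase == "warmup"].total.to_numpy()
        for a, b in zip(warm, warm[1:]):
            assert b <= a * 1.01  # no epoch-over-epoch increase beyond 1%

    def test_resume_matches_uninterrupted_run(self, toy_spec, tmp_path):
        ds = fr.generate_dataset(toy_spec, m=16, snr=0.5, seed=31)
        mesh = default_mesh(ds.volume, element_size_A=24.0)

        def cfg(n_epochs):
            return quiet_config(k_latent=1, batch_size=16, n_epochs=n_epochs,
                                warmup_epochs=2, latent_cycles=1, latent_steps=4,
                                seed=5, freq_start_shell=4, freq_end_shell=8,
                                freq_ramp_epochs=2, early_stop_patience=100)

        full = train(ds.particles, ds.volume, mesh, cfg(6))
        part = train(ds.particles, ds.volume, mesh, cfg(6), stop_epoch=3)
        # round-trip the partial state through a checkpoint file
        from flexrec.model import load_checkpoint, save_checkpoint

        save_checkpoint(tmp_path / "part.npz", part, mesh, cfg(6))
        loaded, _, _ = load_checkpoint(tmp_path / "part.npz")
        resumed = train(ds.particles, ds.volume, mesh, cfg(6), resume=loaded)
        assert np.array_equal(resumed.trace.total.to_numpy(), full.trace.total.to_numpy())
        assert np.array_equal(resumed.latents, full.latents)
        assert np.array_equal(resumed.volume.data, full.volume.data)
        for wa, wb in zip(resumed.generator.weights, full.generator.weights):
            assert np.array_equal(wa, wb)

    def test_nesterov_optimizer_runs_and_descends(self, toy_spec):
        ds = fr.generate_dataset(toy_spec, m=12, snr=0.5, seed=4)
        mesh = default_mesh(ds.volume, element_size_A=24.0)
        cfg = quiet_config(k_latent=1, batch_size=12, n_epochs=3, warmup_epochs=3,
                           latent_cycles=1, latent_steps=4, seed=1,
                           optimizer="sgd_nesterov", lr_theta=1e-5,
                           freq_start_shell=4, freq_end_shell=8, freq_ramp_epochs=2,
                           early_stop_patience=100)
        state = train(ds.particles, ds.volume, mesh, cfg)
        assert np.all(np.isfinite(state.trace.total))
        assert state.trace.total.iloc[-1] <= state.trace.total.iloc[0] * 1.01

    def test_grid_mismatch_rejected(self, toy_spec):
        ds = fr.generate_dataset(toy_spec, m=4, snr=0.5, seed=4)
        mesh = default_mesh(ds.volume, element_size_A=24.0)
        bad_vol = fr.CanonicalVolume(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError, match="grid"):
            train(ds.particles, bad_vol, mesh, quiet_config(batch_size=4))


class TestConfigValidation:
    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda_rigid=0.0)

    def test_small_batch_warns(self):
        with pytest.warns(UserWarning, match="below the recommended floor"):
            TrainConfig(batch_size=100)

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")
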