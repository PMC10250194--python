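"""Convection, projection, CTF and the end-to-end generative pipeline."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

import flexrec as fr
from flexrec import forward_model as fm
from flexrec.flow_model import FlowGenerator
from tests.conftest import gaussian_volume


def smooth_flow(n, rng, amplitude=1.0, margin=3):
    """Random smooth displacement field, zero within ``margin`` of the edge."""
    d = rng.standard_normal((n, n, n, 3))
    from scipy.ndimage import gaussian_filter

    for c in range(3):
        d[..., c] = gaussian_filter(d[..., c], sigma=2.0)
    d *= amplitude / max(np.abs(d).max(), 1e-12)
    edge = np.zeros((n, n, n), bool)
    edge[margin:-margin, margin:-margin, margin:-margin] = True
    d[~edge] = 0.0
    return d


def splat_oracle(V, disp):
    """Naive triple-loop trilinear forward splat."""
    n = V.shape[0]
    W = np.zeros((n, n, n))
    for z in range(n):
        for y in range(n):
            for x in range(n):
                px, py, pz = x + disp[z, y, x, 0], y + disp[z, y, x, 1], z + disp[z, y, x, 2]
                ix, iy, iz = int(np.floor(px)), int(np.floor(py)), int(np.floor(pz))
                fx, fy, fz = px - ix, py - iy, pz - iz
                for dz in (0, 1):
                    for dy in (0, 1):
                        for dx in (0, 1):
                            xx, yy, zz = ix + dx, iy + dy, iz + dz
                            if 0 <= xx < n and 0 <= yy < n and 0 <= zz < n:
                                w = (
                                    (fx if dx else 1 - fx)
                                    * (fy if dy else 1 - fy)
                                    * (fz if dz else 1 - fz)
                                )
                                W[zz, yy, xx] += w * V[z, y, x]
    return W


class TestConvect:
    def test_zero_displacement_is_identity(self, rng):
        V = rng.standard_normal((16, 16, 16))
        assert np.array_equal(fm.convect(V, np.zeros((16, 16, 16, 3))), V)

    def test_unit_shift_along_x(self, rng):
        V = rng.standard_normal((16, 16, 16))
        d = np.zeros((16, 16, 16, 3))
        d[..., 0] = 1.0
        W = fm.convect(V, d)
        assert np.allclose(W[:, :, 1:], V[:, :, :-1])
        assert np.allclose(W[:, :, 0], 0.0)

    def test_mass_conservation_and_oracle_agreement(self, rng):
        V = rng.standard_normal((16, 16, 16))
        d = smooth_flow(16, rng, amplitude=1.5, margin=3)
        W = fm.convect(V, d)
        assert W.sum() == pytest.approx(V.sum(), rel=1e-9)
        assert np.max(np.abs(W - splat_oracle(V, d))) < 1e-9 * max(1.0, np.abs(W).max())

    def test_divergent_flow_rejected(self):
        d = np.zeros((16, 16, 16, 3))
        d[0, 0, 0, 0] = 10.0
        with pytest.raises(ValueError, match="divergent"):
            fm.convect(np.ones((16, 16, 16)), d)

    def test_tricubic_also_conserves_mass_in_interior(self, rng):
        V = np.zeros((16, 16, 16))
        V[5:11, 5:11, 5:11] = rng.standard_normal((6, 6, 6))
        d = smooth_flow(16, rng, amplitude=1.0, margin=4)
        W = fm.convect(V, d, kernel="tricubic")
        assert W.sum() == pytest.approx(V.sum(), rel=1e-9)

    def test_backward_matches_finite_differences(self, rng):
        n = 10
        V = rng.standard_normal((n, n, n))
        d = rng.standard_normal((n, n, n, 3)) * 0.6
        gW = rng.standard_normal((n, n, n))
        for kernel in ("trilinear", "tricubic"):
            gV, gd = fm.convect_backward(V, d, gW, kernel=kernel)
            # adjoint identity for the V-gradient (convect is linear in V)
            assert np.sum(fm.convect(V, d, kernel=kernel) * gW) == pytest.approx(
                np.sum(V * gV), rel=1e-10
            )
            eps = 1e-6
            for idx in [(4, 5, 6, 0), (2, 7, 3, 2)]:
                dp, dm = d.copy(), d.copy()
                dp[idx] += eps
                dm[idx] -= eps
                fd = (
                    np.sum(fm.convect(V, dp, kernel=kernel) * gW)
                    - np.sum(fm.convect(V, dm, kernel=kernel) * gW)
                ) / (2 * eps)
                assert gd[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestProject:
    def test_constant_cube_projects_to_side_length(self):
        n, s = 24, 10
        V = np.zeros((n, n, n))
        V[7:17, 7:17, 7:17] = 1.0
        img = fm.project(V, np.eye(3))
        assert img[12, 12] == pytest.approx(s)

    def test_inplane_rotation_symmetry(self, rng):
        vol = gaussian_volume(24, [((12, 12, 12), 3.0, 1.0), ((15, 10, 13), 2.0, 0.5)])
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        img0 = fm.project(vol.data, np.eye(3))
        img90 = fm.project(vol.data, R90)
        # rotation is about the center voxel c = N//2: img90[c+b, c+a] must
        # equal img0 at the back-rotated pixel (a, b) -> (b, -a)
        n, c = 24, 12
        a = np.arange(n) - c
        for qy in range(1, n):
            for qx in range(1, n):
                x0, y0 = c + (qy - c), c - (qx - c)
                if 0 <= x0 < n and 0 <= y0 < n:
                    assert img90[qy, qx] == pytest.approx(
                        img0[y0, x0], rel=1e-6, abs=1e-6 * np.abs(img0).max()
                    )

    def test_linearity(self, rng):
        R = Rotation.random(random_state=np.random.RandomState(0)).as_matrix()
        V1, V2 = rng.standard_normal((2, 16, 16, 16))
        a, b = 1.7, -0.4
        lhs = fm.project(a * V1 + b * V2, R)
        rhs = a * fm.project(V1, R) + b * fm.project(V2, R)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_fourier_slice_agreement_tricubic(self):
        n = 32
        c = n // 2
        blobs = [((15.0, 16.5, 17.0), 4.0, 1.0), ((18.0, 14.0, 15.0), 3.5, 0.7)]
        vol = gaussian_volume(n, blobs)
        R = Rotation.from_euler("zyz", [25, 40, 10], degrees=True).as_matrix()
        img = fm.project(vol.data, R, kernel="tricubic")
        # oracle: exact DFT central slice perpendicular to the viewing axis
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        X = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(float) - c
        vals = vol.data.ravel()
        ks = (np.arange(n) - c).astype(float)
        KX, KY = np.meshgrid(ks, ks, indexing="xy")
        P = np.column_stack([KX.ravel(), KY.ravel(), np.zeros(n * n)]) @ R
        sl = np.empty(n * n, complex)
        for lo in range(0, n * n, 128):
            pp = P[lo : lo + 128]
            sl[lo : lo + 128] = np.exp(-2j * np.pi * (pp @ X.T) / n) @ vals
        sl = sl.reshape(n, n)
        img_f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        assert np.linalg.norm(img_f - sl) / np.linalg.norm(sl) < 1e-3

    def test_fourier_slice_agreement_trilinear_coarse(self):
        # the fast trilinear path is accurate only to ~1% on these blobs
        n = 32
        vol = gaussian_volume(n, [((15.0, 16.5, 17.0), 4.0, 1.0)])
        R = Rotation.from_euler("zyz", [25, 40, 10], degrees=True).as_matrix()
        img_tri = fm.project(vol.data, R)
        img_cub = fm.project(vol.data, R, kernel="tricubic")
        assert np.linalg.norm(img_tri - img_cub) / np.linalg.norm(img_cub) < 0.02

    def test_adjoint_identity(self, rng):
        n = 16
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        W = rng.standard_normal((n, n, n))
        g = rng.standard_normal((n, n))
        sh = np.array([0.7, -1.2])
        for kernel in ("trilinear", "tricubic"):
            lhs = np.sum(fm.project(W, R, sh, kernel=kernel) * g)
            rhs = np.sum(W * fm.project_backward(g, R, sh, n, kernel=kernel))
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_shift_moves_image(self):
        vol = gaussian_volume(24, [((12, 12, 12), 2.0, 1.0)])
        img0 = fm.project(vol.data, np.eye(3))
        img_sh = fm.project(vol.data, np.eye(3), (3.0, 0.0))
        assert np.allclose(img_sh[:, 3:], img0[:, :-3], atol=1e-9)


class TestCTF:
    def test_pure_amplitude_contrast_negates(self, rng):
        p = fm.CTFParams(1e-9, 1e-9, 0.0, 300.0, 0.0, 1.0, 0.0)
        img = rng.standard_normal((16, 16))
        assert np.allclose(fm.apply_ctf(img, p, pixel_size=1.0), -img, atol=1e-6)

    def test_first_zero_crossing_matches_chi_root(self):
        # w = 0: CTF(s) = -sin(chi); first zero at chi(s) = pi
        p = fm.CTFParams(15000.0, 15000.0, 0.0, 300.0, 2.7, 0.0, 0.0)
        lam = fm.electron_wavelength_A(300.0)
        cs = 2.7e7

        def chi(s):
            return np.pi * lam * 15000.0 * s**2 - 0.5 * np.pi * cs * lam**3 * s**4

        s_root = brentq(lambda s: chi(s) - np.pi, 1e-4, 0.2)
        n, pix = 512, 0.5
        mult = fm.ctf_multiplier(n, pix, p)
        freqs = np.fft.rfftfreq(n, d=pix)
        row = mult[0]  # along +x axis
        sign_change = np.nonzero(np.diff(np.sign(row[1:])))[0]
        assert len(sign_change) > 0
        i = sign_change[0] + 1
        f0, f1 = freqs[i], freqs[i + 1]
        v0, v1 = row[i], row[i + 1]
        crossing = f0 - v0 * (f1 - f0) / (v1 - v0)
        assert crossing == pytest.approx(s_root, abs=1e-6 + (freqs[1] - freqs[0]) * 0.01)

    def test_applying_twice_squares_spectrum(self, rng):
        p = fm.CTFParams(12000.0, 11000.0, 30.0, 200.0, 2.0, 0.07, 0.0)
        img = rng.standard_normal((32, 32))
        twice = fm.apply_ctf(fm.apply_ctf(img, p, 1.1), p, 1.1)
        mult = fm.ctf_multiplier(32, 1.1, p)
        direct = np.fft.irfft2(np.fft.rfft2(img) * mult**2, s=img.shape)
        assert np.allclose(twice, direct, atol=1e-12)
        # squared multiplier is nonnegative: power at every frequency
        assert np.all(mult**2 >= 0)

    def test_zero_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            fm.ctf_multiplier(16, 0.0, fm.CTFParams(1e4, 1e4))


class TestPredictImage:
    def _setup(self, rng, init_scale=0.5):
        vol = gaussian_volume(16, [((8, 8, 8), 2.0, 1.0), ((11, 6, 9), 1.5, 0.6)])
        mask = fr.make_soft_mask(vol, 0.05, dilation_vox=2)
        mesh = fr.generate_regular_mesh(mask, 5.0, 1.0)
        gen = FlowGenerator(k=1, n_v=mesh.n_vertices, n_layers=2, hidden=8,
                            init_scale=init_scale, seed=4)
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        ctf = fm.CTFParams(12000.0, 12000.0, 0.0, 300.0, 2.7, 0.07)
        return vol, mesh, gen, R, ctf

    def test_zero_flow_equals_rigid_pipeline_bitwise(self, rng):
        vol, mesh, gen, R, ctf = self._setup(rng, init_scale=0.0)
        z = np.array([0.7])
        pred = fm.predict_image(vol, gen, mesh, z, R, (1.0, -2.0), ctf)
        rigid = fm.apply_ctf(
            fm.project(vol.data, R, np.array([1.0, -2.0]) / vol.voxel_size),
            ctf,
            vol.voxel_size,
        )
        assert np.array_equal(pred, rigid)

    def test_matches_compose_by_hand_oracle(self, rng):
        vol, mesh, gen, R, ctf = self._setup(rng)
        z = np.array([1.3])
        pred = fm.predict_image(vol, gen, mesh, z, R, (0.5, 0.25), ctf)
        # compose the pipeline explicitly, stage by stage
        u = gen(np.array([z]))[0]
        disp = mesh.interpolate_flow(u)
        W = fm.convect(vol.data, disp)
        img = fm.project(W, R, np.array([0.5, 0.25]) / vol.voxel_size)
        by_hand = fm.apply_ctf(img, ctf, vol.voxel_size)
        assert np.max(np.abs(pred - by_hand)) < 1e-9

    def test_deterministic(self, rng):
        vol, mesh, gen, R, ctf = self._setup(rng)
        z = np.array([0.4])
        a = fm.predict_image(vol, gen, mesh, z, R, (0, 0), ctf)
        b = fm.predict_image(vol, gen, mesh, z, R, (0, 0), ctf)
        assert np.array_equal(a, b)


class TestDataEnergy:
    def test_exact_prediction_gives_zero(self, rng):
        vol = gaussian_volume(16, [((8, 8, 8), 2.0, 1.0)])
        mask = fr.make_soft_mask(vol, 0.05, dilation_vox=2)
        mesh = fr.generate_regular_mesh(mask, 5.0, 1.0)
        gen = FlowGenerator(k=1, n_v=mesh.n_vertices, init_scale=0.0)
        import pandas as pd

        ctf = pd.DataFrame(
            dict(defocus_u_A=[12000.0], defocus_v_A=[12000.0], astig_angle_deg=[0.0],
                 voltage_kV=[300.0], cs_mm=[2.7], amplitude_contrast=[0.07],
                 phase_shift_rad=[0.0])
        )
        img = fm.predict_image(vol, gen, mesh, np.zeros(1), np.eye(3), (0, 0),
                               fm.CTFParams.from_row(ctf.iloc[0]))
        ps = fr.ParticleSet(images=img[None], rotations=np.eye(3)[None],
                            shifts_A=np.zeros((1, 2)), ctf=ctf, pixel_size=vol.voxel_size)
        e = fm.data_energy(ps, vol, gen, mesh, np.zeros((1, 1)))
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_half_sum_of_squares(self):
        # 4x4 image of ones against a zero prediction: E = 1/2 * 16 = 8
        resid = np.ones((4, 4))
        assert 0.5 * np.sum(resid**2) == 8.0

    def test_batch_additivity(self, rng, small_dataset):
        ds = small_dataset
        from flexrec.model import default_mesh

        mesh = default_mesh(ds.volume, element_size_A=24.0)
        gen = FlowGenerator(k=1, n_v=mesh.n_vertices, seed=0)
        sub = ds.particles.subset(np.arange(3))
        z = rng.standard_normal((3, 1))
        total = fm.data_energy(sub, ds.volume, gen, mesh, z)
        parts = sum(
            fm.data_energy(ds.particles.subset([i]), ds.volume, gen, mesh, z[i : i + 1])
            for i in range(3)
        )
        assert total == pytest.approx(parts, rel=1e-12)
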