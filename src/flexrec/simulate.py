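"""Synthetic flexible-particle datasets with exact ground truth.

The toy molecule is a sum of isotropic Gaussian blobs in two domains joined
by a connector: a static domain, and a mobile domain that rotates rigidly
about a hinge axis by an angle proportional to a scalar conformational
coordinate.  The rotation is blended smoothly to zero across the connector,
so the true deformation is exactly rigid inside the mobile core (zero local
nonrigidity there) and exactly zero in the static domain.

Images are rendered through the same physics as the fitted model — convect,
project, CTF, additive white Gaussian noise at a requested SNR — but on a
2x-oversampled grid with the *analytic* deformation field (not the mesh
parameterization), then Fourier-cropped to the dataset box.  Rendering on a
finer grid than the one later used for fitting avoids the inverse crime of
testing the model against data produced by its own discretization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward_model import apply_ctf, convect, CTFParams, ctf_multiplier, project
from .io_formats import CanonicalVolume, fourier_crop, ParticleSet, write_particles, write_volume
import pandas as pd

__all__ = [
    "ToyMoleculeSpec",
    "SimulatedDataset",
    "make_toy_volume",
    "true_deformation",
    "generate_dataset",
]


@dataclass
class ToyMoleculeSpec:
    """Geometry of the hinged two-domain toy molecule.

    Blobs are ``(center_xyz_voxels, sigma_voxels, amplitude)``.  The mobile
    domain rotates about the axis through ``hinge_point`` along
    ``hinge_axis`` by ``z * max_angle_deg / 3`` degrees; the rotation angle
    is blended from 0 to its full value as the coordinate along
    ``mobile_direction`` (measured from the hinge point) goes from
    ``blend_lo`` to ``blend_hi`` voxels.
    """

    box_n: int = 32
    voxel_A: float = 3.0
    static_blobs: tuple = (
        ((9.0, 16.0, 13.0), 2.0, 1.0),
        ((9.0, 16.0, 19.0), 2.0, 1.0),
        ((11.0, 12.0, 16.0), 1.8, 0.9),
    )
    mobile_blobs: tuple = (
        ((22.0, 16.0, 13.0), 2.0, 1.0),
        ((22.0, 16.0, 19.0), 2.0, 1.0),
        ((24.0, 20.0, 16.0), 1.8, 0.9),
    )
    connector_blob: tuple = ((16.0, 16.0, 16.0), 2.2, 0.8)
    hinge_point: tuple = (16.0, 16.0, 16.0)
    hinge_axis: tuple = (0.0, 0.0, 1.0)
    mobile_direction: tuple = (1.0, 0.0, 0.0)
    blend_lo: float = 1.0
    blend_hi: float = 5.0
    max_angle_deg: float = 20.0
    k_true: int = 1

    def __post_init__(self) -> None:
        if self.max_angle_deg > 45.0:
            raise ValueError("max hinge angle must be <= 45 degrees")
        for center, sigma, _ in self.all_blobs():
            c = np.asarray(center)
            if np.any(c - 3 * sigma < 0) or np.any(c + 3 * sigma > self.box_n):
                raise ValueError(f"blob at {center} (sigma {sigma}) breaches the 3-sigma margin")

    def all_blobs(self):
        return list(self.static_blobs) + list(self.mobile_blobs) + [self.connector_blob]


def make_toy_volume(spec: ToyMoleculeSpec, oversample: int = 1) -> CanonicalVolume:
    """Render the canonical (undeformed) molecule on a grid.

    With ``oversample > 1`` the grid is finer by that factor and amplitudes
    are scaled by ``1 / oversample`` so that Fourier-cropping a projection of
    the oversampled volume back to the native box reproduces the native
    projection scale.
    """
    n = spec.box_n * oversample
    zz, yy, xx = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    data = np.zeros((n, n, n))
    for (cx, cy, cz), sigma, amp in spec.all_blobs():
        s = sigma * oversample
        a = amp / oversample
        d2 = (
            (xx - cx * oversample) ** 2
            + (yy - cy * oversample) ** 2
            + (zz - cz * oversample) ** 2
        )
        data += a * np.exp(-d2 / (2.0 * s * s))
    return CanonicalVolume(data, spec.voxel_A / oversample)


def make_validation_spec(box_n: int = 64, voxel_A: float = 1.5) -> ToyMoleculeSpec:
    """Fine-featured hinge phantom for beyond-band-limit FSC validation.

    Same domain layout as the default phantom but on a finer grid with
    sharp (sigma ~1.3 voxel) blobs, so the molecule carries spectral power
    well beyond half-Nyquist, and a larger hinge range (40 degrees at
    |z| = 3) so the motion amplitude is large relative to the feature size
    and a rigid reconstruction visibly blurs the mobile domain.
    """
    base = ToyMoleculeSpec()
    f = box_n / base.box_n
    scale = lambda blobs: tuple(
        ((f * x, f * y, f * z), 1.3 * f / 2.0, a) for (x, y, z), s, a in blobs
    )
    c = box_n / 2.0
    return ToyMoleculeSpec(
        box_n=box_n,
        voxel_A=voxel_A,
        static_blobs=scale(base.static_blobs),
        mobile_blobs=scale(base.mobile_blobs),
        connector_blob=((c, c, c), f, 0.8),
        hinge_point=(c, c, c),
        blend_lo=base.blend_lo * f,
        blend_hi=base.blend_hi * f,
        max_angle_deg=40.0,
    )


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def true_deformation(spec: ToyMoleculeSpec, z: float, points: np.ndarray, scale: float = 1.0):
    """Ground-truth displacement field at arbitrary points.

    ``points`` are (P, 3) positions in units of a grid scaled by ``scale``
    relative to the native ``box_n`` grid (e.g. ``scale=2`` for the
    2x-oversampled rendering grid); the returned displacements are in the
    same units.  ``|z| <= 3`` maps linearly to rotation angles up to
    ``max_angle_deg``.
    """
    if abs(float(z)) > 3.0 + 1e-12:
        raise ValueError("latent coordinate out of range: |z| must be <= 3")
    pts = np.asarray(points, dtype=np.float64) / scale
    hp = np.asarray(spec.hinge_point)
    axis = np.asarray(spec.hinge_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    ndir = np.asarray(spec.mobile_direction, dtype=np.float64)
    ndir = ndir / np.linalg.norm(ndir)
    rel = pts - hp
    s = rel @ ndir
    w = _smoothstep((s - spec.blend_lo) / (spec.blend_hi - spec.blend_lo))
    theta = w * (float(z) * np.deg2rad(spec.max_angle_deg) / 3.0)
    # Rodrigues rotation of rel about axis by per-point angle theta
    ct = np.cos(theta)[:, None]
    st = np.sin(theta)[:, None]
    k_cross = np.cross(np.broadcast_to(axis, rel.shape), rel)
    k_dot = (rel @ axis)[:, None]
    rot = rel * ct + k_cross * st + axis[None, :] * k_dot * (1.0 - ct)
    return (rot - rel) * scale


def true_vertex_displacements(spec, mesh, z: float, scale: float = 1.0) -> np.ndarray:
    """True deformation sampled at mesh vertices (vertices on a grid scaled
    by ``scale`` relative to the native box)."""
    return true_deformation(spec, z, mesh.vertices, scale=scale)


@dataclass
class SimulatedDataset:
    """A fully specified synthetic dataset: particles plus all ground truth."""

    particles: ParticleSet
    volume: CanonicalVolume  # ground-truth canonical map, native box
    latents_true: np.ndarray  # (M, K_true)
    noise_sigma: float
    snr: float
    seed: int
    spec: ToyMoleculeSpec
    clean_images: np.ndarray = field(repr=False, default=None)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_particles(self.particles, outdir / "particles.mrcs", outdir / "particles.csv")
        write_volume(self.volume, outdir / "canonical_map.mrc")
        gt = pd.DataFrame(
            self.latents_true, columns=[f"z_{k + 1}" for k in range(self.latents_true.shape[1])]
        )
        gt.insert(0, "particle_index", np.arange(len(gt)))
        gt.to_csv(outdir / "true_latents.csv", index=False)
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "noise_sigma": self.noise_sigma,
                    "snr": self.snr,
                    "seed": self.seed,
                    "box_n": self.spec.box_n,
                    "voxel_A": self.spec.voxel_A,
                    "max_angle_deg": self.spec.max_angle_deg,
                },
                indent=2,
            )
        )


def _random_rotations(m: int, rng: np.random.Generator, mode: str) -> np.ndarray:
    if mode == "identity":
        return np.tile(np.eye(3), (m, 1, 1))
    if mode != "uniform":
        raise ValueError(f"unknown pose mode {mode!r}")
    q = rng.standard_normal((m, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((m, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def generate_dataset(
    spec: ToyMoleculeSpec,
    m: int,
    snr: float = 0.5,
    ctf_range: tuple = (8000.0, 20000.0),
    pose_mode: str = "uniform",
    seed: int = 0,
    oversample: int = 2,
    voltage_kV: float = 300.0,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.07,
) -> SimulatedDataset:
    """Simulate a particle stack with known structure, motion and noise.

    Latents are standard normal (clipped to +-3 to stay within the hinge's
    angular range); poses are uniform over SO(3); defoci uniform over
    ``ctf_range``.  Clean images are formed with the analytic deformation on
    the oversampled grid, Fourier-cropped, then CTF-modulated; white noise is
    scaled so that the clean-signal variance inside the central disk divided
    by the noise variance equals ``snr``.  Bit-identical for a given seed.
    """
    if m < 1 or snr <= 0:
        raise ValueError("need m >= 1 and snr > 0")
    rng = np.random.default_rng(seed)
    n = spec.box_n
    n_hi = n * oversample

    z_true = np.clip(rng.standard_normal((m, spec.k_true)), -3.0, 3.0)
    rots = _random_rotations(m, rng, pose_mode)
    shifts = rng.uniform(-2.0, 2.0, (m, 2))
    du = rng.uniform(ctf_range[0], ctf_range[1], m)
    dv = du * rng.uniform(0.95, 1.0, m)
    ang = rng.uniform(0.0, 180.0, m)
    ctf = pd.DataFrame(
        {
            "defocus_u_A": du,
            "defocus_v_A": dv,
            "astig_angle_deg": ang,
            "voltage_kV": voltage_kV,
            "cs_mm": cs_mm,
            "amplitude_contrast": amplitude_contrast,
            "phase_shift_rad": 0.0,
        }
    )

    vol_native = make_toy_volume(spec)
    vol_hi = make_toy_volume(spec, oversample=oversample)
    zz, yy, xx = np.meshgrid(np.arange(n_hi), np.arange(n_hi), np.arange(n_hi), indexing="ij")
    pts_hi = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(np.float64)

    mults = np.stack(
        [ctf_multiplier(n, spec.voxel_A, CTFParams.from_row(ctf.iloc[i])) for i in range(m)]
    )
    clean = np.empty((m, n, n))
    pixel_hi = spec.voxel_A / oversample
    for i in range(m):
        disp = true_deformation(spec, z_true[i, 0], pts_hi, scale=oversample)
        disp_grid = disp.reshape(n_hi, n_hi, n_hi, 3)
        W = convect(vol_hi.data, disp_grid)
        img_hi = project(W, rots[i], shifts[i] / pixel_hi)
        img = fourier_crop(img_hi, n)
        clean[i] = np.fft.irfft2(np.fft.rfft2(img) * mults[i], s=img.shape)

    gy, gx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (gx - n // 2) ** 2 + (gy - n // 2) ** 2 <= (n // 2 - 1) ** 2
    signal_var = float(np.var(clean[:, disk]))
    sigma = float(np.sqrt(signal_var / snr))
    images = clean + sigma * rng.standard_normal(clean.shape)

    particles = ParticleSet(
        images=images,
        rotations=rots,
        shifts_A=shifts,
        ctf=ctf,
        pixel_size=spec.voxel_A,
    )
    return SimulatedDataset(
        particles=particles,
        volume=vol_native,
        latents_true=z_true,
        noise_sigma=sigma,
        snr=snr,
        seed=seed,
        spec=spec,
        clean_images=clean,
    )
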