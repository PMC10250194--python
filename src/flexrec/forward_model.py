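"""Differentiable generative image-formation pipeline.

A particle image is predicted as CTF( Project( Convect(V, u) ) ): the
canonical density V is convected by the dense deformation field u (forward
splat, density conserving), projected along the particle pose by
rotate-and-sum in real space, translated, and CTF-modulated in Fourier
space.  Under a white-noise model the data energy is
E_data = 1/2 sum_i ||I_i - prediction_i||^2.

The CTF follows the standard weak-phase approximation,

    CTF(s) = -( sqrt(1 - w^2) sin chi(s) + w cos chi(s) ),
    chi(s) = pi lambda s^2 df(alpha) - (pi/2) Cs lambda^3 s^4 + phase_shift,

with relativistic electron wavelength lambda, astigmatic defocus df(alpha)
and amplitude contrast w.  Underfocus is positive, so the CTF is negative at
low frequency.  The spectral multiplier is real and even, hence the CTF
operator is self-adjoint; gradients reuse the forward multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .io_formats import CanonicalVolume, ParticleSet
from .mesh import TetraMesh

__all__ = [
    "CTFParams",
    "ctf_multiplier",
    "apply_ctf",
    "convect",
    "convect_backward",
    "project",
    "project_backward",
    "predict_image",
    "data_energy",
    "batch_energy_and_grads",
    "electron_wavelength_A",
]


@dataclass(frozen=True)
class CTFParams:
    defocus_u_A: float
    defocus_v_A: float
    astig_angle_deg: float = 0.0
    voltage_kV: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    phase_shift_rad: float = 0.0

    @classmethod
    def from_row(cls, row) -> "CTFParams":
        return cls(
            defocus_u_A=float(row["defocus_u_A"]),
            defocus_v_A=float(row["defocus_v_A"]),
            astig_angle_deg=float(row["astig_angle_deg"]),
            voltage_kV=float(row["voltage_kV"]),
            cs_mm=float(row["cs_mm"]),
            amplitude_contrast=float(row["amplitude_contrast"]),
            phase_shift_rad=float(row["phase_shift_rad"]),
        )


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_multiplier(n: int, pixel_size: float, p: CTFParams) -> np.ndarray:
    """Real CTF multiplier on the rfft2 grid of an n x n image."""
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    lam = electron_wavelength_A(p.voltage_kV)
    fy = np.fft.fftfreq(n, d=pixel_size)[:, None]
    fx = np.fft.rfftfreq(n, d=pixel_size)[None, :]
    s2 = fx**2 + fy**2
    ang = np.arctan2(fy, fx)
    df = 0.5 * (p.defocus_u_A + p.defocus_v_A) + 0.5 * (
        p.defocus_u_A - p.defocus_v_A
    ) * np.cos(2.0 * (ang - np.deg2rad(p.astig_angle_deg)))
    cs = p.cs_mm * 1e7  # mm -> A
    chi = np.pi * lam * s2 * df - 0.5 * np.pi * cs * lam**3 * s2**2 + p.phase_shift_rad
    w = p.amplitude_contrast
    mult = -(np.sqrt(max(1.0 - w**2, 0.0)) * np.sin(chi) + w * np.cos(chi))
    # the fx = +Nyquist column aliases fx = -Nyquist: under astigmatism the
    # two give different angles, so average them to keep the operator
    # real-symmetric (self-adjoint) on the rfft grid
    if n % 2 == 0:
        col = mult[:, -1]
        mult[:, -1] = 0.5 * (col + np.concatenate([col[:1], col[1:][::-1]]))
    return mult


def apply_ctf(image: np.ndarray, ctf, pixel_size: float | None = None) -> np.ndarray:
    """CTF-modulate an image; ``ctf`` is a CTFParams or a precomputed rfft2
    multiplier."""
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    if isinstance(ctf, CTFParams):
        mult = ctf_multiplier(n, pixel_size, ctf)
    else:
        mult = ctf
    return np.fft.irfft2(np.fft.rfft2(image) * mult, s=image.shape)


# ---------------------------------------------------------------------------
# convection


def _splat(kernel: str):
    if kernel == "trilinear":
        return _kernels.splat_trilinear, _kernels.splat_trilinear_backward
    if kernel == "tricubic":
        return _kernels.splat_tricubic, _kernels.splat_tricubic_backward
    raise ValueError(f"unknown interpolation kernel {kernel!r}")


def convect(V, dense_displacement: np.ndarray, kernel: str = "trilinear"):
    """Convect a density by a dense per-voxel displacement field.

    Each source voxel y contributes V(y) * k(x - y - d(y)) at destinations x
    (forward splat).  With the trilinear kernel, total mass is conserved
    exactly whenever every mapped position stays >= 1 voxel inside the grid.
    """
    is_vol = isinstance(V, CanonicalVolume)
    data = V.data if is_vol else np.asarray(V, dtype=np.float64)
    disp = np.ascontiguousarray(dense_displacement, dtype=np.float64)
    n = data.shape[0]
    mmax = np.abs(disp).max() if disp.size else 0.0
    if mmax > n / 2:
        raise ValueError(
            f"divergent deformation: max displacement {mmax:.1f} voxels exceeds N/2 = {n / 2}"
        )
    fwd, _ = _splat(kernel)
    W = fwd(np.ascontiguousarray(data, dtype=np.float64), disp)
    if is_vol:
        return CanonicalVolume(W, V.voxel_size, V.bandlimit_radius)
    return W


def convect_backward(V, dense_displacement, gW, kernel="trilinear", need_gd=True):
    """Gradients of ``sum(gW * convect(V, d))`` w.r.t. V and d."""
    data = V.data if isinstance(V, CanonicalVolume) else np.asarray(V, dtype=np.float64)
    _, bwd = _splat(kernel)
    return bwd(
        np.ascontiguousarray(data, dtype=np.float64),
        np.ascontiguousarray(dense_displacement, dtype=np.float64),
        np.ascontiguousarray(gW, dtype=np.float64),
        need_gd,
    )


# ---------------------------------------------------------------------------
# projection


def project(W, rotation: np.ndarray, shift_px=(0.0, 0.0), kernel: str = "trilinear") -> np.ndarray:
    """Real-space projection: rotate about the center voxel, sum along z,
    apply the 2D shift.  A constant volume of value c projects to N*c per
    pixel in the interior.  Resampling is trilinear by default; ``tricubic``
    (Keys) is available where higher interpolation accuracy matters more
    than speed."""
    data = W.data if isinstance(W, CanonicalVolume) else np.asarray(W, dtype=np.float64)
    R = np.ascontiguousarray(rotation, dtype=np.float64)
    fn = _kernels.project_forward if kernel == "trilinear" else _kernels.project_forward_cubic
    return fn(
        np.ascontiguousarray(data, dtype=np.float64), R, np.asarray(shift_px, dtype=np.float64)
    )


def project_backward(
    g_image: np.ndarray, rotation: np.ndarray, shift_px, n: int, kernel: str = "trilinear"
) -> np.ndarray:
    """Adjoint of :func:`project`."""
    fn = _kernels.project_adjoint if kernel == "trilinear" else _kernels.project_adjoint_cubic
    return fn(
        np.ascontiguousarray(g_image, dtype=np.float64),
        np.ascontiguousarray(rotation, dtype=np.float64),
        np.asarray(shift_px, dtype=np.float64),
        n,
    )


# ---------------------------------------------------------------------------
# end-to-end prediction and energy


def predict_image(
    V: CanonicalVolume,
    generator,
    mesh: TetraMesh,
    z: np.ndarray,
    rotation: np.ndarray,
    shift_A=(0.0, 0.0),
    ctf: CTFParams | np.ndarray | None = None,
    kernel: str = "trilinear",
) -> np.ndarray:
    """Predicted particle image CTF(P(phi) D(f_theta(z), V)).

    The convected map is built in an internal scratch buffer and never
    retained; :func:`convect` + :func:`project` expose the same pipeline with
    the intermediate map materialized.
    """
    u_vert = generator.forward(np.atleast_2d(z))[0]
    disp = mesh.interpolate_flow(u_vert)
    W = convect(V.data, disp, kernel=kernel)
    shift_px = np.asarray(shift_A, dtype=np.float64) / V.voxel_size
    img = project(W, rotation, shift_px)
    if ctf is not None:
        img = apply_ctf(img, ctf, pixel_size=V.voxel_size)
    return img


def data_energy(
    particles: ParticleSet,
    V: CanonicalVolume,
    generator,
    mesh: TetraMesh,
    z_batch: np.ndarray,
    kernel: str = "trilinear",
) -> float:
    """White-noise negative log likelihood 1/2 sum_i ||I_i - pred_i||^2."""
    z_batch = np.atleast_2d(z_batch)
    total = 0.0
    for i in range(particles.m):
        pred = predict_image(
            V,
            generator,
            mesh,
            z_batch[i],
            particles.rotations[i],
            particles.shifts_A[i],
            CTFParams.from_row(particles.ctf.iloc[i]),
            kernel=kernel,
        )
        total += 0.5 * np.sum((particles.images[i] - pred) ** 2)
    return float(total)


def batch_energy_and_grads(
    images: np.ndarray,
    rotations: np.ndarray,
    shifts_px: np.ndarray,
    ctf_mults: np.ndarray | None,
    V_data: np.ndarray,
    disp_batch: np.ndarray,
    mesh: TetraMesh,
    kernel: str = "trilinear",
    need_gV: bool = True,
    need_gu: bool = True,
):
    """Data energy and its gradients for a batch sharing one canonical map.

    Parameters
    ----------
    disp_batch : (B, n_v, 3) per-image vertex displacements.
    ctf_mults : (B, n, n//2+1) rfft2 multipliers, or None for no CTF.

    Returns
    -------
    energy : float
    gV : (n, n, n) or None
    gu : (B, n_v, 3) or None -- gradients w.r.t. vertex displacements
    """
    B = images.shape[0]
    n = V_data.shape[0]
    Vc = np.ascontiguousarray(V_data, dtype=np.float64)
    gV = np.zeros((n, n, n)) if need_gV else None
    gu = np.zeros_like(disp_batch) if need_gu else None
    energy = 0.0
    for i in range(B):
        disp = mesh.interpolate_flow(disp_batch[i])
        W = convect(Vc, disp, kernel=kernel)
        proj = project(W, rotations[i], shifts_px[i])
        if ctf_mults is not None:
            pred = np.fft.irfft2(np.fft.rfft2(proj) * ctf_mults[i], s=proj.shape)
        else:
            pred = proj
        resid = pred - images[i]
        energy += 0.5 * np.sum(resid**2)
        if not (need_gV or need_gu):
            continue
        if ctf_mults is not None:
            g_img = np.fft.irfft2(np.fft.rfft2(resid) * ctf_mults[i], s=resid.shape)
        else:
            g_img = resid
        gW = project_backward(g_img, rotations[i], shifts_px[i], n)
        gVi, gd = convect_backward(Vc, disp, gW, kernel=kernel, need_gd=need_gu)
        if need_gV:
            gV += gVi
        if need_gu:
            gu[i] = mesh.interpolate_flow_adjoint(gd)
    return float(energy), gV, gu
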