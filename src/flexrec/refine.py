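"""High-resolution half-map reconstruction under frozen motion, and validation.

Once the flow generator and latents are trained (on a small box, up to a
limited frequency band), the canonical map is re-estimated at full box size
for each half-set by full-batch L-BFGS on the least-squares objective, with
the motion model frozen.  The two half-maps are then compared by Fourier
shell correlation: correlation beyond the training-time Nyquist/band-limit
indicates consistent signal recovered independently from both half-sets
rather than overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .forward_model import batch_energy_and_grads, ctf_multiplier, CTFParams, convect
from .io_formats import CanonicalVolume, MaskVolume, ParticleSet
from .mesh import TetraMesh

__all__ = [
    "reconstruct_highres",
    "fsc",
    "FSCCurve",
    "symmetrize_cn",
    "convected_series",
]


def reconstruct_highres(
    particles: ParticleSet,
    mesh_high: TetraMesh,
    flows: np.ndarray | None,
    max_iters: int = 200,
    kernel: str = "trilinear",
    lbfgs_memory: int = 10,
    grad_reduction: float = 1e-3,
    ridge: float = 0.0,
) -> CanonicalVolume:
    """L-BFGS canonical-map reconstruction with frozen per-particle flows.

    Parameters
    ----------
    particles : the (half-)set to reconstruct from, at full box size.
    mesh_high : mesh rescaled to the full-resolution grid.
    flows : (M, n_v, 3) per-particle vertex displacements in full-res voxel
        units (vertex positions and displacements both scale by N_H / N_L
        from the training grid), or None for a rigid reconstruction.
    ridge : optional Tikhonov weight adding ``ridge/2 ||V||^2``; a small
        value pins the weakly observed corner frequencies, making the
        least-squares minimizer unique.

    The map is initialized to zero and optimized by full-batch L-BFGS with a
    strong-Wolfe line search until the gradient norm drops by 1e3 (by
    default) or ``max_iters`` is reached.
    """
    n = particles.n
    if mesh_high.grid_n != n:
        raise ValueError("mesh grid does not match particle box size")
    m = particles.m
    if flows is None:
        flows = np.zeros((m, mesh_high.n_vertices, 3))
    images = np.ascontiguousarray(particles.images)
    rots = np.ascontiguousarray(particles.rotations)
    shifts_px = particles.shifts_A / particles.pixel_size
    mults = np.stack(
        [
            ctf_multiplier(n, particles.pixel_size, CTFParams.from_row(particles.ctf.iloc[i]))
            for i in range(m)
        ]
    )

    def fun(x):
        V = x.reshape(n, n, n)
        e, gV, _ = batch_energy_and_grads(
            images, rots, shifts_px, mults, V, flows, mesh_high, kernel, need_gu=False
        )
        if not np.isfinite(e):
            raise FloatingPointError("non-finite reconstruction objective")
        if ridge > 0:
            e += 0.5 * ridge * np.dot(x, x)
            return e, gV.ravel() + ridge * x
        return e, gV.ravel()

    x0 = np.zeros(n * n * n)
    _, g0 = fun(x0)
    gtol = max(np.max(np.abs(g0)) * grad_reduction, 1e-14)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=max_iters, maxcor=lbfgs_memory, gtol=gtol, ftol=1e-14),
    )
    return CanonicalVolume(res.x.reshape(n, n, n), particles.pixel_size)


# ---------------------------------------------------------------------------
# Fourier shell correlation


@dataclass
class FSCCurve:
    """Per-shell correlation between two volumes.

    ``shell`` are integer Fourier-shell indices, ``freq`` the corresponding
    spatial frequencies in 1/Angstrom, ``fsc`` the normalized correlations in
    [-1, 1].
    """

    shell: np.ndarray
    freq: np.ndarray
    fsc: np.ndarray

    def resolution(self, threshold: float = 0.143) -> float:
        """Resolution (Angstrom) at the first crossing of ``threshold``,
        linearly interpolated between shells; inf frequency -> 0 never
        happens, returns the Nyquist resolution if the curve never drops."""
        vals = self.fsc
        for i in range(1, len(vals)):
            if vals[i] < threshold <= vals[i - 1]:
                t = (vals[i - 1] - threshold) / (vals[i - 1] - vals[i])
                f = self.freq[i - 1] + t * (self.freq[i] - self.freq[i - 1])
                return 1.0 / f if f > 0 else np.inf
        return 1.0 / self.freq[-1] if self.freq[-1] > 0 else np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shell": self.shell, "freq_invA": self.freq, "fsc": self.fsc})

    def plot(self, ax=None, label=None, threshold: float = 0.143):
        """Plot the curve (FSC vs spatial frequency) with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.freq, self.fsc, label=label)
        ax.axhline(threshold, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("spatial frequency (1/$\\mathrm{\\AA}$)")
        ax.set_ylabel("FSC")
        ax.set_ylim(-0.1, 1.05)
        if label:
            ax.legend()
        return ax


def fsc(V_a: CanonicalVolume, V_b: CanonicalVolume, mask: MaskVolume | None = None) -> FSCCurve:
    """Fourier shell correlation between two same-sized volumes."""
    if V_a.data.shape != V_b.data.shape:
        raise ValueError(
            f"volume shapes differ: {V_a.data.shape} vs {V_b.data.shape}"
        )
    a = V_a.data
    b = V_b.data
    if mask is not None:
        a = a * mask.data
        b = b * mask.data
    n = a.shape[0]
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    f = np.fft.fftfreq(n) * n
    r = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2)
    shells = np.rint(r).astype(int).ravel()
    nmax = n // 2
    keep = shells <= nmax
    shells = shells[keep]
    cross = np.bincount(shells, weights=(Fa * np.conj(Fb)).real.ravel()[keep], minlength=nmax + 1)
    pa = np.bincount(shells, weights=(np.abs(Fa) ** 2).ravel()[keep], minlength=nmax + 1)
    pb = np.bincount(shells, weights=(np.abs(Fb) ** 2).ravel()[keep], minlength=nmax + 1)
    den = np.sqrt(pa * pb)
    vals = np.divide(cross, den, out=np.zeros_like(cross), where=den > 0)
    vals = np.clip(vals, -1.0, 1.0)
    idx = np.arange(nmax + 1)
    freq = idx / (n * V_a.voxel_size)
    return FSCCurve(shell=idx, freq=freq, fsc=vals)


# ---------------------------------------------------------------------------
# symmetrization and display maps


def _axis_rotation(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def symmetrize_cn(V: CanonicalVolume, n_fold: int, axis=(0.0, 0.0, 1.0)) -> CanonicalVolume:
    """Average the map over the Cn point group about an axis through the
    center voxel (trilinear resampling)."""
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    if n_fold == 1:
        return V.copy()
    acc = np.zeros_like(V.data)
    for k in range(n_fold):
        R = _axis_rotation(axis, 2.0 * np.pi * k / n_fold)
        acc += _kernels.rotate_volume(np.ascontiguousarray(V.data), np.ascontiguousarray(R))
    return CanonicalVolume(acc / n_fold, V.voxel_size)


def convected_series(
    V: CanonicalVolume,
    generator,
    mesh: TetraMesh,
    z_points: np.ndarray,
    kernel: str = "trilinear",
) -> list[CanonicalVolume]:
    """Explicitly convected display maps W = D(f_theta(z), V) at chosen
    latent points (e.g. +-1 latent standard deviation along each axis)."""
    z_points = np.atleast_2d(z_points)
    out = []
    for z in z_points:
        u = generator.forward(z[None])[0]
        disp = mesh.interpolate_flow(u)
        out.append(convect(V, disp, kernel=kernel))
    return out
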