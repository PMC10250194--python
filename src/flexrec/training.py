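"""Joint optimization of canonical map, flow generator and per-particle latents.

The total loss is L = E_data + lambda * E_rigid, plus the unit-variance
Gaussian prior on latents.  Optimization is block coordinate descent over
minibatches: latents are inferred per image (auto-decoder) before each
generator update, noise is injected into the latent point estimates during
generator updates, and the canonical map is updated in separate epochs under
a frequency-marching band-limit and an optional solvent mask.  When latents
start from zero, the first ``warmup_epochs`` epochs update (theta, z) with V
fixed; when latents are supplied externally, those epochs update theta with z
fixed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow_model import FlowGenerator, inject_latent_noise, latent_prior_energy
from .forward_model import batch_energy_and_grads, ctf_multiplier, CTFParams, convect, project
from .io_formats import CanonicalVolume, MaskVolume, ParticleSet
from .mesh import TetraMesh, rigidity_energy

__all__ = [
    "TrainConfig",
    "TrainState",
    "train",
    "infer_latents",
    "frequency_march",
    "bandlimit_volume",
]


@dataclass
class TrainConfig:
    """Hyper-parameters of the block-coordinate training loop.

    ``lambda_rigid`` (default 2.0, useful range roughly 0.5-5) weights the
    local-rigidity penalty; ``batch_size`` defaults to the recommended floor
    of 500 images per minibatch.  Learning rates, the epoch budget, the
    frequency-marching ramp and the latent-noise schedule are implementation
    defaults exposed here.
    """

    k_latent: int = 2
    lambda_rigid: float = 2.0
    batch_size: int = 500
    optimizer: str = "adam"  # or "sgd_nesterov"
    lr_theta: float = 1e-4
    lr_v: float = 0.1
    n_epochs: int = 40
    warmup_epochs: int = 5
    freq_start_shell: int | None = None  # default N/8
    freq_end_shell: int | None = None  # default N/2
    freq_ramp_epochs: int | None = None  # default n_epochs // 2
    latent_method: str = "coordinate_descent"  # or "gradient"
    latent_cycles: int = 2
    latent_steps: int = 8
    latent_bounds: tuple = (-4.0, 4.0)
    noise_sigma_start: float = 0.1
    noise_sigma_end: float = 0.02
    n_layers: int = 6
    hidden: int = 64
    init_scale: float = 1e-2
    kernel: str = "trilinear"
    train_box: int | None = None  # Fourier-crop particles/map to this box for training
    early_stop_rel: float = 1e-3
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rigid <= 0:
            raise ValueError("lambda_rigid must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.batch_size < 500:
            warnings.warn(
                f"batch_size {self.batch_size} is below the recommended floor of 500; "
                "gradient noise may destabilize training",
                stacklevel=2,
            )
        if self.optimizer not in ("adam", "sgd_nesterov"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def schedule(self, n: int) -> tuple[int, int, int]:
        start = self.freq_start_shell if self.freq_start_shell is not None else max(n // 8, 2)
        end = self.freq_end_shell if self.freq_end_shell is not None else n // 2
        ramp = (
            self.freq_ramp_epochs if self.freq_ramp_epochs is not None else max(self.n_epochs // 2, 1)
        )
        return start, end, ramp

    def noise_sigma(self, epoch: int) -> float:
        if self.n_epochs <= 1:
            return self.noise_sigma_end
        t = min(epoch / (self.n_epochs - 1), 1.0)
        return self.noise_sigma_start + t * (self.noise_sigma_end - self.noise_sigma_start)


def frequency_march(epoch: int, schedule: tuple[int, int, int]) -> int:
    """Band-limit shell for a given epoch: linear ramp from start to end."""
    start, end, ramp = schedule
    if ramp <= 0 or epoch >= ramp:
        return end
    shell = start + (end - start) * epoch / ramp
    return int(min(round(shell), end))


def bandlimit_volume(V: CanonicalVolume, shell: int) -> CanonicalVolume:
    """Low-pass the map to a Fourier shell with a 2-shell cosine rolloff.

    Re-applying at the same shell is a no-op (the volume records its current
    band-limit), so the constraint is idempotent.
    """
    n = V.n
    if not (0 < shell <= n // 2):
        raise ValueError(f"shell must be in (0, {n // 2}], got {shell}")
    if V.bandlimit_radius is not None and V.bandlimit_radius == shell:
        return V
    if shell >= n // 2:
        out = CanonicalVolume(V.data.copy(), V.voxel_size, shell)
        return out
    f = np.fft.fftfreq(n) * n
    r = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2)
    w = np.zeros_like(r)
    w[r <= shell] = 1.0
    roll = (r > shell) & (r <= shell + 2)
    w[roll] = 0.5 * (1.0 + np.cos(np.pi * (r[roll] - shell) / 2.0))
    data = np.fft.ifftn(np.fft.fftn(V.data) * w).real
    return CanonicalVolume(data, V.voxel_size, shell)


# ---------------------------------------------------------------------------
# optimizers


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def get_state(self):
        return {"m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v], "t": self.t}

    def set_state(self, state):
        self.m = [np.asarray(a).copy() for a in state["m"]]
        self.v = [np.asarray(a).copy() for a in state["v"]]
        self.t = int(state["t"])

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


class _NesterovSGD:
    def __init__(self, shapes, lr, momentum=0.9):
        self.lr = lr
        self.mu = momentum
        self.vel = [np.zeros(s) for s in shapes]

    def get_state(self):
        return {"m": [a.copy() for a in self.vel], "v": [], "t": 0}

    def set_state(self, state):
        self.vel = [np.asarray(a).copy() for a in state["m"]]

    def step(self, params, grads):
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            v_prev = self.vel[i]
            self.vel[i] = self.mu * v_prev - self.lr * g
            out.append(p + self.mu * self.vel[i] - self.lr * g)
        return out


def _make_opt(name, shapes, lr):
    return _Adam(shapes, lr) if name == "adam" else _NesterovSGD(shapes, lr)


# ---------------------------------------------------------------------------
# latent inference (auto-decoder)


def _golden_min(f, lo, hi, steps, x0=None, f0=None):
    """Golden-section minimization on [lo, hi] with best-seen tracking.

    Returns the best point among all evaluations (and the starting point, if
    given), so the objective can never increase.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc <= fd else (d, fd)
    if x0 is not None and f0 is not None and f0 < best_f:
        best_x, best_f = x0, f0
    for _ in range(steps):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
            if fc < best_f:
                best_x, best_f = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
            if fd < best_f:
                best_x, best_f = d, fd
    return best_x, best_f


def infer_latents(
    images: np.ndarray,
    V: CanonicalVolume,
    generator: FlowGenerator,
    mesh: TetraMesh,
    z_init: np.ndarray,
    rotations: np.ndarray,
    shifts_px: np.ndarray,
    ctf_mults: np.ndarray | None,
    method: str = "coordinate_descent",
    cycles: int = 2,
    steps: int = 8,
    bounds: tuple = (-4.0, 4.0),
    kernel: str = "trilinear",
):
    """Per-image latent inference with V and theta fixed.

    The per-image objective 1/2 ||I - pred(z)||^2 + 1/2 ||z||^2 is minimized
    either by cyclic per-dimension golden-section line search on ``bounds``
    (default) or by fixed-step gradient descent with backtracking.  The
    objective never increases relative to ``z_init``.
    """
    z = np.array(z_init, dtype=np.float64, copy=True)
    B, K = z.shape
    Vd = np.ascontiguousarray(V.data)

    def objective(i, zi):
        u = generator.forward(zi[None])[0]
        disp = mesh.interpolate_flow(u)
        try:
            W = convect(Vd, disp, kernel=kernel)
        except ValueError:  # divergent deformation at this probe point
            return np.inf
        pred = project(W, rotations[i], shifts_px[i], kernel=kernel)
        if ctf_mults is not None:
            pred = np.fft.irfft2(np.fft.rfft2(pred) * ctf_mults[i], s=pred.shape)
        return 0.5 * np.sum((images[i] - pred) ** 2) + 0.5 * np.sum(zi**2)

    if method == "coordinate_descent":
        for i in range(B):
            zi = z[i].copy()
            fi = objective(i, zi)
            for _ in range(cycles):
                for k in range(K):
                    def f1(t, i=i, k=k, zi=zi):
                        trial = zi.copy()
                        trial[k] = t
                        return objective(i, trial)

                    best_t, best_f = _golden_min(f1, bounds[0], bounds[1], steps, zi[k], fi)
                    zi[k] = best_t
                    fi = best_f
            z[i] = zi
        return z

    if method == "gradient":
        for i in range(B):
            zi = z[i].copy()
            fi = objective(i, zi)
            lr = 0.2
            for _ in range(cycles * steps):
                g = _latent_grad(images[i], Vd, generator, mesh, zi, rotations[i], shifts_px[i], None if ctf_mults is None else ctf_mults[i], kernel)
                step_ok = False
                for _bt in range(6):
                    trial = np.clip(zi - lr * g, bounds[0], bounds[1])
                    ft = objective(i, trial)
                    if ft <= fi:
                        zi, fi = trial, ft
                        step_ok = True
                        break
                    lr *= 0.5
                if not step_ok or np.linalg.norm(g) < 1e-8:
                    break
            z[i] = zi
        return z

    raise ValueError(f"unknown latent inference method {method!r}")


def _latent_grad(image, Vd, generator, mesh, zi, R, shift_px, ctf_mult, kernel):
    """Analytic gradient of the per-image objective w.r.t. z."""
    mults = None if ctf_mult is None else ctf_mult[None]
    u, acts = generator.forward(zi[None], cache=True)
    _, _, gu = batch_energy_and_grads(
        image[None], R[None], shift_px[None], mults, Vd, u, mesh, kernel, need_gV=False
    )
    _, _, gz = generator.backward(gu, acts)
    return gz[0] + zi


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainState:
    """Fitted (or in-progress) training state.

    ``epoch`` is the last completed epoch and ``resume`` carries the RNG and
    optimizer state needed for :func:`train` to continue a run exactly as if
    it had never stopped.
    """

    generator: FlowGenerator
    latents: np.ndarray
    volume: CanonicalVolume
    trace: pd.DataFrame
    diverged: bool = False
    epoch: int = -1
    resume: dict | None = field(default=None, repr=False)


def train(
    particles: ParticleSet,
    V0: CanonicalVolume,
    mesh: TetraMesh,
    config: TrainConfig,
    solvent_mask: MaskVolume | None = None,
    resume: TrainState | None = None,
    stop_epoch: int | None = None,
) -> TrainState:
    """Fit generator parameters, latents and the canonical map to particles.

    ``V0`` is typically a (low-passed) consensus map on the same grid as
    ``mesh.grid_n``.  If ``particles.latents`` is set, those coordinates are
    used as initialization and held fixed during warmup; otherwise latents
    start at zero and are inferred jointly with theta from the start.  The
    zero-deformation constraint is carried by ``mesh.frozen_vertices``
    (enforced exactly: those vertices never move).  Fully reproducible given
    ``config.seed``; passing a previous :class:`TrainState` as ``resume``
    continues that run bitwise-identically to an uninterrupted one.
    ``stop_epoch`` ends the run early (exclusive), e.g. to checkpoint.
    """
    n = V0.n
    if mesh.grid_n != n or particles.n != n:
        raise ValueError("particles, volume and mesh must share one grid size")
    M = particles.m
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    schedule = cfg.schedule(n)

    z_external = particles.latents is not None
    if z_external:
        z = np.array(particles.latents, dtype=np.float64, copy=True)
        if z.shape[1] != cfg.k_latent:
            cfg = replace(cfg, k_latent=z.shape[1])
    else:
        z = np.zeros((M, cfg.k_latent))

    generator = FlowGenerator(
        k=cfg.k_latent,
        n_v=mesh.n_vertices,
        n_layers=cfg.n_layers,
        hidden=cfg.hidden,
        init_scale=cfg.init_scale,
        seed=int(rng.integers(2**31 - 1)),
    )
    generator.frozen = mesh.frozen_vertices if mesh.frozen_vertices.any() else None

    if resume is not None:
        if resume.resume is None:
            raise ValueError("state lacks resume information (older checkpoint?)")
        generator = copy.deepcopy(resume.generator)
        z = resume.latents.copy()
        z_external = bool(resume.resume["z_external"])
        rng.bit_generator.state = resume.resume["rng_state"]

    images = np.ascontiguousarray(particles.images)
    rots = np.ascontiguousarray(particles.rotations)
    shifts_px = particles.shifts_A / V0.voxel_size
    ctf_mults = np.stack(
        [
            ctf_multiplier(n, V0.voxel_size, CTFParams.from_row(particles.ctf.iloc[i]))
            for i in range(M)
        ]
    )

    if resume is not None:
        V = resume.volume.copy()
    else:
        V = bandlimit_volume(V0, frequency_march(0, schedule))
        if solvent_mask is not None:
            V = CanonicalVolume(V.data * solvent_mask.data, V.voxel_size)

    opt_theta = _make_opt(cfg.optimizer, [p.shape for p in generator.parameters()], cfg.lr_theta)
    opt_v = _make_opt(cfg.optimizer, [V.data.shape], cfg.lr_v)

    rows = []
    stall = 0
    prev_total = np.inf
    start_epoch = 0
    if resume is not None:
        opt_theta.set_state(resume.resume["opt_theta"])
        opt_v.set_state(resume.resume["opt_v"])
        rows = resume.trace.to_dict("records")
        stall = int(resume.resume["stall"])
        prev_total = float(resume.resume["prev_total"])
        start_epoch = resume.epoch + 1
    last_good = None

    def theta_epoch(epoch, update_z):
        nonlocal z
        sigma = cfg.noise_sigma(epoch)
        order = rng.permutation(M)
        e_data = e_rigid = 0.0
        for lo in range(0, M, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            if update_z:
                z[idx] = infer_latents(
                    images[idx],
                    V,
                    generator,
                    mesh,
                    z[idx],
                    rots[idx],
                    shifts_px[idx],
                    ctf_mults[idx],
                    method=cfg.latent_method,
                    cycles=cfg.latent_cycles,
                    steps=cfg.latent_steps,
                    bounds=cfg.latent_bounds,
                    kernel=cfg.kernel,
                )
            z_noisy = inject_latent_noise(z[idx], sigma, rng)
            u, acts = generator.forward(z_noisy, cache=True)
            ed, _, gu = batch_energy_and_grads(
                images[idx], rots[idx], shifts_px[idx], ctf_mults[idx],
                V.data, u, mesh, cfg.kernel, need_gV=False,
            )
            er, gr = rigidity_energy(mesh, u)
            gu = gu + cfg.lambda_rigid * gr
            g_w, g_b, _ = generator.backward(gu, acts)
            grads = g_w + [g for g in g_b if g is not None]
            generator.set_parameters(opt_theta.step(generator.parameters(), grads))
            e_data += ed
            e_rigid += er
        return e_data, e_rigid

    def v_epoch(epoch):
        nonlocal V
        order = rng.permutation(M)
        e_data = e_rigid = 0.0
        shell = frequency_march(epoch, schedule)
        for lo in range(0, M, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            u = generator.forward(z[idx])
            ed, gV, _ = batch_energy_and_grads(
                images[idx], rots[idx], shifts_px[idx], ctf_mults[idx],
                V.data, u, mesh, cfg.kernel, need_gu=False,
            )
            er = rigidity_energy(mesh, u, with_grad=False)
            (new_data,) = opt_v.step([V.data], [gV])
            V = bandlimit_volume(CanonicalVolume(new_data, V.voxel_size), shell)
            if solvent_mask is not None:
                V = CanonicalVolume(V.data * solvent_mask.data, V.voxel_size, V.bandlimit_radius)
            e_data += ed
            e_rigid += er
        return e_data, e_rigid

    def snapshot(epoch, deep=True):
        gen = copy.deepcopy(generator) if deep else generator
        return TrainState(
            gen,
            z.copy(),
            V.copy(),
            pd.DataFrame(rows),
            epoch=epoch,
            resume={
                "rng_state": rng.bit_generator.state,
                "opt_theta": opt_theta.get_state(),
                "opt_v": opt_v.get_state(),
                "prev_total": prev_total,
                "stall": stall,
                "z_external": z_external,
            },
        )

    end_epoch = cfg.n_epochs if stop_epoch is None else min(cfg.n_epochs, stop_epoch)
    for epoch in range(start_epoch, end_epoch):
        shell = frequency_march(epoch, schedule)
        V = bandlimit_volume(V, shell)
        warm = epoch < cfg.warmup_epochs
        if warm:
            phase = "warmup"
            ed, er = theta_epoch(epoch, update_z=not z_external)
        elif (epoch - cfg.warmup_epochs) % 2 == 0:
            phase = "volume"
            ed, er = v_epoch(epoch)
        else:
            phase = "flow"
            ed, er = theta_epoch(epoch, update_z=True)
        prior = latent_prior_energy(z)
        total = ed + cfg.lambda_rigid * er + prior
        rows.append(
            dict(epoch=epoch, phase=phase, e_data=ed, e_rigid=er, prior=prior,
                 total=total, bandlimit=shell, noise_sigma=cfg.noise_sigma(epoch))
        )
        if not np.isfinite(total):
            state = last_good or snapshot(epoch)
            state.diverged = True
            state.trace = pd.DataFrame(rows)
            return state
        # early stop bookkeeping (only once the band-limit stops ramping),
        # updated before the snapshot so resumed runs continue it exactly
        if shell == schedule[1]:
            if prev_total - total < cfg.early_stop_rel * abs(prev_total):
                stall += 1
            else:
                stall = 0
        prev_total = total
        last_good = snapshot(epoch)
        if stall >= cfg.early_stop_patience:
            break

    return last_good if last_good is not None else snapshot(start_epoch - 1, deep=False)
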