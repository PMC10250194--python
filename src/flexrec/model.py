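"""Model / Results interface for flexible refinement.

:class:`FlexModel` bundles the data (particles, consensus map, mesh, masks)
with a :class:`~flexrec.training.TrainConfig`; :meth:`FlexModel.fit` runs the
block-coordinate training and returns a :class:`FlexResults` carrying the
fitted generator, per-particle latents, the trained canonical map and the
loss trace, with methods for half-map reconstruction, FSC validation and
convected display maps.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from .flow_model import FlowGenerator
from .io_formats import CanonicalVolume, fourier_crop, MaskVolume, ParticleSet
from .mesh import (
    compute_element_weights,
    freeze_vertices_in_mask,
    generate_regular_mesh,
    TetraMesh,
)
from .refine import convected_series, fsc, reconstruct_highres
from .training import train, TrainConfig, TrainState  # noqa: F401 (TrainState re-exported)
from .io_formats import make_soft_mask

__all__ = ["FlexModel", "FlexResults", "save_checkpoint", "load_checkpoint"]


def default_mesh(
    consensus: CanonicalVolume,
    element_size_A: float | None = None,
    threshold: float | None = None,
    w_min: float = 0.5,
) -> TetraMesh:
    """Regular mesh covering the consensus density above a threshold.

    The default threshold is 10% of the map maximum and the default element
    size about a quarter of the box, dilated by one element so the mesh
    extends slightly past the molecular envelope.
    """
    if threshold is None:
        threshold = 0.1 * float(consensus.data.max())
    if element_size_A is None:
        element_size_A = consensus.n * consensus.voxel_size / 4.0
    h_vox = element_size_A / consensus.voxel_size
    mask = make_soft_mask(consensus, threshold, dilation_vox=h_vox / 2.0)
    mesh = generate_regular_mesh(mask, element_size_A, consensus.voxel_size)
    compute_element_weights(mesh, consensus, w_min=w_min)
    return mesh


class FlexModel:
    """Generative model of a flexible molecule, bound to one dataset.

    Parameters
    ----------
    particles : full-resolution particle set with poses and CTFs.
    consensus : consensus density map on the particles' grid (used to
        initialize the canonical map and to place the mesh).
    mesh : deformation mesh on the consensus grid; built automatically when
        omitted.
    config : training hyper-parameters; ``config.train_box`` selects the
        (smaller) box used during flow training.
    solvent_mask : multiplied into the canonical map after every update.
    zero_deformation_mask : mesh vertices inside it are pinned (e.g. a
        detergent micelle region).
    """

    def __init__(
        self,
        particles: ParticleSet,
        consensus: CanonicalVolume,
        mesh: TetraMesh | None = None,
        config: TrainConfig | None = None,
        solvent_mask: MaskVolume | None = None,
        zero_deformation_mask: MaskVolume | None = None,
    ):
        if particles.n != consensus.n:
            raise ValueError("particle box and consensus box differ")
        self.particles = particles
        self.consensus = consensus
        self.config = config or TrainConfig()
        self.mesh = mesh if mesh is not None else default_mesh(consensus)
        if zero_deformation_mask is not None:
            freeze_vertices_in_mask(self.mesh, zero_deformation_mask)
        self.solvent_mask = solvent_mask

        n = particles.n
        tb = self.config.train_box or n
        if tb > n or tb % 2:
            raise ValueError(f"train_box must be even and <= {n}")
        self.train_box = tb
        if tb < n:
            imgs = np.stack([fourier_crop(img, tb) for img in particles.images])
            self._train_particles = ParticleSet(
                images=imgs,
                rotations=particles.rotations,
                shifts_A=particles.shifts_A,
                ctf=particles.ctf,
                pixel_size=particles.pixel_size * n / tb,
                half_set=particles.half_set,
                latents=particles.latents,
            )
            self._train_volume = fourier_crop(consensus, tb)
            self._train_mesh = self.mesh.rescaled(tb / n, tb)
            self._train_solvent = (
                None
                if solvent_mask is None
                else MaskVolume(np.clip(fourier_crop(solvent_mask.data, tb), 0, 1))
            )
        else:
            self._train_particles = particles
            self._train_volume = consensus
            self._train_mesh = self.mesh
            self._train_solvent = solvent_mask

    def fit(self, resume: TrainState | None = None) -> "FlexResults":
        """Run (or, given a previous state, continue) training."""
        state = train(
            self._train_particles,
            self._train_volume,
            self._train_mesh,
            self.config,
            solvent_mask=self._train_solvent,
            resume=resume,
        )
        return FlexResults(self, state)


class FlexResults:
    """Fitted flexible-refinement model."""

    def __init__(self, model: FlexModel, state: TrainState):
        self.model = model
        self._state = state

    # -- fitted quantities -------------------------------------------------

    @property
    def generator(self) -> FlowGenerator:
        return self._state.generator

    @property
    def latents(self) -> np.ndarray:
        return self._state.latents

    @property
    def canonical_volume(self) -> CanonicalVolume:
        return self._state.volume

    @property
    def trace(self) -> pd.DataFrame:
        return self._state.trace

    @property
    def diverged(self) -> bool:
        return self._state.diverged

    def summary(self) -> str:
        m = self.model
        tr = self.trace
        z = self.latents
        buf = _io.StringIO()
        w = buf.write
        w("Flexible refinement results\n")
        w("=" * 60 + "\n")
        w(f"particles:            {m.particles.m}\n")
        w(f"box (full / train):   {m.particles.n} / {m.train_box}\n")
        w(f"pixel size (full):    {m.particles.pixel_size:.3f} A\n")
        w(f"mesh:                 {m._train_mesh.n_vertices} vertices, "
          f"{m._train_mesh.n_cells} cells\n")
        w(f"latent dimension K:   {z.shape[1]}\n")
        w(f"lambda_rigid:         {m.config.lambda_rigid}\n")
        w(f"epochs run:           {len(tr)}\n")
        if len(tr):
            last = tr.iloc[-1]
            w(f"final E_data:         {last.e_data:.4g}\n")
            w(f"final E_rigid:        {last.e_rigid:.4g}\n")
            w(f"final latent prior:   {last.prior:.4g}\n")
            w(f"final band-limit:     shell {int(last.bandlimit)}\n")
        w("latent moments per dimension:\n")
        for k in range(z.shape[1]):
            w(f"  z_{k + 1}: mean {z[:, k].mean():+.3f}  std {z[:, k].std():.3f}\n")
        if self.diverged:
            w("WARNING: training diverged; state is the last finite checkpoint\n")
        return buf.getvalue()

    # -- downstream computations -------------------------------------------

    def _flows_at(self, n_high: int, latents: np.ndarray) -> np.ndarray:
        scale = n_high / self.model.train_box
        flows = np.concatenate(
            [self.generator.forward(latents[i : i + 256]) for i in range(0, len(latents), 256)]
        )
        return flows * scale

    def mesh_at(self, n_high: int) -> TetraMesh:
        scale = n_high / self.model.train_box
        if n_high == self.model.train_box:
            return self.model._train_mesh
        return self.model._train_mesh.rescaled(scale, n_high)

    def reconstruct_halfmaps(
        self,
        max_iters: int = 100,
        kernel: str = "trilinear",
        rigid: bool = False,
    ) -> tuple[CanonicalVolume, CanonicalVolume]:
        """Full-box half-set reconstructions under the frozen motion model.

        Vertex positions and displacements are rescaled from the training
        grid to the full grid by N_H / N_L.  ``rigid=True`` reconstructs with
        zero flows (the conventional rigid baseline on the same half-sets).
        """
        particles = self.model.particles
        n_high = particles.n
        mesh_high = self.mesh_at(n_high)
        out = []
        for label in ("A", "B"):
            sel = np.nonzero(particles.half_set == label)[0]
            half = particles.subset(sel)
            flows = None if rigid else self._flows_at(n_high, self.latents[sel])
            out.append(
                reconstruct_highres(half, mesh_high, flows, max_iters=max_iters, kernel=kernel)
            )
        return tuple(out)

    def fsc_halfmaps(self, V_a, V_b, mask: MaskVolume | None = None):
        return fsc(V_a, V_b, mask=mask)

    def convected_series(self, z_points: np.ndarray, kernel: str = "trilinear"):
        """Convected display maps at chosen latent points (training grid)."""
        return convected_series(
            self.canonical_volume, self.generator, self.model._train_mesh, z_points, kernel
        )

    def plot_trace(self, ax=None):
        """Per-epoch energies on a log scale, with the band-limit schedule."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.trace
        ax.semilogy(tr.epoch, tr.e_data, label="$E_{data}$")
        ax.semilogy(tr.epoch, tr.e_rigid.clip(lower=1e-12), label="$E_{rigid}$")
        ax.semilogy(tr.epoch, tr.prior.clip(lower=1e-12), label="latent prior")
        ax.set_xlabel("epoch")
        ax.set_ylabel("energy")
        ax2 = ax.twinx()
        ax2.plot(tr.epoch, tr.bandlimit, color="gray", lw=0.8, ls=":")
        ax2.set_ylabel("band-limit shell")
        ax.legend(loc="center right")
        return ax

    def plot_latents(self, true_latents=None, ax=None):
        """Learned latent distribution; scatter against ground truth if given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = self.latents
        if true_latents is not None:
            ax.scatter(np.asarray(true_latents)[:, 0], z[:, 0], s=4, alpha=0.4)
            ax.set_xlabel("true latent")
            ax.set_ylabel("learned $z_1$")
        elif z.shape[1] >= 2:
            ax.scatter(z[:, 0], z[:, 1], s=4, alpha=0.4)
            ax.set_xlabel("$z_1$")
            ax.set_ylabel("$z_2$")
        else:
            ax.hist(z[:, 0], bins=40)
            ax.set_xlabel("$z_1$")
            ax.set_ylabel("count")
        return ax

    def save(self, path) -> None:
        save_checkpoint(path, self._state, self.model._train_mesh, self.model.config)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, state: TrainState, mesh: TetraMesh, config: TrainConfig) -> None:
    """Write generator weights, latents, map, mesh, config and the resume
    state (RNG + optimizer moments) to one npz."""
    import json as _json

    payload = {f"gen_{k}": v for k, v in state.generator.state_dict().items()}
    payload.update(
        latents=state.latents,
        volume=state.volume.data,
        voxel_size=state.volume.voxel_size,
        bandlimit=-1 if state.volume.bandlimit_radius is None else state.volume.bandlimit_radius,
        mesh_vertices=mesh.vertices,
        mesh_cells=mesh.cells,
        mesh_weights=mesh.element_weights,
        mesh_grid_n=mesh.grid_n,
        mesh_frozen=mesh.frozen_vertices,
        trace_csv=state.trace.to_csv(index=False, float_format="%.17g"),
        config_json=pd.Series(asdict(config)).to_json(),
        diverged=state.diverged,
        epoch=state.epoch,
    )
    if state.resume is not None:
        res = state.resume
        payload["resume_json"] = _json.dumps(
            {
                "rng_state": res["rng_state"],
                "prev_total": res["prev_total"],
                "stall": res["stall"],
                "z_external": bool(res["z_external"]),
                "opt_theta_t": res["opt_theta"]["t"],
                "opt_v_t": res["opt_v"]["t"],
                "n_theta": len(res["opt_theta"]["m"]),
                "n_theta_v": len(res["opt_theta"]["v"]),
                "n_v": len(res["opt_v"]["m"]),
                "n_v_v": len(res["opt_v"]["v"]),
            }
        )
        for name, arrs in [("tm", res["opt_theta"]["m"]), ("tv", res["opt_theta"]["v"]),
                           ("vm", res["opt_v"]["m"]), ("vv", res["opt_v"]["v"])]:
            for i, a in enumerate(arrs):
                payload[f"opt_{name}_{i}"] = a
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[TrainState, TetraMesh, TrainConfig]:
    from .mesh import assign_voxels
    import json as _json

    with np.load(path, allow_pickle=False) as f:
        gen_state = {k[4:]: f[k] for k in f.files if k.startswith("gen_")}
        generator = FlowGenerator.from_state_dict(gen_state)
        bl = int(f["bandlimit"])
        volume = CanonicalVolume(
            f["volume"], float(f["voxel_size"]), None if bl < 0 else bl
        )
        mesh = TetraMesh(
            vertices=f["mesh_vertices"],
            cells=f["mesh_cells"],
            element_weights=f["mesh_weights"],
            grid_n=int(f["mesh_grid_n"]),
            frozen_vertices=f["mesh_frozen"].astype(bool),
        )
        assign_voxels(mesh)
        trace = pd.read_csv(_io.StringIO(str(f["trace_csv"])), float_precision="round_trip")
        cfg_dict = _json.loads(str(f["config_json"]))
        cfg_dict["latent_bounds"] = tuple(cfg_dict["latent_bounds"])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            config = TrainConfig(**cfg_dict)
        resume = None
        if "resume_json" in f.files:
            meta = _json.loads(str(f["resume_json"]))
            resume = {
                "rng_state": meta["rng_state"],
                "prev_total": meta["prev_total"],
                "stall": meta["stall"],
                "z_external": meta["z_external"],
                "opt_theta": {
                    "m": [f[f"opt_tm_{i}"] for i in range(meta["n_theta"])],
                    "v": [f[f"opt_tv_{i}"] for i in range(meta["n_theta_v"])],
                    "t": meta["opt_theta_t"],
                },
                "opt_v": {
                    "m": [f[f"opt_vm_{i}"] for i in range(meta["n_v"])],
                    "v": [f[f"opt_vv_{i}"] for i in range(meta["n_v_v"])],
                    "t": meta["opt_v_t"],
                },
            }
        state = TrainState(
            generator=generator,
            latents=f["latents"],
            volume=volume,
            trace=trace,
            diverged=bool(f["diverged"]),
            epoch=int(f["epoch"]) if "epoch" in f.files else -1,
            resume=resume,
        )
    return state, mesh, config
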