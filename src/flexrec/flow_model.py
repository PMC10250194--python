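"""Latent space and neural flow generator.

A fully connected network (ReLU hidden layers, bias-free linear final layer)
maps a K-dimensional conformational coordinate z to one 3-vector displacement
per mesh vertex.  Per-particle latents are inferred by direct per-image
optimization (auto-decoder); a unit-variance Gaussian prior keeps the latent
distribution centered and bounded, and noise injected into the latents during
generator updates encourages a smooth latent-to-deformation map.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FlowGenerator",
    "latent_prior_energy",
    "latent_prior_grad",
    "inject_latent_noise",
]


class FlowGenerator:
    """MLP mapping latent coordinates to per-vertex displacements.

    Parameters
    ----------
    k : latent dimension (>= 1)
    n_v : number of mesh vertices
    n_layers : total number of weight layers (default 6)
    hidden : hidden width (default 64)
    init_scale : scale of the final-layer weights; small values start
        training near the identity deformation (default 1e-2)
    seed : RNG seed; initialization is deterministic given the seed
    """

    def __init__(
        self,
        k: int,
        n_v: int,
        n_layers: int = 6,
        hidden: int = 64,
        init_scale: float = 1e-2,
        seed: int = 0,
    ):
        if k < 1 or n_layers < 1 or hidden < 1:
            raise ValueError("k, n_layers and hidden must all be >= 1")
        self.k = k
        self.n_v = n_v
        self.n_layers = n_layers
        self.hidden = hidden
        self.init_scale = init_scale
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [k] + [hidden] * (n_layers - 1) + [3 * n_v]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray | None] = []
        for layer in range(n_layers):
            fan_in = dims[layer]
            w = rng.standard_normal((fan_in, dims[layer + 1])) * np.sqrt(2.0 / fan_in)
            if layer == n_layers - 1:
                w *= init_scale
                self.weights.append(w)
                self.biases.append(None)  # final layer: linear, no bias
            else:
                self.weights.append(w)
                self.biases.append(np.zeros(dims[layer + 1]))
        self.frozen: np.ndarray | None = None  # (n_v,) bool; pinned vertices

    # -- parameter plumbing ----------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.weights + [b for b in self.biases if b is not None]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        nw = len(self.weights)
        for i in range(nw):
            self.weights[i] = params[i]
        j = nw
        for i in range(nw):
            if self.biases[i] is not None:
                self.biases[i] = params[j]
                j += 1

    # -- forward / backward ----------------------------------------------

    def forward(self, z: np.ndarray, cache: bool = False):
        """Displacements (B, n_v, 3) for a latent batch (B, K)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.k:
            raise ValueError(f"latent dimension {z.shape[1]} != generator K {self.k}")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite latent coordinates")
        acts = [z]
        h = z
        for layer in range(self.n_layers):
            h = h @ self.weights[layer]
            if self.biases[layer] is not None:
                h = h + self.biases[layer]
                h = np.maximum(h, 0.0)
            if cache:
                acts.append(h)
        out = h.reshape(-1, self.n_v, 3)
        if self.frozen is not None:
            out = out.copy()
            out[:, self.frozen, :] = 0.0
        if cache:
            return out, acts
        return out

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.forward(z)

    def backward(self, g_out: np.ndarray, acts: list[np.ndarray]):
        """Backprop ``dE/d(output)`` to parameter and latent gradients.

        Returns ``(g_weights, g_biases, g_z)`` with ``g_biases[i]`` None for
        the final layer.
        """
        g = np.asarray(g_out, dtype=np.float64).reshape(g_out.shape[0], -1)
        if self.frozen is not None:
            g = g.reshape(-1, self.n_v, 3).copy()
            g[:, self.frozen, :] = 0.0
            g = g.reshape(g.shape[0], -1)
        g_w = [None] * self.n_layers
        g_b = [None] * self.n_layers
        for layer in range(self.n_layers - 1, -1, -1):
            a_in = acts[layer]
            if self.biases[layer] is not None:
                g = g * (acts[layer + 1] > 0)  # ReLU mask on post-activation
                g_b[layer] = g.sum(axis=0)
            g_w[layer] = a_in.T @ g
            g = g @ self.weights[layer].T
        return g_w, g_b, g

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        state = {
            "k": self.k,
            "n_v": self.n_v,
            "n_layers": self.n_layers,
            "hidden": self.hidden,
            "init_scale": self.init_scale,
            "seed": self.seed,
        }
        for i, w in enumerate(self.weights):
            state[f"w{i}"] = w
        for i, b in enumerate(self.biases):
            if b is not None:
                state[f"b{i}"] = b
        if self.frozen is not None:
            state["frozen"] = self.frozen
        return state

    @classmethod
    def from_state_dict(cls, state: dict) -> "FlowGenerator":
        gen = cls(
            k=int(state["k"]),
            n_v=int(state["n_v"]),
            n_layers=int(state["n_layers"]),
            hidden=int(state["hidden"]),
            init_scale=float(state["init_scale"]),
            seed=int(state["seed"]),
        )
        for i in range(gen.n_layers):
            gen.weights[i] = np.asarray(state[f"w{i}"])
            if f"b{i}" in state:
                gen.biases[i] = np.asarray(state[f"b{i}"])
        if "frozen" in state:
            gen.frozen = np.asarray(state["frozen"]).astype(bool)
        return gen


def latent_prior_energy(z_batch: np.ndarray) -> float:
    """Unit-variance Gaussian prior energy, 1/2 sum_i ||z_i||^2."""
    z = np.asarray(z_batch, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latent coordinates")
    return float(0.5 * np.sum(z**2))


def latent_prior_grad(z_batch: np.ndarray) -> np.ndarray:
    return np.asarray(z_batch, dtype=np.float64)


def inject_latent_noise(
    z_batch: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian perturbation of the latent point estimates (training only)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    z = np.asarray(z_batch, dtype=np.float64)
    if sigma == 0:
        return z.copy()
    return z + sigma * rng.standard_normal(z.shape)
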