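# flexrec

Motion-based reconstruction of continuously flexible macromolecules from
single-particle cryo-EM images.

Most biological macromolecules move. In a cryo-EM dataset every particle
image catches the molecule in a different conformation, and conventional
("rigid") refinement, which averages all images against a single static map,
blurs the moving parts away. flexrec implements a generative model in which
every conformation is a *deformation of one canonical 3D density map*:

    I_i = C_i P(φ_i) D(f_θ(z_i), V) + η

- `V` — the canonical density map (real-space voxel grid),
- `z_i` — a low-dimensional latent coordinate placing particle *i* on the
  molecule's conformational landscape,
- `f_θ` — a small MLP (the *flow generator*) mapping `z` to a deformation
  field on a tetrahedral mesh covering the molecule,
- `D` — a density-conserving convection operator (forward splat),
- `P(φ_i)`, `C_i` — projection along the known particle pose and CTF.

`V`, `θ` and `z_{1:M}` are learned jointly by minimizing
`E_data + λ E_rigid` (plus a unit-variance Gaussian prior on `z`), where
`E_rigid = Σ_ij w_j Σ_ℓ (s_ijℓ − 1)²` penalizes the deviation of each mesh
element's affine deformation from a rotation (`s` are singular values).
Latents are inferred per image by direct optimization against the model
(auto-decoder). After training at a small box size and band-limit, the
canonical map is re-estimated at full resolution for each particle half-set
by L-BFGS with the motion frozen, and the half-maps are validated by
Fourier shell correlation: correlation *beyond* the training band-limit is
signal the motion model recovered, not overfitting.

The package is aimed at methods work on continuous heterogeneity: it runs
desk-scale problems on one CPU (numpy + numba), ships a synthetic-data
module with exact ground truth (structure, motion, latents, noise), and
exposes both a library API (`FlexModel` / `FlexResults`) and a CLI.

## Worked example

Simulate a hinged two-domain molecule (box 32, 3 Å voxels, a mobile domain
rotating ±20° about a hinge, SNR 0.5), fit the model, and inspect the fit:

```python
import numpy as np
import flexrec as fr
from flexrec.model import FlexModel, default_mesh
from flexrec.training import TrainConfig

spec = fr.ToyMoleculeSpec()                      # the hinge phantom
ds = fr.generate_dataset(spec, m=2000, snr=0.5, seed=11)

mesh = default_mesh(ds.volume, element_size_A=24.0)
cfg = TrainConfig(k_latent=1, batch_size=500, n_epochs=24, warmup_epochs=5,
                  lr_theta=5e-3, latent_cycles=1, latent_steps=6,
                  freq_start_shell=5, freq_end_shell=9, freq_ramp_epochs=10,
                  train_box=24, seed=0, early_stop_patience=100)
results = FlexModel(ds.particles, ds.volume, mesh=mesh, config=cfg).fit()

r = np.corrcoef(results.latents[:, 0], ds.latents_true[:, 0])[0, 1]
print(f"latent recovery |r| = {abs(r):.3f}")
print(results.summary())
```

which prints:

```
latent recovery |r| = 0.930
Flexible refinement results
============================================================
particles:            2000
box (full / train):   32 / 24
pixel size (full):    3.000 A
mesh:                 80 vertices, 180 cells
latent dimension K:   1
lambda_rigid:         2.0
epochs run:           24
final E_data:         4.664e+05
final E_rigid:        142.2
final latent prior:   397.1
final band-limit:     shell 9
latent moments per dimension:
  z_1: mean -0.052  std 0.628
```

The learned latent coordinate tracks the true hinge angle of each particle
(|r| ≈ 0.9 at SNR 0.5; sign and scale are gauge freedoms of the model), and
`results.generator` maps latents to the recovered deformation field —
`results.convected_series(z_points)` renders the motion as a series of
density maps. `results.reconstruct_halfmaps()` then produces the two
full-box half-set reconstructions under the frozen motion for FSC
validation (`flexrec.fsc`).

The same workflow is available from the shell:

```bash
flexrec simulate --out data/ --m 2000 --snr 0.5 --seed 11
flexrec mesh --volume data/canonical_map.mrc --out mesh.json --element-size 24
flexrec train --stack data/particles.mrcs --metadata data/particles.csv \
              --consensus data/canonical_map.mrc --mesh mesh.json \
              --k 1 --train-box 24 --out run/ckpt.npz
flexrec reconstruct --stack data/particles.mrcs --metadata data/particles.csv \
                    --checkpoint run/ckpt.npz --out-dir run/ --rigid-baseline
flexrec flexmap --checkpoint run/ckpt.npz --out-dir run/maps
```

Volumes and stacks are MRC/MRCS (mode 2); particle metadata is RELION-style
STAR or CSV with the same column names; meshes are JSON; FSC curves are CSV.

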