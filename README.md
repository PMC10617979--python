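# ledshape

Generative models of anatomical surface meshes — variational autoencoders and
GANs on fixed-topology triangle meshes — whose latent variables are
**disentangled per anatomical region** through a local-eigenprojection (LE)
loss grounded in spectral graph theory.

## The problem

Statistical shape models of heads and bodies (morphable models, mesh VAEs,
mesh GANs) generate plausible anatomy but give no control over *local*
identity attributes: one latent variable typically moves the nose, the jaw
and the forehead together.  `ledshape` is for researchers and technical
artists who need a single generative model in which a designated block of
latent variables controls one segmented region and little else — for random
per-region resampling, latent traversal, or drag-style direct editing.

## The method

All shapes share one topology and a template segmentation into F attributes.
For a shape X, the per-vertex signed distance from the training mean M is

    sd(X) = sign(⟨X − M, N⟩) · ‖X − M‖ ,

with N the frozen template normals.  For each attribute ω the Kirchhoff
graph Laplacian K_ω = D_ω − A_ω (connectivity only, so diagonalized once) is
eigendecomposed; sd restricted to the attribute is projected onto the κ
eigenvectors U*_ω whose training projections have the highest variance, and
standardized by that projection's mean m*_ω and std s*_ω.  The latent vector
z = {z_ω} (length F·κ) is tied to these descriptors by

    L_LE(X, z) = (1 / Fκ) Σ_ω ‖ z_ω − (U*_ωᵀ sd(X_ω) − m*_ω) / s*_ω ‖₁ ,

added to the VAE loss twice with gradient routing (once into the encoder
against μ, once into the generator against the reconstruction) or to the
LSGAN/WGAN generator loss against the sampled z.  Because the eigenvectors
are orthonormal on disjoint vertex sets, the latent targets are decorrelated
within and across attributes — no curated mini-batching is required.

Networks are spiral-convolution mesh autoencoders with quadric-sampling
resolution changes, running on a compact numpy autodiff core; everything is
seeded and CPU-friendly.  See `docs/methods.md` for the full model, defaults
and limitations.

## Worked example

A synthetic population (license-free stand-in for corresponded head scans;
642 vertices, 4 attribute sectors, Gaussian bump factors) is generated, an
LED-VAE is fitted, and the disentanglement is measured:

```python
import numpy as np
from ledshape import LEDShapeModel, SyntheticSpec, TrainConfig, sample_population

pop, factors = sample_population(SyntheticSpec(seed=7), 889)   # 800 train
model = LEDShapeModel(pop, flavour="vae", led=True, kappa=3,
                      train_config=TrainConfig(epochs=20, seed=3))
results = model.fit()
print(results.summary())
scores = results.localization_scores()
print("median localization:", round(float(np.median(scores)), 2))
```

prints (abridged):

```
LED-VAE shape model
==========================================================
shapes (train/val/test)                          800/44/45
vertices / attributes                              642 / 4
latent size (F x kappa)                         12 (4 x 3)
epochs / batch / lr                        20 / 32 / 0.001
LE weights                               eta1=0.5 eta2=0.5
final reconstruction                                1.1058
final le_generator                                  0.0642
final val_reconstruction                            1.1297
median localization score                             4.98
==========================================================
median localization: 4.98
```
(abridged; the full table also lists the Laplacian, KL and total losses)

A localization score of 4.98 means that sweeping a typical latent dimension
from −3 to +3 moves vertices of its own attribute about five times more than
any other attribute; the same model trained with the LE weights at zero (a
vanilla VAE, `led=False`) scores about 0.6, i.e. no localization.  From a
fitted model, `results.sample(n)` generates shapes, `results.evaluate()`
computes the generation metrics and the VP disentanglement score, and
`results.edit(...)` performs handle-based direct manipulation restricted to
the latent block of the edited region.

The same pipeline is scriptable from the shell:

```bash
ledshape run-all -o my_run          # synth -> fit-basis -> train -> evaluate
ledshape edit -o my_run --handles handles.json
```

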