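# Methods

`ledshape` trains generative models of fixed-topology anatomical surface
meshes whose latent variables are disentangled per anatomical region
("attribute").  This note records the model, the choices that were genuinely
open, and what the bundled synthetic data does and does not demonstrate.

## Shape representation and statistics

All meshes share one triangulation (edges E, faces F) and differ only in
vertex positions X ∈ R^{N×3}, assumed aligned, scaled and in dense point
correspondence.  A template segmentation assigns every vertex to exactly one
of F_attr attributes; seam vertices belong to a single attribute so the
per-attribute operators act on disjoint vertex sets.

From the training split we compute the per-vertex mean M and per-vertex,
per-coordinate standard deviation S (floored at 1e-8 template units to keep
rigid regions finite under division).  Whether S should be scalar-per-vertex
or per-coordinate is ambiguous; we use per-coordinate because it makes
standardization exactly invertible elementwise.  Unit vertex normals are
computed once on the mean shape M by area-weighted averaging of incident face
normals and then frozen; they are never recomputed per sample.

The per-vertex **signed distance** of a shape is

    sd_i(X) = sign(<X_i − M_i, N_i>) · ‖X_i − M_i‖ ,

with sign(0) := +1 (it only matters on a measure-zero set).  On standardized
input the displacement is recovered as X ⊙ S first, so both routes agree.

## Local eigenprojections and the LE loss

For each attribute w with vertex set of size N_w, the Kirchhoff graph
Laplacian K_w = D_w − A_w depends only on connectivity, so its
eigendecomposition K_w = U_w Λ_w U_wᵀ is computed once per topology.  The
training-set signed distances restricted to the attribute are projected onto
the first K candidate eigenvectors (default K = 10·κ; the selection needs
headroom beyond κ) and the κ components with the highest training variance
are kept, together with their projection mean m*_w and std s*_w.  Ties in
variance break toward the lower eigenvalue index, and the constant (λ = 0)
eigenvector is eligible — it captures uniform inflation of an attribute.

Eigenvector sign and ordering are arbitrary for the mathematics but not for
reproducibility, so we fix both: the largest-magnitude entry of each
eigenvector is made positive (ties: lowest index), and within a degenerate
eigenspace columns are ordered by the row index of that largest entry.
A dense symmetric solver is used up to 2000 vertices per attribute,
shift-invert Lanczos above.

The latent vector z of every model is split into F_attr blocks of κ
variables.  The **local-eigenprojection (LE) loss** ties block w to the
standardized projections:

    L_LE(X, z) = (1 / F·κ) Σ_w ‖ z_w − (U*_wᵀ sd(X_w) − m*_w) / s*_w ‖₁ .

Because the selected eigenvectors are orthonormal and attribute supports are
disjoint, the target components are decorrelated across and within blocks.
The basis is fitted on standardized signed distances by default; the raw
form is exposed and produces identical results up to the standardization
identity above.

## Models and training

Networks use spiral convolutions (per-vertex ordered neighbour sequences;
the spiral starts at the vertex, walks its 1-ring counter-clockwise from the
smallest-index neighbour, then continues ring by ring to length L, padding
with zeros) and fixed resolution changes built by quadric-error edge
collapse: the down-transform selects the surviving vertex subset, the
up-transform re-embeds removed vertices barycentrically in their nearest
coarse face on the template.  Collapse ties break on insertion order and an
edge is skipped when it would break the link condition, so the hierarchy is
deterministic and manifold.  Default architecture: three spiral-conv levels
with channels (16, 32, 64), L = 9, downsampling factor 4, ELU activations,
linear heads; all configurable.  The networks run in float32 on a small
reverse-mode autodiff core written for this package.

**VAE.**  The encoder predicts (μ, σ) with σ = exp of a log-std head; the
loss is

    L = L_R(X, X′) + α·L_L(X′) + β·L_KL(μ, σ) + η₁·L_LE(X, μ) + η₂·L_LE(X′, μ)

with reconstruction L_R = ‖X′ − X‖²_F / N, Tutte-Laplacian smoothing
L_L = ‖T X′‖²_F / N computed on the whole mesh (T = I − D⁻¹A, applied to
de-standardized coordinates), and KL divergence σ² + μ² − log σ − 1 reduced
by the mean over latent dimensions and batch so that β is comparable across
latent sizes.  The two LE terms are gradient-routed: the η₁ term reaches
only the encoder (its shape argument is data), and for the η₂ term the
generator is re-run on a detached latent and compared against a detached μ,
so it reaches only the generator.  With η₁ = η₂ = 0 the step is exactly the
vanilla VAE step.

**GANs.**  LSGAN trains the discriminator on the least-squares real/fake
objective and the generator on ½E[(D(G(z)) − 1)²] + α·L_L + η·L_LE(X′, z);
WGAN trains a critic on E[C(G(z))] − E[C(X)] with all critic weights clipped
to [−c, c] after every update (n_critic critic steps per generator step) and
the generator on −E[C(G(z))] + α·L_L + η·L_LE(X′, z).  Setting η = 0 gives
the vanilla GANs.

Defaults: α = 1, β = 1e-3 with a 5-epoch linear warm-up, η₁ = η₂ = η = 0.5,
Adam at lr 1e-3, batch 32, n_critic = 5, c = 0.01.  Mini-batching is plain
shuffling — no attribute-swapping curation is needed, which is the point of
the LE loss.  A truncation-trick sampling std (< 1) is exposed at generation
time and off by default.

## Synthetic data

Real corresponded head/body datasets are license-restricted, so the package
ships a generator that reproduces the statistical structure the method
assumes rather than anatomy.  The template is a subdivided icosahedron
(N = 10·4^s + 2; default s = 3, N = 642) segmented into F_attr = 4 connected
pole-to-pole azimuthal sectors.  Each attribute owns g = 5 smooth bump
fields — its lowest non-constant Kirchhoff eigenvectors, zero outside the
attribute — and a shape is the template displaced along its normals by a
Gaussian linear combination of these fields (scale 0.05 template radii per
factor) plus i.i.d. normal-direction noise (std 0.0005, i.e. 1% of the
factor scale).  Everything is seeded and bit-reproducible.

By construction the signed distance of a sampled shape equals the scalar
displacement field, so its local eigenprojections are exactly linear in the
Gaussian factors: the population satisfies the normality assumption the
method makes about neutral-pose anatomies, and the fitted basis can recover
the generative factors perfectly.  A bimodal variant shifts one attribute's
coefficients by ±3σ on a fair mixture label, emulating datasets whose
projections are Gaussian mixtures (expression-like data).  What passing
tests on this data shows is that the pipeline recovers known structure under
its own assumptions; it does not show robustness to registration error,
non-Gaussian identity variation, articulated pose, or anatomical detail.

## Evaluation

Generation quality against a reference set uses the symmetric squared
Chamfer distance: diversity (mean per-vertex distance over random generated
pairs — correspondence-based, not Chamfer), Jensen–Shannon divergence of
pooled-vertex voxel histograms (28³ grid on the joint bounding box, natural
log), minimum matching distance, coverage, and |1-NN two-sample accuracy −
50|.  Disentanglement uses (a) the variation-predictability (VP) metric — a
classifier with the encoder's trunk is trained few-shot (fraction 0.1 of
N pairs, 5 epochs, Adam lr 1e-4, 3 repeats) to predict which latent
dimension differs between two generated shapes from their vertex-difference
field; the varied dimension's value is redrawn from N(0, 1), an
interpretation we fix explicitly — and (b) latent-traversal distance maps:
each latent dimension is swept from −3 to +3 with the others at 0, and the
per-vertex distances are averaged per attribute.  The localization score of
a dimension is its designated attribute's mean distance divided by the
largest mean distance among the other attributes (an all-zero row reports 1).

## Editing

`attribute_resample` redraws one latent block from the prior.  Direct
manipulation minimizes the squared handle error ‖S∘G(z) − Y‖² in template
units with Adam (lr 0.1, 50 iterations) over only the latent block of the
attribute containing the handles; when handles span several attributes the
per-attribute optimizations run sequentially in ascending attribute index
(the order is an artifact choice; joint optimization would also be
defensible).  Latent blocks without handles are untouched by construction.

## Problem sizes and numerical notes

The packaged study conditions train on 800 shapes (90/5/5 split of 889) at
N = 642, κ = 3, 20 epochs — a desk-scale configuration chosen so the whole
comparison (LED-VAE vs vanilla VAE plus metrics) reruns in minutes on one
CPU.  VP is computed from 6000 pairs (the full protocol uses 10000); fewer pairs leave the few-shot classifier data-starved and the score noise-dominated.  Gradients of |·| and of the Euclidean
norm at zero use the zero subgradient; the signed-distance sign factor is
treated as locally constant.  Checkpoints store network parameters,
optimizer moments and the RNG state, so resumed training is bit-identical
to an uninterrupted run.

## Known limitations

- Combinatorial Laplacians ignore geometry by design; attributes with very
  irregular triangulation would bias the spectral descriptors.
- The LE loss presumes approximately Gaussian projections; on mixture-like
  data (e.g. expressions) the latent prior and the projections disagree and
  sampled shapes may show local artifacts.
- Weight clipping is the only Lipschitz mechanism implemented for the WGAN;
  gradient-penalty variants are out of scope.
- The float32 training stack targets meshes of order 10³–10⁴ vertices on a
  CPU; it is not a general-purpose deep-learning framework.
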