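# Methods

## Model

`hyperseg` segments the four diabetic-retinopathy lesion classes (EX hard
exudates, HE haemorrhages, MA microaneurysms, SE soft exudates) plus
background from RGB fundus images. The architecture has three parts.

**ViT encoder.** Non-overlapping patch embedding (patch 16), learned 1-D
positional embeddings (bilinearly interpolated for grids other than the
reference), and `depth` pre-norm transformer blocks
(`y' = MSA(LN(y)) + y`, `y = MLP(LN(y')) + y'`). The blocks are split into
`interactions = N` equal groups. No class token is used by default — for
dense prediction the token ↔ patch bijection is what matters; a flag can
prepend-and-discard one for weight-compatibility experiments. Full-size
defaults are width 768, FFN 3072, 12 heads, depth 12, N 4; depth 12 is
inferred from the width/FFN/head setting, and learned positions are
standard practice where nothing else is specified.

**Spatial-prior adapter.** A convolutional stem (three stride-2 3×3
conv + channel-LayerNorm + ReLU stages to 1/8 resolution, then two more to
1/16 and 1/32, each scale tapped by a 1×1 projection) produces a feature
pyramid that is flattened scale-major into spatial tokens. Per interaction
round i: the **injector** adds `γ_i · Attention(LN(b_i), LN(F_i^sp))` to the
ViT tokens, with the scalar gate γ_i initialized to exactly 0, so at
initialization the ViT stream is bitwise independent of the adapter branch;
the group of encoder blocks runs; the **extractor** updates the spatial
tokens by cross-attention against the group output followed by a
convolutional FFN (linear down-projection to a hidden size, shared 3×3
depthwise convolution per scale, GELU, linear up-projection), both
residual. Attention is plain dense multi-head cross-attention throughout.
The published adapter dimension (1024) differs from the ViT width (768);
since cross-attention requires one width, the package uses a single
`adapter_width` defaulting to the ViT width, with the stem's 1×1
projections absorbing the choice.

**Decoder and hyperbolic head.** The final extracted pyramid is reshaped to
maps, the 1/16 and 1/32 maps are bilinearly upsampled to 1/8 and summed, a
1×1 convolution projects to the embedding dimension n (default 64,
config-exposed; never prescribed upstream), and bilinear upsampling yields
per-pixel Euclidean features f(X) at full resolution. Each pixel is lifted
into the Poincaré ball of curvature c ≥ 0 with the exponential map at the
origin and classified by one gyroplane (offset p_y in the ball, tangent
normal a_y) per class; the logit is the scaled signed gyroplane distance
ζ_y = (λ_{p_y}‖a_y‖/√c)·asinh(·). Both Möbius-addition quantities in the
distance are computed with the bilinear rewrite (three scalar reductions
per pixel–class pair), never by materializing the sum. Training minimizes
mean softmax cross-entropy over non-ignored pixels (`ignore_index = 255`).

### Sign convention

Two equivalent gyroplane conventions exist: ⟨p ⊕_c z, a⟩ and
⟨(−p) ⊕_c z, a⟩, differing only by the reparameterization p → −p of a
learned offset. The package defaults to the negated-offset form because its
c → 0 limit is the familiar Euclidean logit 4⟨z − p, a⟩, which is also the
exact branch taken at c = 0; `negate_offset=False` selects the literal
form (whose c = 0 branch is then 4⟨z + p, a⟩, keeping the head continuous
in c). With offsets initialized at the origin the two are identical.

### Curvature c = 0

Zero curvature is a first-class configuration (it appears in curvature
sweeps), handled everywhere as an explicit Euclidean code branch — never as
a small-c limit: Möbius addition becomes vector addition, the distance
becomes 2‖u − v‖ (the conformal factor at flat curvature is 2), the head
becomes an affine classifier with the metric factor 4 = λ₀², and the
Riemannian update becomes plain SGD scaled by 1/4.

## Numerics

All computation is float64 on a small reverse-mode autodiff engine written
for this package (numpy only; im2col convolutions, half-pixel bilinear
resampling, dense attention). Numerical guards, chosen once:

* ball containment margin ε_ball = 1e−5; every ball-valued result is
  re-projected to norm ≤ (1 − ε_ball)/√c (including exp₀, whose tanh
  saturates to exactly 1.0 in float64 for very large arguments);
* arctanh arguments clamped to 1 − 1e−7;
* divisions by a vector norm are guarded at 1e−15, returning the exact
  limit value (base point / zero) below it;
* the implicit Möbius sum in the head has its squared norm capped at the
  same containment margin, mirroring point re-projection;
* the Riemannian update carries a trust region: the per-offset tangent
  step is capped at 0.1 and offsets are kept at scaled norm ≤ 0.9,
  bounding the conformal factor λ_p (and with it the logit scale λ_p‖a‖)
  at about 10. Without these, a single gradient spike can fling an offset
  onto the ball shell, where the inverse-metric scaling makes every
  subsequent step vanishingly small — the offset is trapped, the logits
  inflate by λ ≈ 10⁴, and training diverges irrecoverably.

**Feature clipping before the lift.** Hyperbolic classifiers are prone to
vanishing gradients: once ‖f‖ is large, z = exp₀(f) saturates onto the ball
shell and the head stops learning, while the cross-entropy keeps pushing
feature norms outward. The standard remedy — capping the Euclidean feature
norm before the exponential map — is applied with `max_feature_norm = 3`
(disable with `None`; inactive at c = 0). The decoder's 1×1 projection is
initialized small (std 0.02) for the same reason: embeddings start in the
gradient-responsive region near the origin and grow only as far as useful.

## Optimization

Euclidean parameters and manifold parameters are optimized separately:
the gyroplane bank always takes Riemannian SGD (Euclidean gradient scaled
by the inverse metric λ_p⁻², applied through the exponential map at the
offset, then re-projected; normals take a tangent-space SGD step), while
the Euclidean side uses SGD with momentum 0.9 by default — the full-scale
recipe — with `optimizer="adam"` as an option. Both follow polynomial
learning-rate decay `lr₀ (1 − t/T)^0.9` (defaults lr₀ = 0.001, batch 2),
with optional linear warmup. A gradient-norm clip covers the Euclidean
parameters (the bank has its own off-by-default clip — the Riemannian
trust region above already bounds its steps, and folding the bank into a
joint clipped norm silently starves its few hundred parameters, since RSGD
— unlike Adam — is not gradient-scale invariant); `head_lr_scale`
multiplies the bank's learning rate. Training aborts on a non-finite
loss, naming the offending batch.

## Synthetic data

The generator emulates the *structure* of IDRiD/DDR-style datasets: a dark
field with a reddish radial-gradient disc plus low-frequency noise, and
four programmatically placed lesion archetypes — EX bright sharp yellowish
blobs, HE dark blobs, MA dots of radius ≤ 3 px, SE large heavily blurred
pale patches. Masks are the pre-blur supports; overlaps are resolved in the
label map by the fixed priority MA > SE > HE > EX (the rarest, smallest
lesion wins a contested pixel), and the standard 8-sample fixture set
guarantees at least one overlap so the rule is exercised. Samples are
bitwise-reproducible from a per-sample stream derived from (global seed,
sample index). Deliberately absent: vessel trees, illumination artefacts,
camera noise, JPEG artefacts, anatomical variation. Tests passing on these
fixtures demonstrate the mechanics and trainability of the implementation,
not clinical performance on real fundus photographs.

## Desk-scale study sizes

The `tiny_config` factory defines the configuration used by the end-to-end
tests and the acceptance script: image 128, patch 16, width 64, depth 4,
2 heads, N = 2, adapter width 64, CFFN hidden 16, embedding n = 16, c = 1,
trained for 300 steps on 8 synthetic images. Its training recipe is the
package's own choice for a from-scratch run at this scale: Adam (lr₀
4e−3, poly 0.9) on the Euclidean side with RSGD ×20 on the bank, batch 4.
Plain SGD at this step budget stalls near the class-prior entropy
(~0.65 nats) because the gradient magnitudes of the conv stem, the
transformer and the head differ by orders of magnitude; Adam's
per-parameter scaling removes that imbalance. The full-size defaults keep
the SGD/RSGD split. The 300-step schedule is aggressive for a
from-scratch run, and not every seed escapes the class-prior plateau
within the budget; the study therefore pins the seed recorded in
`tiny_config`, and that seed is part of the study conditions in the same
way as the image count and step budget. Head-only experiments (wrapped
two-cluster recovery) use 600 points in an 8-dimensional ball, 200 RSGD
steps at lr 0.5.

## Evaluation

Per class, scores are pooled over every annotated pixel of every image in
the split (micro-average) against the binary mask. AUC_ROC integrates the
ROC curve by trapezoid; AUC_PR is computed as average precision
(Σ precision · Δrecall), avoiding the optimistic bias of trapezoidal
interpolation between PR points. A class with no positive pixels in a
split has no defined AUC and is reported as missing, never as 0. A
checkpoint stores weights, both configs and the seed; save → load →
evaluate is bitwise reproducible.

## Known limitations

* The decoder predicts from 1/8-resolution maps; structures of one or two
  pixels (microaneurysms) are ranked well (an ideal 1/8-resolution
  predictor reaches AUC_ROC ≈ 0.98 on the synthetic fixtures) but cannot
  be delineated sharply.
* The ablation baseline ("ViT with transposed convolution") is described
  upstream as both upsampling between blocks and preserving sequence size,
  which is self-contradictory; the package implements it as a
  size-preserving stride-1 transposed-convolution refinement between
  groups plus a stride-2 transposed-convolution decoder.
* No pretraining of any kind; all weights are randomly initialized, so
  headline numbers on real datasets are out of scope.
* Single-device, single-precision-class (float64) CPU execution only.
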